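"""End-to-end experiment pipelines on the synthetic cohort.

These functions wire the package together the way the study does: generate
the cohort, split 80-20 at subject level, triple the training images by
augmentation, split the augmented pool 70-30 into train/validation, train the
CNN with checkpointing, evaluate on the untouched test images, then extract
FC_3 deep features and run the hybrid RF-selection + classical-ML comparison.

Problem sizes default to the package's reduced-scale study conditions:
64x64 images (4-block RANet) with 100 subjects per class, hot-spot effect
size 0.4 and noise sd 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import datapipe, hybrid, quanv, synthgen
from .evalrep import classification_metrics, confusion_matrix, roc_auc
from .ranet import RANetClassifier

__all__ = ["EndToEndResult", "prepare_synthetic_splits", "run_ranet_experiment",
           "run_qnn_experiment"]


@dataclass
class EndToEndResult:
    test_accuracy: float
    report: object
    model: object
    hybrid: dict | None = None
    n_train: int = 0
    n_val: int = 0
    n_test: int = 0


def prepare_synthetic_splits(
    n_subjects_per_class: int = 100,
    image_size: int = 64,
    effect_size: float = 0.4,
    noise_sd: float = 0.05,
    seed: int = 0,
):
    """Generate, split 80-20 (subject level), augment x3, split 70-30.

    Returns dict with train/val/test arrays, integer labels (1 = RA) and the
    subject ids of every partition.
    """
    cfg = synthgen.GeneratorConfig(
        n_subjects_per_class=n_subjects_per_class,
        image_size=image_size,
        effect_size=effect_size,
        noise_sd=noise_sd,
        seed=seed,
    )
    manifest, X = synthgen.generate_arrays(cfg)
    labels = (manifest["label"] == "RA").to_numpy().astype(int)
    subjects = manifest["subject_id"].to_numpy()

    tr_idx, te_idx = datapipe.split_indices(labels, 0.2, groups=subjects, seed=seed)
    X_tr_pool, y_tr_pool, g_tr_pool = X[tr_idx], labels[tr_idx], subjects[tr_idx]
    X_test, y_test, g_test = X[te_idx], labels[te_idx], subjects[te_idx]

    aug_cfg = datapipe.AugmentConfig(seed=seed + 10)
    X_aug, src = datapipe.augment_arrays(X_tr_pool, aug_cfg)
    y_aug, g_aug = y_tr_pool[src], g_tr_pool[src]

    tr2, va2 = datapipe.split_indices(y_aug, 0.3, groups=g_aug, seed=seed + 20)
    return {
        "X_train": X_aug[tr2], "y_train": y_aug[tr2], "g_train": g_aug[tr2],
        "X_val": X_aug[va2], "y_val": y_aug[va2], "g_val": g_aug[va2],
        "X_test": X_test, "y_test": y_test, "g_test": g_test,
        "config": cfg,
    }


def run_ranet_experiment(
    splits: dict,
    n_blocks: int = 4,
    epochs: int = 20,
    seed: int = 0,
    with_hybrid: bool = True,
    hybrid_k: int = 12,
) -> EndToEndResult:
    """Train RANet on prepared splits, evaluate held-out accuracy, and
    optionally run the hybrid deep-feature pipeline on FC_3 activations of
    the augmented pool plus test images (subject-level 70-30 feature split).
    """
    image_size = splits["X_train"].shape[1]
    clf = RANetClassifier(
        input_size=image_size, n_blocks=n_blocks, epochs=epochs, seed=seed
    )
    clf.fit(splits["X_train"], splits["y_train"], splits["X_val"], splits["y_val"])
    pred = clf.predict(splits["X_test"])
    cm = confusion_matrix(splits["y_test"] == 1, pred == 1)
    report = classification_metrics(cm)
    proba = clf.predict_proba(splits["X_test"])[:, list(clf.classes_).index(1)]
    report.auc = roc_auc(splits["y_test"], proba).auc
    result = EndToEndResult(
        test_accuracy=report.accuracy,
        report=report,
        model=clf,
        n_train=len(splits["X_train"]),
        n_val=len(splits["X_val"]),
        n_test=len(splits["X_test"]),
    )
    if with_hybrid:
        X_pool = np.concatenate(
            [splits["X_train"], splits["X_val"], splits["X_test"]]
        )
        y_pool = np.concatenate(
            [splits["y_train"], splits["y_val"], splits["y_test"]]
        )
        g_pool = np.concatenate(
            [splits["g_train"], splits["g_val"], splits["g_test"]]
        )
        feats = clf.extract_features(X_pool, "FC_3")
        result.hybrid = hybrid.run_hybrid_experiment(
            feats, y_pool, k=hybrid_k, split_seed=seed, groups=g_pool
        )
    return result


def run_qnn_experiment(
    splits: dict,
    n_layers: int = 1,
    epochs: int = 30,
    seed: int = 0,
) -> EndToEndResult:
    """Quanvolve all images with one shared seeded random circuit, then train
    the classical QNN head and evaluate held-out accuracy."""
    qt = quanv.QuanvolutionTransformer(n_layers=n_layers, seed=seed).fit()
    F_train = qt.transform(splits["X_train"])
    F_val = qt.transform(splits["X_val"])
    F_test = qt.transform(splits["X_test"])
    clf = quanv.QNNClassifier(epochs=epochs, seed=seed)
    clf.fit(F_train, splits["y_train"], F_val, splits["y_val"])
    pred = clf.predict(F_test)
    cm = confusion_matrix(splits["y_test"] == 1, pred == 1)
    report = classification_metrics(cm)
    report.auc = roc_auc(splits["y_test"], clf.decision_function(F_test)).auc
    return EndToEndResult(
        test_accuracy=report.accuracy,
        report=report,
        model=clf,
        n_train=len(F_train),
        n_val=len(F_val),
        n_test=len(F_test),
    )
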