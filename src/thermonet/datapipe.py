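"""Dataset splitting and augmentation.

Implements the study's split arithmetic — an 80-20 stratified train/test split
of the 600-image cohort (480/120), a three-transform augmentation that maps
each training image to exactly three outputs (480 -> 1440), and a 70-30
train/validation split of the augmented pool (1008/432) — plus the three image
transforms themselves: elastic deformation (uniform displacement field,
Gaussian-smoothed with sd sigma, scaled by alpha), multiplicative brightness,
and central zoom.

Stratified rounding rule: the smaller side gets floor(n_total * fraction)
records in total, apportioned across classes by largest remainder with seeded
tie-breaking, so per-class counts differ from the exact fraction by less than
one.  With ``group_by_subject`` the same rule is applied to subjects within
each class, so all images of a subject land on one side of the split.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.transform import resize

__all__ = [
    "SplitConfig",
    "AugmentConfig",
    "split_train_test",
    "split_train_val",
    "split_indices",
    "elastic_deform",
    "adjust_brightness",
    "scale_zoom",
    "augment_arrays",
    "augment_training_set",
]

AUG_SUFFIXES = ("_el", "_br", "_sc")


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.3
    stratified: bool = True
    group_by_subject: bool = True
    seed: int = 0

    def validate(self) -> None:
        for f in (self.test_fraction, self.val_fraction_of_train):
            if not (0.0 < f < 1.0):
                raise ValueError(f"split fractions must lie in (0, 1), got {f}")


@dataclass(frozen=True)
class AugmentConfig:
    elastic_sigma: float = 2.0
    elastic_alpha: float = 8.0
    brightness_fraction: float = 0.10
    scale_fraction: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.elastic_sigma <= 0:
            raise ValueError("elastic_sigma must be > 0")
        for f in (self.brightness_fraction, self.scale_fraction):
            if not (0.0 <= f < 1.0):
                raise ValueError(f"fractions must lie in [0, 1), got {f}")


def _apportion(sizes: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder apportionment of floor(sum(sizes)*fraction) across
    groups; random (seeded) tie-break among equal remainders."""
    sizes = np.asarray(sizes, dtype=int)
    total_small = int(np.floor(sizes.sum() * fraction + 1e-9))
    exact = sizes * fraction
    base = np.floor(exact + 1e-9).astype(int)
    remainder = exact - base
    deficit = total_small - base.sum()
    order = np.lexsort((rng.permutation(len(sizes)), -remainder))
    take = base.copy()
    for g in order[: max(deficit, 0)]:
        take[g] += 1
    return np.minimum(take, sizes)


def split_indices(
    labels: np.ndarray,
    fraction_small: float,
    groups: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Partition row indices into (large, small) sides.

    ``fraction_small`` is the proportion of the smaller side (test or val).
    Stratified by label; when ``groups`` is given, whole groups (subjects) are
    assigned to one side within each class.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    classes = sorted(pd.unique(labels).tolist())
    small_idx: list[np.ndarray] = []
    if groups is None:
        sizes = np.array([(labels == c).sum() for c in classes])
        per_class = _apportion(sizes, fraction_small, rng)
        for c, k in zip(classes, per_class):
            idx = np.flatnonzero(labels == c)
            small_idx.append(rng.permutation(idx)[:k])
    else:
        groups = np.asarray(groups)
        sizes = np.array(
            [len(pd.unique(groups[labels == c])) for c in classes]
        )
        per_class = _apportion(sizes, fraction_small, rng)
        for c, k in zip(classes, per_class):
            cls_groups = pd.unique(groups[labels == c])
            chosen = set(rng.permutation(cls_groups)[:k].tolist())
            idx = np.flatnonzero(labels == c)
            small_idx.append(idx[[groups[i] in chosen for i in idx]])
    small = np.sort(np.concatenate(small_idx)) if small_idx else np.array([], dtype=int)
    large = np.setdiff1d(np.arange(n), small)
    return large, small


def _split_manifest(
    manifest: pd.DataFrame,
    fraction_small: float,
    tags: tuple[str, str],
    group_by_subject: bool,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if len(manifest) == 0:
        return manifest.copy(), manifest.copy()
    groups = manifest["subject_id"].to_numpy() if group_by_subject else None
    large, small = split_indices(
        manifest["label"].to_numpy(), fraction_small, groups=groups, seed=seed
    )
    big = manifest.iloc[large].assign(split=tags[0]).reset_index(drop=True)
    sml = manifest.iloc[small].assign(split=tags[1]).reset_index(drop=True)
    return big, sml


def split_train_test(
    manifest: pd.DataFrame, config: SplitConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """80-20 stratified split: 600 images -> 480 train / 120 test."""
    config = config or SplitConfig()
    config.validate()
    return _split_manifest(
        manifest,
        config.test_fraction,
        ("train", "test"),
        config.group_by_subject,
        config.seed,
    )


def split_train_val(
    manifest: pd.DataFrame, config: SplitConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """70-30 stratified split of the augmented pool: 1440 -> 1008 / 432."""
    config = config or SplitConfig()
    config.validate()
    return _split_manifest(
        manifest,
        config.val_fraction_of_train,
        ("train", "val"),
        config.group_by_subject,
        config.seed + 1,
    )


# ---------------------------------------------------------------------------
# image transforms
# ---------------------------------------------------------------------------


def _check_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = image[:, :, None]
    if image.ndim != 3:
        raise ValueError("image must be H x W or H x W x C")
    return image


def elastic_deform(
    image: np.ndarray,
    elastic_sigma: float = 2.0,
    elastic_alpha: float = 8.0,
    seed: int = 0,
) -> np.ndarray:
    """Elastic deformation: per-pixel displacements drawn uniform in [-1, 1],
    Gaussian-smoothed with sd ``elastic_sigma``, scaled by ``elastic_alpha``
    pixels; bilinear resampling with edge clamping."""
    if elastic_sigma <= 0:
        raise ValueError("elastic_sigma must be > 0")
    img = _check_image(image)
    squeeze = np.asarray(image).ndim == 2
    h, w, c = img.shape
    rng = np.random.default_rng(seed)
    dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), elastic_sigma) * elastic_alpha
    dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), elastic_sigma) * elastic_alpha
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [rr + dy, cc + dx]
    out = np.empty_like(img)
    for ch in range(c):
        out[:, :, ch] = map_coordinates(
            img[:, :, ch], coords, order=1, mode="nearest"
        )
    out = np.clip(out, 0.0, 1.0)
    return out[:, :, 0] if squeeze else out


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness: pixels * factor, clipped to [0, 1]."""
    if factor <= 0:
        raise ValueError("brightness factor must be > 0")
    return np.clip(np.asarray(image, dtype=np.float64) * factor, 0.0, 1.0)


def scale_zoom(image: np.ndarray, factor: float) -> np.ndarray:
    """Central zoom: factor > 1 crops the centre then resizes back up;
    factor < 1 shrinks and pads with edge values.  Output shape unchanged."""
    if not (0.5 <= factor <= 2.0):
        raise ValueError("zoom factor must lie in [0.5, 2]")
    img = _check_image(image)
    squeeze = np.asarray(image).ndim == 2
    h, w, _ = img.shape
    if factor == 1.0:
        out = img.copy()
    elif factor > 1.0:
        ch, cw = max(int(round(h / factor)), 1), max(int(round(w / factor)), 1)
        r0, c0 = (h - ch) // 2, (w - cw) // 2
        crop = img[r0 : r0 + ch, c0 : c0 + cw]
        out = resize(
            crop, (h, w), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    else:
        nh, nw = max(int(round(h * factor)), 1), max(int(round(w * factor)), 1)
        small = resize(
            img, (nh, nw), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
        r0, c0 = (h - nh) // 2, (w - nw) // 2
        out = np.empty_like(img)
        # edge padding: fill with nearest edge value of the shrunken image
        rows = np.clip(np.arange(h) - r0, 0, nh - 1)
        cols = np.clip(np.arange(w) - c0, 0, nw - 1)
        out[:] = small[np.ix_(rows, cols)]
    out = np.clip(out, 0.0, 1.0)
    return out[:, :, 0] if squeeze else out


# ---------------------------------------------------------------------------
# augmentation of a training set
# ---------------------------------------------------------------------------


def _draw_factors(rng: np.random.Generator, config: AugmentConfig):
    el_seed = int(rng.integers(0, 2**31 - 1))
    br = rng.uniform(1 - config.brightness_fraction, 1 + config.brightness_fraction)
    sc = rng.uniform(1 - config.scale_fraction, 1 + config.scale_fraction)
    return el_seed, br, sc


def augment_arrays(
    X: np.ndarray, config: AugmentConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Each input image yields exactly three outputs (elastic, brightness,
    zoom); originals are not retained.  Returns (X_aug, source_index) where
    ``source_index[j]`` is the row of X that produced output j."""
    config = config or AugmentConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    outs, src = [], []
    for i in range(len(X)):
        el_seed, br, sc = _draw_factors(rng, config)
        outs.append(
            elastic_deform(X[i], config.elastic_sigma, config.elastic_alpha, el_seed)
        )
        outs.append(adjust_brightness(X[i], br))
        outs.append(scale_zoom(X[i], sc))
        src.extend([i, i, i])
    if not outs:
        return np.zeros((0,) + tuple(X.shape[1:])), np.array([], dtype=int)
    return np.stack(outs), np.asarray(src, dtype=int)


def augment_training_set(
    manifest: pd.DataFrame,
    out_dir: str,
    config: AugmentConfig | None = None,
) -> pd.DataFrame:
    """File-based augmentation: reads each manifest image, writes three
    transformed PNGs with suffixes ``_el``, ``_br``, ``_sc``, and returns the
    tripled manifest (labels and metadata inherited)."""
    import os

    from .synthgen import load_png, save_png

    config = config or AugmentConfig()
    config.validate()
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    records = []
    for _, row in manifest.iterrows():
        img = load_png(row["path"])
        el_seed, br, sc = _draw_factors(rng, config)
        variants = (
            elastic_deform(img, config.elastic_sigma, config.elastic_alpha, el_seed),
            adjust_brightness(img, br),
            scale_zoom(img, sc),
        )
        stem = os.path.splitext(os.path.basename(row["path"]))[0]
        for suffix, out in zip(AUG_SUFFIXES, variants):
            path = os.path.join(out_dir, stem + suffix + ".png")
            save_png(out, path)
            rec = row.to_dict()
            rec["path"] = path
            records.append(rec)
    return pd.DataFrame(records, columns=manifest.columns).reset_index(drop=True)
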