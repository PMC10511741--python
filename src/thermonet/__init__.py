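"""thermonet: hand-thermogram classification for rheumatoid arthritis.

A reimplementation-quality package around three classifiers of false-colour
hand thermograms — a compact custom CNN (RANet), a quanvolutional network
(4-qubit statevector quanvolution + small CNN head), and a hybrid pipeline
(deep FC_3 features -> random-forest importance selection -> SVM/kNN/GB) —
exercised end-to-end on a synthetic thermogram generator with a controllable
class effect size.
"""

from . import datapipe, evalrep, hybrid, nn, quanv, ranet, synthgen
from .datapipe import AugmentConfig, SplitConfig, split_train_test, split_train_val
from .evalrep import ConfusionMatrix, classification_metrics, confusion_matrix, roc_auc
from .hybrid import TopKImportanceSelector, rf_feature_importance, select_top_features
from .quanv import QNNClassifier, QuanvolutionTransformer, build_random_circuit
from .ranet import RANetClassifier, build_ranet_spec, count_parameters
from .synthgen import GeneratorConfig, generate_dataset, render_hand_thermogram

__version__ = "0.1.0"
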