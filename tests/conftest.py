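"""Shared fixtures: the published mixture-classification reference results.

The three classifier variants (plain back-propagation, colony-optimized, and
adaptive-colony-optimized) were each evaluated on 20 test samples per
mole-fraction class (seven classes, 140 samples). The misclassification
narratives below are the complete error lists; every other sample was
classified correctly. The expected per-class metrics are the published
values, printed as percentages (recall/precision/accuracy) and on the 0-1
scale (F-score).
"""

import numpy as np
import pytest

MIXTURE_CLASSES = ["0", "10", "20", "30", "40", "50", "60"]

# (actual %, predicted %) -> count of misclassified samples; 20 per class
MISCLASSIFICATIONS = {
    "bpann": {(10, 0): 6, (20, 30): 6, (40, 30): 2, (40, 50): 2, (60, 50): 4},
    "abc": {(10, 0): 4, (20, 30): 4, (40, 30): 2, (40, 50): 2, (60, 50): 2},
    "iaabc": {(10, 0): 2, (20, 30): 2, (40, 30): 2, (60, 50): 2},
}

# published per-class metrics: class -> (recall %, precision %, F-score)
EXPECTED_CLASS_METRICS = {
    "bpann": {
        "0": (100, 76.9, 0.869), "10": (70, 100, 0.824), "20": (70, 100, 0.824),
        "30": (100, 71.4, 0.833), "40": (80, 100, 0.889), "50": (100, 76.9, 0.869),
        "60": (80, 100, 0.889),
    },
    "abc": {
        "0": (100, 83.3, 0.909), "10": (80, 100, 0.889), "20": (80, 100, 0.889),
        "30": (100, 76.9, 0.869), "40": (80, 100, 0.889), "50": (100, 83.3, 0.909),
        "60": (90, 100, 0.947),
    },
    "iaabc": {
        "0": (100, 90.9, 0.952), "10": (90, 100, 0.947), "20": (90, 100, 0.947),
        "30": (100, 83.3, 0.909), "40": (90, 100, 0.947), "50": (100, 90.9, 0.952),
        "60": (90, 100, 0.947),
    },
}

EXPECTED_ACCURACY = {"bpann": 85.7, "abc": 90.0, "iaabc": 94.3}


def label_vectors_from_narrative(model: str, per_class: int = 20):
    """Actual/predicted 1-based code vectors implied by the error narrative."""
    frac_to_code = {int(c): i + 1 for i, c in enumerate(MIXTURE_CLASSES)}
    actual, predicted = [], []
    for frac in (int(c) for c in MIXTURE_CLASSES):
        errors = [(dst, n) for (src, dst), n in
                  MISCLASSIFICATIONS[model].items() if src == frac]
        n_wrong = sum(n for _, n in errors)
        actual.extend([frac_to_code[frac]] * per_class)
        predicted.extend([frac_to_code[frac]] * (per_class - n_wrong))
        for dst, n in errors:
            predicted.extend([frac_to_code[dst]] * n)
    return np.asarray(actual), np.asarray(predicted)


@pytest.fixture
def mixture_reference():
    return {
        "classes": MIXTURE_CLASSES,
        "misclassifications": MISCLASSIFICATIONS,
        "expected_class_metrics": EXPECTED_CLASS_METRICS,
        "expected_accuracy": EXPECTED_ACCURACY,
        "label_vectors": label_vectors_from_narrative,
    }
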