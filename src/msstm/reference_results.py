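"""Published cross-subject benchmark accuracies on the OVPD-II dataset.

Per-subject recognition accuracies (%) under video stimulation, after
style-transfer-mapping adaptation, for three feature families (source
microstate, differential entropy, power spectral density) and two
classifiers (linear SVM, single-layer CNN).  The raw dataset is not
public; these printed per-subject columns are the reference input for the
summary arithmetic (column means and sample standard deviations).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

SUBJECTS = [
    "CL", "CSY", "HH", "LHY", "LWX", "RJ", "SX",
    "WCQ", "WJQ", "XD", "XJ", "XMX", "YXK",
]

#: columns: (classifier, feature kind) -> per-subject accuracy (%)
ACCURACIES = {
    ("svm", "microstate"): [93.44, 84.22, 82.15, 87.25, 89.90, 89.65, 88.33,
                            92.36, 62.53, 85.08, 83.43, 89.82, 75.60],
    ("svm", "de"): [88.76, 81.65, 83.78, 82.69, 80.05, 93.08, 83.48,
                    84.86, 73.49, 86.47, 76.71, 85.86, 86.23],
    ("svm", "psd"): [85.07, 60.65, 78.96, 81.34, 88.81, 81.34, 91.79,
                     81.25, 60.30, 84.78, 63.48, 86.49, 65.94],
    ("cnn", "microstate"): [98.83, 88.68, 77.18, 53.85, 99.39, 63.94, 98.26,
                            92.47, 97.18, 91.94, 87.59, 97.922, 76.48],
    ("cnn", "de"): [92.96, 83.31, 86.57, 88.69, 88.45, 81.925, 82.96,
                    84.32, 84.37, 59.58, 85.185, 83.59, 86.71],
    ("cnn", "psd"): [94.37, 72.50, 83.80, 83.80, 86.62, 83.10, 92.25,
                     87.04, 88.73, 38.06, 63.889, 62.47, 94.37],
}


def reference_table() -> pd.DataFrame:
    """Per-subject accuracies as a tidy DataFrame (one column per condition)."""
    cols = {f"{clf}_{kind}": vals for (clf, kind), vals in ACCURACIES.items()}
    return pd.DataFrame(cols, index=pd.Index(SUBJECTS, name="participant"))


def column(classifier: str, kind: str) -> np.ndarray:
    return np.asarray(ACCURACIES[(classifier, kind)], dtype=float)
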