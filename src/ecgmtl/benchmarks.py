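"""Published per-class benchmark results for the multi-task CoT architecture.

These are the reported evaluation tables of the reference study on the
CPSC2018 and PTB-XL test sets (full model, random-auxiliary-task control,
and the two ablations).  They are inputs for validating the package's
metric arithmetic — the macro averages and the F1 cells must be exactly
reproducible from the per-class entries via :mod:`ecgmtl.metrics` — and for
comparing desk-scale synthetic runs against the published aggregate level.
Column order: AUC, Accuracy, Precision, Recall, F1.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "PTBXL_FULL", "CPSC_FULL", "CPSC_RANDOM_AUX", "PTBXL_RANDOM_AUX",
    "PTBXL_NO_COT", "CPSC_NO_COT", "PTBXL_NO_BIGRU", "CPSC_NO_BIGRU",
    "as_frame",
]

_COLS = ("auc", "accuracy", "precision", "recall", "f1")

# Full model, PTB-XL (5 superclasses); reported AVG row: F1 0.833, AUC 0.925.
PTBXL_FULL = {
    "NORM": (0.924, 0.905, 0.877, 0.849, 0.863),
    "MI":   (0.898, 0.912, 0.814, 0.734, 0.772),
    "STTC": (0.926, 0.869, 0.834, 0.813, 0.823),
    "CD":   (0.946, 0.868, 0.867, 0.872, 0.869),
    "HYP":  (0.933, 0.883, 0.852, 0.819, 0.835),
}

# Full model, CPSC2018 (9 classes); reported AVG row: F1 0.827, AUC 0.977.
CPSC_FULL = {
    "SNR":  (0.973, 0.948, 0.824, 0.824, 0.824),
    "AF":   (0.981, 0.962, 0.885, 0.968, 0.925),
    "IAVB": (0.981, 0.977, 0.923, 0.845, 0.882),
    "LBBB": (0.999, 0.996, 0.957, 0.917, 0.937),
    "RBBB": (0.994, 0.965, 0.944, 0.934, 0.939),
    "PAC":  (0.961, 0.951, 0.712, 0.758, 0.734),
    "PVC":  (0.962, 0.959, 0.885, 0.676, 0.767),
    "STD":  (0.984, 0.962, 0.868, 0.805, 0.835),
    "STE":  (0.960, 0.977, 0.667, 0.545, 0.600),
}

# Random-auxiliary-task control; reported AVG F1: 0.807 (CPSC), 0.818 (PTB-XL).
CPSC_RANDOM_AUX = {
    "SNR":  (0.974, 0.952, 0.848, 0.824, 0.836),
    "AF":   (0.980, 0.965, 0.866, 0.915, 0.890),
    "IAVB": (0.983, 0.975, 0.897, 0.859, 0.878),
    "LBBB": (0.999, 0.996, 0.957, 0.917, 0.937),
    "RBBB": (0.993, 0.969, 0.936, 0.960, 0.948),
    "PAC":  (0.952, 0.948, 0.671, 0.823, 0.739),
    "PVC":  (0.969, 0.962, 0.809, 0.765, 0.786),
    "STD":  (0.980, 0.956, 0.777, 0.890, 0.830),
    "STE":  (0.956, 0.968, 0.500, 0.318, 0.389),
}
PTBXL_RANDOM_AUX = {
    "NORM": (0.917, 0.889, 0.845, 0.839, 0.842),
    "MI":   (0.883, 0.907, 0.807, 0.699, 0.749),
    "STTC": (0.923, 0.863, 0.840, 0.781, 0.809),
    "CD":   (0.935, 0.859, 0.861, 0.865, 0.863),
    "HYP":  (0.925, 0.879, 0.851, 0.806, 0.828),
}

# Ablation: CoT block removed; reported AVG F1: 0.819 (PTB-XL), 0.761 (CPSC).
PTBXL_NO_COT = {
    "NORM": (0.908, 0.893, 0.870, 0.815, 0.842),
    "MI":   (0.881, 0.904, 0.782, 0.735, 0.758),
    "STTC": (0.917, 0.865, 0.824, 0.816, 0.820),
    "CD":   (0.935, 0.859, 0.858, 0.861, 0.859),
    "HYP":  (0.911, 0.869, 0.827, 0.808, 0.817),
}
CPSC_NO_COT = {
    "SNR":  (0.973, 0.946, 0.835, 0.794, 0.814),
    "AF":   (0.979, 0.958, 0.860, 0.868, 0.864),
    "IAVB": (0.979, 0.971, 0.905, 0.803, 0.851),
    "LBBB": (0.998, 0.988, 0.750, 0.900, 0.818),
    "RBBB": (0.992, 0.964, 0.918, 0.960, 0.939),
    "PAC":  (0.956, 0.948, 0.741, 0.645, 0.690),
    "PVC":  (0.960, 0.961, 0.918, 0.662, 0.769),
    "STD":  (0.983, 0.951, 0.809, 0.878, 0.842),
    "STE":  (0.941, 0.957, 0.444, 0.182, 0.258),
}

# Ablation: Bi-GRU removed; reported AVG F1: 0.820 (PTB-XL), 0.807 (CPSC).
PTBXL_NO_BIGRU = {
    "NORM": (0.904, 0.892, 0.855, 0.832, 0.843),
    "MI":   (0.877, 0.899, 0.766, 0.749, 0.757),
    "STTC": (0.914, 0.869, 0.835, 0.810, 0.822),
    "CD":   (0.931, 0.861, 0.859, 0.860, 0.859),
    "HYP":  (0.911, 0.874, 0.850, 0.789, 0.818),
}
CPSC_NO_BIGRU = {
    "SNR":  (0.964, 0.939, 0.768, 0.843, 0.804),
    "AF":   (0.989, 0.965, 0.918, 0.849, 0.882),
    "IAVB": (0.982, 0.975, 0.922, 0.831, 0.874),
    "LBBB": (0.998, 0.988, 0.750, 0.900, 0.818),
    "RBBB": (0.991, 0.955, 0.935, 0.944, 0.939),
    "PAC":  (0.963, 0.948, 0.716, 0.774, 0.744),
    "PVC":  (0.952, 0.952, 0.893, 0.735, 0.806),
    "STD":  (0.982, 0.965, 0.890, 0.793, 0.839),
    "STE":  (0.961, 0.964, 0.571, 0.545, 0.558),
}


def as_frame(table: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    """Benchmark table as a DataFrame with the standard report columns."""
    return pd.DataFrame.from_dict(
        table, orient="index",
        columns=["AUC", "Accuracy", "Precision", "Recall", "F1"])
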