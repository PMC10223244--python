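"""Literature-reported figures for the original anxiolytic consensus model.

This package re-implements a published consensus ensemble multitarget
neural-network model of anxiolytic activity.  The original study's printed
accuracy table (21 selected networks, per-ensemble means and consensus rows)
and neuron-sensitivity table (17 sites x 7 high-level networks) are kept
here as fixtures: the aggregation, significance-counting and consensus
routines of this package must reproduce the printed summary rows and the
printed significance counts exactly when fed the printed per-network values.

Values are stored exactly as printed (one decimal, percentages).
"""

from __future__ import annotations

import numpy as np

# --- study protocol constants -------------------------------------------------

N_COMPOUNDS = 216
N_SITES = 17
DOCKING_REPEATS = 5  # docking runs per (compound, site)
POSES_PER_RUN = 10  # most favorable conformations kept per run
CONFORMERS_PER_COMPOUND = 10  # conformer models built per compound

#: Activity-grade composition of the verified 216-compound set:
#: high, moderate, low, active (level unstated), inactive.
CLASS_COUNTS = {"high": 30, "moderate": 64, "low": 67, "active": 34, "inactive": 21}

# --- accuracy table of the 21 selected networks ------------------------------
# per level: rows (network id, architecture, train, test, val, F0, Fa, Fn, ROC)

ACCURACY_ROWS: dict[str, list[tuple]] = {
    "h": [
        (634, "MLP 17-16-2 Tanh Softmax", 100.0, 74.2, 90.0, 94.9, 90.0, 95.7, 91.5),
        (39, "MLP 17-16-2 Tanh Softmax", 100.0, 96.7, 71.0, 95.4, 86.7, 96.8, 90.7),
        (417, "MLP 17-16-2 Tanh Softmax", 99.4, 74.2, 80.6, 93.1, 83.3, 94.6, 89.1),
        (250, "MLP 17-16-2 Tanh Softmax", 100.0, 87.1, 80.6, 95.4, 83.3, 97.3, 87.9),
        (467, "MLP 17-11-2 Tanh Softmax", 99.4, 74.2, 90.3, 94.4, 80.0, 96.8, 84.8),
        (427, "MLP 17-16-2 Tanh Softmax", 100.0, 80.6, 77.4, 94.0, 80.0, 96.2, 83.8),
        (215, "MLP 17-12-2 Tanh Softmax", 100.0, 77.4, 80.6, 94.0, 90.0, 94.6, 92.5),
    ],
    "hm": [
        (219, "MLP 17-14-2 Tanh Softmax", 94.8, 83.9, 73.3, 90.3, 91.5, 89.3, 91.7),
        (119, "MLP 17-12-2 Exponential Softmax", 99.4, 86.7, 61.3, 92.1, 90.4, 93.4, 92.5),
        (390, "MLP 17-15-2 Logistic Softmax", 98.7, 80.6, 51.6, 89.4, 88.3, 90.2, 91.1),
        (8, "MLP 17-15-2 Exponential Softmax", 98.7, 90.3, 64.5, 92.6, 91.5, 93.4, 93.1),
        (587, "MLP 17-16-2 Tanh Softmax", 100.0, 77.4, 67.7, 92.1, 89.4, 94.3, 92.3),
        (259, "MLP 17-11-2 Tanh Softmax", 98.1, 77.4, 67.7, 90.7, 94.7, 87.7, 93.0),
        (49, "MLP 17-17-2 Tanh Softmax", 96.8, 90.3, 71.0, 92.1, 90.4, 93.4, 92.3),
    ],
    "a": [
        (67, "MLP 17-15-2 Logistic Softmax", 99.4, 93.5, 83.3, 96.3, 97.9, 81.0, 93.6),
        (497, "MLP 17-7-2 Tanh Softmax", 99.4, 80.0, 90.3, 95.4, 95.9, 90.5, 95.6),
        (44, "MLP 17-6-2 Tanh Softmax", 97.4, 100.0, 87.1, 96.3, 96.9, 90.5, 96.4),
        (222, "MLP 17-7-2 Tanh Softmax", 99.4, 93.5, 87.1, 96.8, 98.5, 81.0, 97.0),
        (47, "MLP 17-12-2 Logistic Softmax", 100.0, 100.0, 90.3, 98.6, 99.0, 95.2, 95.8),
        (206, "MLP 17-11-2 Tanh Softmax", 100.0, 77.4, 90.3, 95.4, 96.9, 81.0, 89.2),
        (222, "MLP 17-7-2 Tanh Softmax", 96.8, 93.5, 87.1, 94.9, 95.4, 90.5, 94.6),
    ],
}

#: Printed per-ensemble mean rows: (train, test, val, F0, Fa, Fn, ROC).
MEAN_ROWS = {
    "h": (99.8, 80.6, 81.5, 94.5, 84.8, 96.0, 88.6),
    "hm": (98.1, 83.8, 65.3, 91.3, 90.9, 91.7, 92.3),
    "a": (98.9, 91.1, 87.9, 96.2, 97.2, 87.1, 94.6),
}

#: Printed per-ensemble consensus rows: (F0, Fa, Fn, ROC).
CONSENSUS_ROWS = {
    "h": (100.0, 100.0, 100.0, 100.0),
    "hm": (97.2, 96.8, 97.5, 97.2),
    "a": (99.1, 99.0, 100.0, 99.5),
}

#: Printed grand-mean rows.
GENERAL_MEAN = (98.9, 85.2, 78.2, 94.0, 91.0, 91.6, 91.8)
GENERAL_MEAN_CONSENSUS = (98.8, 98.6, 99.2, 98.9)

# --- neuron-sensitivity table (high-activity ensemble) -----------------------
# site -> (seven normalized sensitivities %, printed significance count)

SENSITIVITY_NETWORK_IDS = (634, 39, 417, 250, 467, 427, 215)

SENSITIVITY_TABLE: dict[str, tuple[tuple[float, ...], int]] = {
    "ADRA1A": ((5.7, 3.3, 3.4, 4.6, 6.8, 3.7, 5.8), 1),
    "ADRA1B": ((6.4, 8.8, 6.9, 7.0, 4.0, 7.7, 8.0), 6),
    "ADRA2A": ((7.6, 12.4, 11.0, 6.0, 6.7, 7.5, 4.1), 5),
    "ADRA2B": ((3.0, 3.7, 4.3, 4.5, 11.6, 4.3, 6.0), 1),
    "AGTR1": ((6.7, 6.5, 7.6, 6.1, 4.8, 7.7, 11.2), 6),
    "GABA-A-GABA": ((4.3, 3.1, 4.2, 6.1, 4.2, 3.8, 3.0), 1),
    "GABA-A-Benz": ((6.1, 5.5, 3.3, 4.2, 5.0, 6.7, 7.0), 3),
    "HTR1A": ((6.0, 4.1, 3.6, 5.5, 3.9, 4.3, 2.6), 0),
    "HTR2A-Spec": ((4.7, 4.7, 5.2, 5.8, 8.1, 5.6, 7.0), 2),
    "HTR2A-Allo": ((6.5, 14.6, 12.3, 4.2, 5.9, 2.6, 6.4), 4),
    "HTR4": ((10.9, 6.8, 2.0, 6.1, 5.4, 5.0, 5.6), 3),
    "HTR7": ((3.7, 4.1, 5.8, 8.0, 10.7, 6.8, 6.6), 4),
    "MTNR1A": ((4.4, 3.4, 3.0, 4.5, 4.0, 4.0, 4.2), 0),
    "MTNR1B": ((4.8, 5.0, 4.4, 10.5, 4.7, 3.6, 3.2), 1),
    "NMDA-Glut": ((12.1, 5.7, 15.8, 7.3, 3.2, 12.6, 11.6), 5),
    "NMDA-Ca": ((3.5, 5.0, 4.0, 5.3, 6.4, 10.9, 3.7), 2),
    "SLC18A2": ((3.4, 3.4, 3.3, 4.1, 4.5, 3.1, 4.0), 0),
}

#: Reported consensus-significant targets (significant in >= 5 of 7 networks).
KEY_TARGETS = ("ADRA1B", "ADRA2A", "AGTR1", "NMDA-Glut")


def sensitivity_matrix() -> tuple[list[str], np.ndarray, np.ndarray]:
    """(site ids, 17 x 7 value matrix, printed significance counts)."""
    sites = list(SENSITIVITY_TABLE)
    values = np.array([SENSITIVITY_TABLE[s][0] for s in sites])
    sign = np.array([SENSITIVITY_TABLE[s][1] for s in sites])
    return sites, values, sign
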