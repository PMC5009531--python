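"""Per-residue feature assembly and the 510-value sliding-window encoding.

Each residue is represented by 34 values:

====== ===== ==========================================================
group  width meaning
====== ===== ==========================================================
PSSM     20  logistically scaled PSI-BLAST log-odds, 1/(1+exp(-x))
SCRS      3  context-based state-preference scores (R, I, F)
SS        3  predicted secondary-structure probabilities (H, E, C)
SA        2  predicted solvent-accessibility probabilities (exposed, buried)
AAP       5  amino-acid properties, min-max normalized over the 20 types
term      1  1 when the window position overlaps a chain terminus
====== ===== ==========================================================

A classifier input is the concatenation of these features over a sliding
window of 15 residues centered on the residue being predicted: 15 x 34 =
510 values.  Window positions past either terminus are encoded as padding
(33 zeros and terminal flag 1).  All encoded values lie in [0, 1].
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit

from .chains import PSSM_ALPHABET

N_FEATURES = 34
WINDOW = 15

# Five physicochemical properties per amino acid: steric parameter (graph
# shape index), polarizability, volume, hydrophobicity, isoelectric point.
_AAP_RAW = {
    #     steric  polar  volume  hydro   pI
    "A": (1.28, 0.05, 1.00, 0.31, 6.11),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60),
    "W": (3.21, 0.41, 8.08, 2.25, 5.94),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02),
}


def aa_property_table() -> np.ndarray:
    """(21, 5) property table, min-max normalized per column to [0, 1].

    Rows follow PSSM column order; row 20 is the 'X' (unknown) residue,
    filled with the column means of the normalized table.
    """
    raw = np.array([_AAP_RAW[a] for a in PSSM_ALPHABET], dtype=float)
    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    norm = (raw - lo) / (hi - lo)
    return np.vstack([norm, norm.mean(axis=0)])


AAP_TABLE = aa_property_table()

# column layout of the 34-value residue feature vector
PSSM_SLICE = slice(0, 20)
SCRS_SLICE = slice(20, 23)
SS_SLICE = slice(23, 26)
SA_SLICE = slice(26, 28)
AAP_SLICE = slice(28, 33)
TERMINAL_COL = 33

FEATURE_GROUPS = {
    "pssm": list(range(0, 20)),
    "scrs": list(range(20, 23)),
    "ss": list(range(23, 26)),
    "sa": list(range(26, 28)),
    "aap": list(range(28, 33)),
    "terminal": [TERMINAL_COL],
}


def scale_pssm(log_odds: np.ndarray) -> np.ndarray:
    """Squash PSSM log-odds into (0, 1) with the logistic function."""
    return expit(np.asarray(log_odds, dtype=float))


def residue_features(
    aa: str | None = None,
    pssm_row: np.ndarray | None = None,
    scrs: np.ndarray | None = None,
    ss_probs: np.ndarray | None = None,
    sa_probs: np.ndarray | None = None,
    is_padding: bool = False,
) -> np.ndarray:
    """Assemble the 34-value feature vector for one residue (or padding)."""
    v = np.zeros(N_FEATURES)
    if is_padding:
        v[TERMINAL_COL] = 1.0
        return v
    pssm_row = np.asarray(pssm_row, dtype=float)
    scrs = np.asarray(scrs, dtype=float)
    ss_probs = np.asarray(ss_probs, dtype=float)
    sa_probs = np.asarray(sa_probs, dtype=float)
    for name, arr, n in (
        ("pssm", pssm_row, 20),
        ("scrs", scrs, 3),
        ("ss", ss_probs, 3),
        ("sa", sa_probs, 2),
    ):
        if arr.shape != (n,):
            raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    from .chains import AA_INDEX

    if aa not in AA_INDEX:
        raise ValueError(f"unknown amino acid {aa!r}")
    v[PSSM_SLICE] = scale_pssm(pssm_row)
    v[SCRS_SLICE] = scrs
    v[SS_SLICE] = ss_probs
    v[SA_SLICE] = sa_probs
    v[AAP_SLICE] = AAP_TABLE[AA_INDEX[aa] if AA_INDEX[aa] >= 0 else 20]
    return v


def chain_feature_matrix(
    sequence: str,
    pssm_rows: np.ndarray,
    scrs: np.ndarray,
    ss_probs: np.ndarray,
    sa_probs: np.ndarray,
) -> np.ndarray:
    """Stack residue_features over a chain, shape (L, 34)."""
    L = len(sequence)
    for name, arr, ncol in (
        ("pssm_rows", pssm_rows, 20),
        ("scrs", scrs, 3),
        ("ss_probs", ss_probs, 3),
        ("sa_probs", sa_probs, 2),
    ):
        arr = np.asarray(arr)
        if arr.shape != (L, ncol):
            raise ValueError(f"{name} must have shape ({L}, {ncol}), got {arr.shape}")
    from .chains import aa_indices

    idx = aa_indices(sequence)
    feats = np.zeros((L, N_FEATURES))
    feats[:, PSSM_SLICE] = scale_pssm(pssm_rows)
    feats[:, SCRS_SLICE] = scrs
    feats[:, SS_SLICE] = ss_probs
    feats[:, SA_SLICE] = sa_probs
    feats[:, AAP_SLICE] = AAP_TABLE[np.where(idx >= 0, idx, 20)]
    return feats


def encode_window(
    features: np.ndarray, center: int, window: int = WINDOW
) -> np.ndarray:
    """Window encoding for the residue at 1-based position ``center``.

    Concatenates the per-residue feature vectors at offsets
    -(window//2) .. +(window//2); out-of-range slots become padding
    (zeros with terminal flag 1).  Length is window * 34 = 510 by default.
    """
    L = features.shape[0]
    if not 1 <= center <= L:
        raise IndexError(f"center {center} out of range for chain of length {L}")
    half = window // 2
    pad = residue_features(is_padding=True)
    slots = []
    for k in range(-half, half + 1):
        p = center - 1 + k
        slots.append(features[p] if 0 <= p < L else pad)
    return np.concatenate(slots)


def encode_chain_windows(
    features: np.ndarray,
    window: int = WINDOW,
    groups: Sequence[str] | None = None,
) -> np.ndarray:
    """All window encodings of a chain at once, shape (L, window * width).

    ``groups`` selects a subset of feature groups (e.g. ["pssm",
    "terminal"] for a PSSM-only encoding); the terminal flag is always
    worth including so the network can see chain ends.  Default is the
    full 34-column layout, giving 510 values per window.
    """
    L = features.shape[0]
    half = window // 2
    pad = residue_features(is_padding=True)
    padded = np.vstack([np.tile(pad, (half, 1)), features, np.tile(pad, (half, 1))])
    if groups is not None:
        cols = [c for g in groups for c in FEATURE_GROUPS[g]]
        padded = padded[:, cols]
    width = padded.shape[1]
    out = np.empty((L, window * width))
    for j in range(window):
        out[:, j * width : (j + 1) * width] = padded[j : j + L]
    return out
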