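"""Context-based mean-force pseudo-potentials over a 7-residue window.

From a labeled corpus we count, for every residue i with flexibility state
C, the singlet (R_i), doublet (R_i, R_{i+k}) and triplet
(R_i, R_{i+k1}, R_{i+k2}) occurrences with offsets k, k1, k2 in
{-3..3}\\{0} (k1 < k2; contexts running past a chain end are skipped).
Counts are converted to inverse-Boltzmann potentials

    U(C, x) = -ln( f_hat(C | x) / f(C) )

where f(C) is the corpus-wide state frequency and f_hat is the observed
conditional frequency shrunk toward f(C) with a pseudo-observation mass w:

    f_hat(C | x) = (m * f_obs(C | x) + w * f(C)) / (m + w),   m = sum_C N(C, x).

Never-observed contexts (m = 0) therefore sit exactly at U = 0, and the
triplet tables (3 x 15 x 20^3 cells) stay finite despite their sparsity.
The combined pseudo-potential of residue i in state C sums its singlet
term, the 6 doublet terms and the 15 triplet terms that are in range
(22 terms for an interior residue).  The three state-preference scores
(SCRS) presented to the classifier are softmax(-U) over the states, a
point on the 3-simplex.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .chains import PSSM_ALPHABET, STATES3, LabeledChain, aa_indices

N_AA = 20
N_STATES = 3


def window_offsets(window_half: int) -> tuple[int, ...]:
    """Non-zero offsets of the context window, e.g. (-3,-2,-1,1,2,3)."""
    return tuple(k for k in range(-window_half, window_half + 1) if k != 0)


def offset_pairs(window_half: int) -> tuple[tuple[int, int], ...]:
    """Ordered offset pairs (k1 < k2) of the context window; 15 for half=3."""
    return tuple(itertools.combinations(window_offsets(window_half), 2))


class EmptyCorpusError(ValueError):
    pass


class MissingStateError(ValueError):
    """A flexibility state never occurs in the corpus."""


@dataclass
class ContextCounts:
    """Raw singlet/doublet/triplet occurrence counts from a labeled corpus."""

    window_half: int
    singlet: np.ndarray  # (3, 20)
    doublet: np.ndarray  # (3, n_offsets, 20, 20)
    triplet: np.ndarray  # (3, n_pairs, 20, 20, 20)
    state_totals: np.ndarray  # (3,)
    grand_total: int

    @property
    def offsets(self) -> tuple[int, ...]:
        return window_offsets(self.window_half)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return offset_pairs(self.window_half)


def count_contexts(
    corpus: Sequence[LabeledChain], window_half: int = 3
) -> ContextCounts:
    """Tally singlet/doublet/triplet context statistics over a corpus.

    Every residue must carry a defined state; 'X' residues contribute no
    counts, neither as center nor as neighbor.  Contexts extending past a
    chain end are skipped (no padding, no wraparound).
    """
    offsets = window_offsets(window_half)
    pairs = offset_pairs(window_half)
    singlet = np.zeros((N_STATES, N_AA), dtype=np.int64)
    doublet = np.zeros((N_STATES, len(offsets), N_AA, N_AA), dtype=np.int64)
    triplet = np.zeros((N_STATES, len(pairs), N_AA, N_AA, N_AA), dtype=np.int64)
    pair_index = {p: j for j, p in enumerate(pairs)}

    for chain in corpus:
        if any(s is None for s in chain.states):
            raise ValueError(
                f"chain {chain.chain_id} has undetermined states; filter the "
                "corpus before counting"
            )
        L = len(chain)
        idx = aa_indices(chain.sequence)
        st = np.array([STATES3.index(s) for s in chain.states], dtype=np.int64)
        valid_center = idx >= 0
        centers = np.nonzero(valid_center)[0]
        np.add.at(singlet, (st[centers], idx[centers]), 1)
        for j, k in enumerate(offsets):
            pos = centers[(centers + k >= 0) & (centers + k < L)]
            pos = pos[idx[pos + k] >= 0]
            np.add.at(doublet, (st[pos], j, idx[pos], idx[pos + k]), 1)
        for (k1, k2), j in pair_index.items():
            pos = centers[
                (centers + k1 >= 0)
                & (centers + k1 < L)
                & (centers + k2 >= 0)
                & (centers + k2 < L)
            ]
            pos = pos[(idx[pos + k1] >= 0) & (idx[pos + k2] >= 0)]
            np.add.at(triplet, (st[pos], j, idx[pos], idx[pos + k1], idx[pos + k2]), 1)

    state_totals = singlet.sum(axis=1)
    return ContextCounts(
        window_half=window_half,
        singlet=singlet,
        doublet=doublet,
        triplet=triplet,
        state_totals=state_totals,
        grand_total=int(state_totals.sum()),
    )


@dataclass
class PotentialTable:
    """Smoothed mean-force potentials per state for every context cell."""

    window_half: int
    blend_weight: float
    priors: np.ndarray  # (3,) state frequencies f(C)
    u_singlet: np.ndarray  # (3, 20)
    u_doublet: np.ndarray  # (3, n_offsets, 20, 20)
    u_triplet: np.ndarray  # (3, n_pairs, 20, 20, 20)

    @property
    def offsets(self) -> tuple[int, ...]:
        return window_offsets(self.window_half)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return offset_pairs(self.window_half)

    # -- serialization ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize as JSON, omitting zero cells (implicit U = 0)."""

        def sparse(arr: np.ndarray, keyfn) -> dict:
            out: dict[str, float] = {}
            for index in zip(*np.nonzero(arr)):
                out[keyfn(index)] = float(arr[index])
            return out

        A = PSSM_ALPHABET
        doc = {
            "format": "flexc-potential-table",
            "version": 1,
            "window_half": self.window_half,
            "blend_weight": self.blend_weight,
            "priors": {s: float(self.priors[c]) for c, s in enumerate(STATES3)},
            "singlet": sparse(
                self.u_singlet, lambda ix: f"{STATES3[ix[0]]}|{A[ix[1]]}"
            ),
            "doublet": sparse(
                self.u_doublet,
                lambda ix: f"{STATES3[ix[0]]}|{self.offsets[ix[1]]}|{A[ix[2]]}{A[ix[3]]}",
            ),
            "triplet": sparse(
                self.u_triplet,
                lambda ix: (
                    f"{STATES3[ix[0]]}|{self.pairs[ix[1]][0]},{self.pairs[ix[1]][1]}|"
                    f"{A[ix[2]]}{A[ix[3]]}{A[ix[4]]}"
                ),
            ),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str | Path) -> "PotentialTable":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "flexc-potential-table":
            raise ValueError(f"{path}: not a potential-table document")
        h = int(doc["window_half"])
        offsets = window_offsets(h)
        pairs = offset_pairs(h)
        off_index = {k: j for j, k in enumerate(offsets)}
        pair_index = {p: j for j, p in enumerate(pairs)}
        aa = {a: i for i, a in enumerate(PSSM_ALPHABET)}
        st = {s: c for c, s in enumerate(STATES3)}

        u1 = np.zeros((N_STATES, N_AA))
        for key, val in doc["singlet"].items():
            s, a = key.split("|")
            u1[st[s], aa[a]] = val
        u2 = np.zeros((N_STATES, len(offsets), N_AA, N_AA))
        for key, val in doc["doublet"].items():
            s, k, ab = key.split("|")
            u2[st[s], off_index[int(k)], aa[ab[0]], aa[ab[1]]] = val
        u3 = np.zeros((N_STATES, len(pairs), N_AA, N_AA, N_AA))
        for key, val in doc["triplet"].items():
            s, ks, abc = key.split("|")
            k1, k2 = (int(x) for x in ks.split(","))
            u3[st[s], pair_index[(k1, k2)], aa[abc[0]], aa[abc[1]], aa[abc[2]]] = val
        priors = np.array([doc["priors"][s] for s in STATES3])
        return cls(
            window_half=h,
            blend_weight=float(doc["blend_weight"]),
            priors=priors,
            u_singlet=u1,
            u_doublet=u2,
            u_triplet=u3,
        )


def _smooth_potential(
    counts: np.ndarray, priors: np.ndarray, w: float
) -> np.ndarray:
    """Inverse-Boltzmann potential with additive-prior smoothing.

    counts has the state axis first; cells with zero total count come out
    exactly 0 because the smoothed frequency collapses to the prior.
    """
    counts = counts.astype(float)
    m = counts.sum(axis=0, keepdims=True)
    prior_shape = (N_STATES,) + (1,) * (counts.ndim - 1)
    f_prior = priors.reshape(prior_shape)
    f_hat = (counts + w * f_prior) / (m + w)
    return -np.log(f_hat / f_prior)


def derive_potentials(counts: ContextCounts, blend_weight: float = 10.0) -> PotentialTable:
    """Turn context counts into a smoothed mean-force potential table."""
    if counts.grand_total == 0:
        raise EmptyCorpusError("cannot derive potentials from an empty corpus")
    if blend_weight <= 0:
        raise ValueError("blend_weight must be > 0 for finite potentials")
    if (counts.state_totals == 0).any():
        missing = [s for c, s in enumerate(STATES3) if counts.state_totals[c] == 0]
        raise MissingStateError(f"state(s) never observed in corpus: {missing}")
    priors = counts.state_totals / counts.grand_total
    return PotentialTable(
        window_half=counts.window_half,
        blend_weight=blend_weight,
        priors=priors,
        u_singlet=_smooth_potential(counts.singlet, priors, blend_weight),
        u_doublet=_smooth_potential(counts.doublet, priors, blend_weight),
        u_triplet=_smooth_potential(counts.triplet, priors, blend_weight),
    )


def combined_pseudo_potential(
    table: PotentialTable, sequence: str, i: int, state: str
) -> float:
    """Total pseudo-potential of residue i (1-based) in the given state.

    Sums the singlet term, all in-range doublet terms and all in-range
    triplet terms; 1 + 6 + 15 = 22 terms for an interior residue of a
    chain of length >= 7.  Terms involving an 'X' residue contribute 0.
    """
    L = len(sequence)
    if not 1 <= i <= L:
        raise IndexError(f"position {i} out of range for chain of length {L}")
    c = STATES3.index(state)
    idx = aa_indices(sequence)
    p = i - 1
    if idx[p] < 0:
        return 0.0
    total = float(table.u_singlet[c, idx[p]])
    for j, k in enumerate(table.offsets):
        q = p + k
        if 0 <= q < L and idx[q] >= 0:
            total += float(table.u_doublet[c, j, idx[p], idx[q]])
    for j, (k1, k2) in enumerate(table.pairs):
        q1, q2 = p + k1, p + k2
        if 0 <= q1 < L and 0 <= q2 < L and idx[q1] >= 0 and idx[q2] >= 0:
            total += float(table.u_triplet[c, j, idx[p], idx[q1], idx[q2]])
    return total


def scrs_scores(table: PotentialTable, sequence: str, i: int) -> np.ndarray:
    """State-preference scores of residue i: softmax(-U) over (R, I, F)."""
    u = np.array(
        [combined_pseudo_potential(table, sequence, i, s) for s in STATES3]
    )
    z = np.exp(-(u - u.min()))
    return z / z.sum()


def chain_scrs(table: PotentialTable, sequence: str) -> np.ndarray:
    """SCRS scores for every residue of a chain, shape (L, 3)."""
    return np.vstack([scrs_scores(table, sequence, i + 1) for i in range(len(sequence))])
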