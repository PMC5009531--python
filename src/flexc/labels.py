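"""Per-chain B-factor normalization and flexibility-state assignment.

The crystallographic temperature factor of an atom is B = 8 * pi^2 * U^2,
with U^2 the mean-squares displacement in A^2.  Because raw B-factors from
different refinements sit on different scales, each chain's C-alpha
B-factors are z-normalized against that chain's own mean and standard
deviation before thresholding into discrete flexibility states:

* three-state: b < -1.1 -> Rigid, b > 2.2 -> Flexible, otherwise
  Intermediate (boundary values are Intermediate);
* two-state: b > t -> flexible, else rigid, with t = 0.03 (strict) or
  -0.3 (non-strict).

Dataset filtering removes chains shorter than 40 residues, drops residues
with undetermined state, and re-applies the length cutoff afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chains import LabeledChain, ProteinChain

EIGHT_PI_SQ = 8.0 * math.pi**2

MIN_CHAIN_LENGTH = 40


class DegenerateChainError(ValueError):
    """All defined B-factors of the chain are equal (sigma = 0)."""


class InsufficientDataError(ValueError):
    """Fewer than two residues with a defined B-factor."""


def msd_to_bfactor(msd: float) -> float:
    """Convert a mean-squares displacement U^2 (A^2) to a B-factor (A^2)."""
    if msd < 0:
        raise ValueError(f"mean-squares displacement must be >= 0, got {msd}")
    return EIGHT_PI_SQ * msd


def bfactor_to_msd(bfactor: float) -> float:
    if bfactor < 0:
        raise ValueError(f"B-factor must be >= 0, got {bfactor}")
    return bfactor / EIGHT_PI_SQ


@dataclass
class NormalizedBFactors:
    chain_id: str
    mu: float
    sigma: float
    b_norm: np.ndarray  # NaN where the raw value was missing


@dataclass
class FlexStateScheme:
    """Thresholds mapping normalized B-values to flexibility states."""

    mode: str = "three_state"  # or "two_state"
    t_low: float = -1.1
    t_high: float = 2.2
    t_two: float = 0.03  # strict; -0.3 for the non-strict variant

    def __post_init__(self) -> None:
        if self.mode not in ("three_state", "two_state"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.t_low >= self.t_high:
            raise ValueError("t_low must be < t_high")


def normalize_bfactors(chain: ProteinChain) -> NormalizedBFactors:
    """Z-normalize a chain's raw C-alpha B-factors against its own mean/SD.

    Uses the population standard deviation (divide by N) over residues with
    defined values; residues with missing raw B get NaN.
    """
    raw = chain.raw_bfactors()
    defined = ~np.isnan(raw)
    if defined.sum() < 2:
        raise InsufficientDataError(
            f"chain {chain.chain_id}: needs >= 2 residues with B-factors"
        )
    mu = float(raw[defined].mean())
    sigma = float(raw[defined].std(ddof=0))
    if sigma == 0.0:
        raise DegenerateChainError(
            f"chain {chain.chain_id}: all B-factors equal ({mu}); cannot normalize"
        )
    b_norm = (raw - mu) / sigma
    return NormalizedBFactors(chain_id=chain.chain_id, mu=mu, sigma=sigma, b_norm=b_norm)


def assign_flex_states(
    b_norm: np.ndarray, scheme: FlexStateScheme | None = None
) -> list[Optional[str]]:
    """Map normalized B-values to discrete states; NaN -> undetermined (None)."""
    scheme = scheme or FlexStateScheme()
    states: list[Optional[str]] = []
    for b in np.asarray(b_norm, dtype=float):
        if np.isnan(b):
            states.append(None)
        elif scheme.mode == "three_state":
            if b < scheme.t_low:
                states.append("R")
            elif b > scheme.t_high:
                states.append("F")
            else:
                states.append("I")
        else:
            states.append("flexible" if b > scheme.t_two else "rigid")
    return states


def label_chain(
    chain: ProteinChain, scheme: FlexStateScheme | None = None
) -> LabeledChain:
    """Normalize and threshold one chain into a LabeledChain.

    Non-standard residues ('X') are kept in the sequence but forced to an
    undetermined state so the dataset filter removes them.
    """
    norm = normalize_bfactors(chain)
    states = assign_flex_states(norm.b_norm, scheme)
    for i, r in enumerate(chain.residues):
        if r.aa == "X":
            states[i] = None
    return LabeledChain(
        chain_id=chain.chain_id,
        sequence=chain.sequence,
        positions=[r.position for r in chain.residues],
        b_norm=norm.b_norm,
        states=states,
    )


@dataclass
class FilterStats:
    chains_in: int = 0
    chains_removed_short: int = 0
    chains_removed_after_elimination: int = 0
    residues_removed: int = 0
    chains_out: int = 0


def filter_dataset(
    chains: Sequence[LabeledChain], min_length: int = MIN_CHAIN_LENGTH
) -> tuple[list[LabeledChain], FilterStats]:
    """Apply the dataset filters used before statistics and training.

    Chains shorter than ``min_length`` are removed; residues with an
    undetermined flexibility state are then eliminated from the survivors,
    and chains that fall below the cutoff after elimination are removed
    as well.
    """
    stats = FilterStats(chains_in=len(chains))
    out: list[LabeledChain] = []
    for ch in chains:
        if len(ch) < min_length:
            stats.chains_removed_short += 1
            continue
        keep = ch.defined_mask()
        n_removed = int((~keep).sum())
        if n_removed:
            ch = LabeledChain(
                chain_id=ch.chain_id,
                sequence="".join(np.array(list(ch.sequence))[keep]),
                positions=[p for p, k in zip(ch.positions, keep) if k],
                b_norm=ch.b_norm[keep],
                states=[s for s, k in zip(ch.states, keep) if k],
            )
        stats.residues_removed += n_removed
        if len(ch) < min_length:
            stats.chains_removed_after_elimination += 1
            continue
        out.append(ch)
    stats.chains_out = len(out)
    return out, stats
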