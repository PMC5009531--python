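"""Core domain types shared across the pipeline.

A :class:`ProteinChain` carries, per residue, the information the rest of
the pipeline consumes: sequence position, amino-acid identity, the raw
C-alpha B-factor (temperature factor, in A^2) and, optionally, secondary
structure (H/E/C) and solvent accessibility (B = buried, E = exposed)
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

#: The 20 standard amino acids in PSI-BLAST PSSM column order.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: Index lookup for the PSSM alphabet; 'X' (unknown) maps to -1.
AA_INDEX = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}
AA_INDEX["X"] = -1

#: Three flexibility states, in fixed order: Rigid, Intermediate, Flexible.
STATES3 = ("R", "I", "F")

#: Two-state scheme used for F-measure comparisons.
STATES2 = ("rigid", "flexible")

STATE_INDEX = {s: i for i, s in enumerate(STATES3)}


def aa_indices(sequence: str) -> np.ndarray:
    """Map a sequence to integer indices in PSSM column order ('X' -> -1)."""
    try:
        return np.array([AA_INDEX[a] for a in sequence], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-standard amino acid code {exc} in sequence") from exc


@dataclass
class Residue:
    """One residue of a chain.

    position is 1-based and strictly increasing within a chain; raw_bfactor
    is the C-alpha temperature factor in A^2 (None when the residue has no
    C-alpha atom or no usable B-factor).
    """

    position: int
    aa: str
    raw_bfactor: Optional[float] = None
    ss: Optional[str] = None  # H / E / C
    sa: Optional[str] = None  # B (buried) / E (exposed)


@dataclass
class ProteinChain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        positions = [r.position for r in self.residues]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(
                f"chain {self.chain_id}: residue positions must be strictly increasing"
            )
        for r in self.residues:
            if r.aa != r.aa.upper():
                raise ValueError(f"chain {self.chain_id}: lowercase aa code {r.aa!r}")
            if r.raw_bfactor is not None and not np.isfinite(r.raw_bfactor):
                raise ValueError(
                    f"chain {self.chain_id} pos {r.position}: non-finite B-factor"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def raw_bfactors(self) -> np.ndarray:
        """Raw B-factors as a float array with NaN for missing values."""
        return np.array(
            [np.nan if r.raw_bfactor is None else r.raw_bfactor for r in self.residues],
            dtype=float,
        )


@dataclass
class LabeledChain:
    """A chain with per-residue normalized B-values and flexibility states.

    state entries are drawn from STATES3 (or STATES2 in two-state mode);
    None marks an undetermined state.
    """

    chain_id: str
    sequence: str
    positions: list[int]
    b_norm: np.ndarray  # NaN where missing
    states: list[Optional[str]]

    def __len__(self) -> int:
        return len(self.sequence)

    def defined_mask(self) -> np.ndarray:
        return np.array([s is not None for s in self.states], dtype=bool)


def iter_labeled_residues(chains: Iterable[LabeledChain]):
    """Yield (chain, index) pairs for every residue with a defined state."""
    for chain in chains:
        for i, state in enumerate(chain.states):
            if state is not None:
                yield chain, i
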