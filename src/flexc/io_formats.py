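"""Readers and writers for the external file formats the pipeline touches.

Covers fixed-column PDB ATOM records (C-alpha B-factor extraction only),
PSI-BLAST ASCII PSSM profiles, FASTA, per-residue assignment TSVs
(secondary structure and solvent accessibility, as hard labels or
predicted probabilities), and the prediction TSV emitted by the
classifier.  Potential tables have their own serialization in
:mod:`flexc.potentials`.

The PDB reader is deliberately narrow: it consumes only residue identity
and the temperature-factor column of C-alpha ATOM records, resolves altloc
duplicates by highest occupancy (ties: first in file), and reads only the
first MODEL by default.  Coordinates and header records are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_letters_3to1

from .chains import ProteinChain, Residue


class PDBParseError(ValueError):
    pass


class PSSMParseError(ValueError):
    pass


_3TO1 = {k.upper(): v.upper() for k, v in protein_letters_3to1.items()}


def _three_to_one(resname: str) -> str:
    return _3TO1.get(resname.strip().upper(), "X")


def read_pdb_ca_bfactors(
    path: str | Path, model_policy: str | int = "first"
) -> list[ProteinChain]:
    """Extract per-residue C-alpha B-factors from a PDB file.

    Parameters
    ----------
    path
        PDB file with fixed-column ATOM records.
    model_policy
        ``"first"`` (default) reads only the first MODEL of a multi-model
        file; an integer selects that model number.

    Returns one :class:`ProteinChain` per chain identifier, in file order.
    Residues that appear in ATOM records but lack a C-alpha atom get a
    missing (None) raw_bfactor.  HETATM records (including MSE) are
    excluded; such residues count as undetermined downstream.
    """
    path = Path(path)
    want_model: Optional[int] = None if model_policy == "first" else int(model_policy)

    chains: dict[str, dict] = {}
    current_model = 0
    seen_first_model = False
    done = False

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    current_model = int(line[10:14])
                except ValueError:
                    current_model += 1
                if want_model is None and seen_first_model:
                    done = True
                seen_first_model = True
            elif rec == "ENDMDL":
                if want_model is None:
                    done = True
            if done:
                break
            if rec != "ATOM  ":
                continue
            if want_model is not None and seen_first_model and current_model != want_model:
                continue
            if len(line.rstrip("\n")) < 66:
                raise PDBParseError(
                    f"{path.name}:{lineno}: ATOM record shorter than 66 columns"
                )
            atom_name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20]
            chain_id = line[21]
            try:
                resseq = int(line[22:26])
            except ValueError:
                raise PDBParseError(
                    f"{path.name}:{lineno}: malformed residue number {line[22:26]!r}"
                ) from None
            try:
                occupancy = float(line[54:60])
            except ValueError:
                occupancy = 1.0
            try:
                bfactor = float(line[60:66])
            except ValueError:
                raise PDBParseError(
                    f"{path.name}:{lineno}: malformed B-factor field {line[60:66]!r}"
                ) from None

            chain = chains.setdefault(chain_id, {})
            key = (resseq, line[26])  # icode disambiguates
            entry = chain.setdefault(
                key, {"aa": _three_to_one(resname), "ca": None, "occ": -math.inf}
            )
            if atom_name == "CA":
                # altloc resolution: highest occupancy wins, ties keep the
                # first record in file order
                if altloc == " " and entry["ca"] is None:
                    entry["ca"] = bfactor
                    entry["occ"] = occupancy
                elif occupancy > entry["occ"]:
                    entry["ca"] = bfactor
                    entry["occ"] = occupancy

    out = []
    for chain_id, residues in chains.items():
        keys = sorted(residues)
        recs = []
        pos_seen = set()
        for resseq, icode in keys:
            if resseq in pos_seen:
                continue  # insertion-code duplicate of a numeric position
            pos_seen.add(resseq)
            entry = residues[(resseq, icode)]
            b = entry["ca"]
            recs.append(
                Residue(
                    position=resseq,
                    aa=entry["aa"],
                    raw_bfactor=b if b is not None and np.isfinite(b) else None,
                )
            )
        out.append(ProteinChain(chain_id=chain_id, residues=recs))
    return out


@dataclass
class PSSMProfile:
    """PSI-BLAST position-specific scoring matrix for one chain.

    rows is an (L, 20) integer array of log-odds scores in the fixed
    PSI-BLAST column order (ARNDCQEGHILKMFPSTWYV); sequence holds the
    query residue letters from the profile rows.
    """

    chain_id: str
    sequence: str
    rows: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int64)
        if self.rows.size == 0:
            self.rows = self.rows.reshape(0, 20)
        if self.rows.ndim != 2 or self.rows.shape[1] != 20:
            raise ValueError("PSSM rows must have exactly 20 columns")
        if self.rows.shape[0] != len(self.sequence):
            raise ValueError("PSSM row count must match sequence length")

    def __len__(self) -> int:
        return self.rows.shape[0]


def read_pssm(
    path: str | Path, chain_id: str | None = None, sequence: str | None = None
) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Only the first 20 numeric columns (log-odds scores) of each residue row
    are kept; the second block of 20 weighted-percentage columns, and the
    information-content columns, are ignored.  If ``sequence`` is supplied,
    residue letters in the file are checked against it.
    """
    path = Path(path)
    letters: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 2:
                continue
            # residue rows start with "<index> <letter> <20+ ints>"
            if not parts[0].isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            numeric = parts[2:]
            if len(numeric) < 20:
                raise PSSMParseError(
                    f"{path.name}:{lineno}: expected 20 log-odds values, "
                    f"found {len(numeric)}"
                )
            try:
                rows.append([int(v) for v in numeric[:20]])
            except ValueError:
                raise PSSMParseError(
                    f"{path.name}:{lineno}: non-integer log-odds value"
                ) from None
            letters.append(parts[1].upper())

    seq = "".join(letters)
    if sequence is not None and seq != sequence.upper():
        raise PSSMParseError(
            f"{path.name}: profile sequence does not match the supplied sequence"
        )
    arr = np.array(rows, dtype=np.int64).reshape(len(rows), 20)
    return PSSMProfile(chain_id=chain_id or path.stem, sequence=seq, rows=arr)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping (order preserved)."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


# ---------------------------------------------------------------------------
# assignment / prediction TSVs
# ---------------------------------------------------------------------------

SS_PROB_COLS = ["p_helix", "p_sheet", "p_coil"]
SA_PROB_COLS = ["p_exposed", "p_buried"]


def read_assignments(path: str | Path) -> dict[str, pd.DataFrame]:
    """Read a per-residue assignment TSV, grouped by chain.

    Expected columns: chain_id, position, aa, then either hard labels
    (ss in {H,E,C}, sa in {B,E}) or predicted probabilities
    (p_helix, p_sheet, p_coil, p_exposed, p_buried).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str})
    required = {"chain_id", "position", "aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"assignment TSV missing columns: {sorted(missing)}")
    has_hard = {"ss", "sa"} <= set(df.columns)
    has_probs = set(SS_PROB_COLS + SA_PROB_COLS) <= set(df.columns)
    if not (has_hard or has_probs):
        raise ValueError(
            "assignment TSV needs ss/sa label columns or probability columns"
        )
    return {cid: g.reset_index(drop=True) for cid, g in df.groupby("chain_id", sort=False)}


def write_predictions(records: list[dict], path: str | Path) -> None:
    """Write per-residue predictions as a TSV.

    Each record holds chain_id, position, aa, the per-state probabilities
    and the argmax state; probabilities are written with 6 decimal places.
    """
    cols = ["chain_id", "position", "aa", "p_R", "p_I", "p_F", "state"]
    df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chain_id": str})


def write_labels(chains, path: str | Path) -> None:
    """Write labeled chains (normalized B + state) as a TSV."""
    rows = []
    for ch in chains:
        for i in range(len(ch)):
            rows.append(
                {
                    "chain_id": ch.chain_id,
                    "position": ch.positions[i],
                    "aa": ch.sequence[i],
                    "b_norm": ch.b_norm[i],
                    "state": ch.states[i] if ch.states[i] is not None else ".",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_labels(path: str | Path):
    """Read a label TSV back into LabeledChain objects."""
    from .chains import LabeledChain

    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "state": str})
    chains = []
    for cid, g in df.groupby("chain_id", sort=False):
        chains.append(
            LabeledChain(
                chain_id=cid,
                sequence="".join(g["aa"]),
                positions=list(g["position"].astype(int)),
                b_norm=g["b_norm"].to_numpy(dtype=float),
                states=[None if s == "." else s for s in g["state"]],
            )
        )
    return chains
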