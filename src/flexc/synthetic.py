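"""Synthetic corpus generator for end-to-end testing without downloads.

The generator emulates, at the level of summary statistics, the structure
that real crystallographic data shows:

* residues in coil have higher C-alpha B-factors than residues in helix
  or strand;
* solvent-exposed residues have higher B-factors than buried ones;
* the per-chain normalized B-value distribution is right-skewed (a long
  flexible tail), with most residues in the intermediate band.

Per chain, secondary structure is drawn as a segment process, solvent
accessibility per residue conditioned on the segment type, and the raw
B-factor as a state-dependent baseline plus an AR(1)-smoothed noise term
whose lognormal component produces the right skew.  Sequences are drawn
with residue-type propensities conditioned on secondary structure, which
is what gives sequence-only features (PSSM, context scores) their signal.
Synthetic PSSM rows are integer noise plus a log-odds boost on the true
residue; synthetic "predicted" secondary-structure and accessibility
probabilities are softened one-hot vectors whose argmax matches the truth
at a configurable reliability, standing in for an external predictor.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import protein_letters_1to3

from .chains import PSSM_ALPHABET, STATES3, LabeledChain, ProteinChain, Residue
from .labels import FlexStateScheme, label_chain

_1TO3 = {k.upper(): v.upper() for k, v in protein_letters_1to3.items()}

# residue types favored in each secondary-structure class
_SS_FAVORED = {
    "H": "ALEMKQR",
    "E": "VIYFWTC",
    "C": "GPNSD",
}


@dataclass
class SyntheticConfig:
    """Defaults define the study conditions used throughout the tests."""

    n_chains: int = 200
    length_range: tuple[int, int] = (40, 120)
    seed: int = 0

    # secondary-structure segment process
    ss_type_probs: tuple[float, float, float] = (0.35, 0.25, 0.40)  # H, E, C
    seg_len_mean: dict = field(
        default_factory=lambda: {"H": (4, 5.0), "E": (3, 3.0), "C": (1, 3.0)}
    )  # (min_len, poisson mean of the excess)

    # P(exposed | ss)
    sa_exposed_prob: dict = field(
        default_factory=lambda: {"H": 0.40, "E": 0.25, "C": 0.65}
    )

    # B-factor model.  Baseline: a tight rigid level for buried residues in
    # regular secondary structure, one elevated level as soon as a residue
    # is coil or exposed (base = b0 + flex_shift * [coil or exposed]).
    # Noise: Gaussian core plus a centered lognormal tail whose weight
    # grows with coil and exposure — this produces the right-skewed
    # normalized-B distribution and the sparse flexible class.
    b0: float = 6.0
    flex_shift: float = 14.0
    rho: float = 0.30  # AR(1) neighbor-smoothing weight
    gauss_sd: float = 1.6
    lognorm_sigma: float = 1.0
    tail_scale_base: float = 0.1
    tail_scale_coil: float = 2.0
    tail_scale_exposed: float = 1.4

    # sequence model: favored residues get propensity_boost x the uniform weight
    propensity_boost: float = 3.0

    # synthetic PSSM: boost on the true residue plus integer noise
    pssm_signal: float = 6.0
    pssm_noise_sd: float = 2.0

    # reliability of the stand-in SS / SA predictors (argmax accuracy)
    ss_reliability: float = 0.85
    sa_reliability: float = 0.85

    def __post_init__(self) -> None:
        if self.length_range[0] < 1:
            raise ValueError("length_range minimum must be >= 1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        for p in (*self.ss_type_probs, self.ss_reliability, self.sa_reliability):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")

    def null_model(self) -> "SyntheticConfig":
        """A copy with every planted effect switched off (no signal)."""
        return replace(
            self,
            flex_shift=0.0,
            tail_scale_coil=0.0,
            tail_scale_exposed=0.0,
            propensity_boost=1.0,
        )


@dataclass
class SyntheticChain:
    chain_id: str
    sequence: str
    ss: str  # per-residue H/E/C
    sa: str  # per-residue B/E
    raw_b: np.ndarray
    pssm: np.ndarray  # (L, 20) int
    ss_probs: np.ndarray  # (L, 3) order H, E, C
    sa_probs: np.ndarray  # (L, 2) order exposed, buried

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    chains: list[SyntheticChain]

    def __len__(self) -> int:
        return len(self.chains)


def _sample_ss(rng: np.random.Generator, length: int, cfg: SyntheticConfig) -> str:
    out: list[str] = []
    prev = None
    types = np.array(["H", "E", "C"])
    probs = np.array(cfg.ss_type_probs, dtype=float)
    while len(out) < length:
        p = probs.copy()
        if prev is not None:  # avoid merging identical adjacent segments
            p[types == prev] = 0.0
            p = p / p.sum()
        t = rng.choice(types, p=p)
        min_len, mean_excess = cfg.seg_len_mean[t]
        seg = min_len + rng.poisson(mean_excess)
        out.extend(t * seg)
        prev = t
    return "".join(out[:length])


def _sample_sequence(rng: np.random.Generator, ss: str, cfg: SyntheticConfig) -> str:
    seq = []
    for s in ss:
        w = np.ones(20)
        for a in _SS_FAVORED[s]:
            w[PSSM_ALPHABET.index(a)] = cfg.propensity_boost
        w /= w.sum()
        seq.append(PSSM_ALPHABET[rng.choice(20, p=w)])
    return "".join(seq)


def _sample_bfactors(
    rng: np.random.Generator, ss: str, sa: str, cfg: SyntheticConfig
) -> np.ndarray:
    L = len(ss)
    is_coil = np.array([s == "C" for s in ss])
    is_exposed = np.array([a == "E" for a in sa])
    base = cfg.b0 + cfg.flex_shift * (is_coil | is_exposed)
    tail_scale = (
        cfg.tail_scale_base
        + cfg.tail_scale_coil * is_coil
        + cfg.tail_scale_exposed * is_exposed
    )
    ln_mean = math.exp(cfg.lognorm_sigma**2 / 2)
    noise = rng.normal(0.0, cfg.gauss_sd, L) + tail_scale * (
        rng.lognormal(0.0, cfg.lognorm_sigma, L) - ln_mean
    )
    b = np.empty(L)
    dev = 0.0
    for i in range(L):
        dev = cfg.rho * dev + noise[i]
        b[i] = base[i] + dev
    return np.maximum(b, 0.5)  # B-factors are positive


def _soft_onehot(
    rng: np.random.Generator, true_idx: int, n: int, reliability: float
) -> np.ndarray:
    idx = true_idx
    if rng.random() > reliability:
        others = [j for j in range(n) if j != true_idx]
        idx = others[rng.integers(len(others))]
    p = np.full(n, 0.2 / (n - 1))
    p[idx] = 0.8
    return p


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticCorpus:
    """Generate a full synthetic corpus; deterministic given config.seed."""
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    chains: list[SyntheticChain] = []
    for c in range(cfg.n_chains):
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        ss = _sample_ss(rng, L, cfg)
        sa = "".join(
            "E" if rng.random() < cfg.sa_exposed_prob[s] else "B" for s in ss
        )
        seq = _sample_sequence(rng, ss, cfg)
        raw_b = _sample_bfactors(rng, ss, sa, cfg)
        pssm = np.round(
            rng.normal(0.0, cfg.pssm_noise_sd, (L, 20))
        ).astype(np.int64)
        for i, a in enumerate(seq):
            pssm[i, PSSM_ALPHABET.index(a)] += int(round(cfg.pssm_signal))
        pssm = np.clip(pssm, -12, 13)
        ss_probs = np.vstack(
            [
                _soft_onehot(rng, "HEC".index(s), 3, cfg.ss_reliability)
                for s in ss
            ]
        )
        sa_probs = np.vstack(
            [
                _soft_onehot(rng, 0 if a == "E" else 1, 2, cfg.sa_reliability)
                for a in sa
            ]
        )
        chains.append(
            SyntheticChain(
                chain_id=f"S{c:04d}",
                sequence=seq,
                ss=ss,
                sa=sa,
                raw_b=raw_b,
                pssm=pssm,
                ss_probs=ss_probs,
                sa_probs=sa_probs,
            )
        )
    return SyntheticCorpus(config=cfg, chains=chains)


def corpus_to_protein_chains(corpus: SyntheticCorpus) -> list[ProteinChain]:
    out = []
    for ch in corpus.chains:
        out.append(
            ProteinChain(
                chain_id=ch.chain_id,
                residues=[
                    Residue(
                        position=i + 1,
                        aa=ch.sequence[i],
                        raw_bfactor=float(ch.raw_b[i]),
                        ss=ch.ss[i],
                        sa=ch.sa[i],
                    )
                    for i in range(len(ch))
                ],
            )
        )
    return out


def label_corpus(
    corpus: SyntheticCorpus, scheme: FlexStateScheme | None = None
) -> list[LabeledChain]:
    """Normalize, threshold and label every synthetic chain."""
    return [label_chain(pc, scheme) for pc in corpus_to_protein_chains(corpus)]


def make_tilted_corpus(
    seed: int,
    n_residues: int,
    tilt: dict[str, dict[str, float]],
    base_freqs: tuple[float, float, float] = (0.25, 0.6, 0.15),
    chain_length: int = 50,
) -> list[LabeledChain]:
    """Corpus with a planted singlet preference, for potential-recovery tests.

    Sequences are uniform over the 20 residue types; each residue's state
    is drawn from p(C) proportional to base_freqs[C] * tilt[aa][C] (odds
    multiplier, default 1).  b_norm is not meaningful here and is set to 0.
    """
    rng = np.random.default_rng(seed)
    chains: list[LabeledChain] = []
    made = 0
    c = 0
    while made < n_residues:
        L = min(chain_length, n_residues - made) or chain_length
        seq = "".join(PSSM_ALPHABET[i] for i in rng.integers(0, 20, L))
        states = []
        for a in seq:
            p = np.array(base_freqs, dtype=float)
            for s, odds in tilt.get(a, {}).items():
                p[STATES3.index(s)] *= odds
            p /= p.sum()
            states.append(STATES3[rng.choice(3, p=p)])
        chains.append(
            LabeledChain(
                chain_id=f"T{c:04d}",
                sequence=seq,
                positions=list(range(1, L + 1)),
                b_norm=np.zeros(L),
                states=states,
            )
        )
        made += L
        c += 1
    return chains


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------


def _pdb_atom_line(serial: int, aa: str, resseq: int, b: float) -> str:
    res3 = _1TO3.get(aa, "UNK")
    # trivial helix trace; coordinates are ignored by the reader
    x = 2.3 * math.cos(math.radians(100.0 * resseq))
    y = 2.3 * math.sin(math.radians(100.0 * resseq))
    z = 1.5 * resseq
    return (
        f"ATOM  {serial:5d}  CA  {res3:>3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
    )


def write_pdb(chain: SyntheticChain, path: str | Path) -> None:
    lines = [
        _pdb_atom_line(i + 1, chain.sequence[i], i + 1, float(chain.raw_b[i]))
        for i in range(len(chain))
    ]
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pssm_ascii(chain: SyntheticChain, path: str | Path) -> None:
    """Write the profile in the PSI-BLAST -out_ascii_pssm layout."""
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapped matches\n"
    )
    cols = "            " + "   ".join(PSSM_ALPHABET) + "   " + "   ".join(
        PSSM_ALPHABET
    )
    rows = []
    for i in range(len(chain)):
        scores = "".join(f"{v:4d}" for v in chain.pssm[i])
        pcts = "".join(f"{0:4d}" for _ in range(20))
        rows.append(f"{i + 1:5d} {chain.sequence[i]} {scores} {pcts}  0.00 0.00")
    footer = "\n                      K         Lambda\nStandard Ungapped    0.1337     0.3172\n"
    Path(path).write_text(header + cols + "\n" + "\n".join(rows) + "\n" + footer)


def write_fixture_files(corpus: SyntheticCorpus, out_dir: str | Path) -> dict:
    """Emit the corpus in every supported on-disk format.

    Layout: pdb/<id>.pdb, pssm/<id>.pssm, sequences.fasta,
    assignments_true.tsv (hard SS/SA labels), assignments_pred.tsv
    (predictor-style probabilities) and the file list returned.
    """
    out = Path(out_dir)
    (out / "pdb").mkdir(parents=True, exist_ok=True)
    (out / "pssm").mkdir(parents=True, exist_ok=True)

    fasta_lines = []
    true_rows = []
    pred_rows = []
    for ch in corpus.chains:
        write_pdb(ch, out / "pdb" / f"{ch.chain_id}.pdb")
        write_pssm_ascii(ch, out / "pssm" / f"{ch.chain_id}.pssm")
        fasta_lines.append(f">{ch.chain_id}\n{ch.sequence}")
        for i in range(len(ch)):
            base = {
                "chain_id": ch.chain_id,
                "position": i + 1,
                "aa": ch.sequence[i],
            }
            true_rows.append({**base, "ss": ch.ss[i], "sa": ch.sa[i]})
            pred_rows.append(
                {
                    **base,
                    "p_helix": ch.ss_probs[i, 0],
                    "p_sheet": ch.ss_probs[i, 1],
                    "p_coil": ch.ss_probs[i, 2],
                    "p_exposed": ch.sa_probs[i, 0],
                    "p_buried": ch.sa_probs[i, 1],
                }
            )
    (out / "sequences.fasta").write_text("\n".join(fasta_lines) + "\n")
    pd.DataFrame(true_rows).to_csv(out / "assignments_true.tsv", sep="\t", index=False)
    pd.DataFrame(pred_rows).to_csv(
        out / "assignments_pred.tsv", sep="\t", index=False, float_format="%.6f"
    )
    return {
        "pdb_dir": out / "pdb",
        "pssm_dir": out / "pssm",
        "fasta": out / "sequences.fasta",
        "assignments_true": out / "assignments_true.tsv",
        "assignments_pred": out / "assignments_pred.tsv",
    }
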