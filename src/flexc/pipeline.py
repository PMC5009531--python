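"""Glue between labeling, potentials, encoding and the classifier.

These helpers assemble, for each chain, the per-residue 34-column feature
matrix and the sliding-window input matrix the network consumes, keeping
the chain structure intact so that cross-validation can split by chain.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .chains import STATES3, LabeledChain
from .encoding import chain_feature_matrix, encode_chain_windows
from .model import ChainData
from .potentials import PotentialTable, chain_scrs

ALL_GROUPS = ("pssm", "scrs", "ss", "sa", "aap", "terminal")
PSSM_ONLY_GROUPS = ("pssm", "terminal")


def onehot_ss_probs(ss: str) -> np.ndarray:
    """(L, 3) one-hot probabilities from hard H/E/C labels."""
    return np.array([[s == "H", s == "E", s == "C"] for s in ss], dtype=float)


def onehot_sa_probs(sa: str) -> np.ndarray:
    """(L, 2) one-hot probabilities (exposed, buried) from hard B/E labels."""
    return np.array([[a == "E", a == "B"] for a in sa], dtype=float)


def build_chain_data(
    chain: LabeledChain,
    pssm_rows: np.ndarray,
    ss_probs: np.ndarray,
    sa_probs: np.ndarray,
    table: PotentialTable,
    groups: Sequence[str] = ALL_GROUPS,
    window: int = 15,
    states: Sequence[str] = STATES3,
) -> ChainData:
    """Encode one labeled chain into windows plus integer labels."""
    scrs = chain_scrs(table, chain.sequence)
    feats = chain_feature_matrix(
        chain.sequence, pssm_rows, scrs, ss_probs, sa_probs
    )
    X = encode_chain_windows(feats, window=window, groups=groups)
    y = np.array([states.index(s) for s in chain.states], dtype=np.int64)
    return ChainData(chain_id=chain.chain_id, X=X.astype(np.float32), y=y)


def build_dataset_from_corpus(
    corpus,
    labeled: Sequence[LabeledChain],
    table: PotentialTable,
    groups: Sequence[str] = ALL_GROUPS,
    window: int = 15,
    states: Sequence[str] = STATES3,
    use_true_ss_sa: bool = False,
) -> list[ChainData]:
    """Encode a synthetic corpus against a potential table.

    ``use_true_ss_sa`` switches from the stand-in predictor probabilities
    to one-hot true assignments (the training-time ablation option).
    ``labeled`` may be a filtered subset of the corpus; residues dropped by
    the dataset filter must be contiguous-position subsets, so labeled
    chains are matched to synthetic chains by id and position.
    """
    by_id = {ch.chain_id: ch for ch in corpus.chains}
    out: list[ChainData] = []
    for lab in labeled:
        src = by_id[lab.chain_id]
        keep = np.array(lab.positions, dtype=int) - 1
        pssm = src.pssm[keep]
        if use_true_ss_sa:
            ss_probs = onehot_ss_probs("".join(src.ss[i] for i in keep))
            sa_probs = onehot_sa_probs("".join(src.sa[i] for i in keep))
        else:
            ss_probs = src.ss_probs[keep]
            sa_probs = src.sa_probs[keep]
        out.append(
            build_chain_data(
                lab, pssm, ss_probs, sa_probs, table,
                groups=groups, window=window, states=states,
            )
        )
    return out
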