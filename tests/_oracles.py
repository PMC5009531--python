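"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized code paths: counting is
plain dict arithmetic over explicitly enumerated windows, and the
structure oracle is a Monte-Carlo argmax lookup on the generative model.
"""

from collections import defaultdict

import numpy as np


def brute_force_counts(chains, window_half=3):
    """Dict-based singlet/doublet/triplet recount.

    chains: iterable of (sequence, states) pairs.  Returns dicts keyed by
    (state, aa), (state, k, aa_i, aa_ik) and (state, (k1, k2), a, b, c).
    """
    offsets = [k for k in range(-window_half, window_half + 1) if k != 0]
    singlet = defaultdict(int)
    doublet = defaultdict(int)
    triplet = defaultdict(int)
    for seq, states in chains:
        L = len(seq)
        for i in range(L):
            c = states[i]
            if c is None or seq[i] == "X":
                continue
            singlet[(c, seq[i])] += 1
            for k in offsets:
                j = i + k
                if 0 <= j < L and seq[j] != "X":
                    doublet[(c, k, seq[i], seq[j])] += 1
            for a in range(len(offsets)):
                for b in range(a + 1, len(offsets)):
                    k1, k2 = offsets[a], offsets[b]
                    j1, j2 = i + k1, i + k2
                    if 0 <= j1 < L and 0 <= j2 < L and seq[j1] != "X" and seq[j2] != "X":
                        triplet[(c, (k1, k2), seq[i], seq[j1], seq[j2])] += 1
    return singlet, doublet, triplet


def brute_force_combined(table, sequence, i, state):
    """Re-sum the pseudo-potential by explicit offset enumeration."""
    from flexc.chains import PSSM_ALPHABET, STATES3

    aa = {a: x for x, a in enumerate(PSSM_ALPHABET)}
    c = STATES3.index(state)
    L = len(sequence)
    p = i - 1
    if sequence[p] == "X":
        return 0.0
    total = table.u_singlet[c, aa[sequence[p]]]
    for j, k in enumerate(table.offsets):
        q = p + k
        if 0 <= q < L and sequence[q] != "X":
            total += table.u_doublet[c, j, aa[sequence[p]], aa[sequence[q]]]
    for j, (k1, k2) in enumerate(table.pairs):
        q1, q2 = p + k1, p + k2
        if 0 <= q1 < L and 0 <= q2 < L and sequence[q1] != "X" and sequence[q2] != "X":
            total += table.u_triplet[
                c, j, aa[sequence[p]], aa[sequence[q1]], aa[sequence[q2]]
            ]
    return float(total)


def structure_oracle_q3(config, n_fit=150, n_eval=100):
    """Monte-Carlo lower bound on the Bayes rate of the generative model.

    Fits argmax P(state | coil?, exposed?) on one simulated corpus and
    measures its accuracy on an independent one.  The true Bayes rate can
    only be higher (the optimal predictor also sees window context and
    chain composition).
    """
    from dataclasses import replace

    from flexc.labels import filter_dataset
    from flexc.synthetic import generate_dataset, label_corpus

    def tally(seed, n):
        corpus = generate_dataset(replace(config, n_chains=n, seed=seed))
        labeled, _ = filter_dataset(label_corpus(corpus))
        by_id = {c.chain_id: c for c in corpus.chains}
        cells = []
        for lab in labeled:
            src = by_id[lab.chain_id]
            for pos, state in zip(lab.positions, lab.states):
                i = pos - 1
                cells.append(((src.ss[i] == "C", src.sa[i] == "E"), state))
        return cells

    counts = defaultdict(lambda: defaultdict(int))
    for cell, state in tally(config.seed + 1000, n_fit):
        counts[cell][state] += 1
    rule = {cell: max(d, key=d.get) for cell, d in counts.items()}
    hits = total = 0
    for cell, state in tally(config.seed + 2000, n_eval):
        hits += rule.get(cell) == state
        total += 1
    return hits / total


def chance_agreement(observed, predicted):
    """Expected Q3 of a predictor independent of the truth."""
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    states = np.unique(np.concatenate([observed, predicted]))
    f_obs = np.array([(observed == s).mean() for s in states])
    f_pred = np.array([(predicted == s).mean() for s in states])
    return float((f_obs * f_pred).sum())
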