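# Methods

## The prediction problem

Crystallographic temperature factors (B-factors) measure the positional
fluctuation of atoms: B = 8π²U², with U² the mean-squares displacement in
Å².  The Cα B-factor of a residue is a standard proxy for backbone
flexibility.  Because refinements put B-factors on incomparable scales,
each chain's Cα B-factors are z-normalized against that chain's own mean
μ and standard deviation σ:

    b = (B_raw − μ) / σ

and the normalized value is thresholded into three flexibility states:
Rigid (b < −1.1), Flexible (b > 2.2), Intermediate otherwise; boundary
values fall into Intermediate.  A two-state variant thresholds at 0.03
(strict) or −0.3 (non-strict), with "flexible" strictly above the
threshold.  We use the population standard deviation (divide by N): it
keeps the two-residue minimal case well defined and makes the
mean-0 / SD-1 invariants exact, which the tests assert at 1e-9.

Chains shorter than 40 residues are removed, residues with undetermined
state (missing Cα, missing or non-finite B, non-standard residue) are
eliminated, and chains that fall below 40 residues afterwards are removed
as well — length filter first, elimination second, re-check third, the
conservative composition of the two rules.

## Context-based mean-force potentials (SCRS)

Flexibility is strongly locally dependent, so we collect occurrence
statistics of singlets R_i, doublets (R_i, R_{i+k}) and triplets
(R_i, R_{i+k1}, R_{i+k2}) per flexibility state in a 7-residue window
(offsets k, k1, k2 ∈ {−3..3}\{0}, k1 < k2; 6 doublet offsets, 15 ordered
offset pairs).  Contexts running past a chain end are skipped — no
padding token — and the scoring sum omits exactly the same terms, keeping
counting and scoring consistent.  'X' residues contribute no counts and
score 0.

Counts become inverse-Boltzmann potentials.  With f(C) the corpus-wide
state frequency, m = Σ_C N(C, x) the total count of context cell x, and
f_obs(C|x) = N(C, x)/m:

    f̂(C|x) = (m·f_obs(C|x) + w·f(C)) / (m + w)
    U(C, x) = −ln( f̂(C|x) / f(C) )

The pseudo-observation mass w (default 10) shrinks sparse cells toward
the prior; a never-observed cell sits exactly at U = 0, which keeps the
3 × 15 × 20³ triplet table finite despite its sparsity.  The temperature
factor kT is absorbed into the (dimensionless) unit of U.  The combined
pseudo-potential of residue i in state C sums the singlet term, the
in-range doublet terms and the in-range triplet terms — 22 terms for an
interior residue, 7 at a chain end.

The three context scores (SCRS) fed to the classifier are
softmax(−U(C)) over the states.  This bounds them to (0, 1) like every
other input feature; raw potentials are unbounded and scale with corpus
size, which is poison for a sigmoid network.

## Input encoding

Each residue carries 34 values:

| group | width | content |
|-------|-------|---------|
| PSSM  | 20 | PSI-BLAST log-odds through the logistic 1/(1+e^(−x)) |
| SCRS  | 3  | context-based state preferences (R, I, F) |
| SS    | 3  | predicted secondary-structure probabilities (H, E, C) |
| SA    | 2  | predicted accessibility probabilities (exposed, buried) |
| AAP   | 5  | amino-acid properties, min-max normalized over the 20 types |
| term  | 1  | 1 when the window slot lies past a chain terminus |

The five properties are the classic steric parameter (graph shape
index), polarizability, volume, hydrophobicity and isoelectric point.
Min-max normalization over the 20 standard amino acids is this package's
choice; note that glycine and proline share the minimum polarizability,
so that column attains 0 twice.  'X' residues receive the column means.

A prediction input is the concatenation of these vectors over a sliding
window of 15 residues centered on the target: 15 × 34 = 510 values, all
in [0, 1].  Window slots beyond a terminus are padding: 33 zeros plus
the terminal flag.  Secondary structure and accessibility normally come
from an external predictor as probabilities; a training-time option
substitutes one-hot true assignments for ablations.  Eight-state
secondary-structure labels, when given, map {H,G,I}→Helix, {E,B}→Sheet,
else Coil; relative accessibility ≥ 0.25 counts as exposed.

## Classifier and cross-validation

A single hidden layer of 250 sigmoidal units and a softmax output (3
classes, or 2 in two-state mode) is trained by mini-batch SGD with
momentum on the cross-entropy objective.  Defaults: learning rate 0.01,
momentum 0.9, batch 128, at most 200 epochs, early stopping after 10
epochs without validation improvement, weights restored to the best
validation loss.  Initialization is seeded uniform scaled by fan-in;
training is exactly reproducible given the seed.  Ties in the output
argmax resolve to the earlier state in (R, I, F).

Cross-validation is 7-fold and splits by chain, never by residue, so
windows from one protein cannot leak across sets.  Fold j uses subset j
for validation, subset (j+1) mod 7 for testing and the remaining five
for training; the report averages the seven test-fold metrics
unweighted.

## Evaluation

Q_s is per-state recall (correct in state s over observed in s) — the
reading consistent with Q3 = total correct / total, which equals the
frequency-weighted mean of the Q_s.  Two-state comparisons use the
flexible class as positive: A = TP/(TP+FP), C = TP/(TP+FN),
F = 2AC/(A+C).

## The synthetic corpus

The generator produces chains (default 200 per corpus, lengths 40–120 so
the length filter passes), with secondary structure drawn as a segment
process (H/E/C type weights 0.35/0.25/0.40; minimum segment lengths
4/3/1 plus Poisson excess), accessibility per residue conditioned on
secondary structure (P(exposed) = 0.40/0.25/0.65 for H/E/C), and
sequences drawn with residue propensities conditioned on secondary
structure (helix-formers boosted 3× in helices, and so on) — this
sequence–structure coupling is what gives PSSM and context scores their
signal.

Raw B-factors follow a two-level baseline: a tight rigid level (6 Å²)
for buried residues in regular secondary structure and an elevated level
(+14 Å²) as soon as a residue is coil *or* exposed, plus AR(1)-smoothed
noise (ρ = 0.30) composed of a Gaussian core (SD 1.6) and a centered
lognormal tail (σ_ln = 1.0) whose weight grows with coil and exposure
(0.1 base, +2.0 coil, +1.4 exposed).  This geometry is deliberate: with
per-chain z-score thresholds at (−1.1, 2.2), one-sided Chebyshev bounds
make it impossible for both tails to be heavily populated — mass p below
z = −1.1 forces the low group under ~45 % of the chain and a light right
tail.  The defaults land at roughly 9–16 % Rigid, 83–89 % Intermediate
and 1.5–2 % Flexible with normalized-B skewness ≈ 0.7, reproducing the
qualitative structure of real data: most residues intermediate, coil
B-factors above helix/strand, exposed above buried, a long right tail.

Synthetic PSSM rows are integer noise (SD 2) plus a +6 log-odds boost on
the true residue; stand-in "predicted" secondary structure and
accessibility are softened one-hot vectors whose argmax matches the
truth with probability 0.85.  A null-model switch zeroes every planted
effect, and a tilted-corpus helper plants per-residue-type state odds
for potential-recovery experiments.

What the generator does *not* emulate: real evolutionary profiles
(PSSMs are independent across positions), crystal-packing and
refinement artifacts in B-factors, realistic coordinates (the PDB
fixtures place Cα on a trivial helix trace), and realistic class
difficulty.  The planted signal is stronger than in real proteins, so
test accuracies here (mean 7-fold Q3 ≈ 0.94 on the default corpus) say
that the pipeline recovers structure a generative model planted — not
that it would reach any particular accuracy on crystallographic data.
A Monte-Carlo oracle that classifies by argmax P(state | coil, exposed)
on an independent corpus scores ≈ 0.85–0.89, a lower bound on the Bayes
rate; the network exceeds it because it also sees window context and
chain composition.  The Flexible class is rare by construction, and the
classifier rarely predicts it — per-state recall for F is near zero on
synthetic data, a known limitation of the unweighted objective (class
weights are exposed as an option on the config).

## Problem sizes and numerical choices

Heavy checks run at fixed, seeded sizes chosen as this package's study
conditions: the classifier-recovery check uses the default 200-chain
corpus with epochs capped at 30 (patience 5); the feature-ablation check
uses 80-chain corpora over 5 seeds with epochs 20; the acceptance script
mirrors these sizes.  Library defaults stay at the full epochs ≤ 200 /
patience 10 schedule.  Networks train in float32 with the output layer
in float64 (probability sums hold to 1e-9).  Potential tables serialize
as JSON with zero cells omitted; counts use exact integer arithmetic.
Degenerate inputs fail loudly: constant-B chains, chains with fewer than
two measured B-factors, corpora missing a state, empty training sets and
width mismatches all raise typed errors rather than producing silent
zeros.
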