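# flexc

Sequence-based prediction of protein backbone flexibility.

Residue flexibility is read off crystallographic temperature factors:
B = 8π²U², where U² is the mean-squares displacement of the Cα atom.
Because B-factors from different structures are on different scales,
each chain is z-normalized, b = (B_raw − μ)/σ, and thresholded into
three states — Rigid (b < −1.1), Intermediate, Flexible (b > 2.2).
`flexc` trains a feed-forward classifier to predict these states from
sequence-derived information alone:

* **SCRS** — context-based scores from knowledge-based mean-force
  potentials U(C, x) = −ln(f̂(C|x)/f(C)) over singlet/doublet/triplet
  residue contexts in a 7-residue window;
* **PSSM** — PSI-BLAST evolutionary profiles (logistically scaled);
* **SS / SA** — predicted secondary-structure and solvent-accessibility
  probabilities from any external predictor;
* **AAP** — five physicochemical amino-acid properties.

Each residue is encoded over a 15-residue sliding window,
15 × (20+3+3+2+5+1) = 510 inputs, feeding a 250-hidden-unit network
evaluated by chain-level 7-fold cross-validation (5 training subsets,
1 validation, 1 test per fold) with per-state Q, overall Q3 and, in
two-state mode, the F-measure F = 2AC/(A+C).

A fully synthetic corpus generator (statistically structured chains,
B-factors, SS/SA, PSSMs, and files in every supported format) makes the
whole pipeline runnable and testable without any external data.
See `docs/methods.md` for the model details and the generator's scope.

## Worked example

```sh
flexc simulate --n-chains 120 --seed 5 --out run/
flexc derive-potentials --labels run/labels.tsv --out run/potentials.json
flexc encode --labels run/labels.tsv --pssm-dir run/pssm \
      --assign run/assignments_pred.tsv --potentials run/potentials.json \
      --out run/encodings.npz
flexc cross-validate --encodings run/encodings.npz --seed 1 \
      --epochs 30 --out run/cv.json
```

The last command prints, for this corpus and seed:

```
mean Q3 = 94.8%  (Q_R 84.8%, Q_I 97.8%, Q_F 0.0%)
```

Q3 is the fraction of residues whose flexibility state was predicted
correctly, averaged over the 7 test folds; Q_R/Q_I/Q_F are the per-state
recalls.  On synthetic data the Intermediate state dominates (most
residues fall in the middle of the normalized-B distribution), the Rigid
state is learned from structural context, and the rare Flexible tail is
hardly ever predicted — see the methods note for why the thresholds
make that class sparse.  A trained model can then be applied and scored:

```sh
flexc train --encodings run/encodings.npz --seed 1 --epochs 30 --out run/net.json
flexc predict --encodings run/encodings.npz --labels run/labels.tsv \
      --model run/net.json --out run/pred.tsv
flexc evaluate --pred run/pred.tsv --labels run/labels.tsv
```

which prints `Q3 = 96.0%  (Q_R 96.2%, Q_I 97.9%, Q_F 0.0%)` — higher
than the cross-validated figure because these predictions are on the
training corpus itself.

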