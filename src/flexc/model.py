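"""Feed-forward classifier and 7-fold cross-validation orchestration.

The architecture follows the classic secondary-structure-prediction
recipe: a single hidden layer of 250 sigmoidal units over the 510-value
window encoding, a softmax output over the flexibility states, and
mini-batch stochastic gradient descent with momentum on the cross-entropy
objective.  Early stopping monitors a held-out validation set and the
parameters achieving the best validation loss are restored.

The implementation is a compact, fully seeded numpy network: the training
contract here (caller-supplied validation chains, best-weight restore,
deterministic replay from a seed) is part of the cross-validation design,
so the optimizer is kept under the package's control rather than behind a
higher-level estimator interface.

Cross-validation splits by *chain*, never by residue, so windows from one
protein can never appear on both sides of a fold.  With 7 folds, fold j
uses subset j for validation, subset (j+1) mod 7 for testing and the
remaining 5 subsets for training; reported metrics are the unweighted
mean over the 7 test subsets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .chains import STATES3
from .evaluation import EvalReport, confusion_and_q


@dataclass
class NetworkConfig:
    """Architecture and training hyperparameters."""

    n_in: int = 510
    n_hidden: int = 250
    n_out: int = 3
    seed: int = 0
    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    batch_size: int = 128
    patience: int = 10

    def __post_init__(self) -> None:
        if self.n_hidden <= 0:
            raise ValueError("n_hidden must be positive")
        if self.n_out not in (2, 3):
            raise ValueError("n_out must be 2 or 3")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class FlexNetwork:
    """One-hidden-layer sigmoid/softmax classifier trained by SGD."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        # seeded uniform init scaled by fan-in
        lim1 = 1.0 / np.sqrt(config.n_in)
        lim2 = 1.0 / np.sqrt(config.n_hidden)
        self.W1 = rng.uniform(-lim1, lim1, (config.n_in, config.n_hidden)).astype(
            np.float32
        )
        self.b1 = np.zeros(config.n_hidden, dtype=np.float32)
        self.W2 = rng.uniform(-lim2, lim2, (config.n_hidden, config.n_out)).astype(
            np.float32
        )
        self.b2 = np.zeros(config.n_out, dtype=np.float32)
        self._rng = rng
        self.history: list[dict] = []

    # -- inference --------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.config.n_in:
            raise ValueError(
                f"input width {X.shape} does not match n_in={self.config.n_in}"
            )
        h = _sigmoid(X @ self.W1 + self.b1)
        # final layer in float64 so probabilities sum to 1 tightly
        return _softmax((h @ self.W2 + self.b2).astype(np.float64))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax states; ties resolve to the earlier state in (R, I, F)."""
        return np.argmax(self.predict_proba(X), axis=1)

    # -- training ---------------------------------------------------------
    def _loss(self, X: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(X)
        return float(-np.log(p[np.arange(len(y)), y] + 1e-12).mean())

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
    ) -> "FlexNetwork":
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.int64)
        X_val = np.asarray(X_val, dtype=np.float32)
        y_val = np.asarray(y_val, dtype=np.int64)
        if len(X) == 0:
            raise ValueError("empty training set")
        if X.shape[1] != cfg.n_in:
            raise ValueError(f"training width {X.shape[1]} != n_in {cfg.n_in}")

        onehot = np.zeros((len(y), cfg.n_out), dtype=np.float32)
        onehot[np.arange(len(y)), y] = 1.0

        vW1 = np.zeros_like(self.W1)
        vb1 = np.zeros_like(self.b1)
        vW2 = np.zeros_like(self.W2)
        vb2 = np.zeros_like(self.b2)

        best_loss = np.inf
        best = None
        bad_epochs = 0
        n = len(X)
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                xb, tb = X[sel], onehot[sel]
                h = _sigmoid(xb @ self.W1 + self.b1)
                p = _softmax(h @ self.W2 + self.b2)
                m = len(sel)
                d2 = (p - tb) / m  # dL/dz2 for mean cross-entropy
                gW2 = h.T @ d2
                gb2 = d2.sum(axis=0)
                d1 = (d2 @ self.W2.T) * h * (1.0 - h)
                gW1 = xb.T @ d1
                gb1 = d1.sum(axis=0)
                lr = np.float32(cfg.learning_rate)
                mom = np.float32(cfg.momentum)
                vW1 = mom * vW1 - lr * gW1
                vb1 = mom * vb1 - lr * gb1
                vW2 = mom * vW2 - lr * gW2
                vb2 = mom * vb2 - lr * gb2
                self.W1 += vW1
                self.b1 += vb1
                self.W2 += vW2
                self.b2 += vb2

            val_loss = self._loss(X_val, y_val) if len(X_val) else self._loss(X, y)
            self.history.append({"epoch": epoch, "val_loss": val_loss})
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best = (self.W1.copy(), self.b1.copy(), self.W2.copy(), self.b2.copy())
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        if best is not None:
            self.W1, self.b1, self.W2, self.b2 = best
        return self

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        doc = {
            "format": "flexc-network",
            "config": asdict(self.config),
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path: str | Path) -> "FlexNetwork":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "flexc-network":
            raise ValueError(f"{path}: not a network checkpoint")
        net = cls(NetworkConfig(**doc["config"]))
        net.W1 = np.array(doc["W1"], dtype=np.float32)
        net.b1 = np.array(doc["b1"], dtype=np.float32)
        net.W2 = np.array(doc["W2"], dtype=np.float32)
        net.b2 = np.array(doc["b2"], dtype=np.float32)
        return net


def train_network(
    config: NetworkConfig,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
) -> FlexNetwork:
    """Train a fresh network; fully reproducible given config.seed."""
    return FlexNetwork(config).fit(X, y, X_val, y_val)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ChainData:
    """Encoded windows and integer labels for one chain."""

    chain_id: str
    X: np.ndarray  # (L, width)
    y: np.ndarray  # (L,) indices into the state set


@dataclass
class CVPlan:
    n_folds: int
    assignment: dict[str, int]

    def fold_chains(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]


def make_cv_plan(chain_ids: Sequence[str], n_folds: int, seed: int) -> CVPlan:
    """Assign chains to folds by seeded shuffle; fold sizes differ by <= 1."""
    if len(chain_ids) < n_folds:
        raise ValueError(f"need >= {n_folds} chains, got {len(chain_ids)}")
    rng = np.random.default_rng(seed)
    order = list(chain_ids)
    rng.shuffle(order)
    return CVPlan(
        n_folds=n_folds,
        assignment={cid: i % n_folds for i, cid in enumerate(order)},
    )


@dataclass
class FoldResult:
    fold: int
    test_chains: list[str]
    report: EvalReport


@dataclass
class CVResult:
    plan: CVPlan
    folds: list[FoldResult]
    states: tuple[str, ...] = STATES3

    @property
    def mean_q3(self) -> float:
        return float(np.mean([f.report.q3 for f in self.folds]))

    def mean_q(self, state: str) -> Optional[float]:
        vals = [
            f.report.q_per_state[state]
            for f in self.folds
            if f.report.q_per_state.get(state) is not None
        ]
        return float(np.mean(vals)) if vals else None


def _stack(chains: Sequence[ChainData]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.concatenate([c.X for c in chains], axis=0),
        np.concatenate([c.y for c in chains], axis=0),
    )


def cross_validate_7fold(
    dataset: Sequence[ChainData],
    config: NetworkConfig,
    seed: int,
    n_folds: int = 7,
    states: Sequence[str] = STATES3,
) -> CVResult:
    """Chain-level N-fold cross-validation (default 7).

    For fold j, subset j is the validation set, subset (j+1) mod n_folds
    the test set, and the other subsets form the training set.  Each fold
    trains from scratch with a seed derived from ``seed`` and the fold
    index, so the whole procedure replays exactly.
    """
    plan = make_cv_plan([c.chain_id for c in dataset], n_folds, seed)
    by_id = {c.chain_id: c for c in dataset}
    folds: list[FoldResult] = []
    for j in range(n_folds):
        val_ids = set(plan.fold_chains(j))
        test_ids = set(plan.fold_chains((j + 1) % n_folds))
        train_ids = [
            c.chain_id for c in dataset if c.chain_id not in val_ids | test_ids
        ]
        X_tr, y_tr = _stack([by_id[c] for c in train_ids])
        X_va, y_va = _stack([by_id[c] for c in sorted(val_ids)])
        X_te, y_te = _stack([by_id[c] for c in sorted(test_ids)])
        fold_cfg = NetworkConfig(
            **{**asdict(config), "seed": (config.seed * n_folds + j) % (2**31)}
        )
        net = train_network(fold_cfg, X_tr, y_tr, X_va, y_va)
        pred = net.predict(X_te)
        report = confusion_and_q(
            [states[i] for i in y_te], [states[i] for i in pred], states=states
        )
        folds.append(FoldResult(fold=j, test_chains=sorted(test_ids), report=report))
    return CVResult(plan=plan, folds=folds, states=tuple(states))
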