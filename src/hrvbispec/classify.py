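"""Kappa-optimized one-hidden-layer MLP severity classifiers.

Binary severity classification at the three pediatric AHI cutoffs (1, 5 and
10 events/hour).  The network is a single-hidden-layer perceptron with
logistic activations and one logistic output neuron giving the posterior
probability of the severe side of the cutoff.  Weights minimize mean
cross-entropy plus a squared-weight penalty (lambda / n) * sum(w^2) (biases
unpenalized).  Hidden-layer size N_H and penalty weight lambda are tuned on a
grid — N_H in {2..20 step 1} union {22..50 step 2}, lambda in {0.5..10 step
0.5}, 680 combinations — by maximizing Cohen's kappa averaged over bootstrap
replicates, evaluated on each replicate's out-of-bag subjects.

The optimizer backend is scikit-learn's MLPClassifier (logistic activation,
L-BFGS solver, alpha = 2 * lambda, which reproduces the penalty above since
sklearn adds (alpha / 2n) * sum(w^2) and likewise excludes biases).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neural_network import MLPClassifier

AHI_CUTOFFS = (1.0, 5.0, 10.0)


def default_grid() -> list[tuple[int, float]]:
    """The (N_H, lambda) search grid: (19 + 15) x 20 = 680 combinations."""
    n_h = list(range(2, 21)) + list(range(22, 51, 2))
    lambdas = [0.5 * k for k in range(1, 21)]
    return [(h, lam) for h in n_h for lam in lambdas]


@dataclass(frozen=True)
class MLPSpec:
    n_hidden: int
    lam: float
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6


@dataclass
class TrainedModel:
    """A fitted MLP plus the training standardization statistics."""

    spec: MLPSpec
    net: MLPClassifier
    mean: np.ndarray
    scale: np.ndarray

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": {
                "n_hidden": self.spec.n_hidden,
                "lambda": self.spec.lam,
                "seed": self.spec.seed,
            },
            "standardization": {
                "mean": self.mean.tolist(),
                "scale": self.scale.tolist(),
            },
            "weights": [w.tolist() for w in self.net.coefs_],
            "biases": [b.tolist() for b in self.net.intercepts_],
        }
        Path(path).write_text(json.dumps(payload))


def train_mlp(X: np.ndarray, y: np.ndarray, spec: MLPSpec) -> TrainedModel:
    """Fit the regularized MLP; deterministic given ``spec.seed``.

    Features are standardized with training-set mean/SD (stored on the model
    so test data is transformed with training statistics only).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.any(~np.isfinite(X)):
        raise ValueError("features contain NaN/inf")
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for training")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    net = MLPClassifier(
        hidden_layer_sizes=(spec.n_hidden,),
        activation="logistic",
        solver="lbfgs",
        alpha=2.0 * spec.lam,
        max_iter=spec.max_iter,
        tol=spec.tol,
        random_state=spec.seed,
    )
    net.fit(Xs, y)
    return TrainedModel(spec=spec, net=net, mean=mean, scale=scale)


def predict_posterior(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Posterior probability of the positive class, in (0, 1)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.mean.size:
        raise ValueError("feature count mismatch with the trained model")
    p = model.net.predict_proba(model.standardize(X))[:, 1]
    eps = np.finfo(float).tiny
    return np.clip(p, eps, 1 - eps)


def cohens_kappa(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Chance-corrected agreement k = (p_o - p_e) / (1 - p_e).

    When both sequences are constant and equal (p_e = 1, perfect trivial
    agreement) kappa is defined as 1.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    n = y_true.size
    classes = np.union1d(y_true, y_pred)
    t = np.searchsorted(classes, y_true)
    p = np.searchsorted(classes, y_pred)
    k = classes.size
    table = np.zeros((k, k))
    np.add.at(table, (t, p), 1.0)
    p_o = np.trace(table) / n
    p_e = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    if p_e >= 1.0:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def optimize_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    grid: list[tuple[int, float]] | None = None,
    B: int = 1000,
    seed: int = 0,
    max_redraws: int = 50,
) -> tuple[tuple[int, float], dict[tuple[int, float], float]]:
    """Grid search over (N_H, lambda) maximizing bootstrap-averaged kappa.

    For every grid point, ``B`` bootstrap replicates are drawn (shared across
    grid points so the comparison is paired); the model trains on the
    replicate and kappa is computed on its out-of-bag subjects.  Replicates
    whose bootstrap sample or out-of-bag set is single-class are redrawn.
    Ties break toward smaller N_H, then smaller lambda.

    Returns the winning (N_H, lambda) and the mean-kappa map.
    """
    grid = grid if grid is not None else default_grid()
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    replicates = []
    draws = 0
    while len(replicates) < B:
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if np.unique(y[idx]).size < 2 or oob.size == 0 or np.unique(y[oob]).size < 2:
            draws += 1
            if draws > B + max_redraws * B:
                raise RuntimeError("could not draw two-class bootstrap replicates")
            continue
        replicates.append((idx, oob))

    scores: dict[tuple[int, float], float] = {}
    for n_h, lam in grid:
        kappas = []
        for r, (idx, oob) in enumerate(replicates):
            model = train_mlp(X[idx], y[idx], MLPSpec(n_h, lam, seed=seed + r))
            pred = (predict_posterior(model, X[oob]) >= 0.5).astype(int)
            kappas.append(cohens_kappa(y[oob], pred))
        scores[(n_h, lam)] = float(np.mean(kappas))

    best = max(scores, key=lambda g: (scores[g], -g[0], -g[1]))
    return best, scores


def severity_label(ahi: np.ndarray, cutoff: float) -> np.ndarray:
    """Binary label: 1 where AHI >= cutoff."""
    return (np.asarray(ahi, dtype=float) >= cutoff).astype(int)
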