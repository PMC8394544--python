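"""Fast correlation-based filter (FCBF) feature selection with bootstrap voting.

FCBF ranks features by symmetrical uncertainty with the class label,
SU(x, y) = 2 I(x; y) / (H(x) + H(y)), then removes any feature that is more
strongly associated with an already-kept feature than with the label (the
predominance test), yielding a relevant, non-redundant subset.  Stability is
obtained by rerunning FCBF on bootstrap resamples of the cohort and keeping
the features selected in strictly more than half of the replicates
(B = 1000 replicates, votes > 500 by default).

Continuous features are discretized per replicate with equal-frequency
binning (rank-based, so selection is invariant to monotone transforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_B = 1000
DEFAULT_THRESHOLD = 500
DEFAULT_N_BINS = 10


def discretize_equal_frequency(x: np.ndarray, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Rank-based equal-frequency binning into integer codes."""
    x = np.asarray(x, dtype=float)
    # qcut on ranks: duplicate quantile edges collapse automatically
    codes = pd.qcut(
        pd.Series(x).rank(method="average"), q=n_bins, labels=False, duplicates="drop"
    )
    return np.asarray(codes, dtype=int)


def _entropy_from_counts(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(x, y) = 2 I(x; y) / (H(x) + H(y)), on discrete codes, in [0, 1].

    A constant variable carries no information; SU is defined as 0 there
    (with a warning) rather than 0/0.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    xi = pd.factorize(x)[0]
    yi = pd.factorize(y)[0]
    nx, ny = xi.max() + 1, yi.max() + 1
    if nx < 2 or ny < 2:
        warnings.warn("constant variable: SU defined as 0", stacklevel=2)
        return 0.0
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xi, yi), 1.0)
    hx = _entropy_from_counts(joint.sum(axis=1))
    hy = _entropy_from_counts(joint.sum(axis=0))
    hxy = _entropy_from_counts(joint.ravel())
    mi = hx + hy - hxy
    su = 2.0 * mi / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


def fcbf(X: np.ndarray, y: np.ndarray, feature_names: list[str] | None = None) -> list[str]:
    """Standard FCBF on a discretized feature matrix.

    Features are ranked by SU with the label (descending; ties broken by
    column order for reproducibility); a candidate is kept unless some
    already-kept feature g satisfies SU(candidate, g) >= SU(candidate, y).
    The relevance threshold is zero: every feature with SU > 0 enters the
    ranking.  Returns kept feature names in ranking order.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one feature")
    names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    su_y = np.array([symmetrical_uncertainty(X[:, j], y) for j in range(X.shape[1])])
    order = sorted(range(X.shape[1]), key=lambda j: (-su_y[j], j))
    kept: list[int] = []
    for j in order:
        if su_y[j] <= 0:
            continue
        predominant = True
        for g in kept:
            if symmetrical_uncertainty(X[:, j], X[:, g]) >= su_y[j]:
                predominant = False
                break
        if predominant:
            kept.append(j)
    return [names[j] for j in kept]


@dataclass
class SelectionResult:
    """Bootstrap vote counts and the resulting selected subset."""

    votes: dict[str, int]
    B: int
    threshold: int
    selected: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.selected:
            # strictly more than `threshold` votes; stable column order
            self.selected = [f for f, v in self.votes.items() if v > self.threshold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.votes),
                "votes": list(self.votes.values()),
                "selected": [f in self.selected for f in self.votes],
            }
        )


def bootstrap_select(
    features: pd.DataFrame,
    y: np.ndarray | pd.Series,
    B: int = DEFAULT_B,
    threshold: int = DEFAULT_THRESHOLD,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
) -> SelectionResult:
    """FCBF over ``B`` bootstrap replicates; features with votes > threshold win.

    Discretization (equal-frequency, ``n_bins`` bins) is recomputed inside
    each replicate.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    if features.empty:
        raise ValueError("empty feature table")
    y = np.asarray(y)
    names = list(features.columns)
    Xraw = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    votes = {f: 0 for f in names}
    n = Xraw.shape[0]
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        Xb = np.column_stack(
            [discretize_equal_frequency(Xraw[idx, j], n_bins) for j in range(Xraw.shape[1])]
        )
        for f in fcbf(Xb, y[idx], names):
            votes[f] += 1
    return SelectionResult(votes=votes, B=B, threshold=threshold)
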