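"""Direct-method bispectrum estimation and total-magnitude normalization.

The bispectrum B(f1, f2) = X(f1) X(f2) X*(f1 + f2) measures quadratic phase
coupling between components at f1, f2 and f1 + f2; its expectation vanishes
for Gaussian signals.  The estimator here is the direct (segment-averaging)
method: Hamming-windowed, mean-removed segments with 50% overlap, an FFT of
``nfft`` points, and the triple product averaged across segments.  The stored
matrix covers the first quadrant f1, f2 in [0, f_N] restricted to the
computable support f1 + f2 <= f_N.

Normalization divides every element by the scalar BP = sum of all magnitudes
over the stored support, bounding magnitudes in [0, 1] and removing overall
scale (reducing inter-subject variability unrelated to the quantity of
interest); phases are untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import UniformHRV


@dataclass(frozen=True)
class SegmentPlan:
    """Segmentation/FFT parameters for the direct bispectrum estimator."""

    window_len: int = 1024
    overlap: float = 0.5
    nfft: int = 2048
    detrend: str = "mean"

    def __post_init__(self) -> None:
        if self.nfft < self.window_len:
            raise ValueError("nfft must be >= window length")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def step(self) -> int:
        return int(round(self.window_len * (1 - self.overlap)))


@dataclass
class BispectrumMatrix:
    """Complex bifrequency matrix on the first-quadrant support f1+f2 <= f_N.

    ``values[k1, k2]`` corresponds to bifrequency (k1 df, k2 df) with
    df = fs / nfft; entries outside the support are zero.
    """

    values: np.ndarray  # complex, shape (K+1, K+1) with K = nfft // 2
    fs: float
    nfft: int
    n_segments: int
    normalized: bool = False
    bp: float = 0.0  # total bispectral power (sum of magnitudes) pre-division

    @property
    def freq_axis(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) * self.fs / self.nfft

    @property
    def df(self) -> float:
        return self.fs / self.nfft

    def support_mask(self) -> np.ndarray:
        k = np.arange(self.values.shape[0])
        return k[:, None] + k[None, :] <= self.nfft // 2

    def total_magnitude(self) -> float:
        return float(np.abs(self.values[self.support_mask()]).sum())


def segment_view(x: np.ndarray, plan: SegmentPlan) -> np.ndarray:
    """Stack the overlapping analysis segments as rows."""
    n = x.size
    if n < plan.window_len:
        raise ValueError("signal shorter than one analysis window")
    starts = np.arange(0, n - plan.window_len + 1, plan.step)
    return np.stack([x[s : s + plan.window_len] for s in starts])


def estimate_bispectrum(
    x: UniformHRV | np.ndarray, plan: SegmentPlan | None = None, fs: float | None = None
) -> BispectrumMatrix:
    """Segment-averaged direct bispectrum estimate of a uniform signal."""
    plan = plan or SegmentPlan()
    if isinstance(x, UniformHRV):
        sig, fs_ = x.values, x.fs
    else:
        sig = np.asarray(x, dtype=float)
        if fs is None:
            raise ValueError("fs is required for a bare array input")
        fs_ = fs
    if np.any(~np.isfinite(sig)):
        raise ValueError("input contains NaN/inf")

    segs = segment_view(sig, plan)
    if plan.detrend == "mean":
        segs = segs - segs.mean(axis=1, keepdims=True)
    elif plan.detrend not in (None, "none"):
        raise ValueError(f"unknown detrend mode: {plan.detrend}")
    win = np.hamming(plan.window_len)
    segs = segs * win

    half = plan.nfft // 2
    k = np.arange(half + 1)
    sum_idx = k[:, None] + k[None, :]
    support = sum_idx <= half
    sum_idx = np.where(support, sum_idx, 0)  # out-of-support entries are zeroed

    acc = np.zeros((half + 1, half + 1), dtype=complex)
    buf = np.empty_like(acc)
    for seg in segs:
        X = np.fft.fft(seg, plan.nfft)
        Xh = X[: half + 1]
        np.multiply(Xh[:, None], Xh[None, :], out=buf)
        buf *= np.conj(X)[sum_idx]
        acc += buf
    acc[~support] = 0.0  # clipped gather leaves garbage only off-support
    acc /= segs.shape[0]

    B = BispectrumMatrix(
        values=acc, fs=fs_, nfft=plan.nfft, n_segments=segs.shape[0]
    )
    B.bp = B.total_magnitude()
    return B


def normalize_bispectrum(B: BispectrumMatrix) -> BispectrumMatrix:
    """Divide every element by the scalar BP = sum of support magnitudes.

    Idempotent; phases are unchanged and the normalized magnitudes sum to 1.
    """
    if B.normalized:
        return B
    bp = B.total_magnitude()
    if bp <= 0:
        raise ValueError("degenerate bispectrum: total magnitude is zero")
    return BispectrumMatrix(
        values=B.values / bp,
        fs=B.fs,
        nfft=B.nfft,
        n_segments=B.n_segments,
        normalized=True,
        bp=bp,
    )


def roi_mask(nbins: int, nfft: int) -> np.ndarray:
    """Boolean mask of the non-redundant triangle 0 <= f1 <= f2, f1+f2 <= f_N.

    ``nbins`` is the per-axis grid size (nfft // 2 + 1 on the standard grid).
    """
    k = np.arange(nbins)
    return (k[:, None] <= k[None, :]) & (k[:, None] + k[None, :] <= nfft // 2)


def roi_bins(nbins: int, nfft: int) -> list[tuple[int, int]]:
    """The ROI as an explicit (k1, k2) bin list, k1 <= k2."""
    m = roi_mask(nbins, nfft)
    i, j = np.nonzero(m)
    return list(zip(i.tolist(), j.tolist()))


def diagonal_profile(B: BispectrumMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Magnitudes along f1 = f2 and their whole-diagonal normalization.

    Returns (Diag, DiagN) with Diag(k) = |B(f_k, f_k)| over the computable
    diagonal (2 f_k <= f_N) and DiagN = Diag / DP, DP = sum(Diag); the
    normalized profile sums to one.
    """
    half = B.nfft // 2
    kmax = half // 2  # diagonal support: k + k <= nfft // 2
    diag = np.abs(np.diagonal(B.values)[: kmax + 1]).copy()
    dp = diag.sum()
    if dp <= 0:
        raise ValueError("degenerate diagonal: zero total magnitude")
    return diag, diag / dp


def average_bispectra(mats: list[BispectrumMatrix]) -> BispectrumMatrix:
    """Complex mean of bispectrum estimates from independent realizations.

    Coherent (phase-coupled) structure adds constructively across
    realizations while random-phase contributions cancel — the standard
    ensemble test for quadratic phase coupling.
    """
    if not mats:
        raise ValueError("no matrices to average")
    ref = mats[0]
    for m in mats[1:]:
        if m.values.shape != ref.values.shape or m.nfft != ref.nfft:
            raise ValueError("incompatible bispectrum grids")
    vals = np.mean([m.values for m in mats], axis=0)
    out = BispectrumMatrix(
        values=vals,
        fs=ref.fs,
        nfft=ref.nfft,
        n_segments=sum(m.n_segments for m in mats),
    )
    out.bp = out.total_magnitude()
    return out
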