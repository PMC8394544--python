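"""Bispectral region construction on the bifrequency grid.

Six square band-by-band regions intersected with the non-redundant ROI
triangle: the classic HRV bands (VLF 0-0.04 Hz, LF 0.04-0.15 Hz, HF
0.15-0.40 Hz) and the OSA-specific bands (BW1 0.001-0.005 Hz, BW2
0.028-0.074 Hz, and BWRes, a subject-adaptive 0.04 Hz-wide band centered on
the respiratory spectral peak inside HF).  Bands are half-open [lo, hi)
except each family's topmost edge, which is closed, so boundary bins are
never double-counted within a family.  BWRes carries no diagonal features:
its band tracks the respiratory peak rather than the matrix diagonal, so
f1 = f2 bins lose their harmonic-coupling interpretation there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import welch

from .bispectrum import BispectrumMatrix, roi_mask
from .preprocess import UniformHRV

CLASSIC_BANDS = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.40)}
SPECIFIC_STATIC_BANDS = {"BW1": (0.001, 0.005), "BW2": (0.028, 0.074)}
HF_BAND = (0.15, 0.40)
BWRES_HALF_WIDTH = 0.02  # Hz; 0.04 Hz total width around the respiratory peak


@dataclass
class RegionSpec:
    """A named set of bifrequency bins bounded by one frequency band."""

    name: str
    band: tuple[float, float]
    bins: list[tuple[int, int]]
    diag_bins: list[int] = field(default_factory=list)
    has_diagonal_features: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.bins)


def _band_region(
    name: str,
    band: tuple[float, float],
    df: float,
    nfft: int,
    closed_top: bool,
    has_diagonal_features: bool = True,
) -> RegionSpec:
    """band x band square intersected with the ROI triangle, by nearest bin."""
    lo, hi = band
    nbins = nfft // 2 + 1
    k = np.arange(nbins)
    f = k * df
    if closed_top:
        in_band = (f >= lo - 1e-12) & (f <= hi + 1e-12)
    else:
        in_band = (f >= lo - 1e-12) & (f < hi - 1e-12)
    roi = roi_mask(nbins, nfft)
    member = in_band[:, None] & in_band[None, :] & roi
    i, j = np.nonzero(member)
    bins = list(zip(i.tolist(), j.tolist()))
    diag = [a for a, b in bins if a == b]
    return RegionSpec(
        name=name,
        band=(lo, hi),
        bins=bins,
        diag_bins=diag,
        has_diagonal_features=has_diagonal_features,
    )


def classic_regions(fs: float, nfft: int) -> dict[str, RegionSpec]:
    """VLF, LF and HF bispectral regions on the (fs, nfft) grid."""
    if fs / 2 < HF_BAND[1]:
        raise ValueError("grid Nyquist must reach 0.4 Hz")
    df = fs / nfft
    out = {}
    top = max(b[1] for b in CLASSIC_BANDS.values())
    for name, band in CLASSIC_BANDS.items():
        out[name] = _band_region(name, band, df, nfft, closed_top=band[1] == top)
    return out


def specific_static_regions(fs: float, nfft: int) -> dict[str, RegionSpec]:
    """The fixed OSA-specific regions BW1 and BW2."""
    df = fs / nfft
    return {
        name: _band_region(name, band, df, nfft, closed_top=False)
        for name, band in SPECIFIC_STATIC_BANDS.items()
    }


def respiratory_peak(
    x: UniformHRV, band: tuple[float, float] = HF_BAND, nperseg: int = 1024
) -> float:
    """Frequency of the Welch-PSD maximum inside the HF (respiratory) band."""
    nperseg = min(nperseg, x.values.size)
    f, p = welch(
        x.values, fs=x.fs, window="hamming", nperseg=nperseg, noverlap=nperseg // 2
    )
    sel = (f >= band[0]) & (f <= band[1])
    if not np.any(sel):
        raise ValueError("empty HF spectrum on this grid")
    return float(f[sel][np.argmax(p[sel])])


def locate_bwres(x: UniformHRV, fs: float, nfft: int) -> RegionSpec:
    """Subject-adaptive BWRes region around the respiratory spectral peak.

    The band is f_peak +/- 0.02 Hz, clipped to the physiologic respiratory
    range [0.15, 0.40] Hz; diagonal features are excluded by contract.
    """
    f_peak = respiratory_peak(x)
    lo = max(f_peak - BWRES_HALF_WIDTH, HF_BAND[0])
    hi = min(f_peak + BWRES_HALF_WIDTH, HF_BAND[1])
    df = fs / nfft
    reg = _band_region(
        "BWRes", (lo, hi), df, nfft, closed_top=True, has_diagonal_features=False
    )
    return reg


def all_regions(
    x: UniformHRV, B: BispectrumMatrix
) -> dict[str, RegionSpec]:
    """All six regions for one subject on the bispectrum's grid."""
    out = {}
    out.update(classic_regions(B.fs, B.nfft))
    out.update(specific_static_regions(B.fs, B.nfft))
    out["BWRes"] = locate_bwres(x, B.fs, B.nfft)
    return out


def region_report(regions: dict[str, RegionSpec]) -> list[dict]:
    """JSON-serializable per-region summary (name, band, bin counts)."""
    return [
        {
            "name": r.name,
            "band_hz": [float(r.band[0]), float(r.band[1])],
            "n_bins": r.n_bins,
            "n_diag_bins": len(r.diag_bins),
            "has_diagonal_features": r.has_diagonal_features,
        }
        for r in regions.values()
    ]
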