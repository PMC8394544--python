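"""Per-region bispectral features and cohort feature tables.

Fourteen features characterize each bispectral region Omega of the normalized
bispectrum B_N:

* amplitudes — B_max, B_min (extreme magnitudes) and B_total (summed
  magnitude, a Gaussianity-deviation measure);
* entropies — BE_i (Shannon entropy of the region's magnitude distribution
  raised to power i = 1, 2, 3) and PE (entropy of the region's phase-angle
  histogram);
* moments — H_1 (sum of log-magnitudes over the region), H_2 (over the
  region diagonal), and the first/second diagonal moments H_3, H_4;
* weighted center of bispectrum — f1m, f2m, the magnitude-weighted centroid
  of the region's bifrequencies (the coupling focus);
* RP_Diag — the share of the *whole-diagonal* bispectral magnitude that
  falls inside the region's diagonal, computed on a linear scale after
  normalizing the full diagonal profile to unit sum.  Unlike H_2 it sees the
  redistribution of diagonal power to frequencies outside the region.

Diagonal-dependent features (H_2, H_3, H_4, RP_Diag) are excluded for BWRes,
whose subject-adaptive band need not be centered on the matrix diagonal.
Hence the classic catalog holds 3 x 14 = 42 columns and the OSA-specific
catalog 14 + 14 + 10 = 38.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bispectrum import (
    BispectrumMatrix,
    SegmentPlan,
    diagonal_profile,
    estimate_bispectrum,
    normalize_bispectrum,
)
from .preprocess import UniformHRV
from .regions import RegionSpec, all_regions

logger = logging.getLogger(__name__)

#: floor applied to normalized magnitudes before taking logs
LOG_FLOOR = 1e-15
#: default phase-histogram bin count
PHASE_BINS = 64

FEATURE_ORDER = (
    "B_max",
    "B_min",
    "B_total",
    "BE_1",
    "BE_2",
    "BE_3",
    "PE",
    "H_1",
    "H_2",
    "H_3",
    "H_4",
    "f1m",
    "f2m",
    "RP_Diag",
)
DIAGONAL_FEATURES = ("H_2", "H_3", "H_4", "RP_Diag")

CLASSIC_REGIONS = ("VLF", "LF", "HF")
SPECIFIC_REGIONS = ("BW1", "BW2", "BWRes")

LABEL_COLUMNS = ("ahi", "age", "severity")


def catalog_columns(catalog: str) -> list[str]:
    """Ordered feature-column names for the 'classic' or 'specific' catalog."""
    if catalog == "classic":
        region_names = CLASSIC_REGIONS
    elif catalog == "specific":
        region_names = SPECIFIC_REGIONS
    else:
        raise ValueError("catalog must be 'classic' or 'specific'")
    cols = []
    for rn in region_names:
        for feat in FEATURE_ORDER:
            if rn == "BWRes" and feat in DIAGONAL_FEATURES:
                continue
            cols.append(f"{rn}_{feat}")
    return cols


def _region_mags(B: BispectrumMatrix, region: RegionSpec) -> np.ndarray:
    idx = np.asarray(region.bins)
    return np.abs(B.values[idx[:, 0], idx[:, 1]])


def amplitude_features(
    B: BispectrumMatrix, region: RegionSpec
) -> tuple[float, float, float]:
    """(B_max, B_min, B_total): extreme and summed magnitudes over the region."""
    if not region.bins:
        raise ValueError(f"region {region.name} has no bins")
    mags = _region_mags(B, region)
    return float(mags.max()), float(mags.min()), float(mags.sum())


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def bispectral_entropy(B: BispectrumMatrix, region: RegionSpec, order: int) -> float:
    """BE_i: Shannon entropy of |B_N|^i normalized over the region (nats)."""
    if order not in (1, 2, 3):
        raise ValueError("entropy order must be 1, 2 or 3")
    mags = _region_mags(B, region) ** order
    total = mags.sum()
    if total <= 0:
        raise ValueError(f"region {region.name} has zero magnitude")
    return _shannon(mags / total)


def phase_entropy(
    B: BispectrumMatrix, region: RegionSpec, n_bins: int = PHASE_BINS
) -> float:
    """PE: Shannon entropy of the region's phase histogram over [-pi, pi)."""
    if n_bins < 2:
        raise ValueError("need at least two phase bins")
    if not region.bins:
        raise ValueError(f"region {region.name} has no bins")
    idx = np.asarray(region.bins)
    phases = np.angle(B.values[idx[:, 0], idx[:, 1]])
    # bins Psi_n = [-pi + 2 pi n / N, -pi + 2 pi (n+1) / N); angle() returns
    # values in (-pi, pi], so +pi folds into the top bin
    bin_idx = np.floor((phases + np.pi) * n_bins / (2 * np.pi)).astype(int)
    bin_idx = np.clip(bin_idx, 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins)
    return _shannon(counts / counts.sum())


def moment_features(
    B: BispectrumMatrix, region: RegionSpec, floor: float = LOG_FLOOR
) -> tuple[float, float, float, float]:
    """(H_1, H_2, H_3, H_4): log-magnitude sums and diagonal moments.

    H_1 sums log|B_N| over the whole region; H_2 over the region's diagonal;
    H_3 = sum_k k log|B_N(f_k, f_k)| and H_4 = sum_k (k - H_3)^2 log|B_N|,
    with k the 1-based position along the region's diagonal.  Magnitudes are
    floored at ``floor`` before the log so normalized values cannot underflow
    to -inf.
    """
    if not region.has_diagonal_features:
        raise ValueError(
            f"diagonal features excluded for region {region.name}"
        )
    mags = np.maximum(_region_mags(B, region), floor)
    h1 = float(np.log(mags).sum())
    if not region.diag_bins:
        raise ValueError(f"region {region.name} has an empty diagonal")
    diag_mags = np.maximum(
        np.abs(B.values[region.diag_bins, region.diag_bins]), floor
    )
    logs = np.log(diag_mags)
    h2 = float(logs.sum())
    k = np.arange(1, logs.size + 1, dtype=float)
    h3 = float((k * logs).sum())
    h4 = float((((k - h3) ** 2) * logs).sum())
    return h1, h2, h3, h4


def h1_only(B: BispectrumMatrix, region: RegionSpec, floor: float = LOG_FLOOR) -> float:
    """H_1 for regions whose diagonal features are excluded (BWRes)."""
    mags = np.maximum(_region_mags(B, region), floor)
    return float(np.log(mags).sum())


def wcob(B: BispectrumMatrix, region: RegionSpec) -> tuple[float, float]:
    """Weighted center of bispectrum (f1m, f2m), weights |B_N| (Hz)."""
    idx = np.asarray(region.bins)
    w = np.abs(B.values[idx[:, 0], idx[:, 1]])
    total = w.sum()
    if total <= 0:
        raise ValueError(f"region {region.name} has zero total weight")
    df = B.df
    f1m = float((idx[:, 0] * df * w).sum() / total)
    f2m = float((idx[:, 1] * df * w).sum() / total)
    return f1m, f2m


def rp_diag(B: BispectrumMatrix, region: RegionSpec) -> float:
    """Relative diagonal power: region share of the unit-sum diagonal profile.

    The full bispectral diagonal is normalized to unit total magnitude
    (DiagN); RP_Diag sums DiagN over the region's diagonal bins, on a linear
    scale, so it reads as the proportion of all harmonic self-coupling
    (f3 = 2 f1) power that the region captures.
    """
    if not region.has_diagonal_features:
        raise ValueError(f"diagonal features excluded for region {region.name}")
    _, diag_n = diagonal_profile(B)
    ks = [k for k in region.diag_bins if k < diag_n.size]
    return float(diag_n[ks].sum()) if ks else 0.0


def region_features(
    B: BispectrumMatrix,
    region: RegionSpec,
    phase_bins: int = PHASE_BINS,
) -> dict[str, float]:
    """All features for one region, respecting the diagonal exclusion."""
    if not B.normalized:
        raise ValueError("features are defined on the normalized bispectrum")
    bmax, bmin, btot = amplitude_features(B, region)
    out = {
        "B_max": bmax,
        "B_min": bmin,
        "B_total": btot,
        "BE_1": bispectral_entropy(B, region, 1),
        "BE_2": bispectral_entropy(B, region, 2),
        "BE_3": bispectral_entropy(B, region, 3),
        "PE": phase_entropy(B, region, phase_bins),
    }
    if region.has_diagonal_features:
        h1, h2, h3, h4 = moment_features(B, region)
        out.update({"H_1": h1, "H_2": h2, "H_3": h3, "H_4": h4})
        out["RP_Diag"] = rp_diag(B, region)
    else:
        out["H_1"] = h1_only(B, region)
    f1m, f2m = wcob(B, region)
    out["f1m"] = f1m
    out["f2m"] = f2m
    return out


@dataclass
class SubjectFeatures:
    """Feature rows (classic and specific) for one preprocessed subject."""

    classic: dict[str, float]
    specific: dict[str, float]


def subject_features(
    x: UniformHRV,
    plan: SegmentPlan | None = None,
    phase_bins: int = PHASE_BINS,
) -> SubjectFeatures:
    """Estimate, normalize and featurize one subject's HRV bispectrum."""
    B = normalize_bispectrum(estimate_bispectrum(x, plan or SegmentPlan()))
    regions = all_regions(x, B)
    classic: dict[str, float] = {}
    specific: dict[str, float] = {}
    for rn in CLASSIC_REGIONS:
        feats = region_features(B, regions[rn], phase_bins)
        classic.update({f"{rn}_{k}": v for k, v in feats.items()})
    for rn in SPECIFIC_REGIONS:
        feats = region_features(B, regions[rn], phase_bins)
        specific.update({f"{rn}_{k}": v for k, v in feats.items()})
    return SubjectFeatures(classic=classic, specific=specific)


def extract_feature_table(
    subjects: list[tuple[dict, UniformHRV]],
    plan: SegmentPlan | None = None,
    phase_bins: int = PHASE_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort feature tables (classic, specific) with AHI/age/severity labels.

    ``subjects`` pairs a label dict (subject_id, ahi, age, severity) with the
    subject's uniformly resampled HRV signal.  A subject whose feature
    extraction fails is logged and dropped, never silently imputed.
    Returns DataFrames indexed by subject_id whose feature columns follow the
    classic (42) and OSA-specific (38) catalogs.
    """
    classic_rows, specific_rows, kept = [], [], []
    for labels, x in subjects:
        try:
            sf = subject_features(x, plan, phase_bins)
        except Exception as exc:  # noqa: BLE001 - per-subject isolation
            logger.warning(
                "dropping subject %s: %s", labels.get("subject_id", "?"), exc
            )
            continue
        kept.append(labels)
        classic_rows.append(sf.classic)
        specific_rows.append(sf.specific)

    idx = pd.Index(
        [lab.get("subject_id", str(i)) for i, lab in enumerate(kept)],
        name="subject_id",
    )
    label_df = pd.DataFrame(
        [{k: lab.get(k) for k in LABEL_COLUMNS} for lab in kept], index=idx
    )
    classic = pd.DataFrame(
        classic_rows, index=idx, columns=catalog_columns("classic")
    )
    specific = pd.DataFrame(
        specific_rows, index=idx, columns=catalog_columns("specific")
    )
    return pd.concat([classic, label_df], axis=1), pd.concat(
        [specific, label_df], axis=1
    )


def feature_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Feature columns only (labels stripped)."""
    return table.drop(columns=[c for c in LABEL_COLUMNS if c in table.columns])
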