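"""Shared fixtures: toy bispectra, QPC ensembles, and a cached synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from hrvbispec import features as ft
from hrvbispec import preprocess as pp
from hrvbispec import synthetic as syn
from hrvbispec.bispectrum import (
    BispectrumMatrix,
    SegmentPlan,
    average_bispectra,
    estimate_bispectrum,
    roi_mask,
)
from hrvbispec.regions import RegionSpec


def make_matrix(values: np.ndarray, fs: float = 1.0, nfft: int | None = None,
                normalized: bool = True) -> BispectrumMatrix:
    """Wrap an explicit complex matrix for closed-form feature tests.

    ``nfft`` defaults to a value large enough that the whole matrix lies on
    the computable support.
    """
    values = np.asarray(values, dtype=complex)
    n = values.shape[0]
    nfft = nfft if nfft is not None else 4 * n
    return BispectrumMatrix(
        values=values, fs=fs, nfft=nfft, n_segments=1, normalized=normalized
    )


def make_region(bins, name: str = "toy", band=(0.0, 1.0),
                has_diagonal_features: bool = True) -> RegionSpec:
    bins = [tuple(b) for b in bins]
    return RegionSpec(
        name=name,
        band=band,
        bins=bins,
        diag_bins=[a for a, b in bins if a == b],
        has_diagonal_features=has_diagonal_features,
    )


# --- QPC ensemble -----------------------------------------------------------

QPC_FS = 3.41
QPC_N = 512
QPC_PLAN = SegmentPlan(window_len=512, overlap=0.5, nfft=512)
QPC_DF = QPC_FS / 512
QPC_K1, QPC_K2 = 30, 45
QPC_NOISE_SD = 8.0  # per-bin SNR ~ 1.2: the triad sits near the noise floor


def qpc_peak_ratio(coupled: bool, n_realizations: int, seed0: int) -> float:
    """Peak-to-background ratio of the realization-averaged bispectrum.

    Background is the median nonzero ROI magnitude.  Coherent (coupled)
    triads survive the complex average; uncoupled ones cancel toward it.
    """
    f1, f2 = QPC_K1 * QPC_DF, QPC_K2 * QPC_DF
    mats = [
        estimate_bispectrum(
            syn.simulate_qpc_signal(
                f1, f2, coupled, QPC_N, QPC_FS, seed=seed0 + i,
                noise_sd=QPC_NOISE_SD,
            ),
            QPC_PLAN,
        )
        for i in range(n_realizations)
    ]
    avg = average_bispectra(mats)
    mask = roi_mask(avg.values.shape[0], avg.nfft)
    vals = np.abs(avg.values[mask])
    background = np.median(vals[vals > 0])
    return float(abs(avg.values[QPC_K1, QPC_K2]) / background)


# --- cached synthetic cohort -------------------------------------------------

COHORT_SEED = 2024
COHORT_N = 60


@pytest.fixture(scope="session")
def cohort_tables():
    """Feature tables (classic, specific) for a 60-subject synthetic cohort.

    Session-scoped: the cohort backs the direction-of-effect, catalog-shape
    and characterization tests.
    """
    cohort = syn.generate_cohort(COHORT_N, seed=COHORT_SEED)
    subjects = []
    for prof, cfg in cohort:
        x = pp.preprocess_rr(syn.simulate_rr(prof, cfg))
        labels = dict(
            subject_id=prof.subject_id,
            ahi=prof.ahi,
            age=prof.age,
            severity=prof.severity,
        )
        subjects.append((labels, x))
    return ft.extract_feature_table(subjects)
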