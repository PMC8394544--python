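"""Bispectral features: closed-form values, catalog schema, invariances."""

import numpy as np
import pytest

from conftest import make_matrix, make_region
from hrvbispec import features as ft
from hrvbispec import preprocess as pp
from hrvbispec import synthetic as syn
from hrvbispec.bispectrum import SegmentPlan


def _matrix_from_mags(mags, nfft=None):
    return make_matrix(np.asarray(mags, dtype=complex), nfft=nfft)


class TestAmplitude:
    def test_direct_evaluation(self):
        B = _matrix_from_mags([[0.1, 0.3], [0.0, 0.2]])
        reg = make_region([(0, 0), (0, 1), (1, 1)])
        assert ft.amplitude_features(B, reg) == (0.3, 0.1, pytest.approx(0.6))

    def test_single_bin(self):
        B = _matrix_from_mags([[0.07]])
        reg = make_region([(0, 0)])
        assert ft.amplitude_features(B, reg) == (0.07, 0.07, 0.07)

    def test_whole_support_totals_one(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=4096)
        from hrvbispec.bispectrum import estimate_bispectrum, normalize_bispectrum

        B = normalize_bispectrum(
            estimate_bispectrum(x, SegmentPlan(512, 0.5, 512), fs=1.0)
        )
        i, j = np.nonzero(B.support_mask())
        reg = make_region(list(zip(i.tolist(), j.tolist())))
        _, _, btot = ft.amplitude_features(B, reg)
        assert btot == pytest.approx(1.0, abs=1e-9)

    def test_empty_region_errors(self):
        B = _matrix_from_mags([[0.1]])
        with pytest.raises(ValueError, match="no bins"):
            ft.amplitude_features(B, make_region([]))


class TestBispectralEntropy:
    def test_uniform_is_log_m(self):
        B = _matrix_from_mags(np.full((3, 3), 0.1), nfft=32)
        bins = [(i, j) for i in range(3) for j in range(i, 3)]  # 6 bins
        reg = make_region(bins)
        for i in (1, 2, 3):
            assert ft.bispectral_entropy(B, reg, i) == pytest.approx(np.log(6))

    def test_point_mass_is_zero(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = 0.5
        B = _matrix_from_mags(vals)
        reg = make_region([(0, 0), (0, 1), (1, 1)])
        for i in (1, 2, 3):
            assert ft.bispectral_entropy(B, reg, i) == 0.0

    def test_hand_computed_211(self):
        """Magnitudes {2,1,1}: BE_1 = 1.0397, BE_2 = 0.8675 nats."""
        vals = np.zeros((3, 3))
        vals[0, 0], vals[0, 1], vals[0, 2] = 2.0, 1.0, 1.0
        B = _matrix_from_mags(vals, nfft=32)
        reg = make_region([(0, 0), (0, 1), (0, 2)])
        p = np.array([0.5, 0.25, 0.25])
        assert ft.bispectral_entropy(B, reg, 1) == pytest.approx(
            -(p * np.log(p)).sum()
        )
        assert ft.bispectral_entropy(B, reg, 1) == pytest.approx(1.0397, abs=1e-4)
        assert ft.bispectral_entropy(B, reg, 2) == pytest.approx(0.8675, abs=1e-4)

    def test_bounded_by_log_support(self):
        rng = np.random.default_rng(9)
        vals = np.abs(rng.normal(size=(5, 5)))
        B = _matrix_from_mags(vals, nfft=64)
        bins = [(i, j) for i in range(5) for j in range(i, 5)]
        reg = make_region(bins)
        for i in (1, 2, 3):
            be = ft.bispectral_entropy(B, reg, i)
            assert 0 <= be <= np.log(len(bins)) + 1e-12


class TestPhaseEntropy:
    def test_identical_phases_zero(self):
        vals = 0.1 * np.exp(1j * 0.7) * np.ones((3, 3))
        B = make_matrix(vals, nfft=32)
        reg = make_region([(0, 0), (0, 1), (1, 1)])
        assert ft.phase_entropy(B, reg, 8) == 0.0

    def test_one_phase_per_bin_gives_log_n(self):
        n = 4
        centers = -np.pi + (np.arange(n) + 0.5) * 2 * np.pi / n
        vals = np.zeros((2, 2), dtype=complex)
        vals[0, 0] = 0.1 * np.exp(1j * centers[0])
        vals[0, 1] = 0.1 * np.exp(1j * centers[1])
        vals[1, 0] = 0.1 * np.exp(1j * centers[2])
        vals[1, 1] = 0.1 * np.exp(1j * centers[3])
        B = make_matrix(vals, nfft=32)
        reg = make_region([(0, 0), (0, 1), (1, 0), (1, 1)])
        assert ft.phase_entropy(B, reg, n) == pytest.approx(np.log(n))

    def test_enumerated_histogram(self):
        """Phases {-3,-3,0,0,0,3}, N=4 -> counts {2,3,1} -> 1.0114 nats.

        Bin edges at -pi + 2 pi n / 4: -3 falls in [-pi, -pi/2), 0 in
        [0, pi/2), 3 in [pi/2, pi); PE = (1/3)ln3 + (1/2)ln2 + (1/6)ln6.
        """
        phases = [-3.0, -3.0, 0.0, 0.0, 0.0, 3.0]
        vals = np.zeros((1, 6), dtype=complex)
        for j, ph in enumerate(phases):
            vals[0, j] = 0.1 * np.exp(1j * ph)
        B = make_matrix(vals, nfft=64)
        reg = make_region([(0, j) for j in range(6)])
        expected = np.log(3) / 3 + np.log(2) / 2 + np.log(6) / 6
        assert ft.phase_entropy(B, reg, 4) == pytest.approx(expected, abs=1e-9)


class TestMoments:
    def test_hand_computed_diagonal(self):
        """Diagonal {e^-1, e^-1}: H_2 = -2, H_3 = -3, H_4 = -41."""
        vals = np.zeros((2, 2))
        vals[0, 0] = vals[1, 1] = np.exp(-1.0)
        B = _matrix_from_mags(vals, nfft=32)
        reg = make_region([(0, 0), (1, 1)])
        h1, h2, h3, h4 = ft.moment_features(B, reg)
        assert h2 == pytest.approx(-2.0)
        assert h3 == pytest.approx(-3.0)
        assert h4 == pytest.approx(-41.0)

    def test_h1_uniform(self):
        m = 6
        B = _matrix_from_mags(np.full((3, 3), np.exp(-1.0)), nfft=32)
        bins = [(i, j) for i in range(3) for j in range(i, 3)]
        reg = make_region(bins)
        h1, *_ = ft.moment_features(B, reg)
        assert h1 == pytest.approx(-m)

    def test_bwres_moments_excluded(self):
        B = _matrix_from_mags(np.full((2, 2), 0.1), nfft=32)
        reg = make_region([(0, 0), (0, 1)], has_diagonal_features=False)
        with pytest.raises(ValueError, match="excluded"):
            ft.moment_features(B, reg)


class TestWCOB:
    def test_point_mass(self):
        vals = np.zeros((3, 3))
        vals[2, 1] = 0.4
        B = make_matrix(vals, fs=32 * 0.05, nfft=32)  # df = 0.05 Hz
        reg = make_region([(2, 1), (0, 0)])
        assert ft.wcob(B, reg) == (pytest.approx(0.10), pytest.approx(0.05))

    def test_equal_weights_midpoint(self):
        vals = np.zeros((5, 5))
        vals[1, 1] = vals[2, 2] = 0.3
        B = make_matrix(vals, fs=40 * 0.1, nfft=40)  # df = 0.1 Hz
        reg = make_region([(1, 1), (2, 2)])
        f1m, f2m = ft.wcob(B, reg)
        assert (f1m, f2m) == (pytest.approx(0.15), pytest.approx(0.15))

    def test_weighted_mean(self):
        vals = np.zeros((5, 5))
        vals[1, 1], vals[2, 2] = 1.0, 3.0
        B = make_matrix(vals, fs=40 * 0.1, nfft=40)
        f1m, _ = ft.wcob(B, make_region([(1, 1), (2, 2)]))
        assert f1m == pytest.approx(0.175)


class TestRPDiag:
    def _matrix(self):
        # nfft=16 -> half=8, diagonal support k <= 4; put mass on k=0..3
        vals = np.zeros((9, 9))
        for k, m in enumerate([1.0, 1.0, 2.0, 4.0]):
            vals[k, k] = m
        return make_matrix(vals, nfft=16)

    def test_partial_sum(self):
        """Diag {1,1,2,4}, region covering diagonal bins 3-4 -> 0.75."""
        B = self._matrix()
        reg = make_region([(2, 2), (3, 3)])
        assert ft.rp_diag(B, reg) == pytest.approx(0.75)

    def test_full_diagonal_is_one(self):
        B = self._matrix()
        reg = make_region([(k, k) for k in range(5)])
        assert ft.rp_diag(B, reg) == pytest.approx(1.0)

    def test_no_diagonal_mass_is_zero(self):
        B = self._matrix()
        reg = make_region([(4, 4)])  # diagonal bin with zero magnitude
        assert ft.rp_diag(B, reg) == pytest.approx(0.0)

    def test_bwres_excluded(self):
        B = self._matrix()
        reg = make_region([(0, 0)], has_diagonal_features=False)
        with pytest.raises(ValueError, match="excluded"):
            ft.rp_diag(B, reg)


class TestCatalogs:
    def test_column_counts(self):
        assert len(ft.catalog_columns("classic")) == 42
        assert len(ft.catalog_columns("specific")) == 38

    def test_bwres_columns_lack_diagonal_features(self):
        cols = ft.catalog_columns("specific")
        for feat in ft.DIAGONAL_FEATURES:
            assert f"BWRes_{feat}" not in cols
            assert f"BW2_{feat}" in cols

    def test_empty_cohort_keeps_schema(self):
        classic, specific = ft.extract_feature_table([])
        assert list(classic.columns)[:42] == ft.catalog_columns("classic")
        assert list(specific.columns)[:38] == ft.catalog_columns("specific")
        assert len(classic) == 0 and len(specific) == 0

    def test_naming_convention(self):
        assert "VLF_f2m" in ft.catalog_columns("classic")
        assert "HF_PE" in ft.catalog_columns("classic")
        assert "BW2_RP_Diag" in ft.catalog_columns("specific")
        assert "BWRes_B_min" in ft.catalog_columns("specific")


def _short_subject(scale=1.0, seed=31):
    prof = syn.SubjectProfile("a", ahi=6.0, age=7.0, seed=seed)
    x = pp.preprocess_rr(syn.simulate_rr(prof, syn.SimulationConfig()))
    return pp.UniformHRV(values=scale * x.values, fs=x.fs, t0=x.t0)


def test_scale_invariance_of_all_features():
    """Multiplying the HRV signal by c > 0 changes no feature.

    Exact in real arithmetic (the |c|^3 factor cancels in normalization).
    Numerically, bins whose segment products nearly cancel have
    ill-conditioned phases and log-magnitudes, so the phase-histogram and
    log-sum features are compared at a looser absolute tolerance.
    """
    a = ft.subject_features(_short_subject(1.0))
    b = ft.subject_features(_short_subject(7.3))
    for got, want in ((b.classic, a.classic), (b.specific, a.specific)):
        for key, val in want.items():
            feat = key.split("_", 1)[1]
            if feat == "PE":
                assert got[key] == pytest.approx(val, abs=0.05), key
            elif feat.startswith("H_"):
                assert got[key] == pytest.approx(val, rel=1e-3), key
            else:
                assert got[key] == pytest.approx(val, rel=1e-6), key


def test_subject_feature_bounds():
    sf = ft.subject_features(_short_subject())
    for row, regions in ((sf.classic, ft.CLASSIC_REGIONS), (sf.specific, ft.SPECIFIC_REGIONS)):
        for rn in regions:
            assert 0 <= row[f"{rn}_B_min"] <= row[f"{rn}_B_max"] <= 1
            assert 0 < row[f"{rn}_B_total"] <= 1
            if f"{rn}_RP_Diag" in row:
                assert 0 <= row[f"{rn}_RP_Diag"] <= 1
            lo, hi = {"VLF": (0, .04), "LF": (.04, .15), "HF": (.15, .4),
                      "BW1": (.001, .005), "BW2": (.028, .074), "BWRes": (.15, .4)}[rn]
            assert lo - 1e-9 <= row[f"{rn}_f1m"] <= hi + 1e-9
            assert lo - 1e-9 <= row[f"{rn}_f2m"] <= hi + 1e-9


def test_direction_of_effect(cohort_tables):
    """Apnea-band modulation growing with AHI raises BW2_RP_Diag, lowers BW2_BE_1."""
    from scipy import stats

    _, specific = cohort_tables
    ahi = specific["ahi"].to_numpy(dtype=float)
    rho_rp, p_rp = stats.spearmanr(specific["BW2_RP_Diag"], ahi)
    rho_be, p_be = stats.spearmanr(specific["BW2_BE_1"], ahi)
    assert rho_rp > 0 and p_rp < 0.05
    assert rho_be < 0 and p_be < 0.05


def test_cohort_table_shapes(cohort_tables):
    classic, specific = cohort_tables
    assert ft.feature_matrix(classic).shape[1] == 42
    assert ft.feature_matrix(specific).shape[1] == 38
    assert not ft.feature_matrix(classic).isna().any().any()
    assert not ft.feature_matrix(specific).isna().any().any()
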