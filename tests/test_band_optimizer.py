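import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from angulai.band_optimizer import (
    R2Surface,
    export_surface,
    index_value,
    r2_surface,
    read_surface,
    select_optimum,
)
from angulai.spectra_io import WavelengthGrid
from conftest import make_dataset
from vi_oracle import oracle_r2, oracle_two_band


def naive_surface(dataset, index_type):
    """Brute-force double loop with per-cell OLS fits (oracle)."""
    X = dataset.spectra.reflectance
    y = dataset.lai
    B = X.shape[1]
    out = np.full((B, B), np.nan)
    for i in range(B):
        for j in range(B):
            v = np.array([oracle_two_band(index_type, a, b) for a, b in zip(X[:, i], X[:, j])])
            ok = np.isfinite(v)
            if ok.sum() < 3 or np.ptp(v[ok]) == 0:
                continue
            slope, intercept = np.polyfit(v[ok], y[ok], 1)
            out[i, j] = oracle_r2(list(y[ok]), list(slope * v[ok] + intercept))
    return out


class TestIndexValue:
    def test_direct_arithmetic(self):
        assert index_value("ND", 0.5, 0.1) == pytest.approx(0.4 / 0.6, abs=1e-12)

    def test_identity_cases(self):
        assert index_value("ND", 0.3, 0.3) == pytest.approx(0.0)
        assert index_value("SR", 0.3, 0.3) == pytest.approx(1.0)
        assert index_value("DVI", 0.3, 0.3) == pytest.approx(0.0)

    def test_zero_denominator_marker(self):
        assert np.isnan(index_value("SR", 0.3, 0.0))
        assert np.isnan(index_value("ND", 0.2, -0.2))

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            index_value("XX", 0.1, 0.2)

    @settings(derandomize=True, max_examples=200)
    @given(
        r1=st.floats(1e-6, 1.0, allow_nan=False),
        r2=st.floats(1e-6, 1.0, allow_nan=False),
    )
    def test_nd_bounded_and_forms_consistent(self, r1, r2):
        nd = index_value("ND", r1, r2)
        assert -1.0 <= nd <= 1.0
        # ND, SR and DVI are algebraically linked for positive reflectance
        sr = index_value("SR", r1, r2)
        assert nd == pytest.approx((sr - 1) / (sr + 1), rel=1e-9)
        assert index_value("DVI", r1, r2) == pytest.approx(r2 * (sr - 1), rel=1e-9)


class TestSurface:
    @pytest.mark.parametrize("index_type", ["ND", "SR", "DVI"])
    def test_matches_brute_force_oracle(self, toy_dataset, index_type):
        surf = r2_surface(toy_dataset, index_type, step=10)
        expected = naive_surface(toy_dataset, index_type)
        np.testing.assert_allclose(surf.r2, expected, atol=1e-10, equal_nan=True)

    def test_nd_and_dvi_symmetric_sr_not(self, toy_dataset):
        for t in ("ND", "DVI"):
            r2 = r2_surface(toy_dataset, t, step=10).r2
            np.testing.assert_allclose(r2, r2.T, atol=1e-12, equal_nan=True)
        sr = r2_surface(toy_dataset, "SR", step=10).r2
        off = ~np.eye(sr.shape[0], dtype=bool)
        assert not np.allclose(sr[off], sr.T[off], atol=1e-6)

    def test_diagonal_undefined(self, toy_dataset):
        for t in ("ND", "SR", "DVI"):
            assert np.all(np.isnan(np.diag(r2_surface(toy_dataset, t, step=10).r2))), t

    def test_constant_lai_gives_zero_r2(self, rng):
        ds = make_dataset(
            rng.uniform(0.1, 0.6, (10, 5)), np.full(10, 3.3),
            wavelengths=np.arange(400, 450, 10),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            surf = r2_surface(ds, "ND", step=10)
        defined = np.isfinite(surf.r2)
        assert defined.any() and np.all(surf.r2[defined] == 0.0)

    def test_dvi_never_beats_two_predictor_ols(self, toy_dataset):
        # DVI is a linear function of the two bands, so its single-predictor
        # fit cannot beat the saturated 2-band OLS fit.  (ND and SR are
        # nonlinear transforms and can legitimately exceed the bilinear fit.)
        X = toy_dataset.spectra.reflectance
        y = toy_dataset.lai
        surf = r2_surface(toy_dataset, "DVI", step=10)
        sst = ((y - y.mean()) ** 2).sum()
        B = X.shape[1]
        for i in range(B):
            for j in range(B):
                if not np.isfinite(surf.r2[i, j]):
                    continue
                A = np.column_stack([X[:, i], X[:, j], np.ones(len(y))])
                res = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
                ols_r2 = 1 - (res**2).sum() / sst
                assert surf.r2[i, j] <= ols_r2 + 1e-10


class TestSelectOptimum:
    def _surface(self, r2):
        b = r2.shape[0]
        return R2Surface(
            index_type="ND", vza=0.0,
            grid=WavelengthGrid(np.arange(700, 700 + 10 * b, 10.0)),
            r2=r2, n_used=20,
        )

    def test_unique_max(self):
        r2 = np.zeros((4, 4))
        r2[1, 3] = 0.9
        best = select_optimum(self._surface(r2))
        assert (best.lambda1, best.lambda2, best.r2) == (710.0, 730.0, 0.9)

    def test_tie_break_smallest_lambda(self):
        r2 = np.zeros((8, 8))
        r2[0, 5] = r2[1, 6] = 0.8  # (700,750) and (710,760)
        best = select_optimum(self._surface(r2))
        assert (best.lambda1, best.lambda2) == (700.0, 750.0)

    def test_single_defined_cell(self):
        r2 = np.full((3, 3), np.nan)
        r2[2, 0] = 0.4
        best = select_optimum(self._surface(r2))
        assert (best.lambda1, best.lambda2) == (720.0, 700.0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="no defined cells"):
            select_optimum(self._surface(np.full((3, 3), np.nan)))

    def test_refit_slope_intercept(self, toy_dataset):
        surf = r2_surface(toy_dataset, "DVI", step=10)
        best = select_optimum(surf, toy_dataset)
        assert np.isfinite(best.slope) and np.isfinite(best.intercept)
        assert best.r2 == np.nanmax(surf.r2)


class TestExport:
    def test_round_trip_and_header(self, toy_dataset, tmp_path):
        surf = r2_surface(toy_dataset, "ND", step=10)
        path = tmp_path / "surface.csv"
        export_surface(surf, path)
        header = path.read_text().splitlines()[0]
        assert header == "lambda1,lambda2,r2"
        n_defined = int(np.isfinite(surf.r2).sum())
        assert len(path.read_text().splitlines()) == n_defined + 1
        back = read_surface(path, index_type="ND")
        np.testing.assert_allclose(back.r2, surf.r2, atol=1e-10, equal_nan=True)
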