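"""Profiles, gamma index, DVH, port-effect and the comparison report."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from expanderdose import analysis as AN
from expanderdose.dosegrid import DoseGrid
from expanderdose.phantoms import ContourMask


def _dose_grid(arr, unc=None, spacing=(2.0, 2.0, 2.0)):
    arr = np.asarray(arr, float)
    unc = np.zeros_like(arr) if unc is None else np.asarray(unc, float)
    origin = np.zeros(3)
    return DoseGrid(origin, np.asarray(spacing, float), arr, unc, "test")


# ---------------------------------------------------------------------------
# gamma
# ---------------------------------------------------------------------------
def _gamma_oracle_1d(ref, ev, spacing, dose_pct, dta_mm, subdivisions=3, search_factor=3.0):
    """Independent naive loop implementation of the same gamma definition."""
    ref = np.asarray(ref, float)
    ev = np.asarray(ev, float)
    norm = ref.max()
    n = len(ref)
    pos = np.arange(n) * spacing
    step = spacing / subdivisions
    radius = search_factor * dta_mm
    m = int(np.floor(radius / step))
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for k in range(-m, m + 1):
            x = pos[i] + k * step
            if x < 0 or x > pos[-1]:
                continue
            d = abs(k) * step
            if d > radius:
                continue
            evx = np.interp(x, pos, ev)
            g2 = ((evx - ref[i]) / (norm * dose_pct / 100.0)) ** 2 + (d / dta_mm) ** 2
            best = min(best, g2)
        out[i] = np.sqrt(best)
    return out


class TestGamma:
    def test_identical_curves_give_zero(self):
        ref = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        res = AN.gamma_index(ref, ref.copy(), 1.0, 2.0, 1.0)
        assert np.allclose(res.gamma, 0.0)
        assert res.pass_rate == 1.0

    def test_uniform_offset_at_criterion_gives_unity(self):
        """A flat profile offset by exactly the dose criterion has gamma 1:
        no spatial shift can reduce the dose term for a flat field."""
        ref = np.full(20, 10.0)
        ev = np.full(20, 10.0 + 10.0 * 0.02)  # +2% of the max
        res = AN.gamma_index(ref, ev, 1.0, 2.0, 1.0)
        assert np.allclose(res.gamma, 1.0, atol=1e-9)

    def test_matches_bruteforce_oracle_on_random_curves(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ref = rng.uniform(0.5, 2.0, 10)
            ev = ref * rng.uniform(0.95, 1.05, 10)
            res = AN.gamma_index(ref, ev, 3.0, 2.0, 1.0)
            oracle = _gamma_oracle_1d(ref, ev, 3.0, 2.0, 1.0)
            assert np.allclose(res.gamma, oracle, atol=1e-6)

    def test_not_symmetric_in_general(self):
        """Swapping reference and evaluated changes the result (global
        normalization and the search direction are reference-anchored)."""
        rng = np.random.default_rng(8)
        ref = rng.uniform(1.0, 3.0, 30)
        ev = ref * rng.uniform(0.9, 1.1, 30)
        g1 = AN.gamma_index(ref, ev, 2.0, 3.0, 1.0).gamma
        g2 = AN.gamma_index(ev, ref, 2.0, 3.0, 1.0).gamma
        assert not np.allclose(g1, g2)

    def test_3d_volume(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(1.0, 2.0, (6, 6, 6))
        res = AN.gamma_index(ref, ref * 1.01, (2.0, 2.0, 2.0), 2.0, 1.0)
        assert res.gamma.shape == ref.shape
        assert res.pass_rate == 1.0

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            AN.gamma_index(np.zeros(5), np.ones(5), 1.0, 2.0, 1.0)

    def test_lattice_mismatch_raises(self):
        with pytest.raises(ValueError):
            AN.gamma_index(np.ones(5), np.ones(6), 1.0, 2.0, 1.0)


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------
class TestDVH:
    def test_uniform_dose(self):
        dose = _dose_grid(np.full((4, 4, 4), 7.0))
        mask = ContourMask("m", np.ones((4, 4, 4), bool), dose.spacing)
        r = AN.dvh_parameters(dose, mask)
        assert r.d1 == r.d10 == r.mean == pytest.approx(7.0)

    def test_linear_ramp_quantiles(self):
        vals = np.linspace(0.0, 100.0, 100_001)
        assert AN.dose_at_volume(vals, 10.0) == pytest.approx(90.0, abs=0.01)
        assert AN.dose_at_volume(vals, 1.0) == pytest.approx(99.0, abs=0.01)

    def test_four_voxel_enumeration(self):
        arr = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        dose = _dose_grid(arr)
        mask = ContourMask("m", np.ones((4, 1, 1), bool), dose.spacing)
        r = AN.dvh_parameters(dose, mask)
        # brute force: sorted doses [1,2,3,4]; interpolated quantiles
        assert r.d10 == pytest.approx(np.quantile([1, 2, 3, 4], 0.9))
        assert r.d1 == pytest.approx(np.quantile([1, 2, 3, 4], 0.99))
        assert r.mean == pytest.approx(2.5)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1e3), min_size=2, max_size=100),
           st.floats(0.5, 50.0))
    def test_quantile_matches_sort_oracle(self, doses, pct):
        """Dx equals the linear-interpolated order statistic (sort oracle)."""
        vals = np.array(doses)
        got = AN.dose_at_volume(vals, pct)
        s = np.sort(vals)
        q = 1.0 - pct / 100.0
        h = q * (len(s) - 1)
        lo = int(np.floor(h))
        hi = min(lo + 1, len(s) - 1)
        expect = s[lo] + (h - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_dvh_ordering_invariant(self):
        rng = np.random.default_rng(2)
        arr = rng.uniform(0, 10, (5, 5, 5))
        dose = _dose_grid(arr)
        mask = ContourMask("m", rng.random((5, 5, 5)) > 0.3, dose.spacing)
        r = AN.dvh_parameters(dose, mask)
        assert r.d1 >= r.d10 >= 0
        assert r.mean <= r.d1

    def test_empty_mask_raises(self):
        dose = _dose_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            AN.dvh_parameters(dose, ContourMask("m", np.zeros((3, 3, 3), bool), dose.spacing))


# ---------------------------------------------------------------------------
# profiles & port effect
# ---------------------------------------------------------------------------
class TestProfiles:
    def test_uniform_region_constant(self):
        dose = _dose_grid(np.full((5, 9, 5), 4.0))
        p = AN.extract_profile(dose, 1, (4.0, 0.0, 4.0))
        assert np.allclose(p.dose, 4.0)

    def test_lateral_average_reduces_to_mean(self):
        arr = np.zeros((5, 3, 5))
        arr[:, 1, :] = np.arange(25).reshape(5, 5)
        dose = _dose_grid(arr)
        p = AN.extract_profile(dose, 1, (4.0, 0.0, 4.0), average_mm=100.0)
        assert p.dose[1] == pytest.approx(np.arange(25).mean())

    def test_point_outside_grid_raises(self):
        dose = _dose_grid(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            AN.extract_profile(dose, 1, (100.0, 0.0, 0.0))


class TestPortEffect:
    def test_identical_inputs_zero(self):
        arr = np.random.default_rng(0).uniform(1, 2, (5, 9, 5))
        d = _dose_grid(arr)
        prof = AN.port_effect(d, _dose_grid(arr.copy()), average_mm=0.0)
        assert np.allclose(prof.difference_pct, 0.0)

    def test_known_attenuation_sign_and_size(self):
        base = np.full((5, 9, 5), 10.0)
        att = base.copy()
        att[:, 5:, :] *= 0.9  # 10% underdose distally in the test run
        prof = AN.port_effect(_dose_grid(att), _dose_grid(base), average_mm=0.0)
        assert prof.max_underdose_pct == pytest.approx(10.0)
        assert prof.positions_mm[5] <= prof.max_underdose_position_mm

    def test_null_perturbation_statistically_zero(self):
        """With noisy but identical-in-expectation runs, the mean difference
        is compatible with zero within 2 standard errors."""
        rng = np.random.default_rng(12)
        base = np.full((7, 40, 7), 100.0)
        n1 = base * (1 + rng.normal(0, 0.01, base.shape))
        n2 = base * (1 + rng.normal(0, 0.01, base.shape))
        unc = np.full(base.shape, 0.01)
        prof = AN.port_effect(_dose_grid(n1, unc), _dose_grid(n2, unc), average_mm=6.0)
        mean_diff = prof.difference_pct.mean()
        sem = prof.uncertainty_pct.mean() / np.sqrt(len(prof.difference_pct))
        assert abs(mean_diff) < 2.5 * sem + 0.05

    def test_lattice_mismatch_raises(self):
        with pytest.raises(ValueError):
            AN.port_effect(_dose_grid(np.ones((3, 3, 3))), _dose_grid(np.ones((4, 3, 3))))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------
class TestReport:
    def _runs(self, scale_rs1=1.0, scale_rs2=1.0):
        base = np.random.default_rng(4).uniform(5, 10, (6, 6, 6))
        return {
            "no-port": _dose_grid(base),
            "RS1": _dose_grid(base * scale_rs1),
            "RS2": _dose_grid(base * scale_rs2),
        }

    def _contours(self):
        m = np.zeros((6, 6, 6), bool)
        m[1:5, 1:5, 1:5] = True
        return {"C_Test": ContourMask("C_Test", m, np.array([2.0, 2.0, 2.0]))}

    def test_identical_runs_all_zero(self):
        rep = AN.dvh_difference_report(self._runs(), self._contours())
        cols = [c for c in rep.columns if "(%)" in c and "unc" not in c]
        assert np.allclose(rep[cols].to_numpy(), 0.0)

    def test_sign_convention_first_named_hotter(self):
        rep = AN.dvh_difference_report(self._runs(scale_rs1=0.9), self._contours())
        # no-port is 11% hotter than RS1 -> positive entries
        assert rep["no-port-RS1 D10 (%)"].iloc[0] > 0
        # RS1 colder than RS2 -> negative
        assert rep["RS1-RS2 D10 (%)"].iloc[0] < 0

    def test_missing_run_raises(self):
        runs = self._runs()
        runs.pop("RS2")
        with pytest.raises(ValueError):
            AN.dvh_difference_report(runs, self._contours())
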