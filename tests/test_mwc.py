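"""Unit and property tests of the MWC model core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import chanlink as cl
from chanlink.exceptions import CurveScalingError

from helpers import TRUTH_PARAMS, exact_po_curves

ref = cl.reference_data


def mwc_strategy():
    logu = lambda lo, hi: st.floats(math.log10(lo), math.log10(hi)).map(lambda e: 10.0 ** e)
    return st.builds(cl.MWCParams, L=logu(1e-4, 1e6), K_G=logu(1e-9, 1e-2),
                     K_D=logu(1e-9, 1e-2), c=logu(1e-4, 1.0), d=logu(1e-4, 1.0))


conc_strategy = st.one_of(st.just(0.0),
                          st.floats(-9, -2).map(lambda e: 10.0 ** e))


class TestPoClosedForm:
    def test_unliganded_reduces_to_1_over_1_plus_L(self):
        p = cl.MWCParams(L=1.8, K_G=53e-6, K_D=180e-9, c=0.0031, d=0.59)
        assert cl.po_mwc(p, 0.0, 0.0) == pytest.approx(1.0 / 2.8, abs=1e-15)

    def test_hand_evaluated_single_point(self):
        # L=2, K_G=1 M, c=0.5, 1 M GABA: Po = 1/(1 + 2*(2/3)^2) = 9/17
        p = cl.MWCParams(L=2.0, K_G=1.0, K_D=1.0, c=0.5, d=1.0)
        assert cl.po_mwc(p, 1.0, 0.0) == pytest.approx(9.0 / 17.0, rel=1e-14)

    def test_saturating_limits(self, l9t_params):
        p = l9t_params
        # [GABA] -> inf: Po = 1/(1 + L c^2 fD); [DZ] -> inf at no GABA: 1/(1 + L d)
        assert cl.po_mwc(p, np.inf, 0.0) == pytest.approx(
            1.0 / (1.0 + p.L * p.c ** 2), rel=1e-14)
        assert cl.po_mwc(p, 0.0, np.inf) == pytest.approx(
            1.0 / (1.0 + p.L * p.d), rel=1e-14)

    def test_l9t_maximal_po_approaches_one(self, l9t_params):
        assert cl.po_mwc(l9t_params, np.inf, 0.0) > 0.999

    def test_negative_concentration_rejected(self, l9t_params):
        with pytest.raises(ValueError):
            cl.po_mwc(l9t_params, -1e-6, 0.0)

    def test_monotone_in_gaba_and_silent_when_d_is_one(self, l9t_params):
        x = np.logspace(-9, -2, 50)
        po = cl.po_mwc(l9t_params, x, 0.0)
        assert np.all(np.diff(po) > 0)
        silent = cl.MWCParams(L=1.8, K_G=53e-6, K_D=180e-9, c=0.0031, d=1.0)
        assert np.allclose(cl.po_mwc(silent, 0.0, x), silent.po0, atol=1e-15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            cl.MWCParams(L=-1, K_G=1e-6, K_D=1e-6, c=0.5, d=0.5)
        with pytest.raises(ValueError):
            cl.MWCParams(L=1, K_G=1e-6, K_D=1e-6, c=0.5, d=1.5)
        # inverse-agonist regime must be opted into
        p = cl.MWCParams(L=1, K_G=1e-6, K_D=1e-6, c=0.5, d=1.5, allow_inverse=True)
        assert p.d == 1.5


class TestEnumerationOracle:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(params=mwc_strategy(), gaba=conc_strategy, dz=conc_strategy)
    def test_matches_closed_form(self, params, gaba, dz):
        assert abs(cl.po_enumerate(params, gaba, dz)
                   - cl.po_mwc(params, gaba, dz)) < 1e-12

    def test_reduces_to_two_site_single_ligand_form(self, l9t_params):
        p = l9t_params
        g = 20e-6
        expected = 1.0 / (1.0 + p.L * ((1 + g / p.K_G) / (1 + g / (p.c * p.K_G))) ** 2)
        assert cl.po_enumerate(p, g, 0.0) == pytest.approx(expected, abs=1e-15)

    def test_d_equal_one_makes_dz_silent(self):
        p = cl.MWCParams(L=3.0, K_G=1e-5, K_D=1e-7, c=0.01, d=1.0)
        assert cl.po_enumerate(p, 2e-6, 5e-7) == pytest.approx(
            cl.po_enumerate(p, 2e-6, 0.0), abs=1e-15)

    def test_rejects_infinite_concentration(self, l9t_params):
        with pytest.raises(ValueError):
            cl.po_enumerate(l9t_params, math.inf, 0.0)


class TestEfficiency:
    def test_factor_one_gives_zero(self):
        assert cl.ligand_efficiency(53e-6, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_increases_as_factor_decreases(self):
        etas = [cl.ligand_efficiency(180e-9, f) for f in (0.59, 0.20, 0.05)]
        assert etas[0] < etas[1] < etas[2]

    def test_pathological_unit_product_rejected(self):
        with pytest.raises(ValueError):
            cl.ligand_efficiency(2.0, 0.5)  # factor*K = 1 M


class TestWtLFromEc50:
    def test_equal_ec50s_identity(self):
        assert cl.wt_L_from_ec50(1.8, 1e-6, 1e-6) == pytest.approx(1.8)

    def test_reported_ec50s_give_22579(self):
        assert cl.wt_L_from_ec50(1.8, 28e-6, 0.25e-6) == pytest.approx(22579.2, rel=1e-9)

    def test_quadratic_scaling(self):
        assert cl.wt_L_from_ec50(1.8, 2e-6, 1e-6) == pytest.approx(
            4 * cl.wt_L_from_ec50(1.8, 1e-6, 1e-6))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cl.wt_L_from_ec50(1.8, -1e-6, 1e-6)


class TestEstimatedPoCurve:
    def _hill(self):
        x = 0.25e-6 * np.logspace(-2, 2, 9)
        return cl.fit_hill(x, cl.hill_response(x, 0.25e-6, 0.83), normalize=True)

    def test_endpoints(self):
        hill = self._hill()
        curve = cl.build_estimated_po_curve(
            hill, "GABA", r_ptx_gaba=0.36, po_max=1.0,
            concentrations=np.concatenate([[1e-15], np.logspace(-8, -2, 20)]))
        assert curve.po[0] == pytest.approx(0.36, abs=1e-6)
        assert curve.po[-1] == pytest.approx(1.0, abs=1e-3)

    def test_dz_curve_flat_when_ratio_is_one(self):
        hill = self._hill()
        curve = cl.build_estimated_po_curve(hill, "DZ", r_ptx_gaba=0.36,
                                            r_dz_ptx=1.0, po_max=1.0)
        assert np.allclose(curve.po, 0.36, atol=1e-12)

    def test_overflowing_dz_maximum_rejected(self):
        hill = self._hill()
        with pytest.raises(CurveScalingError):
            cl.build_estimated_po_curve(hill, "DZ", r_ptx_gaba=0.5,
                                        r_dz_ptx=3.0, po_max=1.0)


class TestPotentiation:
    def test_no_dz_or_silent_d_gives_zero(self, l9t_params):
        assert cl.predict_potentiation(l9t_params, 1e-6, 0.0) == pytest.approx(0.0)
        silent = cl.MWCParams(L=1.8, K_G=53e-6, K_D=180e-9, c=0.0031, d=1.0)
        assert cl.predict_potentiation(silent, 1e-6, 1e-5) == pytest.approx(0.0, abs=1e-12)

    def test_wt_saturating_gaba_closed_form(self):
        # independent algebra: at saturating GABA,
        # pot = 100*((1 + L c^2) / (1 + L c^2 fD) - 1) with
        # fD = (1+dz/K_D)/(1+dz/(d K_D))
        p = ref.fitted_mwc_params("WT")
        dz = 1e-6
        fD = (1 + dz / p.K_D) / (1 + dz / (p.d * p.K_D))
        expected = 100.0 * ((1 + p.L * p.c ** 2) / (1 + p.L * p.c ** 2 * fD) - 1)
        got = cl.predict_potentiation(p, np.inf, dz)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(5.8, abs=0.1)

    def test_decomposition_trivial_and_shared_kd_required(self):
        wt = ref.fitted_mwc_params("WT")
        assert cl.decompose_potentiation(wt, wt) == pytest.approx(100.0)
        other = cl.MWCParams(L=wt.L, K_G=wt.K_G, K_D=wt.K_D * 2, c=wt.c, d=wt.d)
        with pytest.raises(ValueError):
            cl.decompose_potentiation(other, wt)


class TestGlobalFitSchemes:
    def _gaba_curves(self):
        rng = np.random.default_rng(7)
        curves = []
        for cid in ("L9'T", "L9'T/V279A", "WT"):
            p = ref.fitted_mwc_params(cid)
            lo, hi = (1e-8, 1e-4) if cid != "WT" else (1e-6, 1e-2)
            x = np.logspace(np.log10(lo), np.log10(hi), 30)
            po = np.clip(cl.po_mwc(p, x, 0.0)
                         * (1 + rng.normal(0, 0.02, x.shape)), 1e-9, 1.0)
            curves.append(cl.EstimatedPoCurve(cid, "GABA", x, po))
        return curves

    def test_front_face_variants_run_and_rank(self):
        """The GABA-only scheme family: shared affinity, L fixed from
        unliganded Po with per-construct K_G, and fully free affinity all
        converge; the most flexible nests the most constrained."""
        curves = self._gaba_curves()
        constructs = [c.construct_id for c in curves]
        shared = cl.MWCGlobalModel(curves, cl.front_face_scheme(constructs)).fit(
            n_starts=2, seed=0)
        fixed_L = {f"L[{cid}]": ref.fitted_mwc_params(cid).L for cid in constructs}
        fixed_L["c"] = ref.MWC_FITTED["c"]
        constrained = cl.MWCGlobalModel(
            curves, cl.front_face_scheme(constructs, per_construct_K_G=True,
                                         fixed=fixed_L)).fit(n_starts=2, seed=0)
        free = cl.MWCGlobalModel(
            curves, cl.front_face_scheme(constructs, per_construct_K_G=True,
                                         per_construct_c=True)).fit(n_starts=2, seed=0)
        for res in (shared, constrained, free):
            assert math.isfinite(res.ssr) and res.ssr >= 0
        # fully free affinities can only improve on the same affinities constrained
        assert free.ssr <= constrained.ssr * (1 + 1e-6) + 1e-12
        ranking = sorted([("shared", shared.ssr), ("constrained", constrained.ssr),
                          ("free", free.ssr)], key=lambda kv: kv[1])
        assert len(ranking) == 3

    def test_single_curve_reduces_to_single_fit(self):
        curve = exact_po_curves()[0]
        single = cl.MWCGlobalModel([curve]).fit(n_starts=2, seed=0)
        assert single.ssr == pytest.approx(
            sum(single.per_curve_ssr.values()), rel=1e-9, abs=1e-15)
        assert single.ssr < 1e-10  # noiseless curve is fit essentially exactly

    def test_results_reconstruct_per_construct_params(self):
        res = cl.MWCGlobalModel(exact_po_curves()).fit(n_starts=2, seed=3)
        p = res.params_for("L9'T/V279A")
        assert p.d == pytest.approx(res.params["d_V279A"], rel=1e-12)
        assert p.K_G == pytest.approx(res.params["K_G"], rel=1e-12)
        assert "SSR" in res.summary()

    def test_noiseless_recovery_of_all_parameters(self):
        res = cl.MWCGlobalModel(exact_po_curves()).fit(n_starts=4, seed=1)
        for name, truth in TRUTH_PARAMS.items():
            assert res.params[name] == pytest.approx(truth, rel=0.05), name
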