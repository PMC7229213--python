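"""Reference FBA/pFBA/FVA, genotype flux estimation, scaling and robustness."""

import numpy as np
import pytest

import netgs
from netgs.errors import InfeasibleError, UnboundedError, ValidationError
from netgs.io import _build_model

from conftest import make_chain


def branch_model(cap=10.0):
    """Uptake feeds RuBisCO carboxylation and oxygenation; both make biomass precursor."""
    records = [
        {"id": "UP", "stoich": {"C": 1}, "lb": 0.0, "ub": cap, "tag": ""},
        {"id": "CARB", "stoich": {"C": -1, "P": 1}, "lb": 0.0, "ub": 1000.0,
         "tag": "carboxylation"},
        {"id": "OXY", "stoich": {"C": -1, "P": 1}, "lb": 0.0, "ub": 1000.0,
         "tag": "oxygenation"},
        {"id": "BIO", "stoich": {"P": -1}, "lb": 0.0, "ub": 1000.0, "tag": "biomass"},
    ]
    return _build_model(["C", "P"], records, model_id="branch")


class TestReferenceFBA:
    def test_chain_limited_by_uptake_bound(self, chain):
        with pytest.warns(UserWarning, match="skipping"):
            ref = netgs.solve_reference_fba(chain)
        assert ref.objective == pytest.approx(10.0)
        np.testing.assert_allclose(ref.values, 10.0)

    def test_branch_respects_fixed_ratio(self):
        # carb + oxy = 10 and carb = 2.88 oxy  =>  oxy = 10/3.88
        ref = netgs.solve_reference_fba(branch_model(), netgs.RatioConstraints.fixed())
        model = branch_model()
        assert ref.flux(model, "OXY") == pytest.approx(10.0 / 3.88)
        assert ref.flux(model, "CARB") == pytest.approx(10.0 * 2.88 / 3.88)

    def test_zero_uptake_gives_zero_fluxes(self, minimal):
        model, _ = minimal
        closed = model.copy()
        for rid in closed.exchange_ids:
            closed.ub[closed.reaction_index(rid)] = 0.0
        ref = netgs.solve_reference_fba(closed, netgs.RatioConstraints.fixed())
        assert ref.objective == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(ref.values, 0.0, atol=1e-9)

    def test_unbounded_network_reports_exchange_hint(self):
        records = [
            {"id": "UP", "stoich": {"A": 1}, "lb": 0.0, "ub": np.inf, "tag": ""},
            {"id": "BIO", "stoich": {"A": -1}, "lb": 0.0, "ub": np.inf, "tag": "biomass"},
        ]
        model = _build_model(["A"], records, model_id="open")
        with pytest.warns(UserWarning), pytest.raises(UnboundedError, match="exchange"):
            netgs.solve_reference_fba(model)

    def test_objective_monotone_in_bound_relaxation(self, rng):
        # enlarging any bound interval cannot decrease the optimum
        for _ in range(10):
            cap = rng.uniform(3.0, 8.0)
            ref = netgs.solve_reference_fba(branch_model(cap))
            wider = netgs.solve_reference_fba(branch_model(cap + rng.uniform(0.1, 5.0)))
            assert wider.objective >= ref.objective - 1e-9


class TestPFBA:
    def test_chain_pfba_equals_fba(self, chain):
        with pytest.warns(UserWarning):
            fba = netgs.solve_reference_fba(chain)
            pfba = netgs.solve_reference_pfba(chain)
        np.testing.assert_allclose(pfba.values, fba.values, atol=1e-8)

    def test_futile_cycle_suppressed(self):
        records = [
            {"id": "UP", "stoich": {"A": 1}, "lb": 0.0, "ub": 10.0, "tag": ""},
            {"id": "FWD", "stoich": {"A": -1, "B": 1}, "lb": -1000.0, "ub": 1000.0, "tag": ""},
            {"id": "BACK", "stoich": {"B": -1, "A": 1}, "lb": -1000.0, "ub": 1000.0, "tag": ""},
            {"id": "BIO", "stoich": {"B": -1}, "lb": 0.0, "ub": 1000.0, "tag": "biomass"},
        ]
        model = _build_model(["A", "B"], records, model_id="cycle")
        with pytest.warns(UserWarning):
            pfba = netgs.solve_reference_pfba(model)
        # the two parallel arcs must not run a loop: net 10 with minimal |flux|
        assert np.abs(pfba.values).sum() == pytest.approx(30.0, abs=1e-6)
        assert pfba.flux(model, "FWD") - pfba.flux(model, "BACK") == pytest.approx(10.0)

    def test_total_flux_never_exceeds_fba(self, minimal):
        model, _ = minimal
        fba = netgs.solve_reference_fba(model)
        pfba = netgs.solve_reference_pfba(model)
        assert pfba.objective == pytest.approx(fba.objective, rel=1e-9)
        assert np.abs(pfba.values).sum() <= np.abs(fba.values).sum() + 1e-8


class TestFVA:
    def test_chain_fully_determined(self, chain):
        with pytest.warns(UserWarning):
            ref = netgs.solve_reference_fba(chain)
            fva = netgs.flux_variability_at_optimum(chain, None, ref)
        np.testing.assert_allclose(fva["min"], ref.values, atol=1e-8)
        np.testing.assert_allclose(fva["max"], ref.values, atol=1e-8)

    def test_parallel_routes_span_capacity(self):
        records = [
            {"id": "UP", "stoich": {"A": 1}, "lb": 0.0, "ub": 10.0, "tag": ""},
            {"id": "R1", "stoich": {"A": -1, "B": 1}, "lb": 0.0, "ub": 1000.0, "tag": ""},
            {"id": "R2", "stoich": {"A": -1, "B": 1}, "lb": 0.0, "ub": 1000.0, "tag": ""},
            {"id": "BIO", "stoich": {"B": -1}, "lb": 0.0, "ub": 1000.0, "tag": "biomass"},
        ]
        model = _build_model(["A", "B"], records, model_id="routes")
        with pytest.warns(UserWarning):
            ref = netgs.solve_reference_fba(model)
            fva = netgs.flux_variability_at_optimum(model, None, ref)
        fva = fva.set_index("reaction_id")
        for rid in ("R1", "R2"):
            assert fva.loc[rid, "min"] == pytest.approx(0.0, abs=1e-8)
            assert fva.loc[rid, "max"] == pytest.approx(10.0, abs=1e-8)
        # the pinned biomass reaction is degenerate
        assert fva.loc["BIO", "min"] == pytest.approx(fva.loc["BIO", "max"])

    def test_minimal_network_has_no_alternate_optima(self, minimal, minimal_ref):
        model, _ = minimal
        fva = netgs.flux_variability_at_optimum(model, netgs.RatioConstraints.fixed(), minimal_ref)
        assert ((fva["max"] - fva["min"]).abs() < 1e-8).all()


class TestGenotypeBiomassMax:
    def test_chain_capacity(self, chain):
        with pytest.warns(UserWarning):
            assert netgs.max_genotype_biomass(chain) == pytest.approx(10.0)

    def test_doubling_biomass_coefficients_halves_maximum(self, minimal):
        model, _ = minimal
        comp = netgs.BiomassComposition.from_model(model)
        m1 = netgs.set_biomass(model, comp)
        m2 = netgs.set_biomass(model, comp.scaled(2.0))
        assert netgs.max_genotype_biomass(m2) == pytest.approx(
            netgs.max_genotype_biomass(m1) / 2.0
        )

    def test_interval_ratios_relax_fixed_optimum(self, minimal, minimal_ref):
        model, _ = minimal
        assert netgs.max_genotype_biomass(model) >= minimal_ref.objective - 1e-9


class TestBuildScaling:
    def test_mean_of_maxima(self):
        s = netgs.build_scaling({"A": 10.0, "B": 20.0}, {"A": 1.0, "B": 1.0}, 1.0, 5.0)
        assert s.s_model == pytest.approx(15.0)

    def test_equal_weights_collapse_ratios(self):
        s = netgs.build_scaling(
            {"A": 10.0, "B": 20.0}, {"A": 2.0, "B": 2.0}, M_ref=2.0, v_bio_ref=5.0
        )
        assert s.s_measurement == pytest.approx(5.0)
        for g in ("A", "B"):
            assert s.scaled_target(g) == pytest.approx(s.s_model - s.delta)

    def test_top_genotype_hits_model_ceiling(self):
        s = netgs.build_scaling(
            {"A": 10.0, "B": 12.0}, {"A": 1.0, "B": 1.6}, M_ref=1.0, v_bio_ref=5.0
        )
        assert s.scaled_target("B") == pytest.approx(s.s_model - s.delta)
        assert s.scaled_target("A") < s.scaled_target("B")

    def test_nonpositive_fresh_weight_rejected(self):
        with pytest.raises(ValidationError, match="fresh weight"):
            netgs.build_scaling({"A": 10.0}, {"A": 0.0}, 1.0, 5.0)


class TestGenotypeFlux:
    def test_reference_is_fixed_point(self, minimal, minimal_ref):
        model, comps = minimal
        mz = netgs.set_biomass(model, comps["E1"])
        est = netgs.estimate_genotype_flux(mz, minimal_ref, minimal_ref.objective)
        assert est.objective == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(est.values, minimal_ref.values, atol=1e-6)

    def test_chain_scales_exactly(self):
        chain = make_chain()
        with pytest.warns(UserWarning):
            ref = netgs.solve_reference_fba(chain)
            est = netgs.estimate_genotype_flux(chain, ref, 5.0, eps_band=1e-9)
        np.testing.assert_allclose(est.values, 5.0, atol=1e-6)

    def test_band_widening_then_failure(self, minimal, minimal_ref):
        model, comps = minimal
        mz = netgs.set_biomass(model, comps["E1"])
        # target far above the model maximum: every widening still infeasible
        with pytest.raises(InfeasibleError, match="widening"):
            netgs.estimate_genotype_flux(mz, minimal_ref, 100.0, eps_band=0.01)

    def test_steady_state_and_bounds_contract(self, minimal, minimal_ref):
        model, comps = minimal
        mz = netgs.set_biomass(model, comps["E2"])
        est = netgs.estimate_genotype_flux(mz, minimal_ref, 0.7 * minimal_ref.objective)
        assert est.steady_state_residual(mz) <= 1e-6
        assert (est.values >= mz.lb - 1e-6).all()
        assert (est.values <= mz.ub + 1e-6).all()


class TestRobustReference:
    def test_zero_variance_returns_reference(self, minimal, minimal_ref):
        model, _ = minimal
        cfg = netgs.RobustnessConfig(e=0.0, n_samples=3, seed=1)
        mean, samples = netgs.robust_reference(model, minimal_ref, cfg)
        np.testing.assert_allclose(mean.values, minimal_ref.values, atol=1e-4)
        for s in samples:
            np.testing.assert_allclose(s.values, minimal_ref.values, atol=1e-4)

    def test_seed_reproducibility(self, minimal, minimal_ref):
        model, _ = minimal
        cfg = netgs.RobustnessConfig(e=0.05, n_samples=5, seed=42)
        m1, _ = netgs.robust_reference(model, minimal_ref, cfg)
        m2, _ = netgs.robust_reference(model, minimal_ref, cfg)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_samples_satisfy_constraints(self, minimal, minimal_ref):
        model, _ = minimal
        cfg = netgs.RobustnessConfig(e=0.10, n_samples=5, seed=3)
        mean, samples = netgs.robust_reference(model, minimal_ref, cfg)
        icarb = model.tag_index("carboxylation")
        ioxy = model.tag_index("oxygenation")
        for s in samples + [mean]:
            assert s.steady_state_residual(model) <= 1e-6
            assert abs(s.values[icarb] - 2.88 * s.values[ioxy]) <= cfg.eps + 1e-8
            assert s.biomass_flux(model) == pytest.approx(minimal_ref.objective, abs=1e-8)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            netgs.RobustnessConfig(e=-0.1)
        with pytest.raises(ValidationError):
            netgs.RobustnessConfig(n_samples=0)
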