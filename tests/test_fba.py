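"""FBA engine: LP solutions, loopless post-processing, flux-ratio builders."""

import itertools

import numpy as np
import pytest

from thermoflux.calibration import experiment_constraints, measured_fluxes
from thermoflux.fba import (
    FluxDistribution,
    FluxRatioConstraint,
    MediaSpec,
    cellodextrin_ratio_constraint,
    ea_ratio_constraint,
    fba,
    flux_sum,
    loopless_postprocess,
    sum_yield_constraint,
)
from thermoflux.model import build_stoichiometric_matrix
from thermoflux.synthetic import build_core_network

from conftest import make_model


def enumerate_vertices(model):
    """Brute-force vertex enumeration of {S v = 0, lb <= v <= ub}.

    Fixes every subset of n - rank(S) variables at a finite bound, solves the
    equality system for the rest, and keeps feasible solutions.  Only viable
    for tiny networks; serves as an independent optimum oracle.
    """
    S = build_stoichiometric_matrix(model)
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    k = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            if any(abs(b) >= 1e5 for b in bounds_choice):
                continue  # unbounded direction; not a vertex of interest
            rhs = -S[:, list(fixed)] @ np.array(bounds_choice)
            A = S[:, free]
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.empty(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.max(np.abs(S @ v)) > 1e-8:
                continue
            if np.all(v >= lb - 1e-9) and np.all(v <= ub + 1e-9):
                vertices.append(v)
    return vertices


class TestFba:
    def test_linear_chain_carries_uptake_limit(self, chain_model):
        sol = fba(chain_model, "R_out")
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0)
        assert sol.fluxes["R_in"] == pytest.approx(-10.0)
        assert sol.fluxes["R_ab"] == pytest.approx(10.0)

    def test_branched_net_matches_vertex_enumeration(self):
        # five-reaction branched net maximising a lumped ATP drain
        model = make_model(
            ["glc", "pyr", "atp"],
            [("up", {"glc": -1.0}, True, -5.0, 0.0),
             ("gly", {"glc": -1.0, "pyr": 2.0, "atp": 2.0}, False, 0, 1000),
             ("ferm", {"pyr": -1.0, "atp": 1.0}, False, 0, 3.0),
             ("spill", {"pyr": -1.0}, False, 0, 1000),
             ("drain", {"atp": -1.0}, False, 0, 1000)],
            objective="drain",
        )
        sol = fba(model, "drain")
        j = model.reaction_ids.index("drain")
        best = max(v[j] for v in enumerate_vertices(model))
        assert sol.objective_value == pytest.approx(best, abs=1e-8)

    def test_core_network_reaches_observed_growth_at_fitted_gam(self, core_model):
        model = build_core_network(gam=13.5, cellulosome_atp=43.28)
        cons = experiment_constraints(model, measured_fluxes("cellobiose"))
        sol = fba(model, "BIOMASS", extra_constraints=cons)
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.33, abs=0.01)

    def test_cobra_agrees_on_core_network_optimum(self):
        # independent solver route: same model, cobrapy/GLPK instead of HiGHS
        import cobra

        from thermoflux.model import to_cobra

        model = build_core_network()
        model.reaction("EX_g2").lower_bound = -3.58
        mine = fba(model, "BIOMASS").objective_value
        cm = to_cobra(model)
        cm.solver = "glpk"
        theirs = cm.optimize().objective_value
        assert mine == pytest.approx(theirs, rel=1e-6)

    def test_infeasible_reported_as_status(self, chain_model):
        cons = [FluxRatioConstraint({"R_out": 1.0}, "ge", 50.0)]
        sol = fba(chain_model, "R_out", extra_constraints=cons)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    def test_redundant_constraint_leaves_optimum_unchanged(self, chain_model):
        base = fba(chain_model, "R_out").objective_value
        cons = [FluxRatioConstraint({"R_ab": 1.0, "R_out": -1.0}, "eq", 0.0)]
        again = fba(chain_model, "R_out", extra_constraints=cons).objective_value
        assert again == pytest.approx(base, abs=1e-9)

    def test_media_preset_bounds_cysteine(self, core_model):
        model = core_model.copy()
        model.reaction("EX_g2").lower_bound = -3.58
        sol = fba(model, "BIOMASS", media=MediaSpec.mtc())
        assert sol.ok
        assert sol.fluxes["EX_cys"] >= -0.5 - 1e-9
        lc = fba(model, "BIOMASS", media=MediaSpec.lc())
        assert lc.ok
        assert lc.fluxes["EX_urea"] >= -1e-9  # urea closed on LC


class TestLoopless:
    def _cycle_model(self):
        return make_model(
            ["A", "B"],
            [("in", {"A": -1.0}, True, -10.0, 0.0),
             ("fwd", {"A": -1.0, "B": 1.0}, False, 0, 1000),
             ("bwd", {"B": -1.0, "A": 1.0}, False, 0, 1000),
             ("out", {"B": -1.0}, False, 0, 1000)],
            objective="out",
        )

    def test_futile_cycle_removed_exchanges_intact(self):
        model = self._cycle_model()
        v = FluxDistribution(
            {"in": -10.0, "fwd": 15.0, "bwd": 5.0, "out": 10.0},
            10.0, "optimal", "out")
        clean = loopless_postprocess(model, v)
        assert clean.fluxes["bwd"] == pytest.approx(0.0, abs=1e-9)
        assert clean.fluxes["fwd"] == pytest.approx(10.0, abs=1e-9)
        assert clean.fluxes["in"] == pytest.approx(-10.0)
        assert clean.objective_value == pytest.approx(10.0, abs=1e-8)

    def test_loop_free_solution_unchanged(self, chain_model):
        sol = fba(chain_model, "R_out")
        clean = loopless_postprocess(chain_model, sol)
        for rid in chain_model.reaction_ids:
            assert clean.fluxes[rid] == pytest.approx(sol.fluxes[rid], abs=1e-9)

    def test_internal_absolute_flux_minimal_by_independent_lp(self, rng):
        # oracle: independently formulated minimum |v|_1 LP over the fixed-
        # exchange polytope, built directly from the matrices here
        from scipy.optimize import linprog

        from thermoflux.synthetic import ToyNetworkParams, generate_toy_network

        for seed in range(5):
            model = generate_toy_network(ToyNetworkParams(4, 9, 0.5, seed))
            sol = fba(model, "R_out")
            if not sol.ok:
                continue
            clean = loopless_postprocess(model, sol)
            S = build_stoichiometric_matrix(model)
            n = S.shape[1]
            internal = [j for j, r in enumerate(model.reactions)
                        if not r.is_exchange]
            lb = [r.lower_bound for r in model.reactions]
            ub = [r.upper_bound for r in model.reactions]
            for j, r in enumerate(model.reactions):
                if r.is_exchange or r.id == "R_out":
                    lb[j] = ub[j] = sol.fluxes[r.id]
            # split v = p - q, p,q >= 0, minimise sum over internal
            c = np.concatenate([np.zeros(n), np.zeros(n)])
            for j in internal:
                c[j] += 1.0
                c[n + j] += 1.0
            A_eq = np.hstack([S, -S])
            bounds = [(max(l, 0), max(u, 0)) for l, u in zip(lb, ub)]
            bounds += [(max(-u, 0), max(-l, 0)) for l, u in zip(lb, ub)]
            res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]),
                          bounds=bounds, method="highs")
            assert res.success
            mine = sum(abs(clean.fluxes[model.reactions[j].id]) for j in internal)
            assert mine == pytest.approx(res.fun, abs=1e-6)


class TestConstraintBuilders:
    def test_cellobiose_only_forces_half_rate(self, core_model):
        model = core_model.copy()
        model.reaction("EX_g2").lower_bound = -1000.0
        con = cellodextrin_ratio_constraint(model, 6.39)
        sol = fba(model, "BIOMASS", extra_constraints=[con])
        assert sol.ok
        assert sol.fluxes["EX_g2"] == pytest.approx(-3.195, abs=1e-6)

    def test_g6_only(self, core_model):
        model = core_model.copy()
        model.reaction("EX_g6").lower_bound = -1000.0
        con = cellodextrin_ratio_constraint(model, 6.0)
        sol = fba(model, "BIOMASS", extra_constraints=[con])
        assert sol.ok
        assert sol.fluxes["EX_g6"] == pytest.approx(-1.0, abs=1e-6)

    def test_all_species_open_residual(self, core_model):
        model = core_model.copy()
        for n in range(1, 7):
            model.reaction(f"EX_g{n}").lower_bound = -1000.0
        con = cellodextrin_ratio_constraint(model, 6.5)
        sol = fba(model, "BIOMASS", extra_constraints=[con])
        assert sol.ok
        assert abs(con.residual(sol.fluxes)) <= 1e-6

    def test_negative_rate_rejected(self, core_model):
        with pytest.raises(ValueError):
            cellodextrin_ratio_constraint(core_model, -1.0)

    def test_sum_yield_intercept_case(self):
        con = sum_yield_constraint(0.0, "EX_g2")
        rid, mult = con.rhs_flux
        assert rid == "EX_g2"
        assert mult == pytest.approx(-1.9 * 2)  # cellobiose carries 2 glu-eq

    def test_sum_yield_at_mu_031(self):
        # (-2.9 * 0.31 + 1.9) * 6.39 = 6.39639 mmol/g DCW/h
        con = sum_yield_constraint(0.31, "EX_g6", glu_eq_weight=1.0)
        _rid, mult = con.rhs_flux
        assert -mult * 6.39 == pytest.approx(6.396, abs=2e-3)

    def test_sum_yield_root_of_line(self):
        con = sum_yield_constraint(0.6551, glu_eq_weight=1.0)
        assert abs(con.rhs_flux[1]) < 1e-3
        with pytest.raises(ValueError):
            sum_yield_constraint(0.66)

    def test_ea_ratio_noiseless_exact(self):
        con = ea_ratio_constraint(0.2, slope=5.0, intercept=0.5)
        assert con.coefficients["EX_ac"] == pytest.approx(-1.5)

    def test_ea_ratio_noise_spread_within_band(self):
        rho0 = 5.0 * 0.2 + 0.5
        draws = np.array([
            -ea_ratio_constraint(0.2, 5.0, 0.5, noise_fraction=0.2,
                                 rng=i).coefficients["EX_ac"]
            for i in range(10_000)])
        ratios = draws / rho0
        assert ratios.min() >= 0.8 - 1e-9
        assert ratios.max() <= 1.2 + 1e-9
        assert ratios.mean() == pytest.approx(1.0, abs=0.01)

    def test_ea_ratio_enforced_on_accepted_solution(self, core_model):
        model = core_model.copy()
        model.reaction("EX_g2").lower_bound = -1000.0
        con = ea_ratio_constraint(0.2, slope=5.0, intercept=0.5)
        cons = [cellodextrin_ratio_constraint(model, 6.5), con]
        sol = fba(model, "BIOMASS", extra_constraints=cons)
        assert sol.ok
        assert sol.fluxes["EX_etoh"] == pytest.approx(
            1.5 * sol.fluxes["EX_ac"], abs=1e-6)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            ea_ratio_constraint(0.1, slope=-10.0, intercept=0.5)


class TestFluxSum:
    def test_linear_chain_turnover(self, chain_model):
        sol = fba(chain_model, "R_out")
        half = flux_sum(chain_model, sol, "B")
        assert half == pytest.approx(10.0)  # 0.5 * (10 + 10)

    def test_inactive_metabolite_zero(self, core_model):
        model = core_model.copy()
        sol = fba(model, "ATPM", sense="min")
        assert flux_sum(model, sol, "g5") == pytest.approx(0.0, abs=1e-9)

    def test_unknown_metabolite_rejected(self, chain_model):
        sol = fba(chain_model, "R_out")
        with pytest.raises(KeyError):
            flux_sum(chain_model, sol, "nope")

    def test_matches_direct_summation_oracle(self, core_model, rng):
        model = core_model.copy()
        model.reaction("EX_g2").lower_bound = -3.58
        sol = fba(model, "BIOMASS")
        S = build_stoichiometric_matrix(model)
        v = np.array([sol.fluxes[rid] for rid in model.reaction_ids])
        for met in rng.choice(model.metabolite_ids, 10, replace=False):
            i = model.metabolite_ids.index(met)
            oracle = 0.5 * float(np.sum(np.abs(S[i, :] * v)))
            assert flux_sum(model, sol, met) == pytest.approx(oracle, abs=1e-9)

    def test_production_equals_consumption_at_steady_state(self, core_model):
        model = core_model.copy()
        model.reaction("EX_g2").lower_bound = -3.58
        sol = fba(model, "BIOMASS")
        S = build_stoichiometric_matrix(model)
        v = np.array([sol.fluxes[rid] for rid in model.reaction_ids])
        for met in ("atp", "nadh", "fdrd", "pyr"):
            i = model.metabolite_ids.index(met)
            terms = S[i, :] * v
            assert terms[terms > 0].sum() == pytest.approx(
                -terms[terms < 0].sum(), abs=1e-6)
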