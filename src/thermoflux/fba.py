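"""Flux balance analysis with flux-ratio constraints.

The LP is built directly from the stoichiometric matrix: maximise (or
minimise) the flux through an objective reaction subject to S.v = 0, flux
bounds, media bounds on exchange reactions, and arbitrary linear
equality/inequality constraints tying fluxes together (used for the
cellodextrin glucose-equivalent balance, the ethanol+acetate sum-yield line,
and the noisy E:A ratio constraint).  scipy's HiGHS solver is used
throughout; every solution is checked post hoc against the steady-state and
irreversibility tolerances before being returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import (
    IRREVERSIBILITY_TOL,
    STEADY_STATE_TOL,
    MetabolicModel,
    build_stoichiometric_matrix,
)

LP_TOL = 1e-9
_UNBOUNDED = 1e6  # large-but-finite cap handed to the solver


class InfeasibleProblemError(RuntimeError):
    """Raised when an LP that is expected to be solvable is not."""


@dataclass
class FluxRatioConstraint:
    """A linear constraint  sum_j coeff_j * v_j  (eq|le|ge)  rhs.

    ``rhs_flux`` expresses the right-hand side as ``multiplier * v_k`` for a
    reaction ``k``; it is folded into the coefficient vector at solve time.
    """

    coefficients: dict[str, float]
    relation: str = "eq"
    rhs: float = 0.0
    rhs_flux: tuple[str, float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("flux ratio constraint needs >=1 nonzero coefficient")
        if self.relation not in ("eq", "le", "ge"):
            raise ValueError(f"unknown relation {self.relation!r}")

    def row(self, rxn_index: dict[str, int], n: int) -> tuple[np.ndarray, float]:
        """Return (row, rhs) with any rhs_flux folded onto the left side."""
        row = np.zeros(n)
        for rid, coeff in self.coefficients.items():
            if rid not in rxn_index:
                raise KeyError(f"constraint references unknown reaction {rid!r}")
            row[rxn_index[rid]] += coeff
        if self.rhs_flux is not None:
            rid, mult = self.rhs_flux
            if rid not in rxn_index:
                raise KeyError(f"constraint references unknown reaction {rid!r}")
            row[rxn_index[rid]] -= mult
            return row, 0.0
        return row, self.rhs

    def residual(self, fluxes: dict[str, float]) -> float:
        """Signed residual lhs - rhs of the constraint at a flux vector."""
        lhs = sum(c * fluxes.get(r, 0.0) for r, c in self.coefficients.items())
        rhs = self.rhs
        if self.rhs_flux is not None:
            rid, mult = self.rhs_flux
            rhs = mult * fluxes.get(rid, 0.0)
        return lhs - rhs


@dataclass
class MediaSpec:
    """Named bounds applied to exchange reactions.

    ``bounds`` maps exchange reaction id -> (lower, upper); ``None`` means
    unbounded on that side.  Presets model the MTC defined medium (urea and
    ammonia as nitrogen sources, sulfate plus cysteine as sulfur sources with
    cysteine uptake capped at 0.5 mmol/g DCW/h) and the LC medium
    (ammonia-only nitrogen, cysteine-only sulfur).
    """

    name: str = "custom"
    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)

    @classmethod
    def mtc(cls) -> "MediaSpec":
        return cls(
            name="MTC",
            bounds={
                "EX_urea": (None, None),
                "EX_nh4": (None, None),
                "EX_so4": (None, None),
                "EX_cys": (-0.5, None),
            },
        )

    @classmethod
    def lc(cls) -> "MediaSpec":
        return cls(
            name="LC",
            bounds={
                "EX_urea": (0.0, None),
                "EX_nh4": (None, None),
                "EX_so4": (0.0, None),
                "EX_cys": (None, None),
            },
        )


@dataclass
class FluxDistribution:
    """A solved flux vector with objective value and solver status."""

    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    objective_id: str | None = None
    message: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


def _solver_bounds(model: MetabolicModel, media: MediaSpec | None):
    bounds = []
    media_bounds = media.bounds if media is not None else {}
    for r in model.reactions:
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in media_bounds:
            mlb, mub = media_bounds[r.id]
            lb = -_UNBOUNDED if mlb is None else mlb
            ub = _UNBOUNDED if mub is None else mub
        lb = max(lb, -_UNBOUNDED)
        ub = min(ub, _UNBOUNDED)
        bounds.append((lb, ub))
    return bounds


def _assemble(model, extra_constraints, media):
    S = build_stoichiometric_matrix(model)
    n = S.shape[1]
    rxn_index = {rid: j for j, rid in enumerate(model.reaction_ids)}
    A_eq = [S]
    b_eq = [np.zeros(S.shape[0])]
    A_ub, b_ub = [], []
    for con in extra_constraints or []:
        row, rhs = con.row(rxn_index, n)
        if con.relation == "eq":
            A_eq.append(row[None, :])
            b_eq.append(np.array([rhs]))
        elif con.relation == "le":
            A_ub.append(row)
            b_ub.append(rhs)
        else:  # ge
            A_ub.append(-row)
            b_ub.append(-rhs)
    A_eq = np.vstack(A_eq)
    b_eq = np.concatenate(b_eq)
    A_ub = np.vstack(A_ub) if A_ub else None
    b_ub = np.array(b_ub) if b_ub else None
    return S, rxn_index, A_eq, b_eq, A_ub, b_ub, _solver_bounds(model, media)


def _check_solution(model, extra_constraints, S, v, bounds) -> None:
    resid = float(np.max(np.abs(S @ v))) if S.size else 0.0
    if resid > STEADY_STATE_TOL:
        raise InfeasibleProblemError(f"steady-state residual {resid:g} exceeds tolerance")
    for r, vj, (lb, _ub) in zip(model.reactions, v, bounds):
        if not r.reversible and lb >= 0 and vj < -IRREVERSIBILITY_TOL:
            raise InfeasibleProblemError(
                f"irreversible reaction {r.id} carries negative flux {vj:g}"
            )


def fba(
    model: MetabolicModel,
    objective_id: str | dict[str, float] | None = None,
    extra_constraints: list[FluxRatioConstraint] | None = None,
    media: MediaSpec | None = None,
    sense: str = "max",
) -> FluxDistribution:
    """Solve the FBA linear programme.

    ``objective_id`` may be a single reaction id or a dict of reaction id ->
    weight for a composite linear objective.  Returns a
    :class:`FluxDistribution`; infeasible or unbounded problems are reported
    through ``status``, never as silent zeros.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction specified")
    weights = {objective_id: 1.0} if isinstance(objective_id, str) else dict(objective_id)
    for rid in weights:
        model.reaction(rid)  # raises on unknown id
    if sense not in ("max", "min"):
        raise ValueError(f"unknown sense {sense!r}")
    S, rxn_index, A_eq, b_eq, A_ub, b_ub, bounds = _assemble(
        model, extra_constraints, media
    )
    sign = -1.0 if sense == "max" else 1.0
    c = np.zeros(S.shape[1])
    for rid, w in weights.items():
        c[rxn_index[rid]] = sign * w
    obj_label = objective_id if isinstance(objective_id, str) else None
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
        method="highs", options={"primal_feasibility_tolerance": LP_TOL,
                                 "dual_feasibility_tolerance": LP_TOL},
    )
    if res.status == 2:
        return FluxDistribution({}, None, "infeasible", obj_label, res.message)
    if res.status == 3:
        return FluxDistribution({}, None, "unbounded", obj_label, res.message)
    if not res.success:
        return FluxDistribution({}, None, "error", obj_label, res.message)
    v = res.x
    _check_solution(model, extra_constraints, S, v, bounds)
    fluxes = {rid: float(v[j]) for rid, j in rxn_index.items()}
    obj_val = float(sum(w * fluxes[rid] for rid, w in weights.items()))
    return FluxDistribution(fluxes, obj_val, "optimal", obj_label)


def loopless_postprocess(
    model: MetabolicModel,
    v: FluxDistribution,
    extra_constraints: list[FluxRatioConstraint] | None = None,
    media: MediaSpec | None = None,
) -> FluxDistribution:
    """Remove internal (type III) cycles from an optimal flux distribution.

    Re-solves an LP that fixes every exchange flux and the objective flux at
    their current values and minimises the total absolute internal flux.  Any
    flux supported only by an internal cycle (which by definition touches no
    exchange) is zeroed; the objective value and all exchange fluxes are
    unchanged.
    """
    if not v.ok:
        raise ValueError("loopless post-processing requires an optimal solution")
    S, rxn_index, A_eq, b_eq, A_ub, b_ub, bounds = _assemble(
        model, extra_constraints, media
    )
    n = S.shape[1]
    fixed_ids = {r.id for r in model.exchanges()}
    if v.objective_id is not None:
        fixed_ids.add(v.objective_id)
    new_bounds = list(bounds)
    for rid in fixed_ids:
        j = rxn_index[rid]
        val = v.fluxes[rid]
        new_bounds[j] = (val, val)
    # minimise sum |v_j| over internal reactions via auxiliary t_j >= |v_j|
    internal = [j for rid, j in rxn_index.items() if rid not in fixed_ids]
    c = np.zeros(2 * n)
    for j in internal:
        c[n + j] = 1.0
    A_ub_rows = [] if A_ub is None else [np.hstack([A_ub, np.zeros_like(A_ub)])]
    b_ub_rows = [] if b_ub is None else [b_ub]
    for j in internal:
        row = np.zeros(2 * n)
        row[j], row[n + j] = 1.0, -1.0  # v_j - t_j <= 0
        A_ub_rows.append(row[None, :])
        b_ub_rows.append(np.array([0.0]))
        row = np.zeros(2 * n)
        row[j], row[n + j] = -1.0, -1.0  # -v_j - t_j <= 0
        A_ub_rows.append(row[None, :])
        b_ub_rows.append(np.array([0.0]))
    A_ub2 = np.vstack(A_ub_rows)
    b_ub2 = np.concatenate(b_ub_rows)
    A_eq2 = np.hstack([A_eq, np.zeros((A_eq.shape[0], n))])
    t_bounds = [(0.0, _UNBOUNDED)] * n
    res = linprog(
        c, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq2, b_eq=b_eq,
        bounds=new_bounds + t_bounds, method="highs",
    )
    if not res.success:
        raise InfeasibleProblemError(f"loopless re-solve failed: {res.message}")
    vv = res.x[:n]
    _check_solution(model, extra_constraints, S, vv, new_bounds)
    fluxes = {rid: float(vv[j]) for rid, j in rxn_index.items()}
    obj = fluxes[v.objective_id] if v.objective_id else v.objective_value
    return FluxDistribution(fluxes, obj, "optimal", v.objective_id)


def flux_sum(model: MetabolicModel, v: FluxDistribution, metabolite_id: str) -> float:
    """Turnover rate of a metabolite: half the sum of |s_ij * v_j|."""
    model.metabolite(metabolite_id)  # raises on unknown id
    total = 0.0
    for rxn in model.reactions:
        coeff = rxn.stoichiometry.get(metabolite_id)
        if coeff:
            total += abs(coeff * v.fluxes.get(rxn.id, 0.0))
    return 0.5 * total


# ---------------------------------------------------------------------------
# Constraint builders
# ---------------------------------------------------------------------------

#: Uptake reactions for glucose (G1) through cellohexaose (G6), and the
#: glucose-equivalent weight each carries in the carbon bookkeeping.
CELLODEXTRIN_UPTAKES = {
    "EX_g1": 1,
    "EX_g2": 2,
    "EX_g3": 3,
    "EX_g4": 4,
    "EX_g5": 5,
    "EX_g6": 6,
}


def cellodextrin_ratio_constraint(
    model: MetabolicModel, glu_eq_rate: float
) -> FluxRatioConstraint:
    """Glucose-equivalent balance over the six cellodextrin uptakes.

    An oligomer of length N counts N glucose equivalents, so
    ``6 r_G6 + 5 r_G5 + ... + 1 r_G1 = r_GluEq``.  Uptake exchanges carry
    negative flux, so the coefficients are negated to make the constraint
    right-hand side the positive uptake magnitude.
    """
    if glu_eq_rate < 0:
        raise ValueError("glucose-equivalent uptake rate must be >= 0")
    missing = [rid for rid in CELLODEXTRIN_UPTAKES if not model.has_reaction(rid)]
    if missing:
        raise KeyError(f"model lacks cellodextrin uptake reaction(s) {missing}")
    coeffs = {rid: -float(n) for rid, n in CELLODEXTRIN_UPTAKES.items()}
    return FluxRatioConstraint(
        coefficients=coeffs, relation="eq", rhs=glu_eq_rate, name="glu_eq_balance"
    )


#: Default slope/intercept of the ethanol+acetate sum-yield line (mol per mol
#: glucose equivalent as a function of growth rate).
SUM_YIELD_SLOPE = -2.9
SUM_YIELD_INTERCEPT = 1.9


def sum_yield_constraint(
    mu: float,
    glu_eq_reaction: str = "EX_g2",
    ethanol_reaction: str = "EX_etoh",
    acetate_reaction: str = "EX_ac",
    slope: float = SUM_YIELD_SLOPE,
    intercept: float = SUM_YIELD_INTERCEPT,
    glu_eq_weight: float | None = None,
) -> FluxRatioConstraint:
    """Constrain r_E + r_A = (slope*mu + intercept) * r_GluEq.

    ``glu_eq_reaction`` may be a substrate exchange (uptake negative); the
    multiplier is negated accordingly and scaled by the oligomer's
    glucose-equivalent weight so the yield basis is per glucose equivalent.
    """
    y = slope * mu + intercept
    if mu < 0 or y < 0:
        raise ValueError(
            f"growth rate {mu} outside the validity range of the sum-yield line "
            f"(requires 0 <= mu <= {-intercept / slope:.4f})"
        )
    if glu_eq_weight is None:
        glu_eq_weight = CELLODEXTRIN_UPTAKES.get(glu_eq_reaction, 1)
    return FluxRatioConstraint(
        coefficients={ethanol_reaction: 1.0, acetate_reaction: 1.0},
        relation="eq",
        rhs_flux=(glu_eq_reaction, -y * glu_eq_weight),
        name="sum_yield",
    )


def ea_ratio_constraint(
    mu: float,
    slope: float,
    intercept: float,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
    ethanol_reaction: str = "EX_etoh",
    acetate_reaction: str = "EX_ac",
) -> FluxRatioConstraint:
    """Linearised ethanol:acetate ratio constraint r_E - rho' * r_A = 0.

    rho = slope*mu + intercept; with ``noise_fraction`` f > 0, the slope and
    intercept are each independently perturbed by a uniform multiplicative
    factor on [1-f, 1+f] (one draw per call, reproducible from ``rng``),
    emulating the experimental scatter of the ratio line.
    """
    if noise_fraction:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        slope = slope * gen.uniform(1 - noise_fraction, 1 + noise_fraction)
        intercept = intercept * gen.uniform(1 - noise_fraction, 1 + noise_fraction)
    rho = slope * mu + intercept
    if rho <= 0:
        raise ValueError(f"E:A ratio {rho:g} must be positive (mu={mu:g})")
    return FluxRatioConstraint(
        coefficients={ethanol_reaction: 1.0, acetate_reaction: -rho},
        relation="eq",
        rhs=0.0,
        name="ea_ratio",
    )
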