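"""Constrained uniform flux sampling across a growth-rate grid.

The protocol mirrors the bioenergetic sampling study design: for each of a
set of randomly drawn growth rates (truncated normal on [0, 0.3] 1/h) and
glucose-equivalent uptake rates (uniform on 5.0-7.5 mmol/g DCW/h, shared
between the cellobiose and cellulose member of each grid pair), the growth
rate and uptake are fixed, the ethanol+acetate sum-yield line and the noisy
ethanol:acetate ratio line are imposed as flux-ratio constraints, all other
fermentation products are left unconstrained, and the resulting flux
polytope is sampled uniformly with a coordinate hit-and-run chain in the
null space of the equality constraints.  Summaries report per-growth-point
means and standard deviations of reaction fluxes and of cofactor turnover
(flux-sum) rates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .fba import (
    FluxRatioConstraint,
    MediaSpec,
    cellodextrin_ratio_constraint,
    ea_ratio_constraint,
    fba,
    sum_yield_constraint,
)
from .model import MetabolicModel, build_stoichiometric_matrix

#: Default E:A-versus-growth-rate lines per substrate (slope, intercept).
#: Reconstructed from the observed ratio trends: cellobiose cultures reach
#: E:A ~2 near mu = 0.3 while cellulose cultures stay below 1.
EA_LINES = {"cellobiose": (5.0, 0.5), "cellulose": (1.0, 0.25)}

RESIDUAL_TOL = 1e-6


@dataclass
class SamplingConfig:
    """Configuration of the sampling protocol."""

    n_growth_points: int = 100
    mu_range: tuple[float, float] = (0.0, 0.3)
    mu_mean: float = 0.15
    mu_sd: float = 0.075
    uptake_range: tuple[float, float] = (5.0, 7.5)
    noise_fraction: float = 0.2
    chain_steps: int = 1000
    retained: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_range[0] >= self.mu_range[1]:
            raise ValueError("growth-rate range is degenerate")
        if self.uptake_range[0] >= self.uptake_range[1]:
            raise ValueError("uptake range is degenerate")
        if self.retained > self.chain_steps:
            raise ValueError("cannot retain more states than chain steps")

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplingConfig":
        """A 10x-reduced preset for quick runs."""
        return cls(n_growth_points=10, chain_steps=100, retained=100, seed=seed)

    @classmethod
    def narrow_uptake(cls, seed: int = 0) -> "SamplingConfig":
        """Preset with the narrower 5.5-7.5 uptake range variant."""
        return cls(uptake_range=(5.5, 7.5), seed=seed)


@dataclass
class ConditionPoint:
    """One growth-rate/uptake grid point for one substrate."""

    index: int
    substrate: str
    mu: float
    uptake: float  # mmol glucose equivalents/g DCW/h
    sum_yield_rhs: float  # (slope*mu + intercept) in mol/mol glucose eq
    ea_ratio: float  # realised (noise-perturbed) E:A ratio rho'
    seed: int

    def __post_init__(self) -> None:
        if self.ea_ratio <= 0:
            raise ValueError("E:A ratio must be positive")


@dataclass
class SampleSet:
    """Retained flux distributions per condition point."""

    config: SamplingConfig
    substrate: str
    points: list[ConditionPoint]
    samples: dict[int, np.ndarray]  # point index -> (retained, n_reactions)
    reaction_ids: list[str]
    infeasible: list[int] = field(default_factory=list)

    def n_samples(self) -> int:
        return sum(s.shape[0] for s in self.samples.values())


def generate_condition_grid(
    config: SamplingConfig, substrate: str,
    ea_line: tuple[float, float] | None = None,
) -> list[ConditionPoint]:
    """Draw the seeded growth-rate/uptake grid for one substrate.

    The random draws depend only on the seed and grid index, never on the
    substrate, so the cellobiose and cellulose grids share identical growth
    and uptake draws point by point; only the E:A line (and its noise draw)
    is substrate-specific.
    """
    if ea_line is None:
        ea_line = EA_LINES[substrate]
    slope, intercept = ea_line
    lo, hi = config.mu_range
    a = (lo - config.mu_mean) / config.mu_sd
    b = (hi - config.mu_mean) / config.mu_sd
    points = []
    for i in range(config.n_growth_points):
        shared = np.random.default_rng((config.seed, i))
        mu = float(truncnorm.rvs(a, b, loc=config.mu_mean, scale=config.mu_sd,
                                 random_state=shared))
        uptake = float(shared.uniform(*config.uptake_range))
        sub_rng = np.random.default_rng(
            (config.seed, i, zlib.crc32(substrate.encode()) % 2**16))
        con = ea_ratio_constraint(mu, slope, intercept,
                                  noise_fraction=config.noise_fraction,
                                  rng=sub_rng)
        rho = -con.coefficients["EX_ac"]
        sum_yield_constraint(mu)  # validates mu against the line's root
        from .fba import SUM_YIELD_INTERCEPT, SUM_YIELD_SLOPE

        y = SUM_YIELD_SLOPE * mu + SUM_YIELD_INTERCEPT
        points.append(ConditionPoint(
            index=i, substrate=substrate, mu=mu, uptake=uptake,
            sum_yield_rhs=y, ea_ratio=rho,
            seed=int(np.random.default_rng((config.seed, i, 7)).integers(2**31))))
    return points


def _point_constraints(
    model: MetabolicModel, point: ConditionPoint,
) -> list[FluxRatioConstraint]:
    cons = [cellodextrin_ratio_constraint(model, point.uptake)]
    cons.append(FluxRatioConstraint({"BIOMASS": 1.0}, "eq", point.mu,
                                    name="fix_growth"))
    cons.append(FluxRatioConstraint(
        {"EX_etoh": 1.0, "EX_ac": 1.0}, "eq",
        point.sum_yield_rhs * point.uptake, name="sum_yield"))
    cons.append(FluxRatioConstraint(
        {"EX_etoh": 1.0, "EX_ac": -point.ea_ratio}, "eq", 0.0, name="ea_ratio"))
    return cons


def _open_uptakes(model: MetabolicModel, substrate: str) -> None:
    if substrate == "cellobiose":
        model.reaction("EX_g2").lower_bound = -1000.0
    else:
        for n in range(1, 7):
            model.reaction(f"EX_g{n}").lower_bound = -1000.0


def sample_point(
    model: MetabolicModel,
    point: ConditionPoint,
    config: SamplingConfig,
    media: MediaSpec | None = None,
) -> np.ndarray | None:
    """Uniformly sample the constraint polytope of one condition point.

    Returns a (retained, n_reactions) array, or None when the polytope is
    empty.  The chain is a hit-and-run walk in the null space of the
    equality constraints, started from the feasibility-LP solution, with a
    warm-up of ``chain_steps`` moves followed by ``chain_steps`` recorded
    moves thinned to ``retained`` states.
    """
    work = model.copy()
    _open_uptakes(work, point.substrate)
    cons = _point_constraints(work, point)
    probe = work.objective_id or work.reactions[0].id
    check = fba(work, probe, extra_constraints=cons, media=media, sense="max")
    if not check.ok:
        return None

    S = build_stoichiometric_matrix(work)
    n = S.shape[1]
    rxn_index = {rid: j for j, rid in enumerate(work.reaction_ids)}
    rows, rhs = [S], [np.zeros(S.shape[0])]
    for con in cons:
        row, r = con.row(rxn_index, n)
        rows.append(row[None, :])
        rhs.append(np.array([r]))
    A = np.vstack(rows)
    b = np.concatenate(rhs)
    lb = np.array([max(r.lower_bound, -1e6) for r in work.reactions])
    ub = np.array([min(r.upper_bound, 1e6) for r in work.reactions])
    if media is not None:
        for rid, (mlb, mub) in media.bounds.items():
            j = rxn_index[rid]
            lb[j] = -1e6 if mlb is None else mlb
            ub[j] = 1e6 if mub is None else mub

    # particular solution (the feasibility-LP optimum) and null-space basis
    v_feas = np.array([check.fluxes[rid] for rid in work.reaction_ids])
    _u, s, vt = np.linalg.svd(A)
    rank = int(np.sum(s > 1e-9 * s[0])) if s.size else 0
    N = vt[rank:].T  # n x d
    d = N.shape[1]
    if d == 0:
        return np.tile(v_feas, (config.retained, 1))

    rng = np.random.default_rng(point.seed)
    t = np.zeros(d)  # walk relative to v_feas, staying in the null space

    def current() -> np.ndarray:
        return v_feas + N @ t

    total = 2 * config.chain_steps  # first half is warm-up
    states = np.empty((config.chain_steps, n))
    for step in range(total):
        direction = N @ rng.standard_normal(d)
        nrm = np.linalg.norm(direction)
        v = current()
        if nrm > 1e-12:
            direction /= nrm
            with np.errstate(divide="ignore", invalid="ignore"):
                to_ub = (ub - v) / direction
                to_lb = (lb - v) / direction
            upper = np.where(direction > 1e-10, to_ub,
                             np.where(direction < -1e-10, to_lb, np.inf))
            lower = np.where(direction > 1e-10, to_lb,
                             np.where(direction < -1e-10, to_ub, -np.inf))
            hi = min(float(np.min(upper)), 1e6)
            lo = max(float(np.max(lower)), -1e6)
            if hi > lo:
                alpha = rng.uniform(lo, hi)
                t = t + alpha * (N.T @ direction)
                v = current()
        if step >= config.chain_steps:
            states[step - config.chain_steps] = v
    idx = np.linspace(0, config.chain_steps - 1, config.retained).astype(int)
    return states[idx]


def run_sampling(
    model: MetabolicModel,
    config: SamplingConfig,
    substrate: str,
    media: MediaSpec | None = None,
    ea_line: tuple[float, float] | None = None,
) -> SampleSet:
    """Run the full protocol for one substrate."""
    points = generate_condition_grid(config, substrate, ea_line)
    samples: dict[int, np.ndarray] = {}
    infeasible: list[int] = []
    for point in points:
        arr = sample_point(model, point, config, media)
        if arr is None:
            infeasible.append(point.index)
        else:
            samples[point.index] = arr
    return SampleSet(config=config, substrate=substrate, points=points,
                     samples=samples, reaction_ids=list(model.reaction_ids),
                     infeasible=infeasible)


def summarize_by_growth(
    samples: SampleSet, reaction_ids: list[str]
) -> pd.DataFrame:
    """Per-growth-point mean and standard deviation of selected fluxes."""
    if not samples.samples:
        raise ValueError("sample set is empty")
    col = {rid: samples.reaction_ids.index(rid) for rid in reaction_ids}
    records = []
    for point in samples.points:
        if point.index not in samples.samples:
            continue
        arr = samples.samples[point.index]
        for rid, j in col.items():
            records.append({
                "substrate": samples.substrate, "mu": point.mu,
                "reaction": rid, "mean": float(arr[:, j].mean()),
                "sd": float(arr[:, j].std(ddof=0)), "n": arr.shape[0],
            })
    return pd.DataFrame.from_records(records).sort_values(
        ["reaction", "mu"]).reset_index(drop=True)


DEFAULT_COFACTORS = ("atp", "gtp", "ppi", "fdrd", "nadh", "nadph")


def cofactor_turnover_profile(
    model: MetabolicModel,
    samples: SampleSet,
    cofactors: tuple[str, ...] = DEFAULT_COFACTORS,
) -> pd.DataFrame:
    """Mean flux-sum turnover of each cofactor at each sampled growth rate."""
    for met in cofactors:
        model.metabolite(met)
    S = build_stoichiometric_matrix(model)
    met_row = {mid: i for i, mid in enumerate(model.metabolite_ids)}
    records = []
    for point in samples.points:
        if point.index not in samples.samples:
            continue
        arr = samples.samples[point.index]
        for met in cofactors:
            weights = np.abs(S[met_row[met], :])
            phi = 0.5 * (np.abs(arr) @ weights)
            records.append({
                "substrate": samples.substrate, "mu": point.mu,
                "cofactor": met, "mean_phi": float(phi.mean()),
                "sd_phi": float(phi.std(ddof=0)), "n": arr.shape[0],
            })
    return pd.DataFrame.from_records(records).sort_values(
        ["cofactor", "mu"]).reset_index(drop=True)


def check_sample_residuals(
    model: MetabolicModel, samples: SampleSet, tol: float = RESIDUAL_TOL
) -> float:
    """Maximum steady-state/constraint residual over all retained samples."""
    work = model.copy()
    _open_uptakes(work, samples.substrate)
    S = build_stoichiometric_matrix(work)
    rxn_index = {rid: j for j, rid in enumerate(work.reaction_ids)}
    worst = 0.0
    for point in samples.points:
        if point.index not in samples.samples:
            continue
        arr = samples.samples[point.index]
        worst = max(worst, float(np.max(np.abs(arr @ S.T))))
        for con in _point_constraints(work, point):
            row, r = con.row(rxn_index, S.shape[1])
            worst = max(worst, float(np.max(np.abs(arr @ row - r))))
    return worst
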