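"""ATP-maintenance calibration and experimental flux computation.

Two scan procedures mirror the model-training protocol: the growth-associated
maintenance (GAM) coefficient is scanned while maximising growth on
cellobiose under the measured fermentation fluxes, and the cellulosome
synthesis ATP coefficient is scanned the same way on cellulose with the
fitted GAM held fixed.  The best fit is the grid point whose predicted
growth rate is closest to the measured one.

Experimental specific rates are computed from concentration time series:
batch cultures via the exponential-phase relation v_P = mu * Y_P/X with mu
from a log-linear fit of biomass, chemostats via v_P = D * dC_P / dC_X.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .biomass import (
    ATPRequirementTable,
    BiomassComposition,
    CellulosomeSpec,
    assemble_biomass,
)
from .fba import FluxDistribution, FluxRatioConstraint, MediaSpec, fba, cellodextrin_ratio_constraint
from .model import MetabolicModel, Reaction

#: Mapping from measured quantity names to exchange reactions.
_PRODUCT_EXCHANGES = {
    "ethanol": "EX_etoh",
    "acetate": "EX_ac",
    "formate": "EX_for",
    "hydrogen": "EX_h2",
    "valine": "EX_val",
    "lactate": "EX_lac",
}

GLUCOSE_EQ_MASS = 0.1620  # g anhydroglucose per mmol glucose equivalent


@dataclass
class ExperimentalFluxSet:
    """Measured fermentation fluxes used as model constraints.

    ``uptake`` is in mmol cellobiose/g DCW/h for cellobiose cultures and in
    mmol glucose equivalents/g DCW/h for cellulose cultures; products are in
    mmol/g DCW/h; unmeasured products are simply absent and left
    unconstrained.
    """

    substrate: str
    uptake: float
    products: dict[str, float]
    mu: float
    uncertainty: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.substrate not in ("cellobiose", "cellulose"):
            raise ValueError(f"unknown substrate {self.substrate!r}")
        if self.uptake < 0 or any(v < 0 for v in self.products.values()):
            raise ValueError("flux magnitudes must be non-negative")
        if self.mu <= 0:
            raise ValueError("growth rate must be positive")

    def glucose_equivalent_uptake(self) -> float:
        return 2.0 * self.uptake if self.substrate == "cellobiose" else self.uptake


def measured_fluxes(substrate: str) -> ExperimentalFluxSet:
    """Load the bundled experimental flux table for one substrate."""
    text = resources.files("thermoflux.data").joinpath("fermentation_fluxes.csv").read_text()
    rows = [r for r in csv.DictReader(io.StringIO(text)) if r["substrate"] == substrate]
    if not rows:
        raise ValueError(f"no bundled fluxes for substrate {substrate!r}")
    values = {r["quantity"]: float(r["mean"]) for r in rows}
    unc = {r["quantity"]: float(r["sd"]) for r in rows}
    uptake_key = ("uptake_cellobiose" if substrate == "cellobiose"
                  else "uptake_glucose_equivalents")
    products = {k: v for k, v in values.items()
                if k in _PRODUCT_EXCHANGES}
    return ExperimentalFluxSet(
        substrate=substrate, uptake=values[uptake_key], products=products,
        mu=values["growth_rate"], uncertainty=unc)


def experiment_constraints(
    model: MetabolicModel,
    exp: ExperimentalFluxSet,
    mode: str = "range",
) -> list[FluxRatioConstraint]:
    """Constraints fixing the measured fluxes on the model.

    ``mode='mean'`` fixes each measured flux at its mean; ``mode='range'``
    bounds it within mean +/- reported SD.  Cellobiose cultures take up the
    disaccharide only; cellulose hydrolysate uptake is expressed through the
    glucose-equivalent balance over all cellodextrin species.  Uptake
    exchanges are opened as a side effect (uptake flux is negative).
    """
    if mode not in ("mean", "range"):
        raise ValueError(f"unknown constraint mode {mode!r}")
    cons: list[FluxRatioConstraint] = []

    def fix(rxn_id: str, value: float, sd: float) -> None:
        if mode == "mean" or sd == 0.0:
            cons.append(FluxRatioConstraint({rxn_id: 1.0}, "eq", value,
                                            name=f"fix_{rxn_id}"))
        else:
            cons.append(FluxRatioConstraint({rxn_id: 1.0}, "ge", value - sd,
                                            name=f"lo_{rxn_id}"))
            cons.append(FluxRatioConstraint({rxn_id: 1.0}, "le", value + sd,
                                            name=f"hi_{rxn_id}"))

    if exp.substrate == "cellobiose":
        model.reaction("EX_g2").lower_bound = -1000.0
        fix("EX_g2", -exp.uptake, exp.uncertainty.get("uptake_cellobiose", 0.0))
    else:
        for n in range(1, 7):
            model.reaction(f"EX_g{n}").lower_bound = -1000.0
        cons.append(cellodextrin_ratio_constraint(model, exp.uptake))
    for name, value in exp.products.items():
        fix(_PRODUCT_EXCHANGES[name], value,
            exp.uncertainty.get(name, 0.0))
    return cons


@dataclass
class MaintenanceFit:
    """Result of an ATP-coefficient scan against a measured growth rate."""

    grid: np.ndarray
    predicted_mu: np.ndarray  # NaN where infeasible
    best_fit: float
    target_mu: float
    target_band: tuple[float, float]
    identifiable: bool = True

    def predicted_at_best(self) -> float:
        i = int(np.nanargmin(np.abs(self.grid - self.best_fit)))
        return float(self.predicted_mu[i])


def _scan(
    build,
    grid: np.ndarray,
    target_mu: float,
    media: MediaSpec | None,
    constraints,
) -> tuple[np.ndarray, list[FluxDistribution | None]]:
    mus = np.full(len(grid), np.nan)
    sols: list[FluxDistribution | None] = [None] * len(grid)
    for i, g in enumerate(grid):
        model = build(float(g))
        sol = fba(model, "BIOMASS", extra_constraints=constraints(model),
                  media=media, sense="max")
        if sol.ok:
            mus[i] = sol.objective_value
            sols[i] = sol
    return mus, sols


def _best(grid: np.ndarray, mus: np.ndarray, target: float) -> float:
    if np.all(np.isnan(mus)):
        raise RuntimeError(
            "scan infeasible at every grid point; check the experimental "
            "constraints for consistency with the network")
    err = np.abs(mus - target)
    best = np.nanmin(err)
    # ties (within solver noise) break toward the larger coefficient
    candidates = grid[np.where(err <= best + 1e-9)]
    return float(np.max(candidates))


def fit_gam(
    model: MetabolicModel,
    exp: ExperimentalFluxSet,
    grid: tuple[float, float, float] = (1.0, 50.0, 0.5),
    refine_step: float = 0.1,
    media: MediaSpec | None = None,
    constraint_mode: str = "range",
    cellulosome_atp: float | None = None,
    biomass: BiomassComposition | None = None,
    atp_table: ATPRequirementTable | None = None,
) -> MaintenanceFit:
    """Scan the GAM coefficient and return the best fit to the measured mu.

    The cellulosome ATP coefficient is held at the protein-term default
    (43.28 mmol ATP/g) unless given, matching the pre-calibration setting.
    """
    if exp.substrate != "cellobiose":
        raise ValueError("GAM is calibrated on cellobiose-grown cultures")
    biomass = biomass or BiomassComposition()
    atp_table = atp_table or ATPRequirementTable()
    if cellulosome_atp is None:
        cellulosome_atp = atp_table.protein_term_atp
    base = model.copy()
    demand = _cellulosome_demand_of(base)

    def build(gam: float) -> MetabolicModel:
        m = base.copy()
        spec = CellulosomeSpec(amino_acid_demand=demand,
                               atp_coefficient=cellulosome_atp)
        assemble_biomass(m, biomass, atp_table, spec, "cellobiose", gam)
        return m

    def constraints(m: MetabolicModel):
        return experiment_constraints(m, exp, constraint_mode)

    lo, hi, step = grid
    coarse = np.round(np.arange(lo, hi + step / 2, step), 6)
    mus, _ = _scan(build, coarse, exp.mu, media, constraints)
    best_coarse = _best(coarse, mus, exp.mu)
    fine = np.round(np.arange(max(lo, best_coarse - step),
                              min(hi, best_coarse + step) + refine_step / 2,
                              refine_step), 6)
    fmus, _ = _scan(build, fine, exp.mu, media, constraints)
    best = _best(fine, fmus, exp.mu)
    grid_all = np.concatenate([coarse, fine])
    mu_all = np.concatenate([mus, fmus])
    order = np.argsort(grid_all, kind="stable")
    band = exp.uncertainty.get("growth_rate", 0.0)
    return MaintenanceFit(grid_all[order], mu_all[order], best, exp.mu,
                          (exp.mu - band, exp.mu + band))


def fit_cellulosome_atp(
    model: MetabolicModel,
    exp: ExperimentalFluxSet,
    gam: float,
    grid: tuple[float, float, float] = (40.0, 100.0, 1.0),
    media: MediaSpec | None = None,
    constraint_mode: str = "range",
    biomass: BiomassComposition | None = None,
    atp_table: ATPRequirementTable | None = None,
) -> MaintenanceFit:
    """Scan the cellulosome synthesis ATP coefficient on cellulose data."""
    if exp.substrate != "cellulose":
        raise ValueError("the cellulosome ATP cost is calibrated on cellulose")
    biomass = biomass or BiomassComposition()
    atp_table = atp_table or ATPRequirementTable()
    base = model.copy()
    demand = _cellulosome_demand_of(base)
    fraction = CellulosomeSpec(amino_acid_demand=demand).dcw_fraction["cellulose"]

    def build(cel_atp: float) -> MetabolicModel:
        m = base.copy()
        spec = CellulosomeSpec(amino_acid_demand=demand, atp_coefficient=cel_atp)
        assemble_biomass(m, biomass, atp_table, spec, "cellulose", gam)
        return m

    def constraints(m: MetabolicModel):
        return experiment_constraints(m, exp, constraint_mode)

    lo, hi, step = grid
    points = np.round(np.arange(lo, hi + step / 2, step), 6)
    mus, _ = _scan(build, points, exp.mu, media, constraints)
    if fraction == 0.0 or (np.sum(~np.isnan(mus)) > 1
                           and np.nanmax(mus) - np.nanmin(mus) < 1e-10):
        band = exp.uncertainty.get("growth_rate", 0.0)
        return MaintenanceFit(points, mus, float("nan"), exp.mu,
                              (exp.mu - band, exp.mu + band), identifiable=False)
    best = _best(points, mus, exp.mu)
    band = exp.uncertainty.get("growth_rate", 0.0)
    return MaintenanceFit(points, mus, best, exp.mu,
                          (exp.mu - band, exp.mu + band))


def _cellulosome_demand_of(model: MetabolicModel) -> np.ndarray:
    """Recover or rebuild the cellulosome amino-acid demand for a model."""
    from .synthetic import default_cellulosome_demand

    return default_cellulosome_demand()


# ---------------------------------------------------------------------------
# Cellodextrin yield analysis
# ---------------------------------------------------------------------------


def cellodextrin_yield_curve(
    model: MetabolicModel,
    glu_eq_rate: float = 6.5,
    media: MediaSpec | None = None,
) -> dict[str, float]:
    """Maximal protein yield (g protein/g glucose equivalent) per sugar.

    For each cellodextrin species G1..G6 as the sole carbon source, the
    glucose-equivalent uptake is fixed at ``glu_eq_rate`` through the chain
    length balance, and the summed flux to cellulosome plus cell protein is
    maximised.  The yield divides the proteinaceous mass flux by the glucose
    equivalent mass uptake.  Infeasible species are recorded as absent.
    """
    yields: dict[str, float] = {}
    for n in range(1, 7):
        m = model.copy()
        for rid in ("DRAIN_protein", "DRAIN_cellulosome"):
            met = rid.split("_")[1]
            m.reactions.append(Reaction(rid, {met: -1.0}, subsystem="analysis"))
        for k in range(1, 7):
            m.reaction(f"EX_g{k}").lower_bound = -1000.0 if k == n else 0.0
        cons = [cellodextrin_ratio_constraint(m, glu_eq_rate)]
        sol = fba(m, {"DRAIN_protein": 1.0, "DRAIN_cellulosome": 1.0},
                  extra_constraints=cons, media=media, sense="max")
        if not sol.ok:
            continue
        protein_flux = sol.objective_value  # g proteinaceous matter/g DCW/h
        yields[f"G{n}"] = protein_flux / (glu_eq_rate * GLUCOSE_EQ_MASS)
    return yields


def predict_mutant_growth(
    model: MetabolicModel,
    fixed_product_fluxes: dict[str, float],
    media: MediaSpec | None = None,
) -> FluxDistribution:
    """Maximal growth with named exchange fluxes pinned to given values."""
    cons = [FluxRatioConstraint({rid: 1.0}, "eq", val, name=f"fix_{rid}")
            for rid, val in fixed_product_fluxes.items()]
    return fba(model, "BIOMASS", extra_constraints=cons, media=media, sense="max")


# ---------------------------------------------------------------------------
# Experimental fluxes from concentration data
# ---------------------------------------------------------------------------


@dataclass
class ConcentrationSeries:
    """Concentration time series from a batch or chemostat culture."""

    times: np.ndarray  # h
    biomass: np.ndarray  # g DCW/L
    concentrations: dict[str, np.ndarray]  # mmol/L per metabolite
    mode: str = "batch"
    dilution_rate: float | None = None  # 1/h (chemostat)
    inlet: dict[str, float] = field(default_factory=dict)  # chemostat inlet

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.biomass = np.asarray(self.biomass, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(self.biomass <= 0):
            raise ValueError("biomass concentrations must be positive")
        if self.mode not in ("batch", "chemostat"):
            raise ValueError(f"unknown mode {self.mode!r}")


def fluxes_from_batch(series: ConcentrationSeries) -> ExperimentalFluxSet:
    """Specific rates from exponential-phase batch data: v_P = mu * Y_P/X.

    mu comes from an ordinary least-squares fit of ln C_X against time;
    yields Y_P/X from linear fits of C_P against C_X (equivalent to the
    ratio of the time derivatives during balanced exponential growth).
    """
    if series.mode != "batch":
        raise ValueError("series is not a batch culture")
    if len(series.times) < 3:
        raise ValueError("need >=3 exponential-phase time points")
    t = series.times
    mu = float(np.polyfit(t, np.log(series.biomass), 1)[0])
    if mu <= 0:
        raise ValueError(f"non-positive growth rate {mu:g} from biomass fit")
    products = {}
    for met, conc in series.concentrations.items():
        y = float(np.polyfit(series.biomass, np.asarray(conc, float), 1)[0])
        products[met] = mu * max(y, 0.0)
    return ExperimentalFluxSet(
        substrate="cellobiose", uptake=products.pop("uptake", 0.0),
        products=products, mu=mu)


def fluxes_from_chemostat(series: ConcentrationSeries) -> ExperimentalFluxSet:
    """Steady-state chemostat rates: v_P = D * (C_P,out - C_P,in)/(C_X,out - C_X,in)."""
    if series.mode != "chemostat":
        raise ValueError("series is not a chemostat culture")
    if series.dilution_rate is None or series.dilution_rate <= 0:
        raise ValueError("chemostat series needs a positive dilution rate")
    d = series.dilution_rate
    cx_out = float(np.mean(series.biomass))
    cx_in = float(series.inlet.get("biomass", 0.0))
    if abs(cx_out - cx_in) < 1e-12:
        raise ValueError("inlet and outlet biomass are equal; rates undefined")
    products = {}
    for met, conc in series.concentrations.items():
        cp_out = float(np.mean(np.asarray(conc, float)))
        cp_in = float(series.inlet.get(met, 0.0))
        products[met] = d * (cp_out - cp_in) / (cx_out - cx_in)
    return ExperimentalFluxSet(
        substrate="cellobiose", uptake=products.pop("uptake", 0.0),
        products={k: max(v, 0.0) for k, v in products.items()}, mu=d)
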