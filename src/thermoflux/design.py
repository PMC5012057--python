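"""Elementary-mode enumeration and constrained minimal cut sets (cMCS).

Elementary modes are support-minimal steady-state flux patterns satisfying
irreversibility; they are enumerated with the classic double-description
(tableau) algorithm on the reversible-split network.  Constrained minimal
cut sets are reaction-deletion sets that remove every undesired mode (yield
below a floor) while leaving at least one desired mode (growth above a floor
at sufficient yield); they are found by enumerating minimal hitting sets of
the target-mode supports and certifying each candidate by FBA.  Both are
toy/core-scale tools: enumeration refuses networks beyond a configurable
size instead of silently truncating.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .fba import FluxRatioConstraint, fba
from .model import MetabolicModel, Reaction, build_stoichiometric_matrix

DEFAULT_SIZE_LIMIT = 30  # reactions after reversible splitting
_TOL = 1e-9


class EnumerationLimitError(RuntimeError):
    """Raised when a network exceeds the elementary-mode enumeration limit."""


@dataclass(frozen=True)
class ElementaryMode:
    """A support-minimal flux pattern, normalised to max |coefficient| 1."""

    support: frozenset[str]
    fluxes: tuple[tuple[str, float], ...]

    def flux_dict(self) -> dict[str, float]:
        return dict(self.fluxes)


@dataclass
class DesignSpec:
    """Growth-coupled production requirements for strain design."""

    product_id: str
    substrate_id: str
    min_yield_fraction: float = 0.6
    min_growth: float = 1e-4
    max_cut_set_size: int = 4
    deletable: list[str] | None = None
    growth_id: str = "BIOMASS"

    def __post_init__(self) -> None:
        if not 0 < self.min_yield_fraction <= 1:
            raise ValueError("yield fraction must be in (0, 1]")
        if self.min_growth <= 0:
            raise ValueError("growth floor must be positive")


@dataclass
class CutSetDesign:
    """A certified set of reaction deletions."""

    deletions: frozenset[str]
    certified: bool
    n_target_modes_removed: int = 0
    n_desired_modes_surviving: int = 0


# ---------------------------------------------------------------------------
# Elementary modes
# ---------------------------------------------------------------------------


def _split_reversible(model: MetabolicModel):
    """Forward/backward split; returns (S, names, original ids)."""
    cols, names, origins = [], [], []
    S = build_stoichiometric_matrix(model)
    for j, rxn in enumerate(model.reactions):
        if rxn.upper_bound > 0:
            cols.append(S[:, j])
            names.append(rxn.id)
            origins.append(rxn.id)
        if rxn.lower_bound < 0:
            cols.append(-S[:, j])
            names.append(rxn.id + "__rev")
            origins.append(rxn.id)
    return np.array(cols).T, names, origins


def enumerate_elementary_modes(
    model: MetabolicModel, size_limit: int = DEFAULT_SIZE_LIMIT
) -> list[ElementaryMode]:
    """Complete, duplicate-free set of elementary modes.

    Uses the Schuster tableau (double description) algorithm on the
    reversible-split network; two-cycle artefacts of the splitting are
    discarded.  Raises :class:`EnumerationLimitError` beyond ``size_limit``
    split reactions.
    """
    model.validate()
    S, names, origins = _split_reversible(model)
    m, n = S.shape
    if n > size_limit:
        raise EnumerationLimitError(
            f"network has {n} reactions after splitting, above the limit "
            f"{size_limit}; refusing to enumerate")
    # tableau: rows are candidate rays of the split (all-irreversible) cone
    def support_of(ray: np.ndarray) -> frozenset[int]:
        return frozenset(np.nonzero(np.abs(ray) > 1e-7 * np.max(np.abs(ray)))[0])

    rays = [np.eye(n)[j] for j in range(n)]
    for i in range(m):
        coeffs = [float(r @ S[i]) for r in rays]
        keep = [r for r, c in zip(rays, coeffs) if abs(c) < _TOL]
        pos = [(r, c) for r, c in zip(rays, coeffs) if c > _TOL]
        neg = [(r, c) for r, c in zip(rays, coeffs) if c < -_TOL]
        candidates = list(keep)
        for (rp, cp), (rn, cn) in itertools.product(pos, neg):
            comb = cp * rn - cn * rp  # positive combination annihilating row i
            comb = comb / np.max(np.abs(comb))
            candidates.append(comb)
        # keep only support-minimal candidates (rank test is equivalent to
        # strict-subset pruning at these problem sizes)
        supports = [support_of(r) for r in candidates]
        rays = []
        seen: set[frozenset[int]] = set()
        for r, s in zip(candidates, supports):
            if s in seen:
                continue
            if any(other < s for other in supports):
                continue
            seen.add(s)
            rays.append(r)
        if not rays:
            return []
    modes: dict[frozenset[str], ElementaryMode] = {}
    for ray in rays:
        ray = ray / np.max(np.abs(ray))
        net: dict[str, float] = {}
        for val, name, orig in zip(ray, names, origins):
            if val > _TOL:
                net[orig] = net.get(orig, 0.0) + (-val if name.endswith("__rev") else val)
        net = {k: v for k, v in net.items() if abs(v) > 1e-7}
        if not net:
            continue  # forward/backward two-cycle artefact
        scale = max(abs(v) for v in net.values())
        net = {k: v / scale for k, v in net.items()}
        support = frozenset(net)
        existing = modes.get(support)
        if existing is None:
            modes[support] = ElementaryMode(
                support, tuple(sorted(net.items())))
    # enforce support minimality across the merged (unsplit) patterns
    final = {}
    for supp, mode in modes.items():
        if not any(other < supp for other in modes if other != supp):
            final[supp] = mode
    return sorted(final.values(), key=lambda em: sorted(em.support))


# ---------------------------------------------------------------------------
# Yields and cMCS
# ---------------------------------------------------------------------------


def theoretical_max_yield(
    model: MetabolicModel, product_id: str, substrate_id: str,
    deletions: frozenset[str] | set[str] = frozenset(),
    uptake_rate: float = 1.0,
) -> float:
    """Maximal mol product per mol substrate at fixed uptake, growth free.

    ``uptake_rate`` sets the substrate basis; for models carrying a fixed
    maintenance demand a realistic rate (e.g. 10 mmol/g DCW/h) should be
    used so the maintenance share does not distort the yield.
    """
    work = _apply_deletions(model, deletions)
    cons = [FluxRatioConstraint({substrate_id: 1.0}, "eq", -uptake_rate,
                                name="fixed_uptake")]
    work.reaction(substrate_id).lower_bound = -1000.0
    sol = fba(work, product_id, extra_constraints=cons, sense="max")
    if not sol.ok:
        return 0.0
    return max(sol.objective_value, 0.0) / uptake_rate


def _apply_deletions(model: MetabolicModel, deletions) -> MetabolicModel:
    work = model.copy()
    for rid in deletions:
        rxn = work.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        rxn.reversible = False
    return work


def verify_design(
    model: MetabolicModel, spec: DesignSpec, deletions: frozenset[str]
) -> bool:
    """Certify a deletion set by FBA.

    Sound iff, after the deletions, (a) some steady state achieves growth
    above the floor, and (b) every steady state with growth above the floor
    and unit substrate uptake has product yield at least the required
    fraction of the wild-type theoretical maximum (checked by minimising the
    product flux under those conditions).
    """
    wt_max = theoretical_max_yield(model, spec.product_id, spec.substrate_id)
    if wt_max <= 0:
        return False
    floor = spec.min_yield_fraction * wt_max
    work = _apply_deletions(model, deletions)
    work.reaction(spec.substrate_id).lower_bound = -1000.0
    cons = [
        FluxRatioConstraint({spec.substrate_id: 1.0}, "eq", -1.0, name="unit_uptake"),
        FluxRatioConstraint({spec.growth_id: 1.0}, "ge", spec.min_growth,
                            name="growth_floor"),
    ]
    grow = fba(work, spec.growth_id, extra_constraints=cons[:1], sense="max")
    if not grow.ok or grow.objective_value < spec.min_growth:
        return False
    worst = fba(work, spec.product_id, extra_constraints=cons, sense="min")
    if not worst.ok:
        return False
    return worst.objective_value >= floor - 1e-9


def compute_cmcs(
    model: MetabolicModel,
    spec: DesignSpec,
    size_limit: int = DEFAULT_SIZE_LIMIT,
) -> list[CutSetDesign]:
    """Enumerate constrained minimal cut sets up to the configured size.

    Elementary modes are partitioned into target modes (substrate-consuming
    modes whose product yield is below the floor) and desired modes (growth
    above the floor with sufficient yield).  Candidate cut sets are minimal
    hitting sets of the target supports that spare at least one desired
    mode; every candidate is then certified by FBA before being returned.
    An empty deletion set is returned when the wild type already satisfies
    the specification.
    """
    deletable = set(spec.deletable) if spec.deletable else {
        r.id for r in model.reactions
        if not r.is_exchange and r.id != spec.growth_id
    }
    if verify_design(model, spec, frozenset()):
        return [CutSetDesign(frozenset(), True)]
    wt_max = theoretical_max_yield(model, spec.product_id, spec.substrate_id)
    if wt_max <= 0:
        return []
    floor = spec.min_yield_fraction * wt_max
    modes = enumerate_elementary_modes(model, size_limit)
    targets, desired = [], []
    for mode in modes:
        v = mode.flux_dict()
        uptake = -v.get(spec.substrate_id, 0.0)
        if uptake <= _TOL:
            continue
        prod = v.get(spec.product_id, 0.0)
        growth = v.get(spec.growth_id, 0.0)
        if prod / uptake < floor - 1e-9:
            targets.append(mode)
        elif growth / uptake > _TOL:
            desired.append(mode)
    results: list[CutSetDesign] = []
    found: list[frozenset[str]] = []
    candidates = sorted(deletable)
    for size in range(1, spec.max_cut_set_size + 1):
        for combo in itertools.combinations(candidates, size):
            cut = frozenset(combo)
            if any(prev <= cut for prev in found):
                continue  # not minimal
            if not all(cut & t.support for t in targets):
                continue  # leaves a target mode intact
            if desired and not any(not (cut & dmode.support) for dmode in desired):
                continue  # kills every desired mode
            if verify_design(model, spec, cut):
                found.append(cut)
                results.append(CutSetDesign(
                    cut, True,
                    n_target_modes_removed=sum(bool(cut & t.support) for t in targets),
                    n_desired_modes_surviving=sum(
                        not (cut & dmode.support) for dmode in desired),
                ))
    return results
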