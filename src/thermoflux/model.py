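"""Stoichiometric model data structures and I/O.

The in-memory containers are deliberately small: an ordered collection of
:class:`Metabolite` and :class:`Reaction` objects plus an objective pointer.
The canonical on-disk format is a flat JSON dialect in which stoichiometric
coefficients and bounds are stored as decimal strings, so that
``write(read(write(m)))`` is byte-identical to ``write(m)`` on every
platform.  SBML Level 3 (FBC) import/export is provided through cobrapy.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import numpy as np

COMPARTMENTS = ("cytosol", "extracellular")

#: Default numeric tolerance for steady-state residuals.
STEADY_STATE_TOL = 1e-6
#: Tolerance for irreversibility violations.
IRREVERSIBILITY_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``is_pseudo`` marks lumped accounting species (biomass, cellulosome,
    protein, DCW ...) that intentionally carry no elemental formula and are
    exempt from mass-balance checking.
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    formula: str | None = None
    charge: int | None = None
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    Bounds are in mmol/g DCW/h, except pseudo-mass reactions (biomass, DCW,
    cellulosome) which are in g/g DCW/h.  Negative coefficients denote
    consumption.  Exchange reactions follow the convention that uptake is a
    negative flux.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gene_rule: str | None = None
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not any(c != 0 for c in self.stoichiometry.values()):
            raise ModelValidationError(
                f"reaction {self.id!r} has no nonzero stoichiometric coefficient"
            )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.reversible and self.lower_bound < 0:
            raise ModelValidationError(
                f"reaction {self.id!r} is irreversible but lower_bound "
                f"{self.lower_bound} < 0"
            )

    @property
    def is_exchange(self) -> bool:
        """True for single-metabolite boundary reactions."""
        return len(self.stoichiometry) == 1


@dataclass
class MetabolicModel:
    """An ordered stoichiometric model; houses the m-by-n matrix S."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None
    annotations: dict = field(default_factory=dict)

    # -- lookup helpers ----------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def _met_index(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index()

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        return read_model_json_str(write_model_json_str(self))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants, raising on the first violation."""
        seen: set[str] = set()
        for m in self.metabolites:
            if m.id in seen:
                raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
        seen_r: set[str] = set()
        met_ids = {m.id for m in self.metabolites}
        for r in self.reactions:
            if r.id in seen_r:
                raise ModelValidationError(f"duplicate reaction id {r.id!r}")
            seen_r.add(r.id)
            for met_id in r.stoichiometry:
                if met_id not in met_ids:
                    raise ModelValidationError(
                        f"reaction {r.id!r} references undeclared metabolite "
                        f"{met_id!r}"
                    )
        if self.objective_id is not None and self.objective_id not in seen_r:
            raise ModelValidationError(
                f"objective_id {self.objective_id!r} is not a declared reaction"
            )


def build_stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Return the dense m-by-n stoichiometric matrix S.

    Entry (i, j) is the coefficient of metabolite i in reaction j; row and
    column order follow declaration order.  Duplicate metabolite ids are
    rejected with the offending id.
    """
    seen: set[str] = set()
    for m in model.metabolites:
        if m.id in seen:
            raise ModelValidationError(f"duplicate metabolite id {m.id!r}")
        seen.add(m.id)
    model.validate()
    row = {mid: i for i, mid in enumerate(model.metabolite_ids)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            S[row[met_id], j] = coeff
    return S


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula such as ``C6H12O6`` into element counts."""
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula or ""):
        raise ValueError(f"malformed formula {formula!r}")
    counts: dict[str, int] = {}
    for element, n in _FORMULA_TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(n) if n else 1)
    return counts


@dataclass
class MassBalanceEntry:
    reaction_id: str
    status: str  # "balanced" | "imbalanced" | "exempt"
    residuals: dict[str, float] = field(default_factory=dict)


def validate_mass_balance(
    model: MetabolicModel, tol: float = 1e-6
) -> list[MassBalanceEntry]:
    """Element-wise balance report for every non-exchange reaction.

    Reactions touching a pseudo-species, or any metabolite without a formula,
    are reported ``exempt`` (never ``imbalanced``).  Exchange reactions are
    boundary transfers and are exempt by construction.
    """
    report: list[MassBalanceEntry] = []
    mets = model._met_index()
    for rxn in model.reactions:
        if rxn.is_exchange:
            report.append(MassBalanceEntry(rxn.id, "exempt"))
            continue
        participants = [mets[mid] for mid in rxn.stoichiometry]
        if any(p.is_pseudo or not p.formula for p in participants):
            report.append(MassBalanceEntry(rxn.id, "exempt"))
            continue
        residual: dict[str, float] = {}
        for mid, coeff in rxn.stoichiometry.items():
            for element, n in parse_formula(mets[mid].formula).items():
                residual[element] = residual.get(element, 0.0) + coeff * n
        bad = {e: r for e, r in residual.items() if abs(r) > tol}
        report.append(
            MassBalanceEntry(rxn.id, "imbalanced" if bad else "balanced", bad)
        )
    return report


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

_JSON_SCHEMA_VERSION = 1


def _num_to_str(x: float) -> str:
    """Render a float as a minimal decimal string (``repr`` round-trips)."""
    if x == math.floor(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "schema_version": _JSON_SCHEMA_VERSION,
        "id": model.id,
        "objective_id": model.objective_id,
        "annotations": model.annotations,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "is_pseudo": m.is_pseudo,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": {
                    k: _num_to_str(v) for k, v in sorted(r.stoichiometry.items())
                },
                "reversible": r.reversible,
                "lower_bound": _num_to_str(r.lower_bound),
                "upper_bound": _num_to_str(r.upper_bound),
                "gene_rule": r.gene_rule,
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "cytosol"),
                formula=m.get("formula"),
                charge=m.get("charge"),
                is_pseudo=bool(m.get("is_pseudo", False)),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                reversible=bool(r.get("reversible", False)),
                lower_bound=float(r["lower_bound"]),
                upper_bound=float(r["upper_bound"]),
                gene_rule=r.get("gene_rule"),
                subsystem=r.get("subsystem", ""),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:
        raise ValueError(f"malformed model JSON: missing element {exc}") from exc
    model = MetabolicModel(
        id=data.get("id", "model"),
        metabolites=mets,
        reactions=rxns,
        objective_id=data.get("objective_id"),
        annotations=data.get("annotations", {}),
    )
    model.validate()
    return model


def write_model_json_str(model: MetabolicModel) -> str:
    return json.dumps(_model_to_dict(model), indent=1, sort_keys=True) + "\n"


def read_model_json_str(text: str) -> MetabolicModel:
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON at line {exc.lineno}: {exc.msg}") from exc
    return _model_from_dict(data)


# ---------------------------------------------------------------------------
# cobra interop + SBML
# ---------------------------------------------------------------------------

_COMPARTMENT_CODES = {"cytosol": "c", "extracellular": "e"}
_COMPARTMENT_NAMES = {v: k for k, v in _COMPARTMENT_CODES.items()}


def to_cobra(model: MetabolicModel):
    """Convert to a cobrapy model (used for SBML I/O and oracle solves)."""
    import cobra

    model.validate()
    cm = cobra.Model(model.id)
    cm.compartments = {"c": "cytosol", "e": "extracellular"}
    cmets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id,
            name=m.name,
            compartment=_COMPARTMENT_CODES[m.compartment],
            formula=m.formula,
            charge=m.charge,
        )
        if m.is_pseudo:
            cmet.notes["is_pseudo"] = True
        cmets[m.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for r in model.reactions:
        crxn = cobra.Reaction(
            r.id, name=r.name, lower_bound=r.lower_bound, upper_bound=r.upper_bound
        )
        crxn.subsystem = r.subsystem
        crxns.append(crxn)
    cm.add_reactions(crxns)
    for r in model.reactions:
        crxn = cm.reactions.get_by_id(r.id)
        crxn.add_metabolites({cmets[k]: v for k, v in r.stoichiometry.items()})
        if r.gene_rule:
            crxn.gene_reaction_rule = r.gene_rule
        if r.reversible:
            crxn.notes["reversible"] = True
    if model.objective_id is not None:
        cm.objective = model.objective_id
    return cm


def from_cobra(cm) -> MetabolicModel:
    """Convert a cobrapy model back to the native container."""
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=_COMPARTMENT_NAMES.get(m.compartment, "cytosol"),
            formula=m.formula or None,
            charge=m.charge,
            is_pseudo=bool(m.notes.get("is_pseudo", False)),
        )
        for m in cm.metabolites
    ]
    rxns = []
    for r in cm.reactions:
        reversible = bool(r.notes.get("reversible", False)) or r.lower_bound < 0
        rxns.append(
            Reaction(
                id=r.id,
                name=r.name or "",
                stoichiometry={m.id: c for m, c in r.metabolites.items()},
                reversible=reversible,
                lower_bound=r.lower_bound,
                upper_bound=r.upper_bound,
                gene_rule=r.gene_reaction_rule or None,
                subsystem=r.subsystem or "",
            )
        )
    objective_id = None
    try:
        expr = cm.objective.expression
        for rxn in cm.reactions:
            if expr.has(rxn.forward_variable) and expr.coeff(rxn.forward_variable) != 0:
                objective_id = rxn.id
                break
    except Exception:  # pragma: no cover - objective introspection best-effort
        objective_id = None
    model = MetabolicModel(id=cm.id or "model", metabolites=mets, reactions=rxns,
                           objective_id=objective_id)
    model.validate()
    return model


def read_model(path: str, format: str = "json") -> MetabolicModel:
    """Read a model from ``path`` in ``json`` or ``sbml`` format."""
    if format == "json":
        with open(path) as fh:
            return read_model_json_str(fh.read())
    if format == "sbml":
        import cobra

        return from_cobra(cobra.io.read_sbml_model(path))
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path: str, format: str = "json") -> None:
    """Write a model to ``path`` in ``json`` or ``sbml`` format."""
    if format == "json":
        with open(path, "w") as fh:
            fh.write(write_model_json_str(model))
        return
    if format == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(model), path)
        return
    raise ValueError(f"unknown model format {format!r}")
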