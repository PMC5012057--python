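"""Biomass energetics and the adjustable cellulosome term.

The dry-cell-weight (DCW) reaction lumps the macromolecular composition of
the cell (g component per g DCW) together with the ATP needed to synthesise
one gram of dry cell weight (the Table-style bookkeeping held in
:class:`ATPRequirementTable`) plus a growth-associated maintenance (GAM)
coefficient.  The cellulosome is a separate pseudo-species whose amino-acid
demand is derived from cellulosomal protein sequences weighted by measured
protein abundances (the A.c construction), and whose ATP coefficient is a
free parameter fixed by calibration.  A whole-cell reaction combines DCW and
cellulosome in a carbon-source-dependent ratio: the cellulosome accounts for
2 % of dry weight on cellobiose and 20 % on cellulose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .model import MetabolicModel, Metabolite, Reaction

# ---------------------------------------------------------------------------
# Macromolecular composition (g per g DCW)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecular mass fractions of dry cell weight (g/g DCW).

    The fractions sum to ~0.9555 (the balance being ash and unaccounted
    mass); they are kept as reported rather than renormalised.
    """

    protein: float = 0.5285
    dna: float = 0.026
    rna: float = 0.0655
    lipid: float = 0.076
    cell_wall: float = 0.2242
    solute_pool: float = 0.00494
    lta: float = 0.0304

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def total(self) -> float:
        return sum(self.as_dict().values())

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not 0 < value < 1:
                raise ValueError(f"mass fraction {name}={value} outside (0, 1)")
        if not 0.9 <= self.total() <= 1.005:
            raise ValueError(
                f"mass fractions sum to {self.total():.4f}; expected within [0.9, 1.005]"
            )


@dataclass(frozen=True)
class ATPRequirementTable:
    """ATP bookkeeping for synthesising 1 g DCW (mmol ATP/g DCW).

    ``protein_term_atp`` is the ATP coefficient of the protein term expressed
    per gram of protein; it is the default cellulosome ATP coefficient before
    calibration.
    """

    polysaccharide_cell_wall: float = 7.16
    amino_acid_synthesis: float = 5.65
    protein_polymerization: float = 17.49
    lipid: float = 0.52
    rna_nmp_formation: float = 1.20
    rna_polymerization: float = 0.27
    rna_mrna_turnover: float = 0.30
    dna_dnmp_formation: float = 0.48
    dna_polymerization: float = 0.18
    subtotal: float = 33.23
    transport_ammonium: float = 8.43
    transport_potassium: float = 0.20
    transport_phosphate: float = 0.80
    total: float = 42.66
    protein_term_atp: float = 43.28  # mmol ATP / g protein

    def line_item_sum(self) -> float:
        return (
            self.polysaccharide_cell_wall
            + self.amino_acid_synthesis
            + self.protein_polymerization
            + self.lipid
            + self.rna_nmp_formation
            + self.rna_polymerization
            + self.rna_mrna_turnover
            + self.dna_dnmp_formation
            + self.dna_polymerization
        )

    def transport_sum(self) -> float:
        return self.transport_ammonium + self.transport_potassium + self.transport_phosphate

    def max_atp_yield(self) -> float:
        """Y_ATP^MAX in g DCW per mol ATP (reciprocal of the total)."""
        return 1000.0 / self.total

    def __post_init__(self) -> None:
        if abs(self.subtotal + self.transport_sum() - self.total) > 0.02:
            raise ValueError(
                "ATP bookkeeping inconsistent: subtotal + transport = "
                f"{self.subtotal + self.transport_sum():.2f} != total {self.total}"
            )


# ---------------------------------------------------------------------------
# Amino-acid counting and the cellulosome demand vector
# ---------------------------------------------------------------------------

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Average residue masses (free amino acid minus one water), g/mol.
_WATER = 18.01528
_FREE_AA_MASS = {
    "A": 89.0932, "C": 121.158, "D": 133.1027, "E": 147.1293, "F": 165.1891,
    "G": 75.0666, "H": 155.1546, "I": 131.1729, "K": 146.1876, "L": 131.1729,
    "M": 149.2113, "N": 132.1179, "P": 115.1305, "Q": 146.1445, "R": 174.201,
    "S": 105.0926, "T": 119.1192, "V": 117.1463, "W": 204.2252, "Y": 181.1885,
}
RESIDUE_MASS = {aa: _FREE_AA_MASS[aa] - _WATER for aa in AMINO_ACIDS}


@dataclass
class AminoAcidCountMatrix:
    """20 x P integer matrix of amino-acid counts per cellulosomal protein."""

    counts: np.ndarray  # shape (20, P)
    protein_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (20, len(self.protein_ids)):
            raise ValueError("count matrix must be 20 x n_proteins")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.any(self.counts.sum(axis=0) == 0):
            raise ValueError("every protein column must have a positive total count")


def count_amino_acids(sequences: dict[str, str]) -> AminoAcidCountMatrix:
    """Count one-letter-coded amino acids per protein (matrix A).

    A[i, j] is the number of occurrences of amino acid i in the sequence of
    protein j; a non-standard residue is rejected naming the residue and the
    protein.
    """
    if not sequences:
        raise ValueError("no sequences given")
    protein_ids = list(sequences)
    counts = np.zeros((20, len(protein_ids)), dtype=int)
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for j, pid in enumerate(protein_ids):
        for residue in sequences[pid].upper():
            if residue not in aa_index:
                raise ValueError(
                    f"non-standard residue {residue!r} in protein {pid!r}"
                )
            counts[aa_index[residue], j] += 1
    return AminoAcidCountMatrix(counts, protein_ids)


@dataclass
class ProteinAbundanceVector:
    """Relative cellulosomal protein abundances, normalised to the scaffoldin.

    The reference protein (CipA by default) has abundance exactly 1 after
    normalisation.
    """

    abundances: dict[str, float]
    reference: str = "CipA"

    def __post_init__(self) -> None:
        if self.reference not in self.abundances:
            raise ValueError(f"reference protein {self.reference!r} not in vector")
        ref = self.abundances[self.reference]
        if ref <= 0:
            raise ValueError("reference abundance must be positive")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        self.abundances = {k: v / ref for k, v in self.abundances.items()}

    def vector(self, protein_ids: list[str]) -> np.ndarray:
        return np.array([self.abundances.get(pid, 0.0) for pid in protein_ids])


def cellulosome_amino_acid_demand(
    A: AminoAcidCountMatrix, c: ProteinAbundanceVector | np.ndarray
) -> np.ndarray:
    """Amino-acid demand of the cellulosome, mmol per g cellulosome protein.

    Computes the abundance-weighted total count A.c, converts counts to mass
    with average residue masses (one water subtracted per peptide bond), and
    scales so the demands are per gram of cellulosome.  The result is
    invariant to uniform rescaling of c.
    """
    cv = c.vector(A.protein_ids) if isinstance(c, ProteinAbundanceVector) else np.asarray(c, float)
    if cv.shape != (len(A.protein_ids),):
        raise ValueError("abundance vector length must match protein count")
    if np.all(cv == 0):
        raise ValueError("abundance vector is all zero")
    if np.any(cv < 0):
        raise ValueError("abundances must be non-negative")
    total = A.counts @ cv  # mol amino acid i per arbitrary unit
    masses = np.array([RESIDUE_MASS[aa] for aa in AMINO_ACIDS])
    grams = float(total @ masses)  # g polypeptide per arbitrary unit (mol basis)
    return 1000.0 * total / grams  # mmol / g


def median_cellulosome_demand(demands: list[np.ndarray]) -> np.ndarray:
    """Element-wise median demand across culture conditions."""
    if not demands:
        raise ValueError("need at least one condition demand vector")
    arr = np.asarray(demands, dtype=float)
    if arr.ndim != 2:
        raise ValueError("demand vectors have inconsistent lengths")
    return np.median(arr, axis=0)


# ---------------------------------------------------------------------------
# Biomass assembly
# ---------------------------------------------------------------------------

#: Cellulosome fraction of biomass by carbon source (g cellulosome added per
#: g DCW in the whole-cell reaction).
CELLULOSOME_FRACTION = {"cellobiose": 0.02, "cellulose": 0.2}

DEFAULT_CELLULOSOME_ATP = 57.0  # mmol ATP/g cellulosome, calibrated


@dataclass
class CellulosomeSpec:
    """Cellulosome composition and synthesis cost.

    ``amino_acid_demand`` is in mmol amino acid per g cellulosome (length-20,
    ordered as :data:`AMINO_ACIDS`); ``atp_coefficient`` in mmol ATP per g
    cellulosome; ``dcw_fraction`` maps carbon source to the grams of
    cellulosome per gram DCW.
    """

    amino_acid_demand: np.ndarray
    atp_coefficient: float = DEFAULT_CELLULOSOME_ATP
    dcw_fraction: dict[str, float] = field(
        default_factory=lambda: dict(CELLULOSOME_FRACTION)
    )

    def __post_init__(self) -> None:
        self.amino_acid_demand = np.asarray(self.amino_acid_demand, float)
        if self.amino_acid_demand.shape != (20,):
            raise ValueError("amino_acid_demand must have length 20")
        if np.any(self.amino_acid_demand < 0):
            raise ValueError("amino-acid demands must be non-negative")

    def total_amino_acid_demand(self) -> float:
        """Total mmol amino acid per g cellulosome (pool-level lumping)."""
        return float(self.amino_acid_demand.sum())


_PRECURSORS = {
    "protein": "protein",
    "dna": "dna",
    "rna": "rna",
    "lipid": "lipid",
    "cell_wall": "cellwall",
    "solute_pool": "solute",
    "lta": "lta",
}


def assemble_biomass(
    model: MetabolicModel,
    biomass: BiomassComposition,
    atp: ATPRequirementTable,
    cellulosome: CellulosomeSpec,
    condition: str,
    gam: float = 0.0,
    protein_atp_separate: bool = True,
) -> MetabolicModel:
    """Install DCW, cellulosome, and whole-cell reactions into ``model``.

    The route from precursors to 1 g DCW consumes the macromolecular
    components plus (total Table ATP + GAM) mmol ATP hydrolysed to ADP + Pi.
    With ``protein_atp_separate`` (the default, matching the bundled core
    network) the protein share of that ATP (protein fraction times the
    protein-term coefficient, 43.28 mmol ATP/g protein) is charged on the
    protein-synthesis reaction itself so that protein production carries its
    cost in analyses that maximise protein rather than growth; the DCW
    reaction then consumes the remainder, and the route total is unchanged.
    The cellulosome reaction consumes charged amino acids from the shared
    pool plus its own ATP coefficient.  The whole-cell reaction combines
    ``1 g DCW + f g cellulosome`` with f = 0.02 for cellobiose and f = 0.2
    for cellulose, normalised to produce 1 g of total biomass so the
    objective flux reads directly as the specific growth rate.  Modifies
    ``model`` in place and returns it.
    """
    if condition not in cellulosome.dcw_fraction:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(cellulosome.dcw_fraction)}"
        )
    for key in ("atp", "adp", "pi", "aa_pool"):
        model.metabolite(key)  # raises naming the missing species
    missing = [p for p in _PRECURSORS.values() if p not in model._met_index()]
    if missing:
        raise KeyError(f"model lacks biomass precursor pseudo-species {missing}")

    for met_id in ("dcw", "cellulosome", "biomass"):
        if met_id not in model._met_index():
            model.metabolites.append(
                Metabolite(met_id, name=met_id, compartment="cytosol", is_pseudo=True)
            )

    atp_total = atp.total + gam
    if protein_atp_separate:
        atp_total -= biomass.protein * atp.protein_term_atp
    dcw_stoich: dict[str, float] = {
        _PRECURSORS[name]: -frac for name, frac in biomass.as_dict().items()
    }
    dcw_stoich.update(
        {"atp": -atp_total, "adp": atp_total, "pi": atp_total, "dcw": 1.0}
    )

    # the cellulosome is a polypeptide: charging its amino acids releases
    # one PPi per residue, exactly as cell protein synthesis does
    cel_aa = cellulosome.total_amino_acid_demand()
    cel_atp = cellulosome.atp_coefficient
    cel_stoich = {
        "aa_pool": -cel_aa,
        "atp": -cel_atp,
        "adp": cel_atp - cel_aa,
        "pi": cel_atp - cel_aa,
        "amp": cel_aa,
        "ppi": cel_aa,
        "cellulosome": 1.0,
    }

    # whole-cell reaction follows the condition convention literally:
    # 1 g DCW + f g cellulosome per unit flux, so the flux is on the g DCW
    # basis in which the specific rates and growth rates are expressed
    frac = cellulosome.dcw_fraction[condition]
    whole_stoich = {
        "dcw": -1.0,
        "cellulosome": -frac,
        "biomass": 1.0,
    }

    new_reactions = {
        "DCW_SYNTH": Reaction(
            "DCW_SYNTH", dcw_stoich, subsystem="biomass",
            name="dry cell weight synthesis",
        ),
        "CELLULOSOME_SYNTH": Reaction(
            "CELLULOSOME_SYNTH", cel_stoich, subsystem="biomass",
            name="cellulosome synthesis",
        ),
        "BIOMASS": Reaction(
            "BIOMASS", whole_stoich, subsystem="biomass",
            name=f"whole-cell biomass ({condition})",
        ),
        "EX_biomass": Reaction(
            "EX_biomass", {"biomass": -1.0}, subsystem="exchange",
            name="biomass drain",
        ),
    }
    model.reactions = [r for r in model.reactions if r.id not in new_reactions]
    model.reactions.extend(new_reactions.values())
    model.objective_id = "BIOMASS"
    model.annotations["biomass_condition"] = condition
    model.annotations["gam"] = gam
    model.annotations["cellulosome_atp"] = cellulosome.atp_coefficient
    model.validate()
    return model


def dcw_route_atp(model: MetabolicModel, biomass: BiomassComposition) -> float:
    """Total mmol ATP consumed per g DCW along the assembled biomass route.

    Sums the ATP drawn by the DCW reaction and the protein share charged on
    the protein-synthesis reaction (if the model carries one), so the result
    is comparable with the bookkeeping total regardless of where the protein
    term is placed.
    """
    total = -model.reaction("DCW_SYNTH").stoichiometry.get("atp", 0.0)
    if model.has_reaction("PROTS"):
        total += -model.reaction("PROTS").stoichiometry.get("atp", 0.0) * biomass.protein
    return total


def set_condition(
    model: MetabolicModel,
    biomass: BiomassComposition,
    atp: ATPRequirementTable,
    cellulosome: CellulosomeSpec,
    condition: str,
    gam: float | None = None,
) -> MetabolicModel:
    """Re-assemble the biomass reactions for a new condition/GAM in place."""
    if gam is None:
        gam = float(model.annotations.get("gam", 0.0))
    return assemble_biomass(model, biomass, atp, cellulosome, condition, gam)
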