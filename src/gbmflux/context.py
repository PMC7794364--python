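"""Cell-line contextualization of a core metabolic model.

A template network is specialized to one cell line by, in order:

1. building a biomass reaction from measured macromolecule mass
   fractions (protein / DNA / RNA / lipid, g/gDW) and the line's
   chromosome count;
2. bounding exchange reactions with measured specific exchange rates
   (mmol/gDW/h; negative = uptake);
3. fixing the biomass flux to the measured growth rate (within a small
   tolerance band);
4. fixing the ATP maintenance flux (non-growth-associated energy
   demand; default 1.07 mmol/gDW/h);
5. capping the oxygen uptake rate at the maximal value the constrained
   model can support (or a fixed value);
6. adding in-silico probe reactions (a pseudo-hypoxia NAD -> NADH
   conversion, and optionally an NADH-oxidase redox probe);
7. contracting the bounds of reactions catalyzed by genes carrying
   predicted-deleterious mutations ("enzymopathies"): for each impaired
   reaction, with (v_min, v_max) its feasible range in the un-contracted
   model from flux variability analysis,

       new_v_max = v_min + factor * |v_min - v_max|,   factor = 0.25

   i.e. the feasible width collapses to `factor` of the original width,
   anchored at v_min.

Each stage preserves feasibility or fails loudly, naming the stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .gpr import evaluate_gpr, genes_in_rule
from .lp import FVAConfig, FVAResult, fba, fva, maximal_exchange
from .model import (
    MetabolicModel,
    Metabolite,
    Reaction,
    SolveStatus,
    ValidationError,
    add_reaction,
)

__all__ = [
    "BiomassComposition",
    "MutationAnnotation",
    "ExchangeConstraint",
    "ContextSpec",
    "ContextualizationResult",
    "ContextualizationError",
    "build_biomass",
    "apply_exchange_constraints",
    "apply_enzymopathies",
    "add_probe_reactions",
    "contextualize_cell_line",
    "load_context_spec",
    "read_mutation_table",
    "read_exchange_table",
    "DEFAULT_PRECURSORS",
    "BIOMASS_ID",
    "ATPM_ID",
    "PSEUDO_HYPOXIA_ID",
    "NADH_OXIDASE_ID",
]

BIOMASS_ID = "BIOMASS"
ATPM_ID = "ATPM"
PSEUDO_HYPOXIA_ID = "PSEUDO_HYPOXIA"
NADH_OXIDASE_ID = "NADH_OXIDASE"

# cytosolic cofactor/species ids the probe reactions rely on
NAD_C, NADH_C, H_C, H2_C, O2_C, H2O_C = "nad_c", "nadh_c", "h_c", "h2_c", "o2_c", "h2o_c"
ATP_C, ADP_C = "atp_c", "adp_c"

#: Default biomass precursor pools per macromolecule class:
#: metabolite id -> molar mass in g/mmol.  Mass within a class is split
#: equally across its pools; the molar mass converts the class's g/gDW
#: share into a mmol/gDW stoichiometric coefficient.  Masses are
#: representative monomer-residue values (mean amino-acid residue 0.109
#: g/mmol, mean dNMP residue 0.327, mean NMP residue 0.320, mean
#: membrane lipid 0.740).
DEFAULT_PRECURSORS: dict[str, dict[str, float]] = {
    "protein": {"aa_pool_c": 0.109},
    "dna": {"dntp_pool_c": 0.327},
    "rna": {"ntp_pool_c": 0.320},
    "lipid": {"lipid_pool_c": 0.740},
}

#: Growth-associated ATP demand folded into the biomass reaction
#: (mmol ATP hydrolyzed per gDW of biomass formed).
DEFAULT_GAM = 30.0


class ContextualizationError(RuntimeError):
    """A contextualization stage produced an invalid or infeasible model."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass(frozen=True)
class BiomassComposition:
    """Macromolecule dry-mass fractions (g per gDW) plus ploidy.

    Fractions must sum to 1.  The chromosome count rescales the DNA
    share relative to the diploid reference (46): a line with 44
    chromosome units carries 44/46 of the reference DNA mass, and the
    mass freed up is redistributed to lipid and RNA in proportion to
    their stated fractions, with protein held fixed.
    """

    protein_fraction: float = 0.70
    dna_fraction: float = 0.02
    rna_fraction: float = 0.08
    lipid_fraction: float = 0.20
    chromosome_count: int = 46

    def __post_init__(self) -> None:
        fracs = (self.protein_fraction, self.dna_fraction,
                 self.rna_fraction, self.lipid_fraction)
        if any(f < 0 for f in fracs):
            raise ValidationError("biomass fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(f"biomass fractions must sum to 1, got {sum(fracs)}")

    def effective_fractions(self) -> dict[str, float]:
        """Class fractions after chromosome-count scaling of DNA."""
        dna = self.dna_fraction * self.chromosome_count / 46.0
        freed = self.dna_fraction - dna
        other = self.rna_fraction + self.lipid_fraction
        if other > 0:
            rna = self.rna_fraction + freed * self.rna_fraction / other
            lipid = self.lipid_fraction + freed * self.lipid_fraction / other
        else:
            rna, lipid = self.rna_fraction, self.lipid_fraction + freed
        return {
            "protein": self.protein_fraction,
            "dna": dna,
            "rna": rna,
            "lipid": lipid,
        }


@dataclass(frozen=True)
class MutationAnnotation:
    """One annotated coding variant with its predicted-damaging probability."""

    gene: str
    variant_label: str
    deleterious_probability: float
    is_deleterious: bool

    @classmethod
    def from_probability(cls, gene: str, variant_label: str, probability: float,
                         threshold: float = 0.95) -> "MutationAnnotation":
        if not 0.0 <= probability <= 1.0:
            raise ValidationError(f"deleterious probability must be in [0,1], got {probability}")
        return cls(gene, variant_label, probability, probability >= threshold)


@dataclass(frozen=True)
class ExchangeConstraint:
    """A measured specific exchange rate for one extracellular metabolite.

    rate is in mmol/gDW/h, negative for net uptake; the bound applied is
    rate +/- tolerance_band * |rate|.
    """

    metabolite: str
    rate: float
    tolerance_band: float = 0.0

    def __post_init__(self) -> None:
        if self.tolerance_band < 0:
            raise ValidationError("tolerance_band must be >= 0")

    def bounds(self) -> tuple[float, float]:
        half = self.tolerance_band * abs(self.rate)
        return self.rate - half, self.rate + half


@dataclass
class ContextSpec:
    """Everything needed to specialize the template to one cell line."""

    cell_line_name: str
    biomass: BiomassComposition = field(default_factory=BiomassComposition)
    exchanges: list[ExchangeConstraint] = field(default_factory=list)
    mutations: list[MutationAnnotation] = field(default_factory=list)
    growth_rate: float = 0.0  # 1/h
    atp_maintenance: float = 1.07  # mmol/gDW/h
    our_cap_mode: str = "fba_max"  # or "fixed"
    our_value: float | None = None  # used when our_cap_mode == "fixed"
    add_pseudo_hypoxia: bool = False
    add_nadh_oxidase: bool = False
    enzymopathy_factor: float = 0.25
    enzymopathy_mode: str = "literal"  # or "symmetric"
    growth_band: float = 0.05
    exchange_band: float | None = None  # overrides per-constraint bands when set
    gam: float = DEFAULT_GAM

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValidationError("growth_rate must be >= 0")
        if self.atp_maintenance < 0:
            raise ValidationError("atp_maintenance must be >= 0")
        if not 0.0 < self.enzymopathy_factor <= 1.0:
            raise ValidationError("enzymopathy_factor must be in (0, 1]")
        if self.our_cap_mode not in ("fba_max", "fixed"):
            raise ValidationError(f"unknown our_cap_mode {self.our_cap_mode!r}")


@dataclass
class ContextualizationResult:
    model: MetabolicModel
    contracted_reactions: list[str]
    our_cap: float | None
    unaltered_fva: FVAResult | None


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------

def build_biomass(
    composition: BiomassComposition,
    template: MetabolicModel,
    precursors: Mapping[str, Mapping[str, float]] | None = None,
    gam: float = DEFAULT_GAM,
) -> Reaction:
    """Construct the biomass reaction from mass fractions.

    Each macromolecule class contributes coefficients
    ``fraction / (n_pools * molar_mass)`` mmol/gDW for each of its
    precursor pools (consumed, so negative).  When the template carries
    cytosolic ATP/ADP, a growth-associated ATP hydrolysis of ``gam``
    mmol/gDW is folded in.  Flux through the reaction is the specific
    growth rate (1/h), so flux * coefficient has units mmol/gDW/h.
    """
    precursors = precursors or DEFAULT_PRECURSORS
    fractions = composition.effective_fractions()
    stoich: dict[str, float] = {}
    for klass, frac in fractions.items():
        pools = precursors.get(klass, {})
        if not pools:
            raise ValidationError(f"no precursor pools declared for class {klass!r}")
        for met_id, molar_mass in pools.items():
            if not template.has_metabolite(met_id):
                raise ValidationError(
                    f"biomass precursor {met_id!r} (class {klass!r}) missing from template"
                )
            stoich[met_id] = stoich.get(met_id, 0.0) - frac / (len(pools) * molar_mass)
    if gam > 0 and template.has_metabolite(ATP_C) and template.has_metabolite(ADP_C):
        stoich[ATP_C] = stoich.get(ATP_C, 0.0) - gam
        stoich[ADP_C] = stoich.get(ADP_C, 0.0) + gam
    return Reaction(id=BIOMASS_ID, name=f"biomass ({composition.chromosome_count} chromosomes)",
                    stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0)


def apply_exchange_constraints(
    model: MetabolicModel,
    exchanges: Sequence[ExchangeConstraint],
    band_override: float | None = None,
) -> MetabolicModel:
    """Re-bound the exchange reaction of each listed metabolite.

    Every listed metabolite must have an exchange reaction; all missing
    ones are reported together.  Exchanges not listed keep their bounds.
    """
    exch_by_met: dict[str, str] = {}
    for r in model.reactions:
        if r.is_exchange:
            (met,) = r.stoichiometry
            exch_by_met[met] = r.id
    missing = [c.metabolite for c in exchanges if c.metabolite not in exch_by_met]
    if missing:
        raise ValidationError(f"no exchange reaction for metabolites: {sorted(missing)}")
    new = model
    for con in exchanges:
        if band_override is not None:
            con = ExchangeConstraint(con.metabolite, con.rate, band_override)
        lo, hi = con.bounds()
        new = new.with_reaction_bounds(exch_by_met[con.metabolite], lo, hi)
    return new


def apply_enzymopathies(
    model: MetabolicModel,
    mutations: Sequence[MutationAnnotation],
    fva_unaltered: FVAResult,
    factor: float = 0.25,
    mode: str = "literal",
) -> tuple[MetabolicModel, list[str]]:
    """Contract bounds of reactions disabled by deleterious mutations.

    A reaction is impaired iff its GPR evaluates false with the
    deleterious genes switched off (so an intact isozyme rescues it, a
    broken complex subunit does not).  For each impaired reaction with
    unaltered-model FVA range (v_min, v_max):

      literal   : bounds become [v_min, v_min + factor * |v_min - v_max|]
      symmetric : bounds become the central `factor` fraction of the range

    Genes that appear in no GPR raise a warning, not an error (the
    mutation may hit a non-metabolic gene).  Returns the new model and
    the list of contracted reaction ids.
    """
    if mode not in ("literal", "symmetric"):
        raise ValueError(f"unknown enzymopathy mode {mode!r}")
    deleterious = {m.gene for m in mutations if m.is_deleterious}
    if not deleterious:
        return model, []
    all_gpr_genes: set[str] = set()
    for r in model.reactions:
        all_gpr_genes |= genes_in_rule(r.gpr)
    orphans = deleterious - all_gpr_genes
    if orphans:
        warnings.warn(
            f"deleterious genes absent from every GPR (ignored): {sorted(orphans)}",
            stacklevel=2,
        )
    new = model
    contracted: list[str] = []
    for r in model.reactions:
        if not r.gpr or r.is_exchange:
            continue
        if evaluate_gpr(r.gpr, deleterious):
            continue
        if r.id not in fva_unaltered.ranges:
            continue
        v_min, v_max = fva_unaltered.ranges[r.id]
        width = abs(v_min - v_max)
        if mode == "literal":
            lo, hi = v_min, v_min + factor * width
        else:
            center = 0.5 * (v_min + v_max)
            lo, hi = center - 0.5 * factor * width, center + 0.5 * factor * width
        new = new.with_reaction_bounds(r.id, lo, hi)
        contracted.append(r.id)
    return new, contracted


def add_probe_reactions(model: MetabolicModel, spec: ContextSpec) -> MetabolicModel:
    """Add the in-silico redox probes requested by the spec.

    Pseudo-hypoxia: NAD[c] + H2[c] -> NADH[c] + H[c], an irreversible
    cytosolic NAD reduction used to probe the NADH/NAD+ balance.
    NADH oxidase: NADH[c] + H[c] + 1/2 O2[c] -> NAD[c] + H2O[c], whose
    maximal flux measures the model's NAD+ recycling capacity.

    The cytosolic NAD/NADH cofactors must already exist; the auxiliary
    species (H, H2, H2O) are created on demand.
    """
    new = model
    if spec.add_pseudo_hypoxia or spec.add_nadh_oxidase:
        for met in (NAD_C, NADH_C):
            if not new.has_metabolite(met):
                raise ValidationError(f"probe reactions need cytosolic cofactor {met!r}")
    if spec.add_pseudo_hypoxia:
        aux = [Metabolite(H2_C, "hydrogen (probe species)", "c"),
               Metabolite(H_C, "proton", "c")]
        new = add_reaction(
            new,
            Reaction(id=PSEUDO_HYPOXIA_ID, name="pseudo-hypoxia probe",
                     stoichiometry={NAD_C: -1.0, H2_C: -1.0, NADH_C: 1.0, H_C: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            new_metabolites=aux,
        )
        # the probe's H2 substrate is supplied freely (probe species, not
        # a physiological metabolite)
        new = add_reaction(
            new, Reaction(id="EX_h2_probe", stoichiometry={H2_C: 1.0},
                          lower_bound=0.0, upper_bound=1000.0))
        if not new.has_reaction("SINK_h_c"):
            new = add_reaction(
                new, Reaction(id="SINK_h_c", stoichiometry={H_C: -1.0},
                              lower_bound=-1000.0, upper_bound=1000.0))
    if spec.add_nadh_oxidase:
        if not new.has_metabolite(O2_C):
            raise ValidationError(f"NADH oxidase probe needs cytosolic oxygen {O2_C!r}")
        aux = [Metabolite(H_C, "proton", "c"), Metabolite(H2O_C, "water", "c")]
        new = add_reaction(
            new,
            Reaction(id=NADH_OXIDASE_ID, name="NADH oxidase probe",
                     stoichiometry={NADH_C: -1.0, H_C: -1.0, O2_C: -0.5,
                                    NAD_C: 1.0, H2O_C: 1.0},
                     lower_bound=0.0, upper_bound=1000.0),
            new_metabolites=aux,
        )
        if not new.has_reaction("SINK_h2o_c"):
            new = add_reaction(
                new, Reaction(id="SINK_h2o_c", stoichiometry={H2O_C: -1.0},
                              lower_bound=0.0, upper_bound=1000.0))
        if not new.has_reaction("SINK_h_c"):
            new = add_reaction(
                new, Reaction(id="SINK_h_c", stoichiometry={H_C: -1.0},
                              lower_bound=-1000.0, upper_bound=1000.0))
    return new


def _assert_feasible(model: MetabolicModel, stage: str) -> None:
    sol = fba(model)
    if sol.status is not SolveStatus.OPTIMAL:
        raise ContextualizationError(stage, f"model became {sol.status.value}")


def contextualize_cell_line(
    template: MetabolicModel,
    spec: ContextSpec,
    precursors: Mapping[str, Mapping[str, float]] | None = None,
    fva_gamma: float = 0.0,
) -> ContextualizationResult:
    """Run the full contextualization pipeline for one cell line.

    Stage order (part of the contract): biomass build -> exchange
    constraints -> growth-rate fix -> ATP maintenance fix -> oxygen
    uptake cap -> probe reactions -> enzymopathy contraction, where the
    contraction uses FVA ranges of the model *before* this last stage
    (``fva_gamma`` controls the sub-optimality level of that FVA; 0
    gives the widest feasible ranges).  Any stage that breaks
    feasibility raises a :class:`ContextualizationError` naming it.
    """
    model = template.copy()
    model.name = spec.cell_line_name

    # 1. biomass
    biomass = build_biomass(spec.biomass, model, precursors, gam=spec.gam)
    if model.has_reaction(BIOMASS_ID):
        model.reactions = [r for r in model.reactions if r.id != BIOMASS_ID]
    model = add_reaction(model, biomass)
    model.objective = {BIOMASS_ID: 1.0}
    _assert_feasible(model, "biomass")

    # 2. measured exchange rates
    model = apply_exchange_constraints(model, spec.exchanges, spec.exchange_band)
    _assert_feasible(model, "exchange_constraints")

    # 3. growth rate
    lo = spec.growth_rate * (1.0 - spec.growth_band)
    hi = spec.growth_rate * (1.0 + spec.growth_band)
    model = model.with_reaction_bounds(BIOMASS_ID, lo, hi)
    _assert_feasible(model, "growth_rate")

    # 4. ATP maintenance
    if not model.has_reaction(ATPM_ID):
        model = add_reaction(
            model, Reaction(id=ATPM_ID, name="ATP maintenance",
                            stoichiometry={ATP_C: -1.0, ADP_C: 1.0},
                            lower_bound=0.0, upper_bound=1000.0))
    model = model.with_reaction_bounds(ATPM_ID, spec.atp_maintenance, spec.atp_maintenance)
    _assert_feasible(model, "atp_maintenance")

    # 5. oxygen uptake cap
    our_cap: float | None = None
    o2_exchange = next(
        (r.id for r in model.reactions
         if r.is_exchange and next(iter(r.stoichiometry)) == "o2_e"),
        None,
    )
    if o2_exchange is not None:
        if spec.our_cap_mode == "fba_max":
            our_cap = maximal_exchange(model, o2_exchange, "uptake")
        else:
            if spec.our_value is None:
                raise ContextualizationError("our_cap", "our_cap_mode='fixed' needs our_value")
            our_cap = spec.our_value
        ub = model.get_reaction(o2_exchange).upper_bound
        model = model.with_reaction_bounds(o2_exchange, -our_cap, ub)
        _assert_feasible(model, "our_cap")

    # 6. probes
    model = add_probe_reactions(model, spec)
    _assert_feasible(model, "probes")

    # 7. enzymopathies, using FVA of the pre-contraction model
    unaltered_fva: FVAResult | None = None
    contracted: list[str] = []
    if any(m.is_deleterious for m in spec.mutations):
        unaltered_fva = fva(model, FVAConfig(gamma=fva_gamma))
        model, contracted = apply_enzymopathies(
            model, spec.mutations, unaltered_fva,
            factor=spec.enzymopathy_factor, mode=spec.enzymopathy_mode)
        _assert_feasible(model, "enzymopathies")

    return ContextualizationResult(model=model, contracted_reactions=contracted,
                                   our_cap=our_cap, unaltered_fva=unaltered_fva)


# ---------------------------------------------------------------------------
# Tabular / config I/O
# ---------------------------------------------------------------------------

def read_mutation_table(path: str | Path, threshold: float = 0.95) -> list[MutationAnnotation]:
    """Read a TSV of (gene, variant, pph2_probability) variant calls."""
    df = pd.read_csv(path, sep="\t")
    return [
        MutationAnnotation.from_probability(
            str(row["gene"]), str(row.get("variant", "")),
            float(row["pph2_probability"]), threshold)
        for _, row in df.iterrows()
    ]


def read_exchange_table(path: str | Path, tolerance_band: float = 0.0) -> list[ExchangeConstraint]:
    """Read a CSV of (metabolite, rate_mmol_gDW_h) measured exchange rates."""
    df = pd.read_csv(path)
    return [
        ExchangeConstraint(str(row["metabolite"]), float(row["rate_mmol_gDW_h"]),
                           tolerance_band)
        for _, row in df.iterrows()
    ]


def load_context_spec(path: str | Path) -> ContextSpec:
    """Load a ContextSpec from YAML or JSON."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    return context_spec_from_dict(payload)


def context_spec_from_dict(payload: dict) -> ContextSpec:
    biomass = BiomassComposition(**payload.get("biomass", {}))
    exchanges = [ExchangeConstraint(**e) for e in payload.get("exchanges", [])]
    threshold = payload.get("deleterious_threshold", 0.95)
    mutations = [
        MutationAnnotation.from_probability(
            m["gene"], m.get("variant", ""), m["deleterious_probability"], threshold)
        for m in payload.get("mutations", [])
    ]
    keys = ("cell_line_name", "growth_rate", "atp_maintenance", "our_cap_mode",
            "our_value", "add_pseudo_hypoxia", "add_nadh_oxidase",
            "enzymopathy_factor", "enzymopathy_mode", "growth_band",
            "exchange_band", "gam")
    kwargs = {k: payload[k] for k in keys if k in payload}
    return ContextSpec(biomass=biomass, exchanges=exchanges, mutations=mutations, **kwargs)


def context_spec_to_dict(spec: ContextSpec) -> dict:
    return {
        "cell_line_name": spec.cell_line_name,
        "biomass": {
            "protein_fraction": spec.biomass.protein_fraction,
            "dna_fraction": spec.biomass.dna_fraction,
            "rna_fraction": spec.biomass.rna_fraction,
            "lipid_fraction": spec.biomass.lipid_fraction,
            "chromosome_count": spec.biomass.chromosome_count,
        },
        "exchanges": [
            {"metabolite": e.metabolite, "rate": e.rate, "tolerance_band": e.tolerance_band}
            for e in spec.exchanges
        ],
        "mutations": [
            {"gene": m.gene, "variant": m.variant_label,
             "deleterious_probability": m.deleterious_probability}
            for m in spec.mutations
        ],
        "growth_rate": spec.growth_rate,
        "atp_maintenance": spec.atp_maintenance,
        "our_cap_mode": spec.our_cap_mode,
        "our_value": spec.our_value,
        "add_pseudo_hypoxia": spec.add_pseudo_hypoxia,
        "add_nadh_oxidase": spec.add_nadh_oxidase,
        "enzymopathy_factor": spec.enzymopathy_factor,
        "enzymopathy_mode": spec.enzymopathy_mode,
        "growth_band": spec.growth_band,
        "exchange_band": spec.exchange_band,
        "gam": spec.gam,
    }
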