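"""Synthetic inputs for every pipeline stage.

Three generators, all seeded and deterministic:

* :func:`make_toy_network` — small networks with analytically known flux
  polytopes (chain, branch, cycle, simplex) or random flux-consistent
  networks, each with a ground-truth record so tests never re-derive
  expectations from the code under test;

* :func:`make_paired_scenario` — a template central-metabolism network
  (glycolysis -> lactate/pyruvate branch, lumped TCA + oxidative
  phosphorylation, macromolecule precursor synthesis, 21 constrained
  exchange metabolites plus oxygen) together with two cell-line context
  specs that differ in growth rate, lactate secretion (Warburg
  phenotype) and planted deleterious mutations.  Exchange rates are
  derived from the network's balance equations, so the planted phenotype
  is exactly feasible and the nutrient uptakes are uniquely determined
  by the constraints — the property the uptake-prediction validation
  relies on;

* :func:`make_timecourses` — Gompertz growth curves sampled every 24 h
  to 96 h and metabolite concentration time courses consistent with the
  planted specific exchange rates, with optional multiplicative noise.

The paired template's energy balance: glycolysis yields 2 ATP + 2 NADH
per glucose, pyruvate is split between lactate dehydrogenase (isozymes
LDHA/LDHB, NADH-consuming) and a lumped PDH+TCA route (4 NADH per
pyruvate), and oxidative phosphorylation regenerates NAD+ at 2.5
ATP/NADH using 0.5 O2.  Fixing growth, ATP maintenance, glucose and
lactate rates pins every pathway flux; only isozyme/parallel-transporter
splits stay free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .context import (
    ATP_C,
    ADP_C,
    BiomassComposition,
    ContextSpec,
    ExchangeConstraint,
    MutationAnnotation,
)
from .model import MetabolicModel, Metabolite, Reaction
from .rates import DEFAULT_DRY_WEIGHT_PER_CELL, gompertz

__all__ = [
    "ScenarioSpec",
    "PairedScenario",
    "TimecourseData",
    "make_toy_network",
    "make_paired_scenario",
    "make_timecourses",
]

# 19 proteinogenic amino acids used alongside glucose and lactate to
# fill the 21 constrained exchanges of the emulated design
_AA_NAMES = ["ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his",
             "ile", "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp", "tyr"]

_AA_RESIDUE_MASS = 0.109  # g/mmol, mean residue
_DNTP_MASS, _NTP_MASS, _LIPID_MASS = 0.327, 0.320, 0.740  # g/mmol

_CULTURE_VOLUME = 0.001  # L per well (24-well plate)


@dataclass
class ScenarioSpec:
    """Knobs of the paired cell-line scenario.

    Line A emulates a fast-growing, strongly glycolytic (high lactate)
    drug-sensitive line with 44 chromosome units; line B a slower,
    less glycolytic resistant line carrying the planted deleterious
    mutations.  Rates not supplied are derived from the network balance
    so each line's phenotype is exactly feasible.
    """

    seed: int = 0
    n_internal_reactions: int = 12  # used by the random toy generator
    n_exchanges: int = 21
    planted_enzymopathies: list[tuple[str, str]] = field(
        default_factory=lambda: [("LDHA", "LDH_A"), ("SLC6A7", "T_pro_1")])
    exchange_rates_a: dict[str, float] | None = None
    exchange_rates_b: dict[str, float] | None = None
    growth_mu_a: float = 0.035  # 1/h
    growth_mu_b: float = 0.020  # 1/h
    lactate_secretion_a: float = 1.0  # mmol/gDW/h
    lactate_secretion_b: float = 0.8
    noise_cv: float = 0.05
    n_replicates: int = 6  # independent replicate wells per condition

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.n_exchanges < 3:
            raise ValueError("need at least glucose, lactate and one amino acid")


# ---------------------------------------------------------------------------
# Toy networks with analytic polytopes
# ---------------------------------------------------------------------------

def make_toy_network(kind: str, size: int = 3, seed: int = 0) -> tuple[MetabolicModel, dict]:
    """A small model plus a ground-truth record.

    kind="chain":   EX_in -> m1 -> ... -> m_size -> EX_out, uptake bound 10;
                    analytic FVA (no objective): every flux in [0, 10].
    kind="branch":  fixed uptake 10 split A->B / A->C with free exports;
                    each branch in [0, 10]; with objective EX_B at full
                    optimality the split is forced to (10, 0).
    kind="cycle":   chain with a 2-reaction micro cycle B<->C capped at 50;
                    forward = 10 + reverse, reverse in [0, 40].
    kind="simplex": branch without an objective; the free coordinates
                    live uniformly on {v1 + v2 = 10, v >= 0}.
    kind="random":  `size` reactions over size//2 + 1 metabolites with
                    finite bounds containing 0 (so the zero flux is a
                    feasible reference point); no analytic truth.
    """
    if kind == "chain":
        return _chain(size)
    if kind in ("branch", "simplex"):
        return _branch(with_objective=(kind == "branch"))
    if kind == "cycle":
        return _cycle()
    if kind == "random":
        return _random_network(size, seed)
    raise ValueError(f"unknown toy kind {kind!r}")


def _chain(size: int) -> tuple[MetabolicModel, dict]:
    size = max(1, size)
    mets = [Metabolite(f"m{i}_c", compartment="c") for i in range(1, size + 1)]
    rxns = [Reaction("EX_in", {"m1_c": -1.0}, -10.0, 0.0)]
    for i in range(1, size):
        rxns.append(Reaction(f"R{i}", {f"m{i}_c": -1.0, f"m{i+1}_c": 1.0}, 0.0, 1000.0))
    rxns.append(Reaction("EX_out", {f"m{size}_c": -1.0}, 0.0, 1000.0))
    model = MetabolicModel(mets, rxns, objective={"EX_out": 1.0}, name=f"chain{size}")
    truth = {
        "fva_gamma0": {r.id: ((-10.0, 0.0) if r.id == "EX_in" else (0.0, 10.0))
                       for r in rxns},
        "optimum": 10.0,
    }
    return model, truth


def _branch(with_objective: bool) -> tuple[MetabolicModel, dict]:
    mets = [Metabolite(m, compartment="c") for m in ("a_c", "b_c", "c_c")]
    rxns = [
        Reaction("EX_A", {"a_c": -1.0}, -10.0, -10.0),
        Reaction("R_AB", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
        Reaction("R_AC", {"a_c": -1.0, "c_c": 1.0}, 0.0, 1000.0),
        Reaction("EX_B", {"b_c": -1.0}, 0.0, 1000.0),
        Reaction("EX_C", {"c_c": -1.0}, 0.0, 1000.0),
    ]
    objective = {"EX_B": 1.0} if with_objective else {}
    model = MetabolicModel(mets, rxns, objective=objective,
                           name="branch" if with_objective else "simplex")
    truth = {
        "fva_gamma0": {"EX_A": (-10.0, -10.0), "R_AB": (0.0, 10.0), "R_AC": (0.0, 10.0),
                       "EX_B": (0.0, 10.0), "EX_C": (0.0, 10.0)},
        "fva_gamma1": {"EX_A": (-10.0, -10.0), "R_AB": (10.0, 10.0), "R_AC": (0.0, 0.0),
                       "EX_B": (10.0, 10.0), "EX_C": (0.0, 0.0)} if with_objective else None,
        "optimum": 10.0 if with_objective else 0.0,
        "simplex_total": 10.0,
        "free_pair": ("R_AB", "R_AC"),
    }
    return model, truth


def _cycle() -> tuple[MetabolicModel, dict]:
    mets = [Metabolite(m, compartment="c") for m in ("a_c", "b_c", "c_c")]
    rxns = [
        Reaction("EX_A", {"a_c": -1.0}, -10.0, -10.0),
        Reaction("R_AB", {"a_c": -1.0, "b_c": 1.0}, 0.0, 1000.0),
        Reaction("R_BC", {"b_c": -1.0, "c_c": 1.0}, 0.0, 50.0),
        Reaction("R_CB", {"c_c": -1.0, "b_c": 1.0}, 0.0, 50.0),
        Reaction("EX_C", {"c_c": -1.0}, 0.0, 1000.0),
    ]
    model = MetabolicModel(mets, rxns, name="microcycle")
    truth = {
        "fva_gamma0": {"EX_A": (-10.0, -10.0), "R_AB": (10.0, 10.0),
                       "R_BC": (10.0, 50.0), "R_CB": (0.0, 40.0),
                       "EX_C": (10.0, 10.0)},
        "cycle_pair": ("R_BC", "R_CB"),
    }
    return model, truth


def _random_network(size: int, seed: int) -> tuple[MetabolicModel, dict]:
    rng = np.random.default_rng(seed)
    n_mets = max(2, size // 2 + 1)
    mets = [Metabolite(f"x{i}_c", compartment="c") for i in range(n_mets)]
    rxns: list[Reaction] = []
    for j in range(size):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {f"x{i}_c": float(np.round(rng.uniform(-2, 2), 2)) or 1.0 for i in chosen}
        lb = float(np.round(rng.uniform(-10, 0), 2))
        ub = float(np.round(rng.uniform(0, 10), 2))
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    model = MetabolicModel(mets, rxns, name=f"random{size}_s{seed}")
    return model, {"fva_gamma0": None, "feasible_point": [0.0] * size}


# ---------------------------------------------------------------------------
# Paired cell-line scenario
# ---------------------------------------------------------------------------

def _exchange_metabolites(n_exchanges: int) -> list[str]:
    n_aa = n_exchanges - 2
    if n_aa <= len(_AA_NAMES):
        aas = _AA_NAMES[:n_aa]
    else:
        aas = _AA_NAMES + [f"aa{i}" for i in range(n_aa - len(_AA_NAMES))]
    return ["glc", "lac"] + aas


def _build_template(n_exchanges: int) -> tuple[MetabolicModel, dict, list[str]]:
    """Template network; returns (model, precursor map, amino-acid names)."""
    names = _exchange_metabolites(n_exchanges)
    aas = names[2:]
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    for m in names + ["o2"]:
        mets.append(Metabolite(f"{m}_e", name=m, compartment="e"))
        mets.append(Metabolite(f"{m}_c", name=m, compartment="c"))
        rxns.append(Reaction(f"EX_{m}", {f"{m}_e": -1.0}, -50.0, 50.0))
        if m == "pro":
            # three parallel transporters (distinct carriers) for proline.
            # With only two, the free partner would mirror any bound
            # contraction of the other exactly (their sum is pinned),
            # making the contracted carrier unidentifiable; a third
            # carrier keeps the unaffected ones freely compensating.
            rxns.append(Reaction("T_pro_1", {"pro_e": -1.0, "pro_c": 1.0},
                                 -20.0, 20.0, gpr="SLC6A7"))
            rxns.append(Reaction("T_pro_2", {"pro_e": -1.0, "pro_c": 1.0},
                                 -20.0, 20.0, gpr="SLC36A1"))
            rxns.append(Reaction("T_pro_3", {"pro_e": -1.0, "pro_c": 1.0},
                                 -20.0, 20.0, gpr="SLC36A2"))
        else:
            rxns.append(Reaction(f"T_{m}", {f"{m}_e": -1.0, f"{m}_c": 1.0},
                                 -50.0, 50.0))
    rxns = [r for r in rxns if r.id != "EX_o2"] + [
        Reaction("EX_o2", {"o2_e": -1.0}, -50.0, 0.0)
    ]

    for m in ("pyr", "acc", "atp", "adp", "nad", "nadh",
              "dntp_pool", "ntp_pool", "lipid_pool"):
        mets.append(Metabolite(f"{m}_c", name=m, compartment="c"))

    rxns += [
        # lumped Embden-Meyerhof glycolysis
        Reaction("GLYC", {"glc_c": -1.0, "adp_c": -2.0, "nad_c": -2.0,
                          "pyr_c": 2.0, "atp_c": 2.0, "nadh_c": 2.0},
                 0.0, 50.0, gpr="HK1 and GAPDH and PKM"),
        # lactate dehydrogenase isozymes (three parallel, individually
        # dispensable routes; see the proline-transporter comment above)
        Reaction("LDH_A", {"pyr_c": -1.0, "nadh_c": -1.0, "lac_c": 1.0, "nad_c": 1.0},
                 -20.0, 20.0, gpr="LDHA"),
        Reaction("LDH_B", {"pyr_c": -1.0, "nadh_c": -1.0, "lac_c": 1.0, "nad_c": 1.0},
                 -20.0, 20.0, gpr="LDHB"),
        Reaction("LDH_C", {"pyr_c": -1.0, "nadh_c": -1.0, "lac_c": 1.0, "nad_c": 1.0},
                 -20.0, 20.0, gpr="LDHC"),
        # pyruvate dehydrogenase + lumped TCA
        Reaction("PDH", {"pyr_c": -1.0, "nad_c": -1.0, "acc_c": 1.0, "nadh_c": 1.0},
                 0.0, 50.0, gpr="PDHA1 and DLAT"),
        Reaction("TCA", {"acc_c": -1.0, "nad_c": -3.0, "nadh_c": 3.0},
                 0.0, 50.0, gpr="CS and SDHA"),
        # lumped respiratory chain + ATP synthase
        Reaction("OXPHOS", {"nadh_c": -1.0, "o2_c": -0.5, "adp_c": -2.5,
                            "nad_c": 1.0, "atp_c": 2.5},
                 0.0, 50.0, gpr="NDUFS1 and ATP5F1A"),
        # macromolecule precursor synthesis
        Reaction("DNTP_SYN", {"glc_c": -1.0, "atp_c": -2.0,
                              "dntp_pool_c": 1.0, "adp_c": 2.0},
                 0.0, 50.0, gpr="RRM1"),
        Reaction("NTP_SYN", {"glc_c": -1.0, "atp_c": -2.0,
                             "ntp_pool_c": 1.0, "adp_c": 2.0},
                 0.0, 50.0, gpr="PRPS1"),
        Reaction("LIPID_SYN", {"glc_c": -4.0, "atp_c": -2.0,
                               "lipid_pool_c": 1.0, "adp_c": 2.0},
                 0.0, 50.0, gpr="FASN"),
        Reaction("ATPM", {"atp_c": -1.0, "adp_c": 1.0}, 0.0, 50.0),
    ]

    precursors = {
        "protein": {f"{aa}_c": _AA_RESIDUE_MASS for aa in aas},
        "dna": {"dntp_pool_c": _DNTP_MASS},
        "rna": {"ntp_pool_c": _NTP_MASS},
        "lipid": {"lipid_pool_c": _LIPID_MASS},
    }
    model = MetabolicModel(mets, rxns, name="gbm_core_template")
    return model, precursors, aas


def _derive_rates(mu: float, lactate: float, biomass: BiomassComposition,
                  aas: list[str], atp_maintenance: float, gam: float) -> dict[str, float]:
    """Exchange rates exactly consistent with the template's balances.

    With growth mu, lactate secretion L and ATP demand
    A = gam*mu + maintenance + 2*(precursor syntheses), the balance
    equations give glycolytic flux G = (A + 12.5 L)/27 and respiratory
    flux 10 (A - L)/27 (see module docstring), hence the glucose and
    oxygen rates; amino-acid uptakes follow the biomass coefficients.
    """
    fr = biomass.effective_fractions()
    v_dntp = fr["dna"] / _DNTP_MASS * mu
    v_ntp = fr["rna"] / _NTP_MASS * mu
    v_lip = fr["lipid"] / _LIPID_MASS * mu
    a_need = gam * mu + atp_maintenance + 2.0 * (v_dntp + v_ntp + v_lip)
    v_glyc = (a_need + 12.5 * lactate) / 27.0
    v_pdh = 2.0 * v_glyc - lactate
    if v_pdh < 0:
        raise ValueError("planted lactate secretion exceeds glycolytic pyruvate supply")
    v_ox = 10.0 * (a_need - lactate) / 27.0
    aa_rate = fr["protein"] / (len(aas) * _AA_RESIDUE_MASS) * mu
    rates = {"glc": -(v_glyc + v_dntp + v_ntp + 4.0 * v_lip), "lac": lactate}
    rates.update({aa: -aa_rate for aa in aas})
    rates["_o2_uptake"] = 0.5 * v_ox  # informational; oxygen is capped, not listed
    rates["_v_glyc"] = v_glyc
    rates["_v_ox"] = v_ox
    return rates


@dataclass
class PairedScenario:
    template: MetabolicModel
    spec_a: ContextSpec
    spec_b: ContextSpec
    precursors: dict[str, dict[str, float]]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        """Emit model JSON, two spec JSONs, rate CSVs and the truth record."""
        from .context import context_spec_to_dict
        from .io import save_model

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_model(self.template, outdir / "template.json")
        for label, spec in (("a", self.spec_a), ("b", self.spec_b)):
            (outdir / f"spec_{label}.json").write_text(
                json.dumps(context_spec_to_dict(spec), indent=1))
            pd.DataFrame(
                [{"metabolite": e.metabolite, "rate_mmol_gDW_h": e.rate}
                 for e in spec.exchanges]
            ).to_csv(outdir / f"exchange_rates_{label}.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


def make_paired_scenario(spec: ScenarioSpec | None = None) -> PairedScenario:
    """Template + two cell-line ContextSpecs + ground-truth record.

    Line B carries the planted deleterious mutations
    (probability 0.998); both lines carry benign passengers and one
    damaging mutation in a non-metabolic gene, so the GPR matching has
    something to ignore.  The truth record lists the reactions whose
    spans must contract in B and the planted exchange-rate tables.
    """
    spec = spec or ScenarioSpec()
    template, precursors, aas = _build_template(spec.n_exchanges)
    for gene, rid in spec.planted_enzymopathies:
        rxn = next((r for r in template.reactions if r.id == rid), None)
        if rxn is None or gene not in rxn.gpr:
            raise ValueError(
                f"planted enzymopathy ({gene!r}, {rid!r}) does not match the template GPRs")

    biomass_a = BiomassComposition(chromosome_count=44)
    biomass_b = BiomassComposition(chromosome_count=46)
    atp_m, gam = 1.07, 30.0
    rates_a = spec.exchange_rates_a or _derive_rates(
        spec.growth_mu_a, spec.lactate_secretion_a, biomass_a, aas, atp_m, gam)
    rates_b = spec.exchange_rates_b or _derive_rates(
        spec.growth_mu_b, spec.lactate_secretion_b, biomass_b, aas, atp_m, gam)

    def _constraints(rates: dict[str, float]) -> list[ExchangeConstraint]:
        return [ExchangeConstraint(f"{m}_e", r)
                for m, r in rates.items() if not m.startswith("_")]

    benign = [MutationAnnotation.from_probability("PKM", "p.A327T", 0.12),
              MutationAnnotation.from_probability("CS", "p.V211I", 0.30)]
    nonmetabolic = [MutationAnnotation.from_probability("TP53", "p.R273H", 0.998)]
    planted = [MutationAnnotation.from_probability(g, f"planted:{rid}", 0.998)
               for g, rid in spec.planted_enzymopathies]

    common = dict(atp_maintenance=atp_m, gam=gam, growth_band=0.0, exchange_band=0.0,
                  add_pseudo_hypoxia=True, add_nadh_oxidase=True)
    spec_a = ContextSpec(cell_line_name="lineA_sensitive", biomass=biomass_a,
                         exchanges=_constraints(rates_a), mutations=benign + nonmetabolic,
                         growth_rate=spec.growth_mu_a, **common)
    spec_b = ContextSpec(cell_line_name="lineB_resistant", biomass=biomass_b,
                         exchanges=_constraints(rates_b),
                         mutations=benign + nonmetabolic + planted,
                         growth_rate=spec.growth_mu_b, **common)

    truth = {
        "contracted_reactions_b": sorted(rid for _, rid in spec.planted_enzymopathies),
        "exchange_rates_a": {m: r for m, r in rates_a.items() if not m.startswith("_")},
        "exchange_rates_b": {m: r for m, r in rates_b.items() if not m.startswith("_")},
        # derived flux info is only known for balance-derived rates; user
        # overrides leave these as None
        "our_uptake_a": rates_a.get("_o2_uptake"),
        "our_uptake_b": rates_b.get("_o2_uptake"),
        "glycolytic_flux_a": rates_a.get("_v_glyc"),
        "glycolytic_flux_b": rates_b.get("_v_glyc"),
        "growth_mu_a": spec.growth_mu_a,
        "growth_mu_b": spec.growth_mu_b,
        "exchange_ids": sorted(f"EX_{m}" for m in _exchange_metabolites(spec.n_exchanges)),
    }
    return PairedScenario(template=template, spec_a=spec_a, spec_b=spec_b,
                          precursors=precursors, truth=truth)


# ---------------------------------------------------------------------------
# Growth and concentration time courses
# ---------------------------------------------------------------------------

@dataclass
class TimecourseData:
    growth: pd.DataFrame  # cell_line, replicate, time_h, count
    concentrations: pd.DataFrame  # cell_line, metabolite, time_h, conc_mM
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.growth.to_csv(outdir / "growth.csv", index=False)
        self.concentrations.to_csv(outdir / "concentrations.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


#: Initial extracellular concentrations (mM): glucose near depletion-matched
#: levels, lactate absent, amino acids at medium-like levels chosen so the
#: slower line still consumes a measurable share (endpoint differences stay
#: well above the multiplicative reading noise).
_C0 = {"glc": 10.0, "lac": 0.0, "_aa": 0.2}

_N0, _K = 1.0e4, 1.0e6  # inoculum and carrying capacity (cells/well)


def make_timecourses(spec: ScenarioSpec | None = None) -> TimecourseData:
    """Gompertz growth counts (0-96 h, every 24 h) and metabolite
    concentration series consistent with the planted specific rates.

    Concentrations follow dC/dt = q * X(t) / V with X(t) the Gompertz
    biomass; multiplicative noise with coefficient of variation
    ``noise_cv`` is applied independently to every count and
    concentration reading of each of ``n_replicates`` replicate wells.
    Deterministic per seed.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    scenario = make_paired_scenario(
        ScenarioSpec(**{**spec.__dict__, "noise_cv": 0.0}))
    times = np.arange(0.0, 97.0, 24.0)

    growth_rows, conc_rows = [], []
    truth = {"volume_L": _CULTURE_VOLUME,
             "dry_weight_per_cell": DEFAULT_DRY_WEIGHT_PER_CELL,
             "n0": _N0, "carrying_capacity": _K, "lines": {}}
    for line, mu, rates in (
        ("lineA_sensitive", spec.growth_mu_a, scenario.truth["exchange_rates_a"]),
        ("lineB_resistant", spec.growth_mu_b, scenario.truth["exchange_rates_b"]),
    ):
        counts = gompertz(times, _N0, _K, mu)
        cum_cells = np.array([quad(lambda t: gompertz(t, _N0, _K, mu), 0.0, t,
                                   limit=200)[0] for t in times])
        biomass_hours = cum_cells * DEFAULT_DRY_WEIGHT_PER_CELL  # gDW*h
        for rep in range(1, spec.n_replicates + 1):
            noisy_counts = counts * _noise(rng, counts.shape, spec.noise_cv)
            for t, c in zip(times, noisy_counts):
                growth_rows.append(dict(cell_line=line, replicate=f"r{rep}",
                                        time_h=t, count=c))
        truth["lines"][line] = {"mu": mu, "rates": rates}
        for met, q in rates.items():
            c0 = _C0.get(met, _C0["_aa"])
            conc = c0 + q * biomass_hours / _CULTURE_VOLUME
            conc = np.maximum(conc, 0.0)
            for rep in range(1, spec.n_replicates + 1):
                noisy = conc * _noise(rng, conc.shape, spec.noise_cv)
                for t, c in zip(times, noisy):
                    conc_rows.append(dict(cell_line=line, metabolite=met,
                                          replicate=f"r{rep}",
                                          time_h=t, conc_mM=c))
    return TimecourseData(growth=pd.DataFrame(growth_rows),
                          concentrations=pd.DataFrame(conc_rows), truth=truth)


def _noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    return np.maximum(1.0 + cv * rng.standard_normal(shape), 0.05)
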