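"""Contextualization stages: biomass, exchange constraints, maintenance,
OUR capping, probes, and the Eq.-4-style enzymopathy contraction."""

import math

import numpy as np
import pytest

import gbmflux as g
from gbmflux.context import (ATPM_ID, BIOMASS_ID, NADH_OXIDASE_ID,
                             PSEUDO_HYPOXIA_ID, BiomassComposition,
                             ContextSpec, ContextualizationError,
                             ExchangeConstraint, MutationAnnotation,
                             apply_enzymopathies, apply_exchange_constraints,
                             add_probe_reactions, build_biomass,
                             context_spec_from_dict, context_spec_to_dict,
                             read_exchange_table, read_mutation_table)
from gbmflux.lp import FVAResult, fba
from gbmflux.model import MetabolicModel, Metabolite, Reaction, ValidationError

from helpers import quiet_contextualize


# ---------------------------------------------------------------------------
# biomass composition
# ---------------------------------------------------------------------------

def test_biomass_fractions_must_sum_to_one():
    with pytest.raises(ValidationError):
        BiomassComposition(protein_fraction=0.5, dna_fraction=0.1,
                           rna_fraction=0.1, lipid_fraction=0.1)
    with pytest.raises(ValidationError):
        BiomassComposition(protein_fraction=-0.1, dna_fraction=0.4,
                           rna_fraction=0.4, lipid_fraction=0.3)


def test_effective_fractions_chromosome_scaling():
    """Hand-checked arithmetic: 44 chromosome units scale DNA by 44/46,
    the freed mass goes to RNA and lipid pro rata, protein untouched."""
    comp = BiomassComposition(chromosome_count=44)
    fr = comp.effective_fractions()
    dna = 0.02 * 44.0 / 46.0
    freed = 0.02 - dna
    assert fr["protein"] == pytest.approx(0.70, abs=1e-12)
    assert fr["dna"] == pytest.approx(dna, abs=1e-12)
    assert fr["rna"] == pytest.approx(0.08 + freed * 0.08 / 0.28, abs=1e-12)
    assert fr["lipid"] == pytest.approx(0.20 + freed * 0.20 / 0.28, abs=1e-12)
    assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)


def test_effective_fractions_diploid_identity():
    fr = BiomassComposition().effective_fractions()
    assert fr == {"protein": 0.70, "dna": 0.02, "rna": 0.08, "lipid": 0.20}


def test_biomass_reaction_mass_accounting(scenario, ctx_pair):
    """Precursor coefficients times molar masses reproduce the class
    fractions (so the built reaction consumes 1 gDW per unit flux)."""
    biomass = ctx_pair[0].model.get_reaction(BIOMASS_ID)
    fr = scenario.spec_a.biomass.effective_fractions()
    for cls, pools in scenario.precursors.items():
        consumed = -sum(biomass.stoichiometry[m] * mass for m, mass in pools.items())
        assert consumed == pytest.approx(fr[cls], abs=1e-12), cls
    # growth-associated ATP demand folded in
    assert biomass.stoichiometry["atp_c"] == pytest.approx(-scenario.spec_a.gam)
    assert biomass.stoichiometry["adp_c"] == pytest.approx(scenario.spec_a.gam)


# ---------------------------------------------------------------------------
# exchange constraints
# ---------------------------------------------------------------------------

def test_exchange_constraint_bounds():
    assert ExchangeConstraint("glc_e", -5.0, 0.1).bounds() == (-5.5, -4.5)
    assert ExchangeConstraint("lac_e", 2.0, 0.5).bounds() == (1.0, 3.0)
    assert ExchangeConstraint("glc_e", -5.0).bounds() == (-5.0, -5.0)
    with pytest.raises(ValidationError):
        ExchangeConstraint("glc_e", -5.0, -0.1)


def test_apply_exchange_constraints_sets_bounds(branch):
    model, _ = branch
    new = apply_exchange_constraints(model, [ExchangeConstraint("b_c", 3.0, 0.1)])
    assert new.get_reaction("EX_B").lower_bound == pytest.approx(2.7)
    assert new.get_reaction("EX_B").upper_bound == pytest.approx(3.3)
    assert model.get_reaction("EX_B").upper_bound == 1000.0


def test_apply_exchange_constraints_reports_all_missing(branch):
    model, _ = branch
    with pytest.raises(ValidationError) as err:
        apply_exchange_constraints(model, [ExchangeConstraint("x_e", -1.0),
                                           ExchangeConstraint("y_e", -1.0)])
    assert "x_e" in str(err.value) and "y_e" in str(err.value)


# ---------------------------------------------------------------------------
# enzymopathy contraction
# ---------------------------------------------------------------------------

def _two_route_model(gpr="G1"):
    """a_c <-> b_c via an internal target reaction plus free exchanges;
    the target's whole-polytope FVA range is [-10, 10]."""
    return MetabolicModel(
        metabolites=[Metabolite("a_c"), Metabolite("b_c")],
        reactions=[Reaction("EX_a", {"a_c": -1.0}, -10.0, 10.0),
                   Reaction("R_target", {"a_c": -1.0, "b_c": 1.0},
                            -10.0, 10.0, gpr=gpr),
                   Reaction("EX_b", {"b_c": -1.0}, -10.0, 10.0)],
    )


def _deleterious(gene):
    return MutationAnnotation.from_probability(gene, "p.X1Y", 0.99)


def test_eq4_literal_contraction_arithmetic():
    model = _two_route_model()
    fva_result = FVAResult(ranges={"R_target": (-10.0, 10.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    new, contracted = apply_enzymopathies(model, [_deleterious("G1")], fva_result)
    assert contracted == ["R_target"]
    rxn = new.get_reaction("R_target")
    assert (rxn.lower_bound, rxn.upper_bound) == (-10.0, -5.0)

    fva_result = FVAResult(ranges={"R_target": (0.0, 8.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    new, _ = apply_enzymopathies(model, [_deleterious("G1")], fva_result)
    rxn = new.get_reaction("R_target")
    assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 2.0)


def test_eq4_symmetric_mode():
    model = _two_route_model()
    fva_result = FVAResult(ranges={"R_target": (-10.0, 10.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    new, _ = apply_enzymopathies(model, [_deleterious("G1")], fva_result,
                                 mode="symmetric")
    rxn = new.get_reaction("R_target")
    assert (rxn.lower_bound, rxn.upper_bound) == (-2.5, 2.5)
    with pytest.raises(ValueError):
        apply_enzymopathies(model, [_deleterious("G1")], fva_result, mode="nope")


def test_isozyme_rescues_but_complex_does_not():
    fva_result = FVAResult(ranges={"R_target": (-10.0, 10.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    for gpr, expect_contracted in (("G1 or G2", False), ("G1 and G2", True)):
        _, contracted = apply_enzymopathies(_two_route_model(gpr),
                                            [_deleterious("G1")], fva_result)
        assert bool(contracted) is expect_contracted, gpr


def test_exchanges_never_contracted():
    model = MetabolicModel(
        metabolites=[Metabolite("a_c")],
        reactions=[Reaction("EX_a", {"a_c": -1.0}, -10.0, 10.0, gpr="G1"),
                   Reaction("R_in", {"a_c": 1.0}, -10.0, 10.0)],
    )
    fva_result = FVAResult(ranges={"EX_a": (-10.0, 10.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    _, contracted = apply_enzymopathies(model, [_deleterious("G1")], fva_result)
    assert contracted == []


def test_orphan_deleterious_gene_warns():
    model = _two_route_model()
    fva_result = FVAResult(ranges={"R_target": (-10.0, 10.0)}, gamma=0.0,
                           objective_value_used=None, failed=[])
    with pytest.warns(UserWarning, match="GHOST"):
        apply_enzymopathies(model, [_deleterious("GHOST")], fva_result)


def test_mutation_threshold():
    assert MutationAnnotation.from_probability("G", "v", 0.95).is_deleterious
    assert not MutationAnnotation.from_probability("G", "v", 0.9499).is_deleterious
    with pytest.raises(ValidationError):
        MutationAnnotation.from_probability("G", "v", 1.5)


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def test_probe_reactions_stoichiometry(ctx_pair):
    model = ctx_pair[0].model
    hyp = model.get_reaction(PSEUDO_HYPOXIA_ID)
    assert hyp.stoichiometry == {"nad_c": -1.0, "h2_c": -1.0,
                                 "nadh_c": 1.0, "h_c": 1.0}
    assert hyp.lower_bound == 0.0
    oxi = model.get_reaction(NADH_OXIDASE_ID)
    assert oxi.stoichiometry == {"nadh_c": -1.0, "h_c": -1.0, "o2_c": -0.5,
                                 "nad_c": 1.0, "h2o_c": 1.0}
    from gbmflux.model import validate_model
    assert validate_model(model) == []


def test_probes_require_cofactors(branch):
    model, _ = branch
    spec = ContextSpec(cell_line_name="x", add_pseudo_hypoxia=True)
    with pytest.raises(ValidationError):
        add_probe_reactions(model, spec)


# ---------------------------------------------------------------------------
# full contextualization
# ---------------------------------------------------------------------------

def test_atp_maintenance_fixed(ctx_pair):
    for result in ctx_pair:
        rxn = result.model.get_reaction(ATPM_ID)
        assert (rxn.lower_bound, rxn.upper_bound) == (1.07, 1.07)


def test_growth_rate_pinned_exactly(scenario, ctx_pair):
    # the generated specs use growth_band = 0, so FBA growth is exact
    assert fba(ctx_pair[0].model).objective_value == pytest.approx(
        scenario.truth["growth_mu_a"], abs=1e-9)
    assert fba(ctx_pair[1].model).objective_value == pytest.approx(
        scenario.truth["growth_mu_b"], abs=1e-9)


def test_our_cap_matches_planted_oxygen_uptake(scenario, ctx_pair):
    result_a, result_b = ctx_pair
    assert result_a.our_cap == pytest.approx(scenario.truth["our_uptake_a"], abs=1e-6)
    assert result_b.our_cap == pytest.approx(scenario.truth["our_uptake_b"], abs=1e-6)
    ex_o2 = result_a.model.get_reaction("EX_o2")
    assert ex_o2.lower_bound == pytest.approx(-result_a.our_cap, abs=1e-9)
    assert ex_o2.upper_bound == 0.0


def test_contracted_reactions_match_truth(scenario, ctx_pair):
    assert ctx_pair[0].contracted_reactions == []
    assert sorted(ctx_pair[1].contracted_reactions) == \
        scenario.truth["contracted_reactions_b"]


def test_contracted_bound_width_is_quarter_of_unaltered(ctx_pair):
    result_b = ctx_pair[1]
    for rid in result_b.contracted_reactions:
        rxn = result_b.model.get_reaction(rid)
        lo, hi = result_b.unaltered_fva.ranges[rid]
        assert (rxn.upper_bound - rxn.lower_bound) == pytest.approx(
            0.25 * (hi - lo), abs=1e-9), rid
        assert rxn.lower_bound == pytest.approx(lo, abs=1e-9)


def test_infeasible_stage_is_named(scenario):
    bad = ContextSpec(cell_line_name="bad", biomass=scenario.spec_a.biomass,
                      exchanges=scenario.spec_a.exchanges,
                      growth_rate=10.0, growth_band=0.0,
                      gam=scenario.spec_a.gam)
    with pytest.raises(ContextualizationError) as err:
        quiet_contextualize(scenario.template, bad, scenario.precursors)
    assert err.value.stage == "growth_rate"


def test_context_spec_validation():
    with pytest.raises(ValidationError):
        ContextSpec(cell_line_name="x", growth_rate=-1.0)
    with pytest.raises(ValidationError):
        ContextSpec(cell_line_name="x", enzymopathy_factor=0.0)
    with pytest.raises(ValidationError):
        ContextSpec(cell_line_name="x", our_cap_mode="banana")


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def test_read_mutation_table(tmp_path):
    path = tmp_path / "muts.tsv"
    path.write_text("gene\tvariant\tpph2_probability\n"
                    "LDHA\tp.R106W\t0.998\n"
                    "PKM\tp.A327T\t0.12\n")
    muts = read_mutation_table(path)
    assert [m.gene for m in muts] == ["LDHA", "PKM"]
    assert [m.is_deleterious for m in muts] == [True, False]


def test_read_exchange_table(tmp_path):
    path = tmp_path / "rates.csv"
    path.write_text("metabolite,rate_mmol_gDW_h\nglc_e,-0.59\nlac_e,1.0\n")
    exchanges = read_exchange_table(path, tolerance_band=0.1)
    assert [(e.metabolite, e.rate) for e in exchanges] == \
        [("glc_e", -0.59), ("lac_e", 1.0)]
    assert all(e.tolerance_band == 0.1 for e in exchanges)


def test_context_spec_dict_roundtrip(scenario):
    payload = context_spec_to_dict(scenario.spec_b)
    back = context_spec_from_dict(payload)
    assert back.cell_line_name == scenario.spec_b.cell_line_name
    assert back.growth_rate == scenario.spec_b.growth_rate
    assert back.biomass == scenario.spec_b.biomass
    assert back.exchanges == scenario.spec_b.exchanges
    assert back.mutations == scenario.spec_b.mutations
    assert back.atp_maintenance == scenario.spec_b.atp_maintenance
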