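"""Differential span/distribution comparison of paired models."""

import numpy as np
import pandas as pd
import pytest

import gbmflux as g
from gbmflux.differential import (build_report, classify_direction,
                                  compare_distributions, compare_spans,
                                  pathway_rollup)
from gbmflux.lp import FVAResult
from gbmflux.sampling import FluxSampleSet, SamplerConfig


def _fva(ranges):
    return FVAResult(ranges=ranges, gamma=0.0, objective_value_used=None,
                     failed=[])


def _samples(matrix, ids):
    return FluxSampleSet(matrix=np.asarray(matrix, dtype=float),
                         reaction_ids=list(ids),
                         config=SamplerConfig(n_warmup=2, n_samples=len(matrix),
                                              thinning=1))


def test_classify_direction():
    assert classify_direction(-1.0, 2.0) == "bidirectional"
    assert classify_direction(0.0, 2.0) == "forward"
    assert classify_direction(-2.0, 0.0) == "reverse"
    assert classify_direction(-1e-12, 1e-12) == "blocked"


def test_compare_spans_identical_is_null():
    fva_result = _fva({"R1": (-2.0, 5.0), "R2": (0.0, 3.0)})
    table = compare_spans(fva_result, fva_result)
    assert (table.span_ratio == 1.0).all()
    assert not table.direction_flip.any()
    assert (table.overlap == table.span_a).all()


def test_compare_spans_direction_flip():
    table = compare_spans(_fva({"R1": (-2.0, 5.0)}), _fva({"R1": (0.0, 5.0)}))
    row = table.loc["R1"]
    assert row.direction_flip and row.flip_type == "bidirectional->forward"
    assert row.span_ratio == pytest.approx(5.0 / 7.0)


def test_compare_spans_degenerate_ratios():
    table = compare_spans(_fva({"R1": (1.0, 1.0), "R2": (0.0, 0.0)}),
                          _fva({"R1": (1.0, 1.0), "R2": (0.0, 4.0)}))
    assert table.loc["R1"].span_ratio == 1.0
    assert np.isinf(table.loc["R2"].span_ratio)


def test_compare_spans_outer_join_and_disjoint_error():
    table = compare_spans(_fva({"R1": (0.0, 1.0), "only_a": (0.0, 1.0)}),
                          _fva({"R1": (0.0, 1.0), "only_b": (0.0, 2.0)}))
    assert table.loc["only_a"].in_both == False  # noqa: E712
    assert np.isnan(table.loc["only_b"].span_a)
    with pytest.raises(ValueError):
        compare_spans(_fva({"A": (0.0, 1.0)}), _fva({"B": (0.0, 1.0)}))


def test_distribution_shift_extremes():
    rng = np.random.default_rng(0)
    x = rng.uniform(0.0, 1.0, size=(500, 1))
    same = compare_distributions(_samples(x, ["R"]), _samples(x, ["R"]))
    assert same.loc["R", "shift"] == pytest.approx(0.0, abs=1e-9)
    disjoint = compare_distributions(_samples(np.zeros((100, 1)), ["R"]),
                                     _samples(np.ones((100, 1)), ["R"]))
    assert disjoint.loc["R", "shift"] == pytest.approx(1.0)
    constant = compare_distributions(_samples(np.full((50, 1), 3.0), ["R"]),
                                     _samples(np.full((50, 1), 3.0), ["R"]))
    assert constant.loc["R", "shift"] == 0.0


def test_distribution_shift_ks_and_errors():
    rng = np.random.default_rng(1)
    a = _samples(rng.normal(0.0, 1.0, size=(400, 1)), ["R"])
    b = _samples(rng.normal(3.0, 1.0, size=(400, 1)), ["R"])
    assert compare_distributions(a, b, method="ks").loc["R", "shift"] > 0.8
    with pytest.raises(ValueError):
        compare_distributions(a, b, method="nope")
    with pytest.raises(ValueError):
        compare_distributions(a, _samples(np.ones((5, 1)), ["other"]))


def test_null_shift_between_seeds_is_small(simplex):
    """Same polytope, different sampler seeds: shift stays near zero
    (calibrated null ~0.04 at this protocol; threshold 2.4x)."""
    model, _ = simplex
    def sample(seed):
        config = SamplerConfig(n_warmup=80, n_samples=5000, thinning=50, seed=seed)
        return g.achr_sample(model, g.generate_warmup(model, config), config)
    shifts = compare_distributions(sample(11), sample(22))
    assert shifts["shift"].max() <= 0.1


def test_pathway_rollup():
    table = pd.DataFrame(
        {"span_ratio": [0.25, 0.26, 1.0, 1.1, np.inf],
         "shift": [0.9, 0.8, 0.05, 0.02, 0.5]},
        index=["R1", "R2", "R3", "R4", "R5"])
    rollup = pathway_rollup(table, {"R1": "glycolysis", "R2": "glycolysis",
                                    "R3": "tca", "R4": "tca"},
                            shift_threshold=0.1)
    assert rollup.loc["glycolysis"].n_reactions == 2
    assert rollup.loc["glycolysis"].median_span_ratio == pytest.approx(0.255)
    assert rollup.loc["glycolysis"].fraction_shifted == 1.0
    assert rollup.loc["tca"].fraction_shifted == 0.0
    assert rollup.loc["unassigned"].n_reactions == 1
    # inf ratios are excluded from medians, not propagated
    assert np.isfinite(rollup.median_span_ratio.drop("unassigned")).all()


def test_build_report_on_paired_models(scenario, ctx_fvas):
    fva_a, fva_b = ctx_fvas
    report = build_report(fva_a, fva_b, metadata={"pair": "a-vs-b"})
    planted = scenario.truth["contracted_reactions_b"]
    table = report.per_reaction
    for rid in planted:
        assert table.loc[rid].span_ratio == pytest.approx(0.25, abs=0.01), rid
    assert table.loc["LDH_A"].flip_type == "bidirectional->reverse"
    assert sorted(report.top_shifted(len(planted))) == planted
    assert report.metadata["pair"] == "a-vs-b"
    # partner routes left free by the planted contraction stay wide
    assert table.loc["LDH_B"].span_ratio > 0.5
    assert table.loc["T_pro_2"].span_ratio > 0.5
    assert table.loc["T_pro_3"].span_ratio > 0.5


def test_build_report_with_samples(ctx_pair, ctx_fvas):
    result_a, result_b = ctx_pair
    fva_a, fva_b = ctx_fvas
    def sample(model, seed):
        config = SamplerConfig(n_warmup=150, n_samples=1500, thinning=40, seed=seed)
        return g.achr_sample(model, g.generate_warmup(model, config), config)
    report = build_report(fva_a, fva_b, sample(result_a.model, 5),
                          sample(result_b.model, 5),
                          subsystem_map={"LDH_A": "glycolysis",
                                         "LDH_B": "glycolysis",
                                         "LDH_C": "glycolysis"})
    assert "shift" in report.per_reaction
    assert report.per_reaction["shift"].between(0.0, 1.0).all()
    assert "glycolysis" in report.pathway.index
    # with zero-band constraints only the two 3-route loops vary, and
    # their pairwise correlations stay below the default threshold, so
    # the correlated sets are legitimately empty lists here
    assert isinstance(report.correlated_sets_a, list)
    assert isinstance(report.correlated_sets_b, list)
    # ranking by shift is available once samples are attached
    assert len(report.top_shifted(3)) == 3
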