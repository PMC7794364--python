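"""ACHR sampler: feasibility (hard), reproducibility, uniformity on
analytic polytopes, and correlated-set detection vs a brute-force oracle."""

import itertools
import json

import numpy as np
import pytest

import gbmflux as g
from gbmflux.model import MetabolicModel, Metabolite, Reaction
from gbmflux.sampling import (SamplerConfig, achr_sample, correlated_sets,
                              flux_histograms, generate_warmup, mean_drift)

from helpers import assert_samples_feasible


def interval_model():
    """One degree of freedom uniform on [0, 1] (R_in = R_out <= 1)."""
    return MetabolicModel(
        metabolites=[Metabolite("a_c")],
        reactions=[Reaction("R_in", {"a_c": 1.0}, 0.0, 1.0),
                   Reaction("R_out", {"a_c": -1.0}, 0.0, 5.0)],
        name="interval",
    )


def _sample(model, **kwargs):
    config = SamplerConfig(**kwargs)
    warmup = generate_warmup(model, config)
    return achr_sample(model, warmup, config)


def test_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(n_warmup=1)
    with pytest.raises(ValueError):
        SamplerConfig(n_samples=0)
    with pytest.raises(ValueError):
        SamplerConfig(thinning=0)


def test_warmup_properties(branch):
    model, _ = branch
    config = SamplerConfig(n_warmup=40, n_samples=10, thinning=1)
    warmup = generate_warmup(model, config)
    assert warmup.matrix.shape == (40, len(model.reactions))
    fixed = warmup.column("EX_A")
    assert np.allclose(fixed, -10.0, atol=1e-8)  # pinned coordinate
    assert_samples_feasible(warmup, model, tol=1e-6)


def test_interval_uniformity():
    """1-dim ACHR resamples the whole chord each step, so stored samples
    are iid uniform: binomial bin-count bounds apply directly."""
    samples = _sample(interval_model(), n_warmup=20, n_samples=4000,
                      thinning=10, seed=3)
    x = samples.column("R_in")
    assert x.mean() == pytest.approx(0.5, abs=0.03)
    counts, _ = np.histogram(x, bins=np.linspace(0.0, 1.0, 11))
    # 4000 draws over 10 bins: expect 400 per bin, sigma ~= 19; allow 5 sigma
    assert counts.min() > 400 - 95 and counts.max() < 400 + 95
    assert x.min() < 0.02 and x.max() > 0.98  # endpoint coverage


def test_simplex_quantile_and_coverage(simplex):
    model, truth = simplex
    samples = _sample(model, n_warmup=100, n_samples=10000, thinning=50, seed=11)
    r1, r2 = truth["free_pair"]
    x = samples.column(r1)
    # uniform on the segment v1 + v2 = 10, v >= 0: P(v1 < 2.5) = 0.25
    assert np.mean(x < 2.5) == pytest.approx(0.25, abs=0.02)
    assert x.max() - x.min() > 0.9 * truth["simplex_total"]
    np.testing.assert_allclose(x + samples.column(r2), 10.0, atol=1e-6)


def test_bit_reproducibility(simplex):
    model, _ = simplex
    a = _sample(model, n_warmup=50, n_samples=500, thinning=20, seed=42)
    b = _sample(model, n_warmup=50, n_samples=500, thinning=20, seed=42)
    assert np.array_equal(a.matrix, b.matrix)
    c = _sample(model, n_warmup=50, n_samples=500, thinning=20, seed=43)
    assert not np.array_equal(a.matrix, c.matrix)


def test_feasibility_hard_invariant(cycle, ctx_pair):
    model, _ = cycle
    samples = _sample(model, n_warmup=60, n_samples=1500, thinning=25, seed=5)
    assert_samples_feasible(samples, model)
    ctx_model = ctx_pair[0].model
    ctx_samples = _sample(ctx_model, n_warmup=150, n_samples=1000,
                          thinning=50, seed=5)
    assert_samples_feasible(ctx_samples, ctx_model)


def test_chain_stays_mobile(simplex):
    """The chain must not freeze: stored rows are overwhelmingly distinct
    and the running mean does not drift between chain segments."""
    model, _ = simplex
    samples = _sample(model, n_warmup=80, n_samples=4000, thinning=20, seed=9)
    x = samples.column("R_AB")
    assert np.unique(np.round(x, 9)).size > 0.99 * x.size
    drift = mean_drift(samples.matrix)
    assert np.max(np.abs(drift)) < 0.5


def test_cycle_relation_holds_in_samples(cycle):
    model, truth = cycle
    samples = _sample(model, n_warmup=60, n_samples=2000, thinning=20, seed=2)
    fwd, rev = truth["cycle_pair"]
    np.testing.assert_allclose(samples.column(fwd) - samples.column(rev),
                               10.0, atol=1e-6)


def test_flux_histograms(simplex):
    model, _ = simplex
    samples = _sample(model, n_warmup=50, n_samples=2000, thinning=10, seed=1)
    hists = flux_histograms(samples, bins=20)
    assert set(hists) == set(samples.reaction_ids)
    edges, freqs = hists["R_AB"]
    assert len(edges) == 21 and len(freqs) == 20
    assert freqs.sum() == samples.n_samples
    with pytest.raises(ValueError):
        flux_histograms(samples, bins=samples.n_samples + 1)


def test_correlated_sets_vs_pairwise_oracle(chain, simplex):
    """Brute-force oracle: every pair with |r| >= threshold must land in
    the same set with the right sign, and no cross-set pair may reach
    the threshold."""
    for model, _ in (chain, simplex):
        samples = _sample(model, n_warmup=50, n_samples=3000, thinning=10, seed=8)
        threshold = 0.99
        sets = correlated_sets(samples, threshold)
        with np.errstate(invalid="ignore"):  # constant columns give NaN rows
            corr = np.corrcoef(samples.matrix.T)
        ids = samples.reaction_ids
        membership = {}
        for k, cs in enumerate(sets):
            for rid in cs.reactions:
                membership[rid] = k
        for i, j in itertools.combinations(range(len(ids)), 2):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                assert membership.get(ids[i]) == membership.get(ids[j]), (ids[i], ids[j])


def test_correlated_sets_signs(chain, simplex):
    model, _ = chain
    samples = _sample(model, n_warmup=50, n_samples=2000, thinning=10, seed=4)
    # a linear pathway: all carried flux is identical except EX_in (= -flux)
    [cs] = correlated_sets(samples, 0.999)
    assert cs.reactions == frozenset(samples.reaction_ids)
    signs = {(frozenset((a, b))): s for a, b, s, _ in cs.edges}
    assert any(s < 0 for s in
               (s for pair, s in signs.items() if "EX_in" in pair))

    model, truth = simplex
    samples = _sample(model, n_warmup=60, n_samples=2000, thinning=20, seed=4)
    r1, r2 = truth["free_pair"]
    anti = [cs for cs in correlated_sets(samples, 0.999)
            if {r1, r2} <= set(cs.reactions)]
    assert anti, "complementary simplex pair must be detected"
    assert any(s == -1 and {a, b} == {r1, r2}
               for a, b, s, _ in anti[0].edges)


def test_to_csv_with_sidecar(tmp_path, simplex):
    model, _ = simplex
    samples = _sample(model, n_warmup=20, n_samples=50, thinning=5, seed=0)
    path = tmp_path / "samples.csv"
    samples.to_csv(path)
    reloaded = np.loadtxt(path, delimiter=",", skiprows=1)
    np.testing.assert_allclose(reloaded, samples.matrix, atol=1e-12)
    meta = json.loads((tmp_path / "samples.csv.meta.json").read_text())
    assert meta["config"]["seed"] == 0 and meta["config"]["n_samples"] == 50
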