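"""Shared helpers for the test suite.

Includes the end-to-end recovery pipeline (timecourses -> rates ->
contextualization -> FVA -> differential report) and an independent FVA
oracle backed by cobrapy, used to cross-check the package's own LP path.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

import gbmflux as g
from gbmflux.rates import ConcentrationSeries, GrowthCurve

# Tolerance bands used by the recovery pipeline, chosen a priori from
# error propagation of the 5% reading noise through endpoint CORE values
# (see docs/methods.md): glucose/lactate rates carry <~8% (1 sigma)
# error, amino-acid rates up to ~16%, the Gompertz mu up to ~25%.
GROWTH_BAND = 0.35
GLC_LAC_BAND = 0.30
AA_BAND = 0.75


def quiet_contextualize(template, spec, precursors):
    """Contextualize while silencing the expected orphan-gene warning
    (the scenarios deliberately include a non-metabolic mutated gene)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return g.contextualize_cell_line(template, spec, precursors)


def recover_line(timecourses, line):
    """Gompertz fit + specific exchange rates for one cell line,
    averaging replicate wells at each time point."""
    gdf = timecourses.growth[timecourses.growth.cell_line == line]
    counts = gdf.groupby("time_h")["count"].mean()
    fit = g.fit_gompertz(GrowthCurve(times=counts.index.to_numpy(),
                                     counts=counts.to_numpy()))
    cdf = timecourses.concentrations[timecourses.concentrations.cell_line == line]
    rates = {}
    for met, grp in cdf.groupby("metabolite"):
        mean = grp.groupby("time_h")["conc_mM"].mean()
        series = ConcentrationSeries(met, mean.index.to_numpy(), mean.to_numpy())
        rates[met] = g.specific_exchange_rate(
            series, fit, timecourses.truth["volume_L"],
            timecourses.truth["dry_weight_per_cell"])
    return fit, rates


def run_recovery_pipeline(seed, noise_cv=0.05, with_sampling=False):
    """Full end-to-end pipeline on one seeded noisy scenario.

    Returns (report, scenario); the recovery statistic is the k smallest
    FVA span ratios (report.top_shifted on an FVA-only report).
    """
    spec0 = g.ScenarioSpec(seed=seed, noise_cv=noise_cv)
    scenario = g.make_paired_scenario(spec0)
    tc = g.make_timecourses(spec0)
    fvas, samples = {}, {}
    for label, base in (("a", scenario.spec_a), ("b", scenario.spec_b)):
        fit, rates = recover_line(tc, base.cell_line_name)
        exchanges = [
            g.ExchangeConstraint(
                f"{met}_e", rate,
                tolerance_band=GLC_LAC_BAND if met in ("glc", "lac") else AA_BAND)
            for met, rate in rates.items()
        ]
        spec = replace(base, exchanges=exchanges, growth_rate=fit.mu_max,
                       growth_band=GROWTH_BAND, exchange_band=None)
        result = quiet_contextualize(scenario.template, spec, scenario.precursors)
        fvas[label] = g.fva(result.model, g.FVAConfig(gamma=0.0))
        if with_sampling:
            config = g.SamplerConfig(n_warmup=200, n_samples=2000,
                                     thinning=100, seed=seed)
            warmup = g.generate_warmup(result.model, config)
            samples[label] = g.achr_sample(result.model, warmup, config)
    if with_sampling:
        report = g.build_report(fvas["a"], fvas["b"], samples["a"], samples["b"])
    else:
        report = g.build_report(fvas["a"], fvas["b"])
    return report, scenario


def cobra_fva(model, gamma, tmp_path):
    """Independent FVA oracle: serialize to COBRA JSON, re-solve with
    cobrapy (a separate parser, LP formulation and solver stack)."""
    import cobra
    from cobra.flux_analysis import flux_variability_analysis

    from gbmflux.io import save_model

    path = tmp_path / f"{model.name or 'model'}.json"
    save_model(model, path)
    cm = cobra.io.load_json_model(str(path))
    frame = flux_variability_analysis(cm, fraction_of_optimum=gamma, processes=1)
    return {rid: (float(frame.minimum[rid]), float(frame.maximum[rid]))
            for rid in frame.index}


def assert_samples_feasible(samples, model, tol=1e-6):
    """Independent re-check that every stored sample lies in the polytope."""
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    order = [samples.reaction_ids.index(rid) for rid in model.reaction_ids]
    X = samples.matrix[:, order]
    resid = np.abs(S @ X.T).max()
    assert resid <= tol, f"mass-balance residual {resid:.2e}"
    assert (X >= lb - tol).all() and (X <= ub + tol).all(), "bound violation"
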