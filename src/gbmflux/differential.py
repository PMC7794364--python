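"""Pairwise comparison of two contextualized models.

Given FVA results and flux samples for two cell-line models (e.g. a
drug-sensitive and a drug-resistant line), this module reports, per
shared reaction:

* the feasible flux-span widths and their ratio (b relative to a);
* a direction classification (forward / reverse / bidirectional /
  blocked) and a flag when it changes between models — e.g. a
  bidirectional reaction in one line forced unidirectional in the other;
* a distribution-shift statistic in [0, 1]: 1 minus the overlap
  coefficient of the two sampled flux histograms on shared bin edges
  (0 = identical distributions, 1 = disjoint supports); a two-sample
  Kolmogorov-Smirnov statistic is available as an alternative.

Pathway-level rollups aggregate the per-reaction table by subsystem.
No p-values are attached: ranking plus seed-replicate null shifts is
the intended inference surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import FVAResult
from .sampling import CorrelatedSet, FluxSampleSet

__all__ = [
    "DifferentialReport",
    "compare_spans",
    "compare_distributions",
    "pathway_rollup",
    "build_report",
    "classify_direction",
]

_DIR_TOL = 1e-9


def classify_direction(lo: float, hi: float, tol: float = _DIR_TOL) -> str:
    """Direction class of a feasible range: forward, reverse,
    bidirectional, or blocked (range pinned at zero)."""
    neg, pos = lo < -tol, hi > tol
    if neg and pos:
        return "bidirectional"
    if pos:
        return "forward"
    if neg:
        return "reverse"
    return "blocked"


def compare_spans(fva_a: FVAResult, fva_b: FVAResult) -> pd.DataFrame:
    """Per-reaction span comparison of two FVA results.

    Returns a DataFrame indexed by reaction id with min/max/span for
    each model, span_ratio = span_b / span_a (1 when both spans are
    zero, inf when only span_a is), interval overlap length, direction
    classes and a direction_flip flag.  Reactions present in only one
    result are kept (outer join) with ``in_both`` False; fully disjoint
    reaction sets are an error.
    """
    ids_a, ids_b = set(fva_a.ranges), set(fva_b.ranges)
    if not ids_a & ids_b:
        raise ValueError("FVA results share no reactions; nothing to compare")
    rows = []
    for rid in sorted(ids_a | ids_b):
        in_both = rid in ids_a and rid in ids_b
        lo_a, hi_a = fva_a.ranges.get(rid, (np.nan, np.nan))
        lo_b, hi_b = fva_b.ranges.get(rid, (np.nan, np.nan))
        span_a, span_b = hi_a - lo_a, hi_b - lo_b
        if in_both:
            if span_a > _DIR_TOL:
                ratio = span_b / span_a
            else:
                ratio = 1.0 if span_b <= _DIR_TOL else np.inf
            overlap = max(0.0, min(hi_a, hi_b) - max(lo_a, lo_b))
            dir_a, dir_b = classify_direction(lo_a, hi_a), classify_direction(lo_b, hi_b)
            flip = dir_a != dir_b
            flip_type = f"{dir_a}->{dir_b}" if flip else ""
        else:
            ratio, overlap = np.nan, np.nan
            dir_a = classify_direction(lo_a, hi_a) if rid in ids_a else ""
            dir_b = classify_direction(lo_b, hi_b) if rid in ids_b else ""
            flip, flip_type = False, ""
        rows.append(
            dict(reaction_id=rid, in_both=in_both,
                 min_a=lo_a, max_a=hi_a, span_a=span_a,
                 min_b=lo_b, max_b=hi_b, span_b=span_b,
                 span_ratio=ratio, overlap=overlap,
                 direction_a=dir_a, direction_b=dir_b,
                 direction_flip=flip, flip_type=flip_type)
        )
    return pd.DataFrame(rows).set_index("reaction_id")


def _overlap_shift(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi - lo < 1e-12:  # both essentially constant at the same value
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    px, _ = np.histogram(x, bins=edges)
    py, _ = np.histogram(y, bins=edges)
    overlap = np.minimum(px / px.sum(), py / py.sum()).sum()
    return float(1.0 - overlap)


def compare_distributions(
    samples_a: FluxSampleSet,
    samples_b: FluxSampleSet,
    bins: int = 30,
    method: str = "overlap",
) -> pd.DataFrame:
    """Per-reaction shift between two sampled flux distributions.

    ``method="overlap"`` (default): 1 - overlap coefficient of the two
    histograms on shared bin edges.  ``method="ks"``: two-sample KS
    statistic.  Both lie in [0, 1] and are symmetric in (a, b).
    Also reports each distribution's median.
    """
    shared = [rid for rid in samples_a.reaction_ids if rid in set(samples_b.reaction_ids)]
    if not shared:
        raise ValueError("sample sets share no reactions")
    if method not in ("overlap", "ks"):
        raise ValueError(f"unknown shift method {method!r}")
    rows = []
    for rid in shared:
        x, y = samples_a.column(rid), samples_b.column(rid)
        if method == "overlap":
            shift = _overlap_shift(x, y, bins)
        else:
            from scipy.stats import ks_2samp
            if x.std() < 1e-12 and y.std() < 1e-12 and abs(x[0] - y[0]) < 1e-12:
                shift = 0.0
            else:
                shift = float(ks_2samp(x, y).statistic)
        rows.append(dict(reaction_id=rid, shift=shift,
                         median_a=float(np.median(x)), median_b=float(np.median(y))))
    return pd.DataFrame(rows).set_index("reaction_id")


def pathway_rollup(
    report_table: pd.DataFrame,
    subsystem_map: dict[str, str],
    shift_threshold: float = 0.1,
) -> pd.DataFrame:
    """Aggregate the per-reaction table by metabolic subsystem.

    Reactions missing from the map fall into "unassigned".  Per
    subsystem: reaction count, median span ratio, and (when a ``shift``
    column is present) the fraction of reactions with shift above the
    threshold.
    """
    table = report_table.copy()
    table["subsystem"] = [subsystem_map.get(rid, "unassigned") for rid in table.index]
    out = []
    for sub, grp in table.groupby("subsystem"):
        row = dict(subsystem=sub, n_reactions=len(grp))
        if "span_ratio" in grp:
            finite = grp["span_ratio"].replace([np.inf, -np.inf], np.nan).dropna()
            row["median_span_ratio"] = float(finite.median()) if len(finite) else np.nan
        if "shift" in grp:
            row["fraction_shifted"] = float((grp["shift"] > shift_threshold).mean())
        out.append(row)
    return pd.DataFrame(out).set_index("subsystem").sort_index()


@dataclass
class DifferentialReport:
    """Full paired comparison between two contextualized models."""

    per_reaction: pd.DataFrame
    pathway: pd.DataFrame
    correlated_sets_a: list[CorrelatedSet] = field(default_factory=list)
    correlated_sets_b: list[CorrelatedSet] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def top_shifted(self, k: int) -> list[str]:
        """Ids of the k reactions with the largest distribution shift
        (falls back to smallest span ratio when no shift column)."""
        if "shift" in self.per_reaction:
            return list(self.per_reaction["shift"].sort_values(ascending=False).index[:k])
        return list(self.per_reaction["span_ratio"].sort_values().index[:k])

    def to_csv(self, path) -> None:
        self.per_reaction.to_csv(path)


def build_report(
    fva_a: FVAResult,
    fva_b: FVAResult,
    samples_a: FluxSampleSet | None = None,
    samples_b: FluxSampleSet | None = None,
    subsystem_map: dict[str, str] | None = None,
    r_threshold: float = 0.99,
    metadata: dict | None = None,
) -> DifferentialReport:
    """Assemble the span table, optional distribution shifts, pathway
    rollup and correlated sets into one report."""
    from .sampling import correlated_sets

    table = compare_spans(fva_a, fva_b)
    sets_a: list[CorrelatedSet] = []
    sets_b: list[CorrelatedSet] = []
    if samples_a is not None and samples_b is not None:
        shifts = compare_distributions(samples_a, samples_b)
        table = table.join(shifts, how="left")
        sets_a = correlated_sets(samples_a, r_threshold)
        sets_b = correlated_sets(samples_b, r_threshold)
    pathway = pathway_rollup(table, subsystem_map or {})
    return DifferentialReport(per_reaction=table, pathway=pathway,
                              correlated_sets_a=sets_a, correlated_sets_b=sets_b,
                              metadata=metadata or {})
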