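"""Model validation by leave-one-out prediction of nutrient uptake rates.

A contextualized model is considered predictive when, after removing the
measured constraint on one primary nutrient at a time (while keeping
growth, maintenance and every other exchange fixed), flux balance
analysis recovers the withheld uptake rate.  Accuracy per nutrient is

    100 * (1 - |predicted - measured| / |measured|)   [%]

clipped below at 0, and the headline score is the mean over all
consumed (uptake, rate < 0) exchanges.
"""

from __future__ import annotations

from dataclasses import replace as _dc_replace

import numpy as np
import pandas as pd

from .context import ContextSpec, ContextualizationError, contextualize_cell_line
from .lp import fba
from .model import MetabolicModel, SolveStatus

__all__ = ["leave_one_out_uptake_accuracy"]


def leave_one_out_uptake_accuracy(
    template: MetabolicModel,
    spec: ContextSpec,
    precursors=None,
    include_secretions: bool = False,
) -> pd.DataFrame:
    """Leave-one-out FBA prediction of each constrained exchange rate.

    For every exchange constraint of ``spec`` (uptakes only unless
    ``include_secretions``), rebuild the contextualized model without
    that constraint — the exchange keeps the template's wide bounds —
    run FBA with the biomass objective, and compare the resulting free
    exchange flux with the withheld measured rate.

    Returns a DataFrame (metabolite, measured, predicted, accuracy_pct).
    """
    rows = []
    for held_out in spec.exchanges:
        if held_out.rate >= 0 and not include_secretions:
            continue
        if held_out.rate == 0:
            continue
        reduced = _dc_replace(
            spec,
            exchanges=[e for e in spec.exchanges if e.metabolite != held_out.metabolite],
            mutations=list(spec.mutations),
        )
        try:
            result = contextualize_cell_line(template, reduced, precursors)
        except ContextualizationError as exc:
            rows.append(dict(metabolite=held_out.metabolite, measured=held_out.rate,
                             predicted=np.nan, accuracy_pct=0.0, note=str(exc)))
            continue
        sol = fba(result.model)
        if sol.status is not SolveStatus.OPTIMAL:
            rows.append(dict(metabolite=held_out.metabolite, measured=held_out.rate,
                             predicted=np.nan, accuracy_pct=0.0,
                             note=f"FBA {sol.status.value}"))
            continue
        exch_id = next(
            r.id for r in result.model.reactions
            if r.is_exchange and next(iter(r.stoichiometry)) == held_out.metabolite
        )
        predicted = sol[exch_id]
        accuracy = 100.0 * max(0.0, 1.0 - abs(predicted - held_out.rate) / abs(held_out.rate))
        rows.append(dict(metabolite=held_out.metabolite, measured=held_out.rate,
                         predicted=predicted, accuracy_pct=accuracy, note=""))
    return pd.DataFrame(rows)
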