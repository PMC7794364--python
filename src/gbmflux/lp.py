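"""Linear-programming analyses: FBA, FVA and extreme exchange fluxes.

Flux balance analysis solves

    Z0 = max c.v    s.t.  S.v = 0,  lb <= v <= ub

and flux variability analysis then bounds each reaction individually,

    max/min v_i     s.t.  S.v = 0,  lb <= v <= ub,  c.v >= gamma * Z0

where ``gamma`` in [0, 1] relaxes the optimality requirement (gamma = 1
restricts to the optimal face, gamma = 0 drops the objective
constraint).  All LPs are solved with the HiGHS backend through
scipy.optimize.linprog; only range endpoints, never the particular
optimal flux vector (FBA optima are generically non-unique), are part of
the numerical contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import FluxVector, MetabolicModel, SolveStatus

__all__ = ["FVAConfig", "FVAResult", "fba", "fva", "maximal_exchange", "InfeasibleModelError"]


class InfeasibleModelError(RuntimeError):
    """The model's constraint set admits no feasible flux vector."""


@dataclass
class FVAConfig:
    """Settings for flux variability analysis.

    gamma: fraction of the FBA optimum the objective must retain
        (0 <= gamma <= 1); ignored when the model has no objective.
    reaction_subset: ids to analyze (None = all reactions).
    tolerance: numerical tolerance for feasibility and range checks.
    """

    gamma: float = 1.0
    reaction_subset: list[str] | None = None
    tolerance: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")


@dataclass
class FVAResult:
    """Per-reaction feasible flux intervals at a given sub-optimality level."""

    ranges: dict[str, tuple[float, float]]
    gamma: float
    objective_value_used: float
    failed: dict[str, str] = field(default_factory=dict)

    def width(self, reaction_id: str) -> float:
        lo, hi = self.ranges[reaction_id]
        return hi - lo


_STATUS_MAP = {0: SolveStatus.OPTIMAL, 2: SolveStatus.INFEASIBLE, 3: SolveStatus.UNBOUNDED}


def _solve(c_min: np.ndarray, S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
           A_ub: np.ndarray | None = None, b_ub: np.ndarray | None = None):
    """Minimize c_min.v over the flux polytope; thin wrapper over HiGHS."""
    return linprog(
        c_min,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=list(zip(lb, ub)),
        method="highs",
    )


def fba(model: MetabolicModel) -> FluxVector:
    """Maximize the model objective; return fluxes, optimum and status.

    Infeasible or unbounded problems are reported through the returned
    status, never silently coerced to zero.
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    res = _solve(-c, S, lb, ub)
    status = _STATUS_MAP.get(res.status, SolveStatus.INFEASIBLE)
    if status is not SolveStatus.OPTIMAL:
        return FluxVector(values={}, objective_value=float("nan"), status=status)
    values = dict(zip(model.reaction_ids, (float(x) for x in res.x)))
    return FluxVector(values=values, objective_value=float(c @ res.x), status=status)


def fva(model: MetabolicModel, config: FVAConfig | None = None) -> FVAResult:
    """Minimum and maximum feasible flux per reaction (double optimization).

    With gamma > 0 and a non-empty objective, ranges are computed on the
    slice where the objective retains at least ``gamma * Z0``.  Ranges at
    a smaller gamma always contain ranges at a larger one.  A per-reaction
    LP failure is recorded in ``result.failed`` rather than dropped.
    """
    config = config or FVAConfig()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_array()
    n = len(model.reactions)
    rxn_ids = model.reaction_ids

    A_ub = b_ub = None
    z0 = 0.0
    if config.gamma > 0.0 and np.any(c != 0):
        opt = fba(model)
        if opt.status is not SolveStatus.OPTIMAL:
            raise InfeasibleModelError(
                f"FBA prerequisite for FVA (gamma={config.gamma}) returned {opt.status.value}"
            )
        z0 = opt.objective_value
        A_ub = -c.reshape(1, -1)
        b_ub = np.array([-config.gamma * z0])

    subset = config.reaction_subset
    indices = range(n) if subset is None else [rxn_ids.index(r) for r in subset]

    ranges: dict[str, tuple[float, float]] = {}
    failed: dict[str, str] = {}
    e_i = np.zeros(n)
    for j in indices:
        e_i[:] = 0.0
        e_i[j] = 1.0
        lo_res = _solve(e_i, S, lb, ub, A_ub, b_ub)
        hi_res = _solve(-e_i, S, lb, ub, A_ub, b_ub)
        if lo_res.status != 0 or hi_res.status != 0:
            failed[rxn_ids[j]] = (
                f"min status {lo_res.status}, max status {hi_res.status}"
            )
            if lo_res.status == 2 and hi_res.status == 2:
                raise InfeasibleModelError(f"FVA subproblem infeasible for {rxn_ids[j]!r}")
            continue
        lo, hi = float(lo_res.x[j]), float(hi_res.x[j])
        if lo > hi:  # solver jitter on a fixed coordinate
            lo = hi = 0.5 * (lo + hi)
        ranges[rxn_ids[j]] = (lo, hi)
    return FVAResult(ranges=ranges, gamma=config.gamma, objective_value_used=z0,
                     failed=failed)


def maximal_exchange(model: MetabolicModel, exchange_id: str,
                     direction: str = "uptake") -> float:
    """Extreme feasible flux through one exchange, as a magnitude.

    ``direction="uptake"`` finds the most negative feasible flux of the
    exchange (net import) and reports |value|; ``"secretion"`` the most
    positive.  Used e.g. to estimate the maximal oxygen uptake rate a
    contextualized model can support.
    """
    rxn = model.get_reaction(exchange_id)
    if not rxn.is_exchange:
        raise ValueError(f"{exchange_id!r} is not an exchange reaction")
    if direction not in ("uptake", "secretion"):
        raise ValueError(f"direction must be 'uptake' or 'secretion', got {direction!r}")
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    j = model.reaction_ids.index(exchange_id)
    e_j = np.zeros(len(model.reactions))
    e_j[j] = 1.0 if direction == "uptake" else -1.0
    res = _solve(e_j, S, lb, ub)
    if res.status != 0:
        raise InfeasibleModelError(
            f"maximal_exchange({exchange_id!r}): solver status {res.status}"
        )
    value = float(res.x[j])
    return abs(value) if direction == "uptake" and value < 0 else (
        max(value, 0.0) if direction == "secretion" else 0.0
    )
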