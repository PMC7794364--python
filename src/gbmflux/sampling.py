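"""Uniform random sampling of the flux polytope.

The steady-state flux space {v : S v = 0, lb <= v <= ub} is a bounded
convex polytope.  Its flux distributions are characterized here with an
artificial-centering hit-and-run (ACHR) walk: starting from a set of
warmup points (flux-variability extreme solutions plus random-objective
optima), each step picks a direction through the running center of all
points seen so far, intersects that chord with the bounds, and jumps to

    alpha = alpha_min + R * (alpha_max - alpha_min),   R ~ U(0, 1)

i.e. a uniform point on the feasible chord segment.  Because every
warmup point and every iterate satisfies S v = 0, chord directions
(differences of feasible points) lie in the null space of S, so the
equality constraints are maintained by construction rather than by
rejection; only floating-point drift is monitored and, if it exceeds the
tolerance, corrected by least-squares re-projection (counted in the
diagnostics).

The chain's inner loop is JIT-compiled (numba), which makes the
published protocol — 1000 warmup points, 50,000 stored samples with 1000
iterations between stored points — a desk-scale computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .lp import InfeasibleModelError, _solve
from .model import MetabolicModel

__all__ = [
    "SamplerConfig",
    "FluxSampleSet",
    "generate_warmup",
    "achr_sample",
    "flux_histograms",
    "correlated_sets",
    "CorrelatedSet",
    "mean_drift",
]


@dataclass
class SamplerConfig:
    """ACHR protocol settings.

    Defaults follow the published protocol: 1000 warmup points, 50,000
    stored samples, 1000 chain iterations between stored points.
    """

    n_warmup: int = 1000
    n_samples: int = 50_000
    thinning: int = 1000
    seed: int = 0
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_warmup < 2:
            raise ValueError("n_warmup must be >= 2")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class FluxSampleSet:
    """A matrix of flux vectors sampled from one model's polytope.

    Every stored row satisfies S v = 0 and the bounds within the
    configured tolerance (a hard invariant, enforced at creation).
    """

    matrix: np.ndarray  # (n_samples, n_reactions)
    reaction_ids: list[str]
    config: SamplerConfig
    model_name: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, reaction_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(reaction_id)]

    def to_csv(self, path: str | Path) -> None:
        """Write samples as CSV (header = reaction ids) with a JSON
        sidecar carrying config, seed and model name."""
        path = Path(path)
        header = ",".join(self.reaction_ids)
        np.savetxt(path, self.matrix, delimiter=",", header=header, comments="")
        sidecar = {
            "model_name": self.model_name,
            "config": asdict(self.config),
            "diagnostics": self.diagnostics,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def _check_feasible(matrix: np.ndarray, S: np.ndarray, lb: np.ndarray,
                    ub: np.ndarray, tol: float, what: str) -> None:
    resid = np.abs(S @ matrix.T).max() if matrix.size else 0.0
    if resid > tol:
        raise InfeasibleModelError(f"{what}: mass-balance residual {resid:.2e} > {tol:.2e}")
    if matrix.size and ((matrix < lb - tol).any() or (matrix > ub + tol).any()):
        raise InfeasibleModelError(f"{what}: bound violation beyond tolerance")


def generate_warmup(model: MetabolicModel, config: SamplerConfig | None = None) -> FluxSampleSet:
    """Build warmup points: FVA-extreme ("orthogonal") solutions first,
    random-objective LP optima for the remainder.

    The orthogonal points are the argmax/argmin flux vectors of each
    reaction (objectives +/- e_i), up to 2 * n_reactions of them; the
    rest are optima of Gaussian random objectives.  Every returned row is
    feasible, checked against S v = 0 and the bounds.
    """
    config = config or SamplerConfig()
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    rng = np.random.default_rng(config.seed)

    points: list[np.ndarray] = []
    for j in range(n):
        if len(points) >= config.n_warmup:
            break
        e = np.zeros(n)
        for sign in (1.0, -1.0):
            if len(points) >= config.n_warmup:
                break
            e[j] = sign
            res = _solve(e, S, lb, ub)
            if res.status == 2:
                raise InfeasibleModelError("model infeasible: cannot generate warmup points")
            if res.status == 0:
                points.append(res.x.astype(float))
    tries = 0
    while len(points) < config.n_warmup:
        c = rng.standard_normal(n)
        res = _solve(-c, S, lb, ub)
        if res.status == 0:
            points.append(res.x.astype(float))
        else:
            tries += 1
            if tries > 100:
                raise InfeasibleModelError(
                    "could not find enough bounded random-objective warmup solutions"
                )
    matrix = np.array(points[: config.n_warmup])
    _check_feasible(matrix, S, lb, ub, config.tolerance, "warmup")
    return FluxSampleSet(matrix=matrix, reaction_ids=model.reaction_ids,
                         config=config, model_name=model.name)


@njit(cache=True)
def _project_affine(x, anchor, basis, scratch):
    """In place: x <- anchor + basis basis^T (x - anchor)."""
    n, d = basis.shape
    for j in range(d):
        acc = 0.0
        for k in range(n):
            acc += basis[k, j] * (x[k] - anchor[k])
        scratch[j] = acc
    for k in range(n):
        acc = anchor[k]
        for j in range(d):
            acc += basis[k, j] * scratch[j]
        x[k] = acc


@njit(cache=True)
def _achr_kernel(warmup, lb, ub, x, center, anchor, basis,
                 n_center, n_samples, thinning, seed):
    """Hit-and-run chain; directions through the running center, uniform
    step on the feasible chord.  Stores one point every `thinning`
    accepted steps; re-projects onto the affine subspace through
    `anchor` spanned by `basis` periodically to cancel float drift."""
    np.random.seed(seed)
    n_pts, n = warmup.shape
    d = basis.shape[1]
    scratch = np.empty(d)
    out = np.empty((n_samples, n))
    stored = 0
    accepted = 0
    rejected_run = 0
    count = float(n_center)
    while stored < n_samples:
        i = np.random.randint(n_pts)
        # chord direction: warmup point through current center (in null(S))
        tmin = -1.0e30
        tmax = 1.0e30
        degenerate = True
        for k in range(n):
            dk = warmup[i, k] - center[k]
            if dk > 1e-11:
                hi = (ub[k] - x[k]) / dk
                lo = (lb[k] - x[k]) / dk
                degenerate = False
            elif dk < -1e-11:
                hi = (lb[k] - x[k]) / dk
                lo = (ub[k] - x[k]) / dk
                degenerate = False
            else:
                continue
            if hi < tmax:
                tmax = hi
            if lo > tmin:
                tmin = lo
        if degenerate or tmax - tmin < 1e-12:
            # degenerate chord; on a (near-)point polytope every proposal
            # degenerates, so eventually store the fixed point itself
            rejected_run += 1
            if rejected_run >= 1000:
                rejected_run = 0
                for k in range(n):
                    out[stored, k] = x[k]
                stored += 1
            continue
        rejected_run = 0
        t = tmin + np.random.random() * (tmax - tmin)
        for k in range(n):
            x[k] = x[k] + t * (warmup[i, k] - center[k])
        count += 1.0
        for k in range(n):
            center[k] += (x[k] - center[k]) / count
        accepted += 1
        if accepted % 8192 == 0 and d > 0:
            _project_affine(x, anchor, basis, scratch)
            _project_affine(center, anchor, basis, scratch)
        if accepted % thinning == 0:
            for k in range(n):
                out[stored, k] = x[k]
            stored += 1
    return out


def achr_sample(model: MetabolicModel, warmup: FluxSampleSet,
                config: SamplerConfig | None = None) -> FluxSampleSet:
    """Run the ACHR chain and return ``n_samples`` stored flux vectors.

    The chain starts at a randomly chosen warmup point, with the
    artificial center initialized to the warmup mean and updated after
    every accepted step.  The run is bit-reproducible for a fixed seed
    and config.  Stored points whose mass-balance residual exceeds the
    tolerance (floating-point drift over very long chains) are
    re-projected onto the null space and counted in
    ``diagnostics["n_reprojected"]``.
    """
    config = config or warmup.config
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    if warmup.reaction_ids != model.reaction_ids:
        raise ValueError("warmup set and model disagree on reaction order")
    _check_feasible(warmup.matrix, S, lb, ub, config.tolerance, "warmup (pre-chain)")

    # LP-derived warmup points satisfy S v = 0 only to solver tolerance;
    # snapping them all onto one affine subspace makes every chord
    # direction lie exactly in that subspace, so the chain cannot leak
    # out faster than float rounding (which the kernel periodically
    # cancels).  The subspace is the polytope's affine hull: null(S)
    # intersected with {d_k = 0 for bound-fixed coordinates} — without
    # the intersection, rounding drift in a bound-pinned coordinate that
    # is free in null(S) eventually empties every chord.
    from scipy.linalg import null_space

    fixed = (ub - lb) <= 1e-9
    if fixed.any():
        S_aug = np.vstack([S, np.eye(len(lb))[fixed]])
    else:
        S_aug = S
    basis = null_space(S_aug)
    anchor = warmup.matrix.mean(axis=0)
    anchor[fixed] = 0.5 * (lb + ub)[fixed]
    if basis.shape[1] > 0:
        w_proj = anchor + (warmup.matrix - anchor) @ basis @ basis.T
    else:  # fully determined polytope: a single point
        w_proj = np.tile(anchor, (warmup.matrix.shape[0], 1))
    w_proj[:, fixed] = anchor[fixed]  # exact, so chord directions vanish there
    basis = np.ascontiguousarray(basis)

    rng = np.random.default_rng(config.seed)
    x0 = w_proj[rng.integers(w_proj.shape[0])].copy()
    center0 = w_proj.mean(axis=0)
    kernel_seed = int(config.seed) % (2**31 - 1)

    matrix = _achr_kernel(
        w_proj, lb, ub, x0, center0, anchor, basis,
        w_proj.shape[0], config.n_samples, config.thinning, kernel_seed,
    )

    # correct and count any numerical escape from the affine subspace
    resid = S @ matrix.T
    bad = np.abs(resid).max(axis=0) > config.tolerance
    n_reproj = int(bad.sum())
    if n_reproj:
        correction, *_ = np.linalg.lstsq(S, resid[:, bad], rcond=None)
        matrix[bad] -= correction.T
    np.clip(matrix, lb, ub, out=matrix)
    _check_feasible(matrix, S, lb, ub, config.tolerance, "stored samples")

    diags = {
        "n_reprojected": n_reproj,
        "mean_drift": {
            rid: float(d) for rid, d in zip(model.reaction_ids, mean_drift(matrix))
        },
    }
    return FluxSampleSet(matrix=matrix, reaction_ids=model.reaction_ids,
                         config=config, model_name=model.name, diagnostics=diags)


def mean_drift(matrix: np.ndarray, first: float = 0.1, last: float = 0.5) -> np.ndarray:
    """Geweke-style convergence check: per-reaction difference between the
    mean over the first `first` fraction and the last `last` fraction of
    the chain, in units of the pooled standard deviation (0 where the
    coordinate is constant)."""
    n = matrix.shape[0]
    a = matrix[: max(1, int(first * n))]
    b = matrix[int((1 - last) * n):]
    sd = matrix.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, np.abs(a.mean(axis=0) - b.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def flux_histograms(samples: FluxSampleSet, bins: int = 30) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-reaction histogram of sampled flux: (bin_edges, frequencies).

    Frequencies are raw counts summing to n_samples; edges span the
    sampled min/max of each reaction.
    """
    if samples.n_samples < bins:
        raise ValueError(f"need at least {bins} samples for {bins} bins, "
                         f"got {samples.n_samples}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for j, rid in enumerate(samples.reaction_ids):
        col = samples.matrix[:, j]
        freqs, edges = np.histogram(col, bins=bins)
        out[rid] = (edges, freqs)
    return out


@dataclass
class CorrelatedSet:
    """A connected group of reactions whose sampled fluxes co-vary."""

    reactions: frozenset[str]
    edges: list[tuple[str, str, int, float]]  # (a, b, sign, pearson r)


def correlated_sets(samples: FluxSampleSet, r_threshold: float = 0.99) -> list[CorrelatedSet]:
    """Connected components of the |Pearson r| >= threshold graph.

    Correlation is computed over the stored samples; constant-flux
    reactions (zero variance, correlation undefined) are excluded.  Each
    edge carries the sign of its correlation; only components with at
    least two reactions are returned, ordered by size then lexicographic
    smallest member.
    """
    import networkx as nx

    if samples.n_samples < 100:
        raise ValueError("need >= 100 samples for stable correlation estimates")
    if not 0.0 < r_threshold <= 1.0:
        raise ValueError("r_threshold must be in (0, 1]")
    sd = samples.matrix.std(axis=0)
    varying = np.where(sd > 1e-9)[0]
    if varying.size < 2:
        return []
    sub = samples.matrix[:, varying]
    r = np.corrcoef(sub, rowvar=False)
    ids = [samples.reaction_ids[j] for j in varying]
    g = nx.Graph()
    edges_by_pair: dict[tuple[str, str], tuple[int, float]] = {}
    m = len(ids)
    for a in range(m):
        for b in range(a + 1, m):
            if abs(r[a, b]) >= r_threshold - 1e-12:
                g.add_edge(ids[a], ids[b])
                edges_by_pair[(ids[a], ids[b])] = (1 if r[a, b] > 0 else -1, float(r[a, b]))
    sets = []
    for comp in nx.connected_components(g):
        comp_edges = [
            (a, b, s, rv) for (a, b), (s, rv) in edges_by_pair.items()
            if a in comp and b in comp
        ]
        sets.append(CorrelatedSet(reactions=frozenset(comp), edges=sorted(comp_edges)))
    sets.sort(key=lambda cs: (-len(cs.reactions), min(cs.reactions)))
    return sets
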