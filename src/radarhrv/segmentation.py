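"""Joint template/segmentation optimization of the acceleration signal.

Successive heartbeats share one morphology up to stretch/compression, so the
record can be segmented by minimizing, over both the cut-off set S and a
single template mu,

    Var(S, mu) = sum_i || a[s_{i-1}+1 : s_i] - warp(mu, s_i - s_{i-1}) ||^2

where warp resamples the template to a segment's length by cubic splines.
The two unknowns are updated alternately: the template as the
length-weighted average of segments warped to a common length, the
segmentation by dynamic programming restricted to the +-B-sample
neighborhood of the previous cut-offs.  Iteration stops when the fraction
of cut-offs that moved by at most alpha1 (ms) reaches alpha2.

The DP restricted to the neighborhood grid is exactly optimal; an
exhaustive enumerator over the full candidate product is provided as an
independent check for small instances.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .config import OptimizerParams
from .enhance import AccelSignal, Segmentation

__all__ = [
    "Template",
    "DPResult",
    "JointOptimizationResult",
    "warp",
    "segment_cost",
    "update_template",
    "dp_update_segmentation",
    "exhaustive_oracle",
    "has_converged",
    "run_joint_optimization",
]

MIN_SEGMENT = 4  # cubic warping needs >= 4 support points


@dataclass
class Template:
    """Canonical single-heartbeat acceleration shape mu of length m."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < MIN_SEGMENT:
            raise ValueError("template needs at least 4 support points")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite template")

    @property
    def length_m(self) -> int:
        return len(self.values)


@dataclass
class DPResult:
    segmentation: Segmentation
    cost: float


@dataclass
class JointOptimizationResult:
    segmentation: Segmentation
    template: Template
    trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def warp(x, p: int) -> np.ndarray:
    """Cubic-spline resampling of ``x`` onto ``p`` uniform abscissae spanning
    the same support; warp(x, len(x)) == x exactly."""
    x = np.asarray(x, dtype=float)
    if len(x) < MIN_SEGMENT:
        raise ValueError("input needs at least 4 points")
    if p < MIN_SEGMENT:
        raise ValueError("target length must be at least 4")
    if p == len(x):
        return x.copy()
    u_src = np.linspace(0.0, 1.0, len(x))
    u_dst = np.linspace(0.0, 1.0, p)
    return CubicSpline(u_src, x)(u_dst)


def segment_cost(a_segment, mu: Template) -> float:
    """Squared Euclidean distance between a segment and the template warped
    to the segment's length (one term of Var(S, mu))."""
    seg = np.asarray(a_segment, dtype=float)
    if len(seg) < MIN_SEGMENT:
        raise ValueError("degenerate segment (shorter than 4 samples)")
    d = seg - warp(mu.values, len(seg))
    return float(d @ d)


def _segments(a: np.ndarray, cutoffs: np.ndarray):
    """Consecutive segments a[s_{i-1}+1 : s_i] (inclusive of s_i)."""
    for lo, hi in zip(cutoffs[:-1], cutoffs[1:]):
        yield a[lo + 1 : hi + 1]


def update_template(a: AccelSignal, s: Segmentation, m: int) -> Template:
    """Length-weighted average of segments warped to length ``m``:
    mu = (1/n) * sum_i (s_i - s_{i-1}) * warp(segment_i, m) with n the total
    covered length, so the weights sum to one."""
    cut = s.cutoffs
    if len(cut) < 2:
        raise ValueError("need at least 2 cut-off points")
    gaps = np.diff(cut)
    if np.any(gaps < MIN_SEGMENT):
        raise ValueError("segment shorter than 4 samples")
    acc = np.zeros(m)
    for seg, g in zip(_segments(a.values, cut), gaps):
        acc += g * warp(seg, m)
    return Template(values=acc / gaps.sum())


def total_cost(a: AccelSignal, s: Segmentation, mu: Template) -> float:
    """Var(S, mu): the joint objective at the given segmentation/template."""
    return sum(segment_cost(seg, mu) for seg in _segments(a.values, s.cutoffs))


def _candidates(s_prev: np.ndarray, b: int, n: int) -> list[np.ndarray]:
    out = []
    for pos in s_prev:
        lo, hi = max(0, pos - b), min(n - 1, pos + b)
        out.append(np.arange(lo, hi + 1))
    return out


class _WarpCache:
    """Template warped to each needed segment length, computed once."""

    def __init__(self, mu: Template):
        self.mu = mu
        self._cache: dict[int, np.ndarray] = {}

    def __call__(self, p: int) -> np.ndarray:
        w = self._cache.get(p)
        if w is None:
            w = warp(self.mu.values, p)
            self._cache[p] = w
        return w


def _pair_cost(a: np.ndarray, lo: int, hi: int, wc: _WarpCache) -> float:
    g = hi - lo
    if g < MIN_SEGMENT:
        return np.inf
    d = a[lo + 1 : hi + 1] - wc(g)
    return float(d @ d)


def dp_update_segmentation(
    a: AccelSignal,
    mu: Template,
    s_prev: Segmentation,
    params: OptimizerParams,
) -> DPResult:
    """One segmentation update: exact minimization of Var(S, mu) over the
    grid of +-B-sample neighborhoods around the previous cut-offs.

    Requires non-overlapping neighborhoods (2B < min gap).  Ties are broken
    toward the lexicographically smallest cut-off tuple, so results are
    deterministic and comparable with :func:`exhaustive_oracle`.  The
    previous segmentation is inside the grid, hence the returned cost never
    exceeds Var(S_prev, mu).
    """
    cut = s_prev.cutoffs
    if len(cut) < 2:
        raise ValueError("need at least 2 cut-off points")
    b = params.b_samples(a.fs)
    if len(cut) >= 2 and 2 * b >= int(np.min(np.diff(cut))):
        raise ValueError(
            "neighborhoods of consecutive cut-offs overlap; reduce neighborhood_b_ms"
        )
    x = a.values
    n = len(x)
    cand = _candidates(cut, b, n)
    wc = _WarpCache(mu)
    k = len(cand)

    # suffix DP: g[i][c] = minimal cost of segments i..end with cut-off i at cand[i][c]
    g = [np.zeros(len(c)) for c in cand]
    for i in range(k - 2, -1, -1):
        gi = np.empty(len(cand[i]))
        for ci, pos in enumerate(cand[i]):
            best = np.inf
            for cj, nxt in enumerate(cand[i + 1]):
                v = _pair_cost(x, pos, nxt, wc) + g[i + 1][cj]
                if v < best:
                    best = v
            gi[ci] = best
        g[i] = gi

    # forward reconstruction, first (smallest-position) minimizer at each step
    total = float(np.min(g[0]))
    if not np.isfinite(total):
        raise ValueError("no feasible segmentation inside the neighborhood grid")
    path = [int(cand[0][int(np.argmin(g[0]))])]
    target = total
    for i in range(1, k):
        for cj, nxt in enumerate(cand[i]):
            v = _pair_cost(x, path[-1], nxt, wc) + g[i][cj]
            if v == target:
                path.append(int(nxt))
                target = g[i][cj]
                break
        else:  # numerical guard: fall back to the closest achievable value
            vals = [
                _pair_cost(x, path[-1], nxt, wc) + g[i][cj]
                for cj, nxt in enumerate(cand[i])
            ]
            cj = int(np.argmin(vals))
            path.append(int(cand[i][cj]))
            target = g[i][cj]
    # canonical left-to-right sum over the chosen path, so the cost is
    # bitwise comparable with the exhaustive enumerator's
    cost = 0.0
    for lo, hi in zip(path[:-1], path[1:]):
        cost += _pair_cost(x, lo, hi, wc)
    return DPResult(segmentation=Segmentation(np.asarray(path), a.fs), cost=cost)


def exhaustive_oracle(
    a: AccelSignal,
    mu: Template,
    s_prev: Segmentation,
    params: OptimizerParams,
    max_combinations: int = 10**6,
) -> DPResult:
    """Brute force over the full candidate product; ties resolved to the
    lexicographically smallest tuple.  Intended as an independent check of
    the DP on small instances."""
    cut = s_prev.cutoffs
    b = params.b_samples(a.fs)
    cand = _candidates(cut, b, len(a.values))
    n_comb = int(np.prod([len(c) for c in cand]))
    if n_comb > max_combinations:
        raise ValueError(f"search space {n_comb} exceeds {max_combinations}")
    wc = _WarpCache(mu)
    x = a.values
    best_cost = np.inf
    best_tuple = None
    for combo in itertools.product(*cand):
        if any(hi - lo < MIN_SEGMENT for lo, hi in zip(combo[:-1], combo[1:])):
            continue
        c = 0.0
        for lo, hi in zip(combo[:-1], combo[1:]):
            c += _pair_cost(x, lo, hi, wc)
            if c >= best_cost:
                break
        if c < best_cost:
            best_cost = c
            best_tuple = combo
    if best_tuple is None:
        raise ValueError("no feasible segmentation inside the neighborhood grid")
    return DPResult(
        segmentation=Segmentation(np.asarray(best_tuple), a.fs), cost=float(best_cost)
    )


def has_converged(
    s_prev: Segmentation, s_new: Segmentation, params: OptimizerParams
) -> tuple[bool, float]:
    """Stability test: cut-off j is stable iff it moved by at most alpha1 ms;
    converged (inclusively) once the stable fraction reaches alpha2."""
    if len(s_prev) != len(s_new):
        raise RuntimeError("segmentation cardinality changed between iterations")
    dt_ms = np.abs(s_new.cutoffs - s_prev.cutoffs) * 1e3 / s_new.fs
    stable = dt_ms <= params.alpha1_ms + 1e-9
    frac = float(np.mean(stable))
    return frac >= params.alpha2 - 1e-12, frac


def run_joint_optimization(
    a: AccelSignal,
    s0: Segmentation,
    params: OptimizerParams | None = None,
) -> JointOptimizationResult:
    """Alternate template and segmentation updates until the stability test
    passes or ``max_iterations`` is hit.

    The acceleration is z-normalized first by default (a pure rescaling of
    the objective; improves conditioning).  The per-iteration trace records
    Var(S^l, mu^l) before and Var(S^{l+1}, mu^l) after each DP step; the DP
    step never increases the objective.  Non-convergence returns the last
    iterate with ``converged=False`` and a warning.
    """
    if params is None:
        params = OptimizerParams()
    if len(s0) < 3:
        raise ValueError("initial segmentation needs at least 3 cut-off points")
    x = a.values
    if params.znormalize:
        sd = float(np.std(x))
        x = (x - np.mean(x)) / (sd if sd > 0 else 1.0)
    work = AccelSignal(values=x, fs=a.fs)

    m = params.template_length or int(np.median(np.diff(s0.cutoffs)))
    m = max(m, MIN_SEGMENT)
    s = s0
    mu = update_template(work, s, m)
    trace: list[dict] = []
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        obj_before = total_cost(work, s, mu)
        res = dp_update_segmentation(work, mu, s, params)
        conv, frac = has_converged(s, res.segmentation, params)
        trace.append(
            {
                "iteration": it,
                "objective_before": obj_before,
                "objective_after": res.cost,
                "stable_fraction": frac,
            }
        )
        s = res.segmentation
        mu = update_template(work, s, m)
        if conv:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"joint optimization did not converge in {params.max_iterations} iterations; "
            "returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return JointOptimizationResult(
        segmentation=s, template=mu, trace=trace, converged=converged, iterations=it
    )
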