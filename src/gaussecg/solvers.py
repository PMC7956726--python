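"""Step-2 global refinement of the two-Gaussian component fit.

Two hybrid strategies refine the matched-filter approximation by minimizing
the RMSE between the model and the segment:

* **ApproxiMul** (multi-start): a bounded local least-squares solver is
  launched from the approximation plus uniformly drawn start points within
  the bound box; the best local optimum wins.
* **ApproxiGlo** (scatter search): a diverse Latin-hypercube candidate pool
  is scored by RMSE before any refinement, then refined in score order with
  basin-distance deduplication, which spends local-solver calls only on
  candidates that look like new basins.

Both are deterministic given a seed, and both include the approximation
itself in the start set, so the refined RMSE can never exceed the
approximation RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .approx import Bounds, approximate
from .metrics import compare
from .model import (COMPONENT_LABELS, BeatModel, ComponentModel, Signal,
                    evaluate_component)

__all__ = [
    "SolverConfig",
    "FitResult",
    "BeatFitResult",
    "local_refine",
    "solve_multistart",
    "solve_scattersearch",
    "solve",
    "fit_beat",
]

_PARAM_NAMES = ("A1", "t1", "sigma1", "A2", "t2", "sigma2", "c")


@dataclass(frozen=True)
class SolverConfig:
    """Settings shared by both hybrid solvers.

    ``epsilon`` is a reporting threshold only: results at or below it are
    flagged ``converged_to_epsilon`` but the solvers never stop early on it.
    """

    method: str = "approxi_mul"  # approxi_mul | approxi_glo | local_only
    n_starts: int = 50
    seed: int = 0
    epsilon: float = 0.0
    max_iter: int = 200
    amp_mode: str = "signal"

    def __post_init__(self) -> None:
        if self.method not in ("approxi_mul", "approxi_glo", "local_only"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """One refined component fit with its objective value and provenance."""

    model: ComponentModel
    rmse: float
    n_starts_used: int
    start_points: tuple[tuple[float, ...], ...]
    converged: bool
    method: str
    converged_to_epsilon: bool = False


@dataclass(frozen=True)
class BeatFitResult:
    beat: BeatModel
    components: dict[str, FitResult]
    segment_rmse: dict[str, float]
    whole_beat: "object"  # MetricsReport of reconstruction vs input
    failed: tuple[str, ...] = ()


def _rmse(params: np.ndarray, template: ComponentModel,
          t: np.ndarray, y: np.ndarray) -> float:
    pred = evaluate_component(template.with_params(params), t)
    return float(np.sqrt(np.mean((pred - y) ** 2)))


def _clip_to_bounds(p: np.ndarray, bounds: Bounds) -> np.ndarray:
    eps = 1e-12 * np.maximum(1.0, np.abs(bounds.upper - bounds.lower))
    return np.clip(p, bounds.lower + 0 * eps, bounds.upper)


def local_refine(segment: Signal, init: ComponentModel, bounds: Bounds,
                 config: SolverConfig | None = None) -> FitResult:
    """Bounded trust-region least squares from a single start point.

    Minimizes the residual vector of the two-Gaussian model against the
    segment (the same minimizer as the RMSE, without the outer square
    root).  The returned RMSE never exceeds the start's RMSE.
    """
    config = config or SolverConfig(method="local_only")
    y = segment.samples
    t = np.arange(y.size) / segment.fs
    x0 = _clip_to_bounds(init.params, bounds)

    def residuals(p):
        return evaluate_component(init.with_params(p), t) - y

    sol = least_squares(residuals, x0, bounds=(bounds.lower, bounds.upper),
                        method="trf", max_nfev=config.max_iter * 10)
    x = np.clip(sol.x, bounds.lower, bounds.upper)
    rmse = _rmse(x, init, t, y)
    rmse0 = _rmse(x0, init, t, y)
    if rmse0 < rmse:  # trf is monotone, but guard the contract anyway
        x, rmse = x0, rmse0
    model = init.with_params(x).canonical()
    rmse = _rmse(model.params, init, t, y)
    return FitResult(model=model, rmse=rmse, n_starts_used=1,
                     start_points=(tuple(x0),), converged=bool(sol.success),
                     method="local_only",
                     converged_to_epsilon=rmse <= config.epsilon)


def solve_multistart(segment: Signal, init: ComponentModel, bounds: Bounds,
                     config: SolverConfig) -> FitResult:
    """ApproxiMul: refine from the approximation plus uniform random starts."""
    rng = np.random.default_rng(config.seed)
    starts = [_clip_to_bounds(init.params, bounds)]
    span = bounds.upper - bounds.lower
    for _ in range(config.n_starts - 1):
        starts.append(bounds.lower + rng.random(7) * span)
    best: FitResult | None = None
    for x0 in starts:
        res = local_refine(segment, init.with_params(x0), bounds, config)
        if best is None or res.rmse < best.rmse:
            best = res
    assert best is not None
    return replace(best, method="approxi_mul", n_starts_used=len(starts),
                   start_points=tuple(tuple(s) for s in starts),
                   converged_to_epsilon=best.rmse <= config.epsilon)


def solve_scattersearch(segment: Signal, init: ComponentModel, bounds: Bounds,
                        config: SolverConfig) -> FitResult:
    """ApproxiGlo: score a Latin-hypercube pool, refine best-first with
    basin deduplication.

    The pool holds 10*n_starts stratified candidates plus the approximation;
    candidates are sorted by their unrefined RMSE and refined in that order,
    skipping any within an L-infinity distance of 5% of each bound width
    from an already refined start.  At most n_starts refinements run; the
    approximation is always refined first.
    """
    y = segment.samples
    t = np.arange(y.size) / segment.fs
    span = bounds.upper - bounds.lower
    sampler = qmc.LatinHypercube(d=7, seed=config.seed)
    pool = bounds.lower + sampler.random(10 * config.n_starts) * span
    scores = np.array([_rmse(p, init, t, y) for p in pool])
    order = np.argsort(scores, kind="stable")
    radius = 0.05 * span

    x_init = _clip_to_bounds(init.params, bounds)
    refined_starts: list[np.ndarray] = [x_init]
    start_points = [tuple(x_init)]
    best = local_refine(segment, init, bounds, config)
    n_used = 1
    for i in order:
        if n_used >= config.n_starts:
            break
        cand = pool[i]
        if any(np.all(np.abs(cand - s) <= radius) for s in refined_starts):
            continue
        res = local_refine(segment, init.with_params(cand), bounds, config)
        refined_starts.append(cand)
        start_points.append(tuple(cand))
        n_used += 1
        if res.rmse < best.rmse:
            best = res
    return replace(best, method="approxi_glo", n_starts_used=n_used,
                   start_points=tuple(start_points),
                   converged_to_epsilon=best.rmse <= config.epsilon)


def solve(segment: Signal, init: ComponentModel, bounds: Bounds,
          config: SolverConfig) -> FitResult:
    if config.method == "approxi_mul":
        return solve_multistart(segment, init, bounds, config)
    if config.method == "approxi_glo":
        return solve_scattersearch(segment, init, bounds, config)
    return local_refine(segment, init, bounds, config)


def fit_beat(beat_signal: Signal, segmentation: Sequence[tuple[str, Signal]],
             config: SolverConfig | None = None) -> BeatFitResult:
    """Fit all five components of one beat.

    ``segmentation`` is the ordered list of (label, segment) pairs produced
    by :func:`gaussecg.preprocess.extract_components`.  Each segment is
    approximated then refined; a degenerate segment flags that component
    (fallback: flat model at the segment mean) while the others proceed.
    """
    config = config or SolverConfig()
    segmentation = list(segmentation)
    if len(segmentation) != 5:
        raise ValueError(f"segmentation must yield 5 segments, got {len(segmentation)}")
    if [lab for lab, _ in segmentation] != list(COMPONENT_LABELS):
        raise ValueError("segments must be labeled P,Q,R,S,T in order")

    fits: dict[str, FitResult] = {}
    failed: list[str] = []
    comps: list[ComponentModel] = []
    seg_samples: list[int] = []
    for label, seg in segmentation:
        seg_samples.append(len(seg))
        try:
            init, bounds = approximate(seg, label=label, amp_mode=config.amp_mode)
            res = solve(seg, init, bounds, config)
        except ValueError:
            failed.append(label)
            flat = ComponentModel(label=label, A1=0.0, t1=0.0, sigma1=seg.duration,
                                  A2=0.0, t2=0.0, sigma2=seg.duration,
                                  c=float(np.mean(seg.samples)),
                                  duration=seg.duration)
            res = FitResult(model=flat,
                            rmse=float(np.std(seg.samples)),
                            n_starts_used=0, start_points=(),
                            converged=False, method=config.method)
        fits[label] = res
        comps.append(res.model)
    beat = BeatModel(components=tuple(comps), fs=beat_signal.fs,
                     segment_samples=tuple(seg_samples))
    from .model import evaluate_beat

    recon = evaluate_beat(beat)
    report = compare(beat_signal, recon)
    return BeatFitResult(beat=beat, components=fits,
                         segment_rmse={k: v.rmse for k, v in fits.items()},
                         whole_beat=report, failed=tuple(failed))
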