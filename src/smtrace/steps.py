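"""Piecewise-constant level models for single-molecule traces.

Fits step functions to intensity traces by *exact* dynamic-programming
change-point segmentation with Gaussian emissions (variance shared within a
trace), selects the number of states by a BIC curve with a two-segment
piecewise-linear knee fit, counts photobleaching steps and bound probes,
and extracts dwell gaps between binding events.

Two fitting regimes are provided, mirroring the standard two-stage
procedure for heterogeneous binding traces:

* free levels — each segment carries its own mean; the global optimum over
  change-point placements is found by dynamic programming (no local EM);
* fixed levels — level positions are calibrated once from the brightest
  traces and then held constant, and only the per-frame state path is
  optimised (a Viterbi-style DP with a minimum run length), which handles
  traces that revisit levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smtrace.errors import InvalidArgumentError
from smtrace.traces import FluorescenceTrace

MIN_SEGMENT_LEN = 2  # frames; noise-spike guard in segmentation
MIN_PLATEAU_LEN = 3  # frames a state must persist to count as visited
_SIGMA2_FLOOR = 1e-12


@dataclass
class StepFit:
    """A fitted piecewise-constant level model.

    ``levels`` are strictly increasing state means (in the trace's own
    intensity units); ``path`` maps each frame to a level index;
    ``change_points`` are the frames at which the path switches state.
    """

    n_states: int
    levels: np.ndarray
    path: np.ndarray
    change_points: np.ndarray
    log_likelihood: float
    bic: float
    sigma: float
    levels_free: bool = True


@dataclass
class BicCurve:
    """BIC versus candidate state count, with the knee-selected count."""

    candidates: np.ndarray
    bic: np.ndarray
    selected: int
    knee: int
    fits: dict = field(default_factory=dict, repr=False)


@dataclass
class DwellGapSet:
    """Gaps (s) from the first binding event to each later binding event."""

    gaps: np.ndarray

    def __post_init__(self):
        self.gaps = np.asarray(self.gaps, dtype=float)
        if np.any(self.gaps <= 0):
            raise InvalidArgumentError("dwell gaps must be positive")

    def __len__(self):
        return self.gaps.size


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def normalize_trace(trace: FluorescenceTrace, scale: float = 800.0):
    """Divide intensities by ``scale`` (default 800 A.U. = 10 eGFP units).

    One probe then contributes ~0.1 scaled units.  The scale is recorded in
    the trace metadata so fitted plateaus can be mapped back to camera
    units.
    """
    if scale <= 0:
        raise InvalidArgumentError("scale must be > 0")
    total = trace.meta.get("scale", 1.0) * scale
    return FluorescenceTrace(
        trace_id=trace.trace_id,
        time=trace.time,
        intensity=trace.intensity / scale,
        frame_interval=trace.frame_interval,
        channel=trace.channel,
        provenance=trace.provenance,
        meta={**trace.meta, "scale": total},
    )


# ---------------------------------------------------------------------------
# Exact change-point segmentation (free levels)
# ---------------------------------------------------------------------------


def _cost_matrix(y, min_len=MIN_SEGMENT_LEN):
    """C[i, j] = SSE of fitting one mean to y[i..j]; inf if too short."""
    n = y.size
    s1 = np.concatenate(([0.0], np.cumsum(y)))
    s2 = np.concatenate(([0.0], np.cumsum(y * y)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = j - i + 1
    with np.errstate(invalid="ignore", divide="ignore"):
        sums = s1[j + 1] - s1[i]
        cost = (s2[j + 1] - s2[i]) - sums * sums / length
    cost = np.where(length >= min_len, np.maximum(cost, 0.0), np.inf)
    return cost


def _dp_segment(y, m_max, min_len=MIN_SEGMENT_LEN):
    """Optimal SSE segmentations of y into 1..m_max segments.

    Returns (D, P): D[m, j] is the minimal SSE of segmenting y[0..j] into m
    segments of length >= min_len; P[m, j] is the start frame of the last
    segment in that optimum.
    """
    n = y.size
    cost = _cost_matrix(y, min_len)
    d = np.full((m_max + 1, n), np.inf)
    p = np.zeros((m_max + 1, n), dtype=np.int64)
    d[1] = cost[0]
    for m in range(2, m_max + 1):
        # last segment starts at i (row index i-1 of prev), previous part ends at i-1
        stacked = d[m - 1, : n - 1, None] + cost[1:, :]
        idx = np.argmin(stacked, axis=0)
        d[m] = stacked[idx, np.arange(n)]
        p[m] = idx + 1
    return d, p


def _backtrack(p, m, n):
    """Segment (start, end) bounds of the m-segment optimum ending at n-1."""
    bounds = []
    j = n - 1
    for seg in range(m, 0, -1):
        start = int(p[seg, j]) if seg > 1 else 0
        bounds.append((start, j))
        j = start - 1
    return bounds[::-1]


def _gaussian_loglik(sse, n):
    sigma2 = max(sse / n, _SIGMA2_FLOOR)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0), np.sqrt(sigma2)


def _fit_from_segments(y, bounds, levels_free=True):
    """Build a StepFit from segment bounds (free-level fit)."""
    n = y.size
    seg_means = np.array([y[a : b + 1].mean() for a, b in bounds])
    levels, inverse = np.unique(seg_means, return_inverse=True)
    path = np.empty(n, dtype=np.int64)
    for (a, b), lev in zip(bounds, inverse):
        path[a : b + 1] = lev
    sse = float(sum(((y[a : b + 1] - m) ** 2).sum()
                    for (a, b), m in zip(bounds, seg_means)))
    change_points = np.flatnonzero(np.diff(path) != 0) + 1
    loglik, sigma = _gaussian_loglik(sse, n)
    n_params = levels.size + 1 + change_points.size
    bic = -2.0 * loglik + n_params * np.log(n)
    return StepFit(
        n_states=int(levels.size),
        levels=levels,
        path=path,
        change_points=change_points,
        log_likelihood=float(loglik),
        bic=float(bic),
        sigma=float(sigma),
        levels_free=levels_free,
    )


# ---------------------------------------------------------------------------
# Fixed-level path decoding
# ---------------------------------------------------------------------------


def _viterbi_fixed(y, levels, min_len=MIN_SEGMENT_LEN):
    """Min-SSE state path over fixed levels with run length >= min_len.

    Exact DP; only min_len == 2 is supported (sufficient here).
    """
    n, k = y.size, levels.size
    cost = (y[:, None] - levels[None, :]) ** 2
    if k == 1 or n == 1:
        return (np.zeros(n, dtype=np.int64) if k == 1
                else np.array([int(np.argmin(cost[0]))], dtype=np.int64))
    # a: current run has length 1 (just entered); b: run length >= 2
    a = cost[0].copy()
    b = np.full(k, np.inf)
    ptr_a = np.zeros((n, k), dtype=np.int64)  # previous state when entering
    ptr_b = np.zeros((n, k), dtype=np.int64)  # 0: from a, 1: from b
    for t in range(1, n):
        # entering a new run at t: previous run must have length >= min_len
        best = np.argmin(b)
        second = np.partition(b, 1)[1] if k > 1 else np.inf
        enter_from = np.full(k, best)
        enter_cost = np.full(k, b[best])
        if np.isfinite(second):
            alt = np.argsort(b)[1]
            enter_from[best] = alt
            enter_cost[best] = second
        else:
            enter_cost[best] = np.inf
        new_a = enter_cost + cost[t]
        ptr_a[t] = enter_from
        stay = np.where(a <= b, a, b)
        ptr_b[t] = (b < a).astype(np.int64)
        new_b = stay + cost[t]
        a, b = new_a, new_b
    path = np.empty(n, dtype=np.int64)
    state = int(np.argmin(b))
    mode = 1  # end in a run of length >= 2
    path[-1] = state
    for t in range(n - 1, 0, -1):
        if mode == 1:
            mode = int(ptr_b[t, state])
        else:
            prev = int(ptr_a[t, state])
            state, mode = prev, 1
        path[t - 1] = state
    return path


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def fit_levels(trace, k, fixed_levels=None):
    """Fit a piecewise-constant model with at most ``k`` states.

    With free levels this is the exact dynamic-programming optimum of the
    change-point segmentation model (each segment its own mean, minimum
    segment length 2).  With ``fixed_levels`` the given level positions are
    the only allowed emission means and only the state path is optimised,
    which accommodates traces that revisit levels.
    """
    y = np.asarray(trace.intensity, dtype=float)
    n = y.size
    if fixed_levels is not None:
        levels = np.sort(np.asarray(fixed_levels, dtype=float))
        if levels.size == 0:
            raise InvalidArgumentError("fixed_levels must be non-empty")
        path = _viterbi_fixed(y, levels)
        sse = float(((y - levels[path]) ** 2).sum())
        change_points = np.flatnonzero(np.diff(path) != 0) + 1
        loglik, sigma = _gaussian_loglik(sse, n)
        n_params = 1 + change_points.size
        return StepFit(
            n_states=int(levels.size),
            levels=levels,
            path=path,
            change_points=change_points,
            log_likelihood=float(loglik),
            bic=float(-2.0 * loglik + n_params * np.log(n)),
            sigma=float(sigma),
            levels_free=False,
        )
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if k > n:
        raise InvalidArgumentError("k cannot exceed the number of frames")
    m = max(1, min(k, n // MIN_SEGMENT_LEN))
    d, p = _dp_segment(y, m)
    while m > 1 and not np.isfinite(d[m, n - 1]):
        m -= 1
    return _fit_from_segments(y, _backtrack(p, m, n))


def _knee_breakpoint(x, y):
    """Best integer breakpoint of a two-segment continuous linear fit."""
    best_b, best_sse = int(x[0]), np.inf
    for b in x[1:-1]:
        design = np.column_stack(
            [np.ones_like(x, dtype=float),
             np.minimum(x - b, 0.0),
             np.maximum(x - b, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        sse = float(((design @ coef - y) ** 2).sum())
        if sse < best_sse - 1e-12:  # ties go to the smaller breakpoint
            best_b, best_sse = int(b), sse
    return best_b


def bic_model_selection(trace, k_max: int = 8) -> BicCurve:
    """Choose the number of states from the BIC-versus-k knee.

    Fits free-level models for k = 1..k_max, then fits every two-segment
    continuous piecewise-linear function with an integer breakpoint to the
    (k, BIC) points by least squares.  The knee is the best breakpoint; the
    selected count is the smallest k at or below the knee whose BIC does
    not exceed the knee's (so monotone-increasing curves select 1).
    """
    if k_max < 2:
        raise InvalidArgumentError("k_max must be >= 2")
    y = np.asarray(trace.intensity, dtype=float)
    n = y.size
    m_cap = max(1, min(k_max, n // MIN_SEGMENT_LEN))
    d, p = _dp_segment(y, m_cap)
    fits = {}
    for k in range(1, k_max + 1):
        m = min(k, m_cap)
        while m > 1 and not np.isfinite(d[m, n - 1]):
            m -= 1
        fits[k] = _fit_from_segments(y, _backtrack(p, m, n))
    candidates = np.arange(1, k_max + 1)
    bic = np.array([fits[k].bic for k in candidates])
    if k_max >= 3:
        knee = _knee_breakpoint(candidates, bic)
    else:
        knee = int(candidates[np.argmin(bic)])
    def smallest_not_worse(limit):
        below = [int(k) for k in candidates
                 if k <= limit and bic[k - 1] <= bic[limit - 1] + 1e-12]
        return min(below) if below else int(limit)

    selected = smallest_not_worse(knee)
    # A two-segment line cannot represent a near-zero-residual cliff beyond
    # the knee; if the knee's model is categorically worse than the best
    # candidate (by far more than the BIC penalty scale), fall through to
    # the smallest candidate within the penalty scale of the best.
    cliff = 10.0 * np.log(n)
    if bic[selected - 1] > bic.min() + cliff:
        limit = min(int(k) for k in candidates if bic[k - 1] <= bic.min() + cliff)
        selected = smallest_not_worse(limit)
    return BicCurve(candidates=candidates, bic=bic, selected=selected,
                    knee=knee, fits=fits)


def count_bleach_steps(trace, k_max: int = 8) -> int:
    """Number of photobleaching steps in a trace.

    Selects the state count by BIC, fits the step function and counts the
    transitions that land on a strictly lower level.
    """
    curve = bic_model_selection(trace, k_max=k_max)
    fit = curve.fits[curve.selected]
    lv = fit.levels[fit.path]
    return int(np.sum(np.diff(lv) < 0))


def count_max_bound(trace, fixed_levels, min_plateau: int = MIN_PLATEAU_LEN):
    """Maximum number of simultaneously bound probes in one trace.

    Decodes the path over calibrated fixed levels and reports the highest
    state index occupied for at least ``min_plateau`` consecutive frames
    (index 0 is the baseline), together with the mean *unscaled* intensity
    of the frames on that plateau.
    """
    fixed_levels = np.asarray(fixed_levels, dtype=float)
    if fixed_levels.size == 0:
        raise InvalidArgumentError("fixed_levels must be non-empty")
    fit = fit_levels(trace, k=fixed_levels.size, fixed_levels=fixed_levels)
    path = fit.path
    scale = trace.meta.get("scale", 1.0)
    best_state = 0
    plateau_frames = np.arange(trace.n_frames)
    runs = _runs(path)
    eligible = [(state, a, b) for state, a, b in runs if b - a + 1 >= min_plateau]
    if eligible:
        best_state = max(state for state, _, _ in eligible)
        frames = np.concatenate(
            [plateau_frames[a : b + 1] for state, a, b in eligible
             if state == best_state]
        )
    else:
        frames = plateau_frames
    intensity = float(trace.intensity[frames].mean() * scale)
    return int(best_state), intensity


def _runs(path):
    """(state, first_frame, last_frame) for each constant run of the path."""
    path = np.asarray(path)
    if path.size == 0:
        return []
    change = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [path.size - 1]))
    return [(int(path[a]), int(a), int(b)) for a, b in zip(starts, ends)]


def _weighted_cluster_1d(values, weights, n_clusters):
    """Exact weighted 1-D k-means via DP on the sorted values.

    Returns (centers ascending, weighted SSE).
    """
    order = np.argsort(values)
    x, w = values[order], weights[order]
    n = x.size
    cw = np.concatenate(([0.0], np.cumsum(w)))
    cwx = np.concatenate(([0.0], np.cumsum(w * x)))
    cwx2 = np.concatenate(([0.0], np.cumsum(w * x * x)))
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    wsum = cw[j + 1] - cw[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        cost = (cwx2[j + 1] - cwx2[i]) - (cwx[j + 1] - cwx[i]) ** 2 / wsum
    cost = np.where(j >= i, np.nan_to_num(np.maximum(cost, 0.0)), np.inf)
    d = np.full((n_clusters + 1, n), np.inf)
    p = np.zeros((n_clusters + 1, n), dtype=np.int64)
    d[1] = cost[0]
    for m in range(2, n_clusters + 1):
        stacked = d[m - 1, : n - 1, None] + cost[1:, :]
        idx = np.argmin(stacked, axis=0)
        d[m] = stacked[idx, np.arange(n)]
        p[m] = idx + 1
    m = min(n_clusters, n)
    bounds = _backtrack(p, m, n)
    centers = np.array(
        [(cwx[b + 1] - cwx[a]) / (cw[b + 1] - cw[a]) for a, b in bounds]
    )
    return centers, float(d[m, n - 1])


def calibrate_levels(traces, k_max: int = 8, jitter_ratio: float = 0.25):
    """Shared ascending level positions from the brightest traces.

    Each trace is segmented with BIC state selection; plateau means lasting
    at least MIN_PLATEAU_LEN frames are pooled and clustered by exact
    weighted 1-D k-means.  A plateau mean of length w is modelled as
    Gaussian around its level with variance sigma^2/w + tau^2, where
    tau = jitter_ratio * sigma captures molecule-to-molecule variation of
    level positions; the effective weight w/(1 + w (tau/sigma)^2) therefore
    saturates, so long plateaus cannot spawn spurious levels from small
    between-trace offsets.  The cluster count is chosen by BIC on the
    chi-square deviance.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise InvalidArgumentError("calibration needs at least 2 traces")
    means, weights, sigmas = [], [], []
    for trace in traces:
        curve = bic_model_selection(trace, k_max=k_max)
        fit = curve.fits[curve.selected]
        sigmas.append(fit.sigma)
        for state, a, b in _runs(fit.path):
            if b - a + 1 >= MIN_PLATEAU_LEN:
                means.append(fit.levels[state])
                weights.append(b - a + 1)
    means = np.asarray(means, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n = means.size
    sigma2 = max(float(np.mean(sigmas)) ** 2, _SIGMA2_FLOOR)
    w_eff = weights / (1.0 + weights * jitter_ratio**2)
    best_centers, best_bic = None, np.inf
    penalty = np.log(n)
    for n_levels in range(1, min(k_max, n) + 1):
        centers, sse = _weighted_cluster_1d(means, w_eff, n_levels)
        bic = sse / sigma2 + n_levels * penalty
        if bic < best_bic - 1e-12:
            best_centers, best_bic = centers, bic
    return np.sort(best_centers)


# ---------------------------------------------------------------------------
# Dwell gaps
# ---------------------------------------------------------------------------


def extract_dwell_gaps(path, frame_interval: float) -> DwellGapSet:
    """Gaps from the first binding event to each later binding event.

    ``path`` is a per-frame occupancy (bound-probe count).  The first
    upward transition anchors the clock; each subsequent upward transition
    contributes one gap per probe gained.  Collection stops once occupancy
    has returned to zero for good (photobleaching end of the trace).
    """
    path = np.asarray(path)
    if frame_interval <= 0:
        raise InvalidArgumentError("frame_interval must be > 0")
    diffs = np.diff(path)
    ups = np.flatnonzero(diffs > 0) + 1
    if ups.size == 0:
        return DwellGapSet(gaps=np.empty(0))
    first = ups[0]
    occupied = np.flatnonzero(path > 0)
    last_occupied = occupied[-1] if occupied.size else first
    gaps = []
    for t in ups[1:]:
        if t > last_occupied:
            break
        gaps.extend([(t - first) * frame_interval] * int(diffs[t - 1]))
    return DwellGapSet(gaps=np.asarray(gaps, dtype=float))
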