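"""Kinetic model fitting for single-molecule count and dwell data.

Exponential progress curves N(t) = N_max (1 - e^{-kt}), Michaelis-Menten
k([S]) = k_cat,max [S]/(K_M + [S]), exponential dwell-time maximum
likelihood, two-state telegraph rate estimation from sampled paths, and
four-parameter logistic dose-response (IC50) fits.  All fitters are
deterministic given the data and recover noiseless model-generated data
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from smtrace.errors import FitError, InvalidArgumentError

_CURVE_FIT_KW = dict(xtol=1e-13, ftol=1e-13, gtol=1e-13, maxfev=20000)


# ---------------------------------------------------------------------------
# Progress curves and Michaelis-Menten
# ---------------------------------------------------------------------------


def fit_progress_curve(curve, with_stderr: bool = False):
    """Fit N(t) = N_max (1 - exp(-k t)) to one progress curve.

    Weighted least squares with counting weights.  When the curve records
    the number of surface molecules the weights follow the binomial
    variance count*(1 - count/n_molecules) (the molecule number per field
    is fixed, so counts saturate); otherwise Poisson-style 1/max(count, 1)
    weights are used.  Returns ``(k, n_max)``; the catalytic rate at this
    [ATP] is ``k``.  With ``with_stderr`` the standard error of ``k`` is
    appended, for propagation into downstream fits.

    Raises
    ------
    FitError
        If the counts are all equal (degenerate) or the curve is already
        saturated at the first positive time point, leaving the rate
        unbounded.
    """
    t = np.asarray(curve.time_s, dtype=float)
    counts = np.asarray(curve.counts, dtype=float)
    if t.size < 4:
        raise InvalidArgumentError("need >= 4 time points")
    if np.ptp(counts) == 0:
        raise FitError("counts are all equal; rate is unidentifiable")
    n0 = float(counts.max())
    rising = counts < 0.95 * n0
    positive = t > 0
    if not np.any(rising & positive):
        raise FitError("curve saturated at every positive time; k unbounded")
    # crude rate guess from the earliest unsaturated point
    t1 = t[rising & positive][0]
    c1 = counts[t == t1][0]
    frac = min(max(c1 / max(n0, 1.0), 1e-3), 0.999)
    k0 = -math.log(1.0 - frac) / t1
    n_mol = getattr(curve, "n_molecules", None)
    if n_mol:
        variance = np.maximum(counts * (1.0 - counts / n_mol), 1.0)
    else:
        variance = np.maximum(counts, 1.0)
    sigma = np.sqrt(variance)

    def model(tt, n_max, k):
        return n_max * (1.0 - np.exp(-k * tt))

    try:
        popt, pcov = optimize.curve_fit(
            model, t, counts, p0=(n0, k0), sigma=sigma, absolute_sigma=True,
            bounds=([0.0, 0.0], [np.inf, np.inf]), **_CURVE_FIT_KW,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"progress-curve fit did not converge: {exc}") from exc
    n_max, k = float(popt[0]), float(popt[1])
    if not np.isfinite(k) or k <= 0:
        raise FitError("fitted rate is not finite and positive")
    if with_stderr:
        return k, n_max, float(np.sqrt(pcov[1, 1]))
    return k, n_max


@dataclass
class MMFit:
    """Michaelis-Menten fit result."""

    K_M: float
    k_cat_max: float
    rates: np.ndarray
    atp_um: np.ndarray
    stderr_K_M: float
    stderr_k_cat_max: float
    residuals: np.ndarray


def fit_michaelis_menten(rates, atp, stderr=None) -> MMFit:
    """Nonlinear least-squares fit of k([S]) = k_cat_max [S]/(K_M + [S]).

    Initial guesses come from the double-reciprocal (Lineweaver-Burk)
    linearisation.  Requires >= 3 distinct concentrations.  When
    per-rate standard errors are supplied (from the upstream progress
    fits) the fit is inverse-variance weighted, which matters for K_M:
    rate errors grow with the rate itself, and unweighted least squares
    lets the saturated high-[S] points swamp the half-saturation region.
    """
    rates = np.asarray(rates, dtype=float)
    atp = np.asarray(atp, dtype=float)
    if rates.shape != atp.shape:
        raise InvalidArgumentError("rates and atp must have equal length")
    if np.unique(atp).size < 3:
        raise InvalidArgumentError("need >= 3 distinct concentrations")
    if np.ptp(rates) == 0:
        raise FitError("rates are all equal; K_M is unidentifiable")
    ok = (rates > 0) & (atp > 0)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / atp[ok], 1.0 / rates[ok], 1)
        vmax0 = 1.0 / intercept if intercept > 0 else rates.max()
        km0 = slope * vmax0 if slope * vmax0 > 0 else np.median(atp)
    else:  # pragma: no cover - pathological input
        vmax0, km0 = rates.max(), np.median(atp)

    def model(s, k_cat_max, km):
        return k_cat_max * s / (km + s)

    sigma = None
    if stderr is not None:
        sigma = np.maximum(np.asarray(stderr, dtype=float), 1e-12)
        if sigma.shape != rates.shape:
            raise InvalidArgumentError("stderr must match rates in length")
    try:
        popt, pcov = optimize.curve_fit(
            model, atp, rates, p0=(vmax0, km0), sigma=sigma,
            absolute_sigma=sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]), **_CURVE_FIT_KW,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    perr = np.sqrt(np.diag(pcov))
    return MMFit(
        K_M=float(popt[1]),
        k_cat_max=float(popt[0]),
        rates=rates,
        atp_um=atp,
        stderr_K_M=float(perr[1]),
        stderr_k_cat_max=float(perr[0]),
        residuals=rates - model(atp, *popt),
    )


# ---------------------------------------------------------------------------
# Dwell times and telegraph rates
# ---------------------------------------------------------------------------


def fit_exponential_dwells(dwells, conf: float = 0.95):
    """Maximum-likelihood exponential rate from dwell times.

    The MLE is 1/mean(dwells); the confidence interval follows from the
    gamma (chi-square) distribution of the summed dwells.
    Returns ``(rate, (lo, hi))``.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size < 10:
        raise InvalidArgumentError("need >= 10 dwells")
    if np.any(dwells <= 0):
        raise InvalidArgumentError("dwells must be positive")
    n = dwells.size
    total = dwells.sum()
    rate = n / total
    alpha = 1.0 - conf
    lo = stats.chi2.ppf(alpha / 2.0, 2 * n) / (2.0 * total)
    hi = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * n) / (2.0 * total)
    return float(rate), (float(lo), float(hi))


@dataclass
class TelegraphFit:
    """Generation/removal rates of a two-state telegraph process."""

    k_gen: float
    k_rem: float
    n_on_dwells: int
    n_off_dwells: int
    ci_k_gen: tuple
    ci_k_rem: tuple


def _interior_dwells(path, frame_interval):
    """(off_dwells, on_dwells) in seconds, first/last runs discarded."""
    path = np.asarray(path)
    change = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    off, on = [], []
    for i, (a, b) in enumerate(zip(starts, ends)):
        if i == 0 or i == len(starts) - 1:
            continue  # censored boundary dwells
        (on if path[a] else off).append((b - a) * frame_interval)
    return off, on


def estimate_telegraph_rates(paths, frame_interval,
                             correct_discretization: bool = True,
                             conf: float = 0.95) -> TelegraphFit:
    """Estimate k_gen and k_rem from grid-sampled two-state paths.

    Dwells are split by state (first and last, censored, dwells of each
    path are discarded); k_gen comes from off-state dwells and k_rem from
    on-state dwells via the exponential MLE.  With
    ``correct_discretization`` (default) the reciprocal-mean estimates are
    mapped through the exact transition probabilities of the grid-sampled
    chain, removing the O((k_gen+k_rem)*dt) downward bias of raw
    frame-quantised dwells; disable it to get the plain reciprocal-mean
    rates.
    """
    if frame_interval <= 0:
        raise InvalidArgumentError("frame_interval must be > 0")
    if isinstance(paths, np.ndarray) and paths.ndim == 1:
        paths = [paths]
    off, on = [], []
    for path in paths:
        o, n = _interior_dwells(path, frame_interval)
        off.extend(o)
        on.extend(n)
    if len(off) < 10 or len(on) < 10:
        raise FitError("need >= 10 complete dwells per state")
    k_gen, ci_gen = fit_exponential_dwells(off, conf=conf)
    k_rem, ci_rem = fit_exponential_dwells(on, conf=conf)
    if correct_discretization:
        dt = frame_interval
        p01 = k_gen * dt  # per-frame switch probabilities (= dt / mean dwell)
        p10 = k_rem * dt
        if p01 + p10 < 1.0:
            lam = -math.log(1.0 - p01 - p10) / dt
            factor = lam / ((p01 + p10) / dt)
            k_gen, k_rem = k_gen * factor, k_rem * factor
            ci_gen = tuple(c * factor for c in ci_gen)
            ci_rem = tuple(c * factor for c in ci_rem)
    return TelegraphFit(
        k_gen=float(k_gen),
        k_rem=float(k_rem),
        n_on_dwells=len(on),
        n_off_dwells=len(off),
        ci_k_gen=ci_gen,
        ci_k_rem=ci_rem,
    )


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Four-parameter logistic inhibition fit."""

    IC50: float
    hill: float
    top: float
    bottom: float
    stderr_IC50: float
    residuals: np.ndarray


def fit_dose_response(activity, conc, fix_hill: float | None = 1.0):
    """Fit activity(c) = bottom + (top-bottom)/(1 + (c/IC50)^hill).

    The Hill coefficient is fixed at 1 by default; pass ``fix_hill=None``
    to fit it.  Requires >= 5 concentrations spanning the transition.
    """
    activity = np.asarray(activity, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if activity.shape != conc.shape:
        raise InvalidArgumentError("activity and conc must have equal length")
    if np.unique(conc).size < 5:
        raise InvalidArgumentError("need >= 5 concentrations")
    top0 = float(np.max(activity))
    bottom0 = float(np.min(activity))
    mid = 0.5 * (top0 + bottom0)
    pos = conc > 0
    ic0 = float(conc[pos][np.argmin(np.abs(activity[pos] - mid))]) if pos.any() else 1.0

    def model_fixed(c, top, bottom, ic50):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** fix_hill)

    def model_free(c, top, bottom, ic50, hill):
        return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)

    try:
        if fix_hill is not None:
            popt, pcov = optimize.curve_fit(
                model_fixed, conc, activity, p0=(top0, bottom0, ic0),
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                **_CURVE_FIT_KW,
            )
            top, bottom, ic50 = popt
            hill = float(fix_hill)
            stderr = float(np.sqrt(pcov[2, 2]))
            resid = activity - model_fixed(conc, *popt)
        else:
            popt, pcov = optimize.curve_fit(
                model_free, conc, activity, p0=(top0, bottom0, ic0, 1.0),
                bounds=([-np.inf, -np.inf, 1e-12, 0.05],
                        [np.inf, np.inf, np.inf, 20.0]),
                **_CURVE_FIT_KW,
            )
            top, bottom, ic50, hill = popt
            stderr = float(np.sqrt(pcov[2, 2]))
            resid = activity - model_free(conc, *popt)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"dose-response fit did not converge: {exc}") from exc
    if not np.isfinite(ic50) or ic50 <= 0:
        raise FitError("fitted IC50 is not finite and positive")
    return DoseResponseFit(
        IC50=float(ic50), hill=float(hill), top=float(top),
        bottom=float(bottom), stderr_IC50=stderr, residuals=resid,
    )


def effective_ic50_vs_phosphatase(comp, phosphatase_scales):
    """Analytic half-activity concentration versus phosphatase activity.

    Under the kinase/phosphatase competition model the steady-state signal
    is f(c) = kp(1-th)/(kp(1-th) + s*kdp); solving f(c) = f(0)/2 gives

        c_1/2 = IC50_intrinsic * ((1 + a)/a)^(1/hill),   a = s*kdp/kp.

    Strictly decreasing in the phosphatase scale s; diverges as s -> 0
    (a slow phosphatase cannot reveal kinase inhibition in the steady
    state).  Returns a dict with ``phosphatase_scale`` and
    ``effective_ic50_um`` arrays.
    """
    scales = np.asarray(phosphatase_scales, dtype=float)
    if np.any(scales <= 0):
        raise InvalidArgumentError("phosphatase scales must be > 0")
    a = scales * comp.k_dp / comp.k_p
    eff = comp.ic50_intrinsic * ((1.0 + a) / a) ** (1.0 / comp.hill)
    return {"phosphatase_scale": scales, "effective_ic50_um": eff}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def mean_inter_spot_distance(n_spots: int, field) -> float:
    """Characteristic spacing sqrt(area / n) of n spots in a (w, h) um field."""
    if n_spots < 1:
        raise InvalidArgumentError("n_spots must be >= 1")
    w, h = field
    return math.sqrt(w * h / n_spots)
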