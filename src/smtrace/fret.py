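"""smFRET efficiency computation, trace filtering and distributions.

Apparent efficiency is Ia/(Id+Ia); the donor-leakage corrected efficiency
is (Ia - beta*Id)/(Id+Ia) with a leakage factor beta (default 0.12, the
Cy3-into-Cy5-channel fraction).  Framewise efficiencies from all kept
traces are pooled into a histogram normalised by the total number of
frames, and a threshold at E = 0.5 splits the population into low- and
high-FRET conformations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from smtrace.errors import InvalidArgumentError

DEFAULT_BETA = 0.12
DEFAULT_THRESHOLD = 0.5
DEFAULT_RANGE = (-0.2, 1.2)


def apparent_efficiency(donor, acceptor):
    """Apparent FRET efficiency Ia/(Id+Ia).

    Frames with non-positive total intensity are undefined and return NaN
    (they are dropped from distributions).
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, acceptor / total, np.nan)
    return e if e.ndim else float(e)


def corrected_efficiency(donor, acceptor, beta: float = DEFAULT_BETA):
    """Leakage-corrected FRET efficiency (Ia - beta*Id)/(Id+Ia)."""
    if not 0 <= beta < 1:
        raise InvalidArgumentError("beta must lie in [0, 1)")
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    total = donor + acceptor
    with np.errstate(invalid="ignore", divide="ignore"):
        e = np.where(total > 0, (acceptor - beta * donor) / total, np.nan)
    return e if e.ndim else float(e)


# ---------------------------------------------------------------------------
# Per-trace series
# ---------------------------------------------------------------------------


@dataclass
class EfficiencySeries:
    """Framewise efficiency of one trace's usable analysis frames."""

    trace_id: str
    frames: np.ndarray
    e: np.ndarray
    corrected: bool
    beta: float


def _channel_noise_sd(x):
    """Noise SD from the MAD of successive differences."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return 0.0
    d = np.diff(x)
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def donor_active_frames(trace, background: float = 0.0):
    """Boolean mask of analysis frames recorded before donor bleaching.

    Frames after the last frame whose summed intensity exceeds
    ``background + 3 * noise_sd`` are flagged as donor-bleached.
    """
    sl = trace.analysis_slice
    total = trace.donor[sl] + trace.acceptor[sl]
    sd = _channel_noise_sd(total)
    above = total > background + 3.0 * sd
    mask = np.zeros(total.size, dtype=bool)
    if np.any(above):
        mask[: np.flatnonzero(above)[-1] + 1] = True
    return mask


def mask_blinks(trace, max_gap: int = 5, background: float = 0.0):
    """Mask short acceptor dark intervals while the donor is still bright.

    Acceptor frames within ``3 * noise_sd`` of the leakage-only expectation
    that form runs of at most ``max_gap`` frames are flagged True (to be
    excluded, not treated as transitions).  Operates on analysis frames.
    """
    sl = trace.analysis_slice
    donor = trace.donor[sl]
    acceptor = trace.acceptor[sl]
    sd_a = _channel_noise_sd(acceptor)
    sd_d = _channel_noise_sd(donor)
    dark = (acceptor < background + 3.0 * sd_a) & (
        donor > background + 3.0 * sd_d
    )
    mask = np.zeros(dark.size, dtype=bool)
    i = 0
    while i < dark.size:
        if dark[i]:
            j = i
            while j + 1 < dark.size and dark[j + 1]:
                j += 1
            if j - i + 1 <= max_gap:
                mask[i : j + 1] = True
            i = j + 1
        else:
            i += 1
    return mask


def trace_efficiencies(trace, corrected: bool = False,
                       beta: float = DEFAULT_BETA, background: float = 0.0,
                       apply_blink_mask: bool = False) -> EfficiencySeries:
    """Framewise efficiencies of the usable analysis frames of one trace.

    Donor-bleached frames are excluded; frames with non-positive summed
    intensity are dropped; optionally, short acceptor blinks are masked.
    """
    sl = trace.analysis_slice
    donor = trace.donor[sl]
    acceptor = trace.acceptor[sl]
    usable = donor_active_frames(trace, background=background)
    if apply_blink_mask:
        usable &= ~mask_blinks(trace, background=background)
    usable &= (donor + acceptor) > 0
    frames = np.flatnonzero(usable) + trace.check_frames
    if corrected:
        e = corrected_efficiency(donor[usable], acceptor[usable], beta=beta)
    else:
        e = apparent_efficiency(donor[usable], acceptor[usable])
    return EfficiencySeries(
        trace_id=trace.trace_id,
        frames=frames,
        e=np.atleast_1d(np.asarray(e, dtype=float)),
        corrected=corrected,
        beta=beta if corrected else 0.0,
    )


# ---------------------------------------------------------------------------
# Trace exclusion rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the trace-exclusion rules, applied in order.

    a) no acceptor signal in the acceptor-excitation check block, or no
       donor-excitation signal at all;
    b) insufficient median summed intensity under donor excitation;
    c) donor:acceptor stoichiometry proxy outside the accepted window
       (obviously different from 1:1);
    d) the trace never shows an apparent efficiency above ``min_peak_e``
       (a steady leakage-level trace belongs to an inactive complex).
    """

    min_check_mean: float = 50.0
    min_sum_median: float = 100.0
    stoich_low: float = 0.3
    stoich_high: float = 0.7
    min_peak_e: float = 0.4
    background: float = 0.0


def _stoichiometry_proxy(check_mean, sum_median):
    denom = check_mean + sum_median
    return check_mean / denom if denom > 0 else 0.0


def filter_fret_traces(traces, rules: FilterRules = FilterRules()):
    """Apply the exclusion rules; returns (kept, rejected_with_reason).

    ``rejected_with_reason`` is a list of (trace, reason) pairs with reason
    in {"no-acceptor", "no-donor", "low-sum", "stoichiometry", "low-fret"}.
    """
    kept, rejected = [], []
    for trace in traces:
        check_acceptor = trace.acceptor[: trace.check_frames]
        check_mean = float(check_acceptor.mean()) if check_acceptor.size else 0.0
        active = donor_active_frames(trace, background=rules.background)
        sl = trace.analysis_slice
        total = (trace.donor[sl] + trace.acceptor[sl])[active]
        if check_mean < rules.min_check_mean:
            rejected.append((trace, "no-acceptor"))
            continue
        if total.size == 0 or np.median(total) <= 0:
            rejected.append((trace, "no-donor"))
            continue
        sum_median = float(np.median(total))
        if sum_median < rules.min_sum_median:
            rejected.append((trace, "low-sum"))
            continue
        stoich = _stoichiometry_proxy(check_mean, sum_median)
        if not rules.stoich_low <= stoich <= rules.stoich_high:
            rejected.append((trace, "stoichiometry"))
            continue
        series = trace_efficiencies(trace, corrected=False,
                                    background=rules.background)
        if series.e.size == 0 or np.nanmax(series.e) <= rules.min_peak_e:
            rejected.append((trace, "low-fret"))
            continue
        kept.append(trace)
    return kept, rejected


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------


@dataclass
class EfficiencyDistribution:
    """Normalised framewise efficiency histogram over a set of traces."""

    bin_edges: np.ndarray
    frequency: np.ndarray
    total_frames: int
    low_e_fraction: float
    threshold: float
    values: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def efficiency_distribution(traces, bins: int = 50, corrected: bool = False,
                            beta: float = DEFAULT_BETA,
                            e_range=DEFAULT_RANGE,
                            threshold: float = DEFAULT_THRESHOLD,
                            background: float = 0.0,
                            apply_blink_mask: bool = False):
    """Pooled framewise efficiency histogram, normalised to unit mass.

    Donor-bleached frames are excluded before pooling; the histogram is
    normalised by the total number of collected frames.  The low-E
    fraction is the mass strictly below ``threshold``, computed from the
    raw frame values (not the binned mass) to avoid bin-edge artefacts.
    Values are clipped into ``e_range`` for binning only.
    """
    traces = list(traces)
    if not traces:
        raise InvalidArgumentError("efficiency_distribution needs >= 1 trace")
    series = [
        trace_efficiencies(t, corrected=corrected, beta=beta,
                           background=background,
                           apply_blink_mask=apply_blink_mask)
        for t in traces
    ]
    values = np.concatenate([s.e for s in series]) if series else np.empty(0)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise InvalidArgumentError("no usable frames after exclusion")
    lo, hi = e_range
    clipped = np.clip(values, lo + 1e-12, hi - 1e-12)
    counts, edges = np.histogram(clipped, bins=bins, range=e_range)
    frequency = counts / values.size
    low = float(np.mean(values < threshold))
    return EfficiencyDistribution(
        bin_edges=edges,
        frequency=frequency,
        total_frames=int(values.size),
        low_e_fraction=low,
        threshold=threshold,
        values=values,
    )


def two_state_occupancy(distribution: EfficiencyDistribution,
                        threshold: float = DEFAULT_THRESHOLD):
    """(low fraction, high fraction) split at the threshold; sums to 1."""
    values = distribution.values
    if values.size == 0:
        raise InvalidArgumentError("distribution carries no raw values")
    low = float(np.mean(values < threshold))
    return low, 1.0 - low
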