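"""Synthetic single-molecule data with known ground truth.

Every input class the analysis consumes can be generated here: quantised
eGFP intensity traces with stochastic photobleaching and binding/unbinding,
Cy3/Cy5 FRET traces with donor leakage, two-state switching, blinking and
bleaching, binomially sampled phosphorylation progress curves under
Michaelis-Menten kinetics, phosphorylation/dephosphorylation telegraph
dynamics, dose-response inhibition series, spot fields and rendered movies.

Continuous-time events are sampled by Gillespie-style exponential waiting
times and then discretised to the camera frame grid.  All randomness flows
through one explicit seeded generator per call, so an identical
configuration (including the seed) reproduces bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from smtrace.errors import InvalidArgumentError
from smtrace.traces import FluorescenceTrace, FretTrace

# ---------------------------------------------------------------------------
# Configuration and ground-truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Camera and signal model shared by all simulators.

    Parameters
    ----------
    n_frames : int
        Number of frames to record.
    frame_interval : float
        Seconds per frame (default 0.1 s, typical TIRF time resolution).
    unit_intensity : float
        Camera counts contributed by one eGFP (default 80 A.U.).
    noise_sd : float
        Gaussian readout noise per frame, A.U. (default 20, i.e. a
        single-fluorophore SNR of 4).
    background_level : float
        Constant background offset added to every frame, A.U.
    seed : int
        Seed for the per-call random generator.
    """

    n_frames: int
    frame_interval: float = 0.1
    unit_intensity: float = 80.0
    noise_sd: float = 20.0
    background_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise InvalidArgumentError("n_frames must be >= 1")
        if self.frame_interval <= 0:
            raise InvalidArgumentError("frame_interval must be > 0")
        if self.unit_intensity <= 0:
            raise InvalidArgumentError("unit_intensity must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class BindingScheme:
    """Per-site probe binding model for a multi-site receptor.

    Defaults reflect the seven effector binding sites of a HER2-HER3
    heterodimer (five on HER3, two on HER2).
    """

    n_sites: int = 7
    k_on_per_site: float = 0.1
    k_off_per_site: float = 0.1
    phospho_gated: bool = False
    probe_bleach_rate: float = 0.0

    def __post_init__(self):
        if self.n_sites < 1:
            raise InvalidArgumentError("n_sites must be >= 1")
        for name in ("k_on_per_site", "k_off_per_site", "probe_bleach_rate"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TelegraphParams:
    """Two-state pTyr generation/removal rates (s^-1)."""

    k_gen: float = 0.8
    k_rem: float = 0.58

    def __post_init__(self):
        if self.k_gen < 0 or self.k_rem < 0:
            raise InvalidArgumentError("rates must be >= 0")
        if self.k_gen == 0 and self.k_rem == 0:
            raise InvalidArgumentError("k_gen and k_rem cannot both be 0")

    @property
    def on_fraction(self) -> float:
        """Stationary fraction of time in the phosphorylated state."""
        return self.k_gen / (self.k_gen + self.k_rem)


@dataclass(frozen=True)
class FretScheme:
    """Emission model for a two-dye FRET pair with switching states.

    ``switch_rates[i, j]`` is the transition rate (s^-1) from efficiency
    state i to state j; the diagonal is ignored.  ``beta`` is the donor
    leakage factor, defined operationally as the acceptor-channel signal per
    unit *detected* donor signal on a donor-only sample, so the ideal
    detected channels at true efficiency E are::

        donor    = total * (1 - E) / (1 + beta)
        acceptor = total * (E + beta) / (1 + beta)

    Leaked photons are removed from the donor channel, which makes the
    standard leakage correction (Ia - beta*Id)/(Id + Ia) exact.
    """

    e_levels: tuple = (0.2, 0.8)
    switch_rates: tuple = ((0.0, 0.65), (0.35, 0.0))
    total_intensity: float = 500.0
    beta: float = 0.12
    donor_bleach_rate: float = 0.0
    acceptor_bleach_rate: float = 0.0
    acceptor_blink_rate: float = 0.0
    acceptor_recovery_rate: float = 1.0
    check_frames: int = 15

    def __post_init__(self):
        levels = np.asarray(self.e_levels, dtype=float)
        if np.any(levels < 0) or np.any(levels > 1):
            raise InvalidArgumentError("e_levels must lie in [0, 1]")
        if not (0 <= self.beta < 1):
            raise InvalidArgumentError("beta must lie in [0, 1)")
        rates = np.asarray(self.switch_rates, dtype=float)
        if rates.shape != (levels.size, levels.size):
            raise InvalidArgumentError("switch_rates must be square in e_levels")
        if np.any(rates - np.diag(np.diag(rates)) < 0):
            raise InvalidArgumentError("switch rates must be >= 0")

    def stationary(self) -> np.ndarray:
        """Stationary occupancy of the switching chain (sums to 1)."""
        q = np.asarray(self.switch_rates, dtype=float).copy()
        np.fill_diagonal(q, 0.0)
        k = q.shape[0]
        if k == 1:
            return np.ones(1)
        gen = q - np.diag(q.sum(axis=1))
        a = np.vstack([gen.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


@dataclass(frozen=True)
class MMParams:
    """Michaelis-Menten parameters: K_M in uM, k_cat_max in s^-1."""

    K_M: float = 29.2
    k_cat_max: float = 0.22

    def __post_init__(self):
        if self.K_M <= 0 or self.k_cat_max <= 0:
            raise InvalidArgumentError("K_M and k_cat_max must be > 0")

    def rate(self, atp_um):
        """Per-site catalytic rate at the given [ATP] (uM)."""
        s = np.asarray(atp_um, dtype=float)
        return self.k_cat_max * s / (self.K_M + s)


@dataclass(frozen=True)
class CompetitionParams:
    """Kinase-phosphatase competition under a reversible inhibitor.

    ``k_p`` is the intrinsic phosphorylation rate, ``k_dp`` the
    phosphatase-driven dephosphorylation rate (both s^-1);
    ``ic50_intrinsic`` is the inhibitor occupancy half-point (uM) and
    ``hill`` its cooperativity.
    """

    k_p: float = 0.8
    k_dp: float = 0.58
    ic50_intrinsic: float = 6.0
    hill: float = 1.0

    def __post_init__(self):
        for name in ("k_p", "k_dp", "ic50_intrinsic", "hill"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")

    def occupancy(self, conc_um):
        """Inhibitor occupancy theta(c) = c^h / (c^h + IC50^h)."""
        c = np.asarray(conc_um, dtype=float)
        ch = np.power(c, self.hill)
        return ch / (ch + self.ic50_intrinsic**self.hill)

    def steady_state_signal(self, conc_um, phosphatase_scale):
        """Normalised steady-state phospho signal.

        With phosphatase present (scale > 0) this is the telegraph
        steady-state occupancy f(c) = kp(1-th)/(kp(1-th) + s*kdp).  At
        scale exactly 0 the steady state is saturated and uninformative,
        so the observable is the phosphorylation rate itself, kp(1-th)
        (progress-slope readout of a no-phosphatase assay).
        """
        u = 1.0 - self.occupancy(conc_um)
        if phosphatase_scale == 0:
            return self.k_p * u
        return self.k_p * u / (self.k_p * u + phosphatase_scale * self.k_dp)


@dataclass
class GroundTruth:
    """Event list, per-frame true path and parameters of one simulation.

    ``events`` is a list of ``(time_s, kind, site_index)`` tuples with kind
    in {"bleach", "bind", "unbind", "state-switch"}; ``path`` is the
    per-frame true state (meaning depends on the simulator); ``params``
    records the full parameter set used, including the seed.
    """

    events: list = field(default_factory=list)
    path: np.ndarray | None = None
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary stochastic machinery
# ---------------------------------------------------------------------------


def _exp_time(rng, rate):
    """Exponential waiting time; inf for rate 0."""
    if rate <= 0:
        return math.inf
    return rng.exponential(1.0 / rate)


def _telegraph_events(rng, k_gen, k_rem, duration, start_on=False):
    """Switch times of a two-state chain on [0, duration).

    Returns (initial_state, [(time, new_state), ...]).
    """
    events = []
    state = 1 if start_on else 0
    t = 0.0
    init = state
    while True:
        rate = k_rem if state else k_gen
        t += _exp_time(rng, rate)
        if t >= duration:
            break
        state = 1 - state
        events.append((t, state))
    return init, events


def _events_to_path(init_state, events, n_frames, dt):
    """Point-sample a piecewise-constant event path onto the frame grid."""
    path = np.full(n_frames, init_state, dtype=int)
    for t, state in events:
        first = int(math.ceil(t / dt - 1e-12))
        if first < n_frames:
            path[first:] = state
    return path


# ---------------------------------------------------------------------------
# Trace simulators
# ---------------------------------------------------------------------------


def simulate_photobleaching_trace(n_fluors, cfg, bleach_rate=0.1):
    """Simulate one spot carrying ``n_fluors`` fluorophores that bleach.

    Each fluorophore bleaches at an independent exponential time with the
    given rate (s^-1); the recorded intensity at frame t is
    ``background + unit_intensity * surviving(t) + noise``.

    Returns
    -------
    (FluorescenceTrace, GroundTruth)
        Ground-truth events record the bleach times; ``path`` holds the
        per-frame number of surviving fluorophores.
    """
    if n_fluors < 0:
        raise InvalidArgumentError("n_fluors must be >= 0")
    if bleach_rate < 0:
        raise InvalidArgumentError("bleach_rate must be >= 0")
    rng = cfg.rng()
    t = cfg.time_grid()
    if bleach_rate > 0 and n_fluors > 0:
        bleach_times = np.sort(rng.exponential(1.0 / bleach_rate, n_fluors))
    else:
        bleach_times = np.full(n_fluors, np.inf)
    surviving = (t[:, None] < bleach_times[None, :]).sum(axis=1)
    noise = rng.normal(0.0, cfg.noise_sd, cfg.n_frames) if cfg.noise_sd else 0.0
    intensity = cfg.background_level + cfg.unit_intensity * surviving + noise
    events = [
        (float(bt), "bleach", i)
        for i, bt in enumerate(bleach_times)
        if bt < cfg.duration
    ]
    truth = GroundTruth(
        events=sorted(events),
        path=surviving.astype(int),
        params={"n_fluors": n_fluors, "bleach_rate": bleach_rate, **vars(cfg)},
    )
    trace = FluorescenceTrace(
        trace_id="bleach-0",
        time=t,
        intensity=np.atleast_1d(np.asarray(intensity, dtype=float)),
        frame_interval=cfg.frame_interval,
    )
    return trace, truth


def simulate_telegraph(params, duration, cfg):
    """Two-state continuous-time Markov path, sampled to the frame grid.

    The path starts in the off (dephosphorylated) state.  Returns a
    GroundTruth whose ``path`` is the 0/1 state at each frame time and whose
    events record every switch.
    """
    if duration <= 0:
        raise InvalidArgumentError("duration must be > 0")
    rng = cfg.rng()
    dt = cfg.frame_interval
    n_frames = max(1, int(round(duration / dt)))
    init, events = _telegraph_events(rng, params.k_gen, params.k_rem, duration)
    path = _events_to_path(init, events, n_frames, dt)
    truth = GroundTruth(
        events=[(t, "state-switch", 0) for t, _ in events],
        path=path,
        params={"k_gen": params.k_gen, "k_rem": params.k_rem, **vars(cfg)},
    )
    return truth


def _simulate_site(rng, scheme, driver, duration):
    """Gillespie trajectory of one binding site.

    Returns (events, occupancy_change_list) where occupancy changes are
    (time, occupied_bool).  Binding requires the site's pTyr state to be on
    when gated; dephosphorylation ejects a bound probe immediately.
    """
    gated = scheme.phospho_gated and driver is not None
    ptyr = not gated  # ungated sites behave as always-phosphorylated
    bound = False
    t = 0.0
    events = []
    occ = []
    while True:
        rates = {}
        if gated:
            rates["ptyr"] = driver.k_rem if ptyr else driver.k_gen
        if ptyr and not bound:
            rates["bind"] = scheme.k_on_per_site
        if bound:
            rates["unbind"] = scheme.k_off_per_site
            rates["bleach"] = scheme.probe_bleach_rate
        total = sum(rates.values())
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        r = rng.uniform(0, total)
        acc = 0.0
        for kind, rate in rates.items():
            acc += rate
            if r < acc:
                break
        if kind == "ptyr":
            ptyr = not ptyr
            events.append((t, "state-switch"))
            if not ptyr and bound:
                bound = False  # dephosphorylation ejects the probe
                events.append((t, "unbind"))
                occ.append((t, False))
        elif kind == "bind":
            bound = True
            events.append((t, "bind"))
            occ.append((t, True))
        elif kind == "unbind":
            bound = False
            events.append((t, "unbind"))
            occ.append((t, False))
        else:  # bleach: probe goes dark, site stays occupied but invisible
            bound = False
            events.append((t, "bleach"))
            occ.append((t, False))
    return events, occ


def simulate_binding_trace(scheme, ptyr_driver, cfg):
    """Simulate recurrent probe binding/unbinding on a multi-site receptor.

    Parameters
    ----------
    scheme : BindingScheme
    ptyr_driver : TelegraphParams or "always-on"
        Per-site pTyr telegraph dynamics gating binding when
        ``scheme.phospho_gated`` is set; pass ``"always-on"`` (or None) for
        constitutively available sites.
    cfg : SimConfig

    Returns (FluorescenceTrace, GroundTruth); the ground-truth ``path`` is
    the per-frame number of visibly occupied sites.
    """
    driver = None if ptyr_driver in (None, "always-on") else ptyr_driver
    rng = cfg.rng()
    t = cfg.time_grid()
    occupancy = np.zeros(cfg.n_frames, dtype=int)
    events = []
    for site in range(scheme.n_sites):
        site_events, occ_changes = _simulate_site(rng, scheme, driver, cfg.duration)
        events.extend((time, kind, site) for time, kind in site_events)
        site_path = _events_to_path(
            0, [(time, int(o)) for time, o in occ_changes], cfg.n_frames,
            cfg.frame_interval,
        )
        occupancy += site_path
    noise = rng.normal(0.0, cfg.noise_sd, cfg.n_frames) if cfg.noise_sd else 0.0
    intensity = cfg.background_level + cfg.unit_intensity * occupancy + noise
    truth = GroundTruth(
        events=sorted(events),
        path=occupancy,
        params={"scheme": vars(scheme), "driver": vars(driver) if driver else None,
                **vars(cfg)},
    )
    trace = FluorescenceTrace(
        trace_id="bind-0",
        time=t,
        intensity=np.asarray(intensity, dtype=float),
        frame_interval=cfg.frame_interval,
    )
    return trace, truth


def simulate_fret_trace(scheme, cfg):
    """Simulate one Cy3/Cy5 FRET trace with an acceptor-excitation check block.

    The first ``scheme.check_frames`` frames are excited at the acceptor
    wavelength (donor channel reads background; acceptor reads the full
    intensity while the acceptor dye is alive and not blinking).  Remaining
    frames follow the leakage emission model documented on
    :class:`FretScheme`.  The efficiency state starts from the stationary
    distribution of the switching chain.

    Returns (FretTrace, GroundTruth); ``path`` is the per-frame index into
    ``e_levels`` (-1 during the check block and after donor bleach).
    """
    rng = cfg.rng()
    n = cfg.n_frames
    dt = cfg.frame_interval
    cb = scheme.check_frames
    if cb >= n:
        raise InvalidArgumentError("check block must be shorter than the trace")
    levels = np.asarray(scheme.e_levels, dtype=float)
    k = levels.size

    # Efficiency state path over the whole recording (CTMC among levels).
    state = int(rng.choice(k, p=scheme.stationary()))
    t_now, states = 0.0, np.full(n, state, dtype=int)
    events = []
    rates = np.asarray(scheme.switch_rates, dtype=float).copy()
    np.fill_diagonal(rates, 0.0)
    while k > 1:
        out = rates[state].sum()
        t_now += _exp_time(rng, out)
        if t_now >= cfg.duration:
            break
        state = int(rng.choice(k, p=rates[state] / out))
        first = int(math.ceil(t_now / dt - 1e-12))
        if first < n:
            states[first:] = state
        events.append((t_now, "state-switch", 0))

    donor_bleach = _exp_time(rng, scheme.donor_bleach_rate)
    acceptor_bleach = _exp_time(rng, scheme.acceptor_bleach_rate)
    if donor_bleach < cfg.duration:
        events.append((donor_bleach, "bleach", 0))
    if acceptor_bleach < cfg.duration:
        events.append((acceptor_bleach, "bleach", 1))
    t = cfg.time_grid()
    donor_alive = t < donor_bleach
    acceptor_alive = t < acceptor_bleach
    if scheme.acceptor_blink_rate > 0:
        init, blink_events = _telegraph_events(
            rng, scheme.acceptor_recovery_rate, scheme.acceptor_blink_rate,
            cfg.duration, start_on=True,
        )
        acceptor_on = _events_to_path(init, blink_events, n, dt).astype(bool)
    else:
        acceptor_on = np.ones(n, dtype=bool)
    acceptor_ok = acceptor_alive & acceptor_on

    total, beta = scheme.total_intensity, scheme.beta
    e_true = levels[states]
    donor = np.zeros(n)
    acceptor = np.zeros(n)
    check = np.zeros(n, dtype=bool)
    check[:cb] = True
    # Acceptor-excitation check block.
    acceptor[check & acceptor_ok] = total
    # Donor-excitation analysis frames.
    analysis = ~check
    live = analysis & donor_alive
    e_eff = np.where(acceptor_ok, e_true, 0.0)  # dark acceptor: no transfer
    donor[live] = total * (1.0 - e_eff[live]) / (1.0 + beta)
    acceptor[live] = total * (e_eff[live] + beta) / (1.0 + beta)
    if cfg.noise_sd:
        donor = donor + rng.normal(0.0, cfg.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, cfg.noise_sd, n)
    donor = donor + cfg.background_level
    acceptor = acceptor + cfg.background_level

    path = np.where(analysis & donor_alive, states, -1)
    truth = GroundTruth(
        events=sorted(events),
        path=path,
        params={"scheme": vars(scheme), **vars(cfg),
                "donor_bleach_time": donor_bleach,
                "acceptor_bleach_time": acceptor_bleach},
    )
    trace = FretTrace(
        trace_id="fret-0",
        time=t,
        donor=donor,
        acceptor=acceptor,
        check_frames=cb,
        frame_interval=dt,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Count-data simulators
# ---------------------------------------------------------------------------


@dataclass
class ProgressCurve:
    """Observed pTyr spot counts versus reaction time at one [ATP]."""

    atp_um: float
    time_s: np.ndarray
    counts: np.ndarray
    n_molecules: int | None = None

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise InvalidArgumentError("counts must be >= 0")
        if self.time_s.size > 1 and not np.all(np.diff(self.time_s) > 0):
            raise InvalidArgumentError("time points must be increasing")


def simulate_progress_curves(mm, atp_concs, time_grid, n_molecules,
                             labeling_eff, cfg):
    """Binomially sampled phosphorylation progress curves.

    The per-site rate at [ATP]=S is ``k = k_cat_max * S / (K_M + S)``; the
    observed count at time t is Binomial(n_molecules, p) with
    ``p = labeling_eff * (1 - exp(-k t))``.  Counts are binomial rather
    than Poisson because the number of surface molecules in a field of view
    is fixed.
    """
    if not 0 <= labeling_eff <= 1:
        raise InvalidArgumentError("labeling_eff must lie in [0, 1]")
    atp = np.asarray(atp_concs, dtype=float)
    times = np.asarray(time_grid, dtype=float)
    if np.any(atp < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    if np.any(times < 0) or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise InvalidArgumentError("time grid must be non-negative increasing")
    rng = cfg.rng()
    curves = []
    for s in atp:
        k = float(mm.rate(s))
        p = labeling_eff * (1.0 - np.exp(-k * times))
        counts = rng.binomial(n_molecules, p)
        curves.append(
            ProgressCurve(atp_um=float(s), time_s=times,
                          counts=counts.astype(float),
                          n_molecules=n_molecules)
        )
    return curves


def expected_progress(mm, atp_um, time_grid, n_molecules, labeling_eff):
    """Noiseless expected counts n * lambda * (1 - exp(-k t))."""
    k = float(mm.rate(atp_um))
    t = np.asarray(time_grid, dtype=float)
    return n_molecules * labeling_eff * (1.0 - np.exp(-k * t))


def simulate_inhibition_series(comp, inhibitor_concs, phosphatase_scale,
                               replicates, noise_cv, cfg):
    """Dose-response activity table under kinase/phosphatase competition.

    Activity is reported as ``100 * g(c) / g(0)`` where g is the
    steady-state signal of :meth:`CompetitionParams.steady_state_signal`,
    with multiplicative Gaussian noise of coefficient ``noise_cv``.

    Returns a dict of ndarray columns: ``inhibitor_um``, ``replicate``,
    ``activity_pct``.
    """
    conc = np.asarray(inhibitor_concs, dtype=float)
    if np.any(conc < 0):
        raise InvalidArgumentError("concentrations must be >= 0")
    if phosphatase_scale < 0:
        raise InvalidArgumentError("phosphatase_scale must be >= 0")
    rng = cfg.rng()
    g0 = comp.steady_state_signal(0.0, phosphatase_scale)
    base = 100.0 * comp.steady_state_signal(conc, phosphatase_scale) / g0
    cols = {"inhibitor_um": [], "replicate": [], "activity_pct": []}
    for rep in range(replicates):
        noise = rng.normal(0.0, noise_cv, conc.size) if noise_cv > 0 else 0.0
        activity = np.clip(base * (1.0 + noise), 0.0, None)
        cols["inhibitor_um"].append(conc)
        cols["replicate"].append(np.full(conc.size, rep))
        cols["activity_pct"].append(activity)
    return {k: np.concatenate(v) for k, v in cols.items()}


# ---------------------------------------------------------------------------
# Spot fields and movie rendering
# ---------------------------------------------------------------------------


def sample_spot_positions(n, area_um2, cfg):
    """Uniform spot positions within a (width, height) field in um.

    Returns an (n, 2) array of (x, y) coordinates.
    """
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    w, h = area_um2
    rng = cfg.rng()
    pos = rng.uniform(0.0, 1.0, size=(n, 2))
    pos[:, 0] *= w
    pos[:, 1] *= h
    return pos


def _psf_weights(row, col, sigma, h, w, radius=None):
    """Pixel-integrated 2-D Gaussian PSF weights around (row, col)."""
    if radius is None:
        radius = max(3, int(math.ceil(4 * sigma)))
    r0 = max(0, int(math.floor(row)) - radius)
    r1 = min(h, int(math.floor(row)) + radius + 1)
    c0 = max(0, int(math.floor(col)) - radius)
    c1 = min(w, int(math.floor(col)) + radius + 1)
    rr = np.arange(r0, r1)
    cc = np.arange(c0, c1)
    s = sigma * math.sqrt(2.0)
    fr = 0.5 * (special.erf((rr + 0.5 - row) / s) - special.erf((rr - 0.5 - row) / s))
    fc = 0.5 * (special.erf((cc + 0.5 - col) / s) - special.erf((cc - 0.5 - col) / s))
    return (slice(r0, r1), slice(c0, c1)), np.outer(fr, fc)


def render_movie(positions, traces, psf_sigma_px, shape, cfg):
    """Render spot traces into a noisy image stack.

    Parameters
    ----------
    positions : sequence of (row, col)
        Spot centres in pixel coordinates (0-based, origin top-left); every
        position must lie inside the frame.
    traces : sequence of FluorescenceTrace
        One per position; each frame's value is the spot's *integrated*
        intensity, which is conserved up to PSF truncation.
    psf_sigma_px : float
        Gaussian PSF standard deviation in pixels.
    shape : (h, w, n_frames)

    Returns an (n_frames, h, w) float array including background and noise.
    """
    h, w, n_frames = shape
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    if len(positions) != len(traces):
        raise InvalidArgumentError("positions and traces lengths differ")
    for r, c in positions:
        if not (0 <= r < h and 0 <= c < w):
            raise InvalidArgumentError("position outside frame")
    rng = cfg.rng()
    stack = np.full((n_frames, h, w), float(cfg.background_level))
    for (r, c), trace in zip(positions, traces):
        if trace.n_frames < n_frames:
            raise InvalidArgumentError("trace shorter than movie")
        window, weights = _psf_weights(r, c, psf_sigma_px, h, w)
        amp = trace.intensity[:n_frames]
        stack[(slice(None), *window)] += amp[:, None, None] * weights[None]
    if cfg.noise_sd:
        stack += rng.normal(0.0, cfg.noise_sd, stack.shape)
    return stack
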