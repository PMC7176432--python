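"""Bundled parameter-recovery studies with published reference conditions.

Each study simulates a complete experiment with known ground truth taken
from the reference single-molecule characterisation of HER2-HER3
heterodimers and ligand-free HER2 complexes, runs the full analysis
pipeline on the synthetic data, and returns the recovered quantities.
These are the end-to-end exercises the package is validated against.
"""

from __future__ import annotations

import numpy as np

from smtrace import fret, kinetics, simkit, steps

# Reference ground-truth conditions (inputs to the simulations).
HETERODIMER_MM = simkit.MMParams(K_M=29.2, k_cat_max=0.22)
LIGAND_FREE_MM = simkit.MMParams(K_M=16.46, k_cat_max=1.4e-3)
EQUILIBRIUM_TELEGRAPH = simkit.TelegraphParams(k_gen=0.8, k_rem=0.58)
HETERODIMER_IC50_UM = 6.0
LIGAND_FREE_IC50_UM = 0.7
HETERODIMER_LOW_E_FRACTION = 0.35

ATP_GRID_UM = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)
# Geometric reaction-time grid: slowest curve reaches >98% saturation,
# fastest keeps >= 3 pre-saturation points.  The ligand-free kinetics are
# ~150x slower, so its grid is stretched by the same factor.
TIME_GRID_S = (2.0, 5.0, 12.0, 30.0, 75.0, 150.0, 300.0, 600.0)
LIGAND_FREE_TIME_STRETCH = 150.0


def michaelis_menten_recovery(mm=HETERODIMER_MM, time_grid=TIME_GRID_S,
                              atp_grid=ATP_GRID_UM, n_molecules=500,
                              labeling_eff=0.8, seed=0):
    """Progress curves -> per-[ATP] exponential rates -> MM fit.

    Returns the :class:`~smtrace.kinetics.MMFit` recovered from binomially
    sampled progress curves generated under ``mm``.
    """
    cfg = simkit.SimConfig(n_frames=1, seed=seed)
    curves = simkit.simulate_progress_curves(
        mm, atp_grid, time_grid, n_molecules, labeling_eff, cfg
    )
    rates, errors = [], []
    for curve in curves:
        k, _, se = kinetics.fit_progress_curve(curve, with_stderr=True)
        rates.append(k)
        errors.append(se)
    return kinetics.fit_michaelis_menten(rates, np.asarray(atp_grid),
                                         stderr=errors)


def telegraph_recovery(params=EQUILIBRIUM_TELEGRAPH, n_paths=200,
                       duration_s=300.0, frame_interval=0.1, seed=0):
    """Dwell-time rate estimation over simulated telegraph trajectories."""
    paths = []
    for i in range(n_paths):
        cfg = simkit.SimConfig(
            n_frames=int(round(duration_s / frame_interval)),
            frame_interval=frame_interval, seed=seed + i,
        )
        paths.append(simkit.simulate_telegraph(params, duration_s, cfg).path)
    return kinetics.estimate_telegraph_rates(paths, frame_interval)


def ic50_recovery(ic50_um=HETERODIMER_IC50_UM, replicates=10,
                  noise_cv=0.05, seed=0):
    """Dose-response fit to a simulated lapatinib inhibition series.

    Half-log concentration grid 0.01-100 uM; the no-phosphatase readout is
    the phosphorylation rate, so the intrinsic IC50 is the ground truth.
    """
    comp = simkit.CompetitionParams(ic50_intrinsic=ic50_um)
    concs = 10.0 ** np.arange(-2.0, 2.01, 0.5)
    table = simkit.simulate_inhibition_series(
        comp, concs, 0.0, replicates, noise_cv,
        simkit.SimConfig(n_frames=1, seed=seed),
    )
    return kinetics.fit_dose_response(table["activity_pct"],
                                      table["inhibitor_um"])


def single_step_percentage(n_traces=500, n_frames=600, bleach_rate=0.1,
                           seed=0):
    """Percentage of single-eGFP traces classified as exactly one step.

    Traces carry one fluorophore at 80 A.U. with 20 A.U. readout noise
    (SNR 4) and bleach at 0.1 s^-1 over 60 s at 0.1 s/frame.
    """
    single = 0
    for i in range(n_traces):
        cfg = simkit.SimConfig(n_frames=n_frames, seed=seed + i)
        trace, _ = simkit.simulate_photobleaching_trace(
            1, cfg, bleach_rate=bleach_rate
        )
        single += steps.count_bleach_steps(trace) == 1
    return 100.0 * single / n_traces


def fret_low_population(low_occupancy=HETERODIMER_LOW_E_FRACTION,
                        n_traces=300, n_frames=615, seed=0):
    """Low-FRET framewise percentage through filters and histogram.

    Dynamic two-state traces at E = 0.2/0.8, beta 0, per-channel noise
    42 A.U. on a 500 A.U. pair (E SD ~ 0.07), switching rates totalling
    1 s^-1 split to give the requested stationary low-E occupancy, and
    modest donor bleaching (0.008 s^-1; donor-bleached frames are excluded
    frame-wise, so bleaching does not bias the histogram).
    """
    k_low_to_high = (1.0 - low_occupancy) * 1.0
    k_high_to_low = low_occupancy * 1.0
    traces = []
    for i in range(n_traces):
        scheme = simkit.FretScheme(
            e_levels=(0.2, 0.8),
            switch_rates=((0.0, k_low_to_high), (k_high_to_low, 0.0)),
            beta=0.0,
            total_intensity=500.0,
            donor_bleach_rate=0.008,
        )
        cfg = simkit.SimConfig(n_frames=n_frames, noise_sd=42.0, seed=seed + i)
        trace, _ = simkit.simulate_fret_trace(scheme, cfg)
        trace.trace_id = f"fret-{i:04d}"
        traces.append(trace)
    kept, _ = fret.filter_fret_traces(traces)
    dist = fret.efficiency_distribution(kept, beta=0.0)
    return 100.0 * dist.low_e_fraction
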