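# smtrace

Single-molecule TIRF trace analysis for immunoprecipitated receptor
complexes — photobleaching step counting, smFRET conformational
populations, and single-complex enzyme kinetics — together with a
synthetic-data generator that produces every input class with known
ground truth.

## Who this is for

Single-molecule pull-down / co-IP experiments immobilise antibody-captured
protein complexes (here, HER2–HER3 receptor heterodimers and ligand-free
HER2 complexes) sparsely on a passivated surface, so that each
diffraction-limited fluorescent spot reports on one complex.  From movies
of such surfaces one wants to know, per complex:

- **how many labelled subunits or bound effectors it carries** — read out
  as discrete intensity steps (one eGFP ≈ 80 A.U.; traces are scaled by
  800 A.U. so one probe = 0.1 scaled units);
- **what conformation its cytoplasmic domains adopt** — read out as smFRET
  efficiency *E* = I_a/(I_d + I_a) between Cy3/Cy5 labels, with donor
  leakage β ≈ 0.12 corrected as (I_a − βI_d)/(I_d + I_a) and a threshold
  at *E* = 0.5 splitting assembled from dissociated kinase-domain dimers;
- **how fast it phosphorylates substrate tyrosines** — progress curves
  N(t) = N_max(1 − e^(−kt)) at a ladder of [ATP] give per-complex rates,
  fitted by Michaelis–Menten k([S]) = k_cat,max·[S]/(K_M + [S]);
- **its kinase/phosphatase balance and drug response** — two-state
  telegraph dynamics of a pTyr site (generation/removal rates from dwell
  times) and logistic inhibition curves (IC50, Hill).

## What is inside

| module | role |
| --- | --- |
| `smtrace.simkit` | synthetic movies, traces, FRET pairs, progress curves, inhibition series — all with ground truth and seeds |
| `smtrace.imaging` | boxcar background subtraction, local-maximum spot detection, 3×3-ROI trace extraction |
| `smtrace.steps` | exact change-point segmentation (dynamic programming, Gaussian emissions), BIC state-number selection with piecewise-linear knee, bleach-step and bound-probe counting, level calibration, dwell gaps |
| `smtrace.fret` | apparent/corrected efficiency, trace-exclusion rules, framewise efficiency distributions, two-state occupancy |
| `smtrace.kinetics` | progress-curve, Michaelis–Menten, exponential-dwell, telegraph and dose–response fitters; spot-density geometry |
| `smtrace.studies` | bundled end-to-end parameter-recovery studies at the reference conditions |
| `smtrace.pipeline` / `smtrace.cli` | reproducible multi-stage runs (`smtrace run`, `detect`, `trace`, `steps`, `fret`, `mm`, `ic50`, `telegraph`) with manifests and child seeds |

The level-fitting model is deliberately a *segmentation* model, not an EM
HMM: the dynamic program returns the exact likelihood optimum, which is
testable against brute-force enumeration.  Heterogeneous binding traces
are handled the standard two-stage way: level positions are calibrated
once from the brightest spots, then held fixed while each trace's state
path is decoded.

## Worked example

```python
from smtrace import kinetics, studies

# 1. stoichiometry by photobleaching step counting
pct = studies.single_step_percentage(n_traces=200, seed=0)
print(f"single-step fraction: {pct:.1f}% of 200 traces")

# 2. enzyme kinetics through the full pipeline
fit = studies.michaelis_menten_recovery(seed=0)
print(f"recovered K_M = {fit.K_M:.1f} uM, k_cat,max = {fit.k_cat_max:.3f} 1/s")

# 3. phosphorylation/dephosphorylation equilibrium
tel = studies.telegraph_recovery(n_paths=50, seed=0)
print(f"recovered k_gen = {tel.k_gen:.2f} 1/s, k_rem = {tel.k_rem:.2f} 1/s")

# 4. conformational populations by smFRET
low = studies.fret_low_population(n_traces=150, seed=0)
print(f"low-FRET population: {low:.1f}% of frames below E = 0.5")

# 5. spot-density geometry
d = kinetics.mean_inter_spot_distance(1000, (40.0, 80.0))
print(f"mean inter-spot distance at 1000 spots / 40x80 um^2: {d:.2f} um")
```

prints

```
single-step fraction: 98.5% of 200 traces
recovered K_M = 29.1 uM, k_cat,max = 0.222 1/s
recovered k_gen = 0.80 1/s, k_rem = 0.58 1/s
low-FRET population: 34.2% of frames below E = 0.5
mean inter-spot distance at 1000 spots / 40x80 um^2: 1.79 um
```

Reading the numbers: 98.5% of simulated single-eGFP spots classify as
exactly one photobleaching step (a mostly-monomeric preparation would
print ≥ 90%).  The Michaelis–Menten study simulates binomially sampled
progress curves under ground truth K_M = 29.2 μM, k_cat,max = 0.22 s⁻¹
and recovers both through the full exponential-fit → MM-fit pipeline.
The telegraph study recovers pTyr generation/removal rates of
0.8/0.58 s⁻¹ from frame-sampled dwell times, and the FRET study returns
the low-*E* (dissociated-dimer) population of a two-state scheme whose
stationary low-state occupancy was set to 35%.  Finally, 1000 complexes
in a 40 × 80 μm² field sit ~1.79 μm apart on average — sparse enough
that each spot is a single complex.

## Command line

```
smtrace simulate --seed 1 --n-traces 50 --out run/
smtrace steps --traces run/traces.tsv --scale 800 --kmax 8 --out run/
smtrace detect --stack movie.tif --out rois.tsv
smtrace telegraph --paths paths.tsv --dt 0.1 --out run/
```

Traces travel as TSV tables (`trace_id, frame, time_s, intensity` or
`…, donor, acceptor`), movies as multi-frame 16-bit grayscale TIFF, and
every pipeline run writes a manifest with the config hash, per-stage
child seeds and output checksums.

See `docs/methods.md` for the models, parameter choices, and known
limitations.
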