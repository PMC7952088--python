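# polfret

Single-molecule FRET analysis of DNA polymerase I domain switching:
trace simulation, correction and selection, global hidden-Markov
idealization, state statistics, dwell-time kinetics and binding-affinity
estimation.

## The scientific problem

*E. coli* DNA polymerase I (Pol I) carries three activities — DNA synthesis
(*pol* domain), proofreading (*exo* domain) and 5' flap removal
(*5' nuc* domain) — and a bound DNA substrate can move between these sites
during a single encounter with the enzyme. smFRET experiments watch this
directly: a donor/acceptor pair reports the distance between a labeled DNA
(or labeled protein) and its partner at 100 ms time resolution, producing
per-molecule intensity trajectories that hop between discrete FRET levels.
Under the donor-on-DNA labeling scheme the states are

| state | meaning                              | apparent E |
|-------|--------------------------------------|-----------|
| U     | unbound DNA                          | ~0 (donor only) |
| P     | DNA engaging the *pol* domain        | ~0.8 |
| N     | DNA engaging the *5' nuc* domain     | ~0.6 |
| E     | DNA engaging the *exo* domain        | ~0.6 (resolved via an exo-site mutant) |

This package implements the complete analysis such trajectories require,
and — because the quantities of interest are kinetic — ships a
continuous-time-Markov-chain trace simulator so every stage can be
validated by parameter recovery against known ground truth.

## Methods at the core

* **FRET efficiency** per frame from corrected intensities:
  `E = I_A / (I_A + I_D)`, after subtracting the post-photobleach median
  background in each channel and removing donor leakage
  (`I_A <- I_A - alpha I_D`).
* **Trace selection**: anti-correlated channel fluctuations, constant total
  intensity, and a single-step photobleach.
* **Global HMM**: one Gaussian-emission hidden Markov model trained by
  Baum-Welch EM on *all* selected traces of a condition simultaneously;
  per-trace idealization by exact Viterbi decoding.
* **State statistics**: composite histograms by Gaussian-kernel density
  estimation (bandwidth 0.04); frame-weighted state populations with
  trace-bootstrap uncertainties; transition density plots from
  adjacent-dwell median-E pairs, with unbound dwells drawn at E = -0.2.
* **Dwell kinetics**: dwell-time histograms with Freedman-Diaconis bin
  widths `w = 2 IQR(x) N^(-1/3)` fit by a single exponential give each
  state's observed decay rate, `k_obs^P = k_P->N + k_P->U`; bootstrap
  transition frequencies (50 traces x 50 reps) split it into microscopic
  rate constants via `k_P->N / k_P->U = f_P->N / f_P->U`.
* **Binding affinity**: `Kd = [Pol]_T / f_B - [Pol]_T` from the fraction of
  frames bound at known protein concentration (5 nM).
* **Distances**: the Forster relation `E = 1 / (1 + (r/R0)^6)` with
  R0 = 52 A converts state FRET means to donor-acceptor distances.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (bulky per-frame artifacts go to `scratch/analysis/`, summary tables
to `results/analysis/`):

```bash
python analysis/01_simulate_traces.py
python analysis/02_correct_and_idealize.py
python analysis/03_state_statistics.py
python analysis/04_dwell_kinetics.py
python analysis/05_binding_and_distances.py
```

Abridged output of one run:

```
wrote 200 traces to .../scratch/analysis/traces.h5
stationary occupancies (U, P, N): 0.333, 0.476, 0.190
QC selected 186/200 traces (93.0%)
state FRET means: 0.061, 0.600, 0.799
bound-state populations (fraction of bound frames):
  state 1: 0.256 +/- 0.008 (stationary 0.286)
  state 2: 0.744 +/- 0.008 (stationary 0.714)
TDP built from 3454 dwell-to-dwell transitions (unbound dwells at E = -0.2)
exo-mutant decomposition: E state 0.15, corrected N 0.59 +/- 0.028
half-bound fixture (true Kd 5 nM): Kd = 5.39 +/- 0.48 nM
P -> N distance change: +7.3 A
 state  fret_mean  distance_A
     1      0.600        48.6
     2      0.799        41.3
```

Reading the numbers: the global HMM recovers the three FRET levels the
traces were generated from (0.05/0.6/0.8); the fraction of bound frames in
each bound state tracks the stationary distribution of the generating
kinetic scheme; the mutant-difference decomposition splits a 74% 0.6-FRET
population into a 15% exo-engaged and 59% 5'-nuclease-engaged part; and
the 0.8 -> 0.6 FRET change corresponds to a ~7 A lengthening of the
donor-acceptor distance at R0 = 52 A.

The same pipeline is available as a CLI:

```bash
polfret simulate --n-traces 200 --duration 60 --seed 1 --out traces.h5
polfret analyze --traces traces.h5 --n-states 3 --seed 1 --out results/run
polfret report results/run
```

## File formats

**HDF5 trace files** (`trace_io.write_traces` / `read_traces`): root
attributes `frame_dt` (s), `schema_version` and free-form metadata; one
group per trace (its id) with float datasets `donor` and `acceptor`
(camera a.u.) and optional attributes `bleach_index`, `selected`.
`read_traces(path, compat=True, dataset_map=...)` ingests externally
produced files: channel datasets can be renamed via the mapping and a
missing `frame_dt` defaults to 0.1 s with a logged warning.

**Idealized paths** (`export_idealized` / `read_idealized`): tidy CSV with
columns `trace_id, frame, time_s, E, state_label` (only analyzed frames).

**Other tables**: `qc_summary.csv` (per-trace criteria and verdict),
`populations.csv` (state, population, population_sd, n_frames),
`rates.csv` (from_state, to_state, k_micro, k_micro_sd, k_obs, k_obs_se,
frequency, frequency_sd), `binding.csv`, `distances.csv`, and per-state
KDE grids `density_state*.csv`.

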