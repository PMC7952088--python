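# Methods

This note documents the models, defaults and numerical choices behind
`polfret`, in the order data flows through the pipeline.

## Kinetic trace simulator

Pol I-DNA dynamics are modeled as a continuous-time Markov chain over a
configurable set of configurations (unbound U, pol-engaged P,
5'-nuclease-engaged N, exo-engaged E, and the protein-labeled P' form).
Dwell times in state *i* are exponential with the total exit rate
`k_i = sum_j k_i->j`; the successor is drawn proportional to the outgoing
rate constants (Gillespie realization). Unless a start state is given,
trajectories start in the stationary distribution, so time averages match
ensemble averages from the first frame.

**Frame quantization.** The camera integrates for `frame_dt` (default
0.1 s); each frame is labeled with the state occupying the majority of its
interval (ties toward the lower state index). This reproduces the key
artifact of real measurements — events shorter than about one frame are
invisible — but *not* partial-frame intensity averaging: a frame is
rendered entirely from its majority state, so genuine cameras show slightly
more intermediate-level frames at transitions than the simulator does.

**Rendering.** A signal-bearing frame in state *s* emits
`total_intensity` a.u. split `(1-E, E)` between donor and acceptor, where
`E ~ Normal(fret_mean_s, fret_sd_s)` per frame models photophysical
broadening. Donor leakage adds `alpha * donor` to the acceptor; both
channels then receive their additive background and Gaussian read noise.
Under labeling scheme 2 (donor on the protein) unbound frames carry no
signal at all; under scheme 1 (donor on the DNA) the unbound state is
rendered from its own FRET signature (default 0.05, the small residual
acceptor signal of a donor-only species), which makes the efficiency
ratio an exact inverse of the rendering at zero noise for every state.
A donor bleach time is drawn `Exponential(bleach_rate)`; from that frame
on both channels contain only background and noise.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| total_intensity | 350 a.u. | single-molecule acceptor level of the acquisition setup being emulated |
| fret_sd | 0.07 | width of the observed state peaks |
| noise_sd | 10 a.u./channel | small additive camera noise; contributes ~0.02 to the E width at 350 a.u. |
| background_d, background_a | 20, 15 a.u. | typical channel offsets; removed by the median rule |
| leakage_alpha | 0.08 | typical donor-into-acceptor bleed-through for this dye pair |
| bleach_rate | 0.05 /s | most traces bleach within a 60 s observation, leaving enough post-bleach frames to estimate the background |

Per-trace randomness comes from `numpy.random.SeedSequence(seed).spawn`,
so datasets are bit-reproducible and traces are independent.

**What the generator does not emulate:** shot (Poisson) noise, triplet
blinking, acceptor direct excitation, detection-efficiency (gamma)
asymmetry, baseline drift, multi-step or acceptor bleaching, and spectral
crosstalk beyond the single leakage coefficient. Parameter-recovery tests
therefore demonstrate the *analysis* is correct and unbiased under the
stated noise model; they do not certify robustness to artifacts the
generator omits.

## Correction and selection

Background is the per-channel median of the post-bleach signal (at least
10 post-bleach frames; a configured static background is the fallback).
Leakage correction subtracts `alpha * donor` from the acceptor, clipped at
zero. The apparent efficiency `E = I_A / (I_A + I_D)` is reported clipped
to [0, 1], with unclipped values retained (`E_raw`).

Photobleach detection: the total intensity is median-filtered (window 5);
the bleach is the start of the final run at or below
`background + 3 sigma`, with sigma a robust noise estimate from successive
differences. A trace whose maximum never clears the background band by 6
sigma has no detectable bleach. Step counting merges adjacent significant
decrements (`> max(5 sigma, 10%% of the dynamic range)`) within one window.

Selection requires all three of: Pearson correlation of frame-to-frame
donor/acceptor changes below -0.2 over the pre-bleach region; coefficient
of variation of the pre-bleach total below 0.25; exactly one detected
step, ending at background. The thresholds are package defaults standing
in for by-eye selection, and are exposed in the pipeline config. Traces
that never bleach are rejected (by design — background cannot be
estimated), which caps the acceptance rate near the bleach probability
within the observation window (~93% under the default conditions).

Under labeling scheme 2, binding is detected as total intensity above half
the 90th percentile of the pre-bleach total for at least 2 consecutive
frames; the fluctuation criteria are evaluated over signal-bearing frames,
and a final signal loss is indistinguishable from a bleach, so the
single-step criterion reduces to requiring it to persist to the end.

## Global HMM and idealization

One Gaussian-emission HMM is shared by all selected traces of a condition:
means, variances, transition matrix and initial probabilities are estimated
by Baum-Welch EM with classic per-frame scaling, vectorized across traces
(each contiguous analysis segment is an independent observation sequence).
Initialization is k-means on the pooled efficiencies plus 5 seeded random
restarts; the best final likelihood wins. Defaults: tolerance 1e-4 nats,
max 500 iterations, variance floor 1e-4. States are canonically ordered by
ascending mean, making results invariant to initialization order.

The HMM consumes the *unclipped* efficiencies: clipping at zero would put
a point mass there that a Gaussian emission cannot represent. Clipped
values remain the reported/plotted quantity. Note that the mandated
acceptor clip in the leakage correction still leaves an exact spike at
E = 0 inside the unbound population; model-selection criteria notice it —
BIC on full scheme-1 datasets happily spends a fourth component splitting
the unbound peak. `select_n_states` therefore returns its full BIC table
so the physically meaningful count can be chosen, mirroring how state
counts are chosen by inspection in practice; on clean well-separated data
it selects the true count.

Idealization is exact Viterbi decoding in log space (ties toward the lower
state index), per contiguous segment; unanalyzed frames carry label -1 and
dwells never bridge gaps. Scheme-2 models operate on bound segments only,
since unbound frames carry no FRET information.

## State statistics

Composite histograms pool all frames assigned to a state across traces and
apply a Gaussian KDE (bandwidth 0.04 on the E axis, 500-point grid over
[-0.3, 1.2]). Populations are frame-weighted fractions over *bound* states
(the unbound state is excluded from the denominator), with SDs from a
200-rep trace-level bootstrap. Transition density plots place one point
per adjacent dwell pair at the median E of each dwell; dwells in the
unbound configuration enter at the -0.2 sentinel, putting association and
dissociation events on a distinct row/column of the plot. The grid extends
to -0.3 so the sentinel peaks render.

The wild-type-vs-exo-mutant correction splits a shared-FRET population:
`exo_fraction = pop_wt - pop_mut` (floored at zero; a mutant increase
beyond 2 SD triggers a warning), `corrected_N = pop_wt - exo_fraction`,
SD by quadrature.

## Dwell kinetics

Dwells are maximal same-state runs; the first and last dwell of every
contiguous analysis region are censored (their true extent is unknown) and
excluded from decay fits by default. For exponential dwells the censored
pieces are themselves exponential by memorylessness, so with dwells much
shorter than the observation window the exclusion is harmless; when dwells
are comparable to the window it is the *exclusion* that biases rates
upward (complete dwells are selected short), which the test suite
demonstrates. Transitions into a bleach or gap boundary are never counted
as events.

Observed decay rates come from density-normalized dwell histograms fit
with `A exp(-k t)` (both free) by least squares. Bin widths follow the
Freedman-Diaconis rule with two discretization safeguards for
frame-quantized dwells: widths round to whole frames with edges on
half-frame boundaries (otherwise bins alternately hold one and two of the
discrete duration values and the histogram develops a sawtooth), and bins
below a two-frame time-resolution cutoff are excluded from the fit — the
camera undercounts sub-frame dwells, and with the amplitude free the early
bins add no information about the decay. A censoring-naive maximum
likelihood estimate (1/mean) is reported as a cross-check.

Transition frequencies and their SDs come from a bootstrap (50 traces
sampled with replacement, 50 repetitions, seeded). Microscopic rate
constants follow from `k_i->j = k_obs_i * f_i->j / sum_j' f_i->j'`, with
first-order error propagation treating the fitted rate and the
frequencies as independent; by construction the microscopic rates out of
each state sum exactly to its observed rate.

**Missed-event correction.** At 100 ms frames, dwells around one frame are
partly invisible: quantization drops sub-half-frame events and Viterbi
suppresses single-frame excursions whose emission evidence does not beat
the transition penalty. Undetected events lengthen flanking dwells
(observed rates biased low) and vanish from the frequency counts
(branching ratios biased toward the slower channel) — about -17% on the
fastest exchange rates under the default conditions, even though the
EM-fitted transition matrix itself is essentially unbiased. Because the
generative model is available, the recovery estimator removes this bias by
a parametric bootstrap: it re-simulates datasets of the same size from the
fitted rates, runs the identical analysis, and divides out each rate's
multiplicative bias factor (3 replicate simulations by default; raw
estimates are always retained alongside). After correction all five rates
of the benchmark scheme are recovered within a few percent on average;
the residual seed-to-seed spread of the fastest rates is roughly 10%,
dominated by the histogram fit.

## Binding affinity and distances

`f_B` is the fraction of analyzed frames in any bound state, with a
trace-bootstrap SD; `Kd = [Pol]_T / f_B - [Pol]_T` at the default
5 nM protein concentration, with the SD by the delta method. `f_B = 0`
yields an infinite Kd with a warning rather than an error.

Distances use the Forster relation with R0 = 52 A by default — the unique
radius (to the nearest Angstrom) jointly consistent with the distances
this labeling system attributes to its FRET states (~49 A at E = 0.6,
~60 A at E = 0.3, and a ~7 A lengthening for 0.8 -> 0.6). No per-state R0
differences or orientation-factor modeling are attempted.

## Benchmark problem sizes

The standard rate-recovery benchmark uses 200 traces of 60 s at 100
ms/frame under the U <-> P <-> N scheme with rates
(k_P->N, k_N->P, k_P->U, k_N->U, k_U->P) = (1.0, 2.0, 0.5, 0.5, 1.0) /s;
the Kd benchmark uses 150 two-state traces with k_on = k_off = 0.5 /s
(stationary bound fraction 0.5, true Kd = 5 nM at 5 nM protein). These
sizes give ~2-4 x 10^3 fit-eligible dwells per bound state and a bound
fraction SE near 0.01 — enough to separate estimator bias from sampling
noise while keeping a full recovery run to a couple of minutes on one CPU.

## Known limitations

* The missed-event correction assumes the generative model family is
  correct; on real data with photophysics outside the noise model the
  bias factors would inherit that mismatch.
* The exponential-histogram fit's reported SE understates its real
  variability (unweighted least squares on correlated bins); the bootstrap
  SDs on frequencies and populations are the more trustworthy
  uncertainties.
* Scheme-2 analyses cannot distinguish a final unbinding from a bleach;
  binding statistics there treat the trace end conservatively.
* No gamma correction or acceptor direct-excitation correction: all
  efficiencies are apparent, matching how the state assignments and
  distances are defined.
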