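# Methods

`oswm` implements the spike-train analyses used to study observational
spatial working memory (oSWM): an observer rat watches a demonstrator choose
a T-maze arm and, after a short delay, must run the same arm itself. The
package quantifies (i) trajectory selectivity of anterior cingulate (ACC)
units in the maze and in the observation box, (ii) sharp-wave-ripple-
associated population bursts in CA1, (iii) Bayesian replay decoding of those
bursts against place-cell templates, and (iv) trial-by-trial coupling
between ACC cells and CA1 ensembles. A synthetic session generator with
ground truth makes every stage testable without recorded data.

## Time base and containers

All times are session-relative seconds. Every interval in the package is
half-open, `[start, end)`, so binning and restriction never double-count a
boundary spike; `IntervalSet` provides exact set algebra (intersection,
subtraction, union, membership) used for lap masks, stop masks and water
periods. Sessions are plain-text CSV bundles (spikes, position, trials,
intervals, units) plus a YAML manifest, written with a fixed `%.9g` float
format so identical sessions are byte-identical on disk.

## Behavioural quantification

- **Stop periods**: maximal runs with speed < 5 cm/s lasting > 3 s,
  excluded from all running-rate computations.
- **Delay period**: the 2 s before the observer's first rewarded poke in
  the box, `[t_poke - 2, t_poke)`. The demonstrator's choice-point crossing
  precedes the poke, so the delay window covers the observation epoch.
- **Poke performance curve**: observer poke times aligned to the
  demonstrator's maze poke (time 0), 0.25 s bins over ±10 s. "Normalised"
  is read as sum-normalisation over the window (the curve sums to 1); a
  per-trial-normalised average is available because the session-total and
  per-trial readings are both defensible.
- **Maze performance**: fraction of correct trials.

## Selectivity and difference indices

A unit's maze rate per trial divides spikes during active running (laps
minus stops, outbound and inbound combined per side) by the running time.
The selectivity index is

    SI = (FR_right - FR_left) / (FR_right + FR_left),

bounded in [-1, 1], undefined (NaN, excluded with a log entry) at 0/0. A
cell is *selective* when its per-trial left and right rates differ by a
two-sided two-sample t-test at alpha = 0.05. The plain reading of
"t-test" is Student's equal-variance test; Welch is a config flag. Maze
selectivity uses correct trials only; box (delay-period) selectivity
defaults to correct trials for symmetry, with an all-trials option, since
the source convention is not stated.

The chance level of same-side (maze and box labels agree) selectivity is
estimated by permuting each cell's delay rates across the pooled
left+right trials — a label permutation that preserves each cell's rate
multiset — re-classifying, and recounting the fraction 1000 times. The
observed fraction is z-scored against this null and p is the one-sided
normal tail (the convention is pinned by the reported pairing Z = 4.1 <->
p = 2.1e-5). If the null has zero spread, the empirical rank p is reported
instead, with a flag.

The difference index DI applies the same functional form to correct- vs
error-trial delay rates on a cell's preferred side. Cells need >= 3 error
trials on that side; the population mean DI is tested against 0 by a
two-sided one-sample t-test, and the fraction of individually significant
positive-DI cells is compared with a correct/error label-permutation null.

## Population-burst (SWR) detection

All CA1 spikes are binned at 10 ms, smoothed with a Gaussian kernel of
sigma = 2 bins (truncated at ±4 sigma and renormalised at the edges), and
min-max standardised to [0, 1]. The standardisation window is the whole
session — the simplest faithful reading of "standardised from 0 to 1" — so
detection is *relative*: adding a constant spike-count offset changes the
scale and hence the detected set, which is tested and documented rather
than hidden. A burst is a maximal run of bins >= 0.15 containing a bin
>= 0.35 (threshold comparisons are inclusive at float equality, avoiding
float-equality flakiness); bursts with gaps < 30 ms merge, keeping the
larger peak. Event bounds are the outer bin edges of the run. Detection is
checked bin-for-bin against a brute-force threshold-scan oracle.

## Templates and replay decoding

Per trajectory (left/right x outbound/inbound), each CA1 unit active in the
maze (mean running rate 0.4-10 Hz, the putative-pyramidal band) gets a
spatial rate curve: spike counts and occupancy per 2 cm bin during active
running, both smoothed with the same 2-bin Gaussian before dividing;
never-visited bins stay invalid. A unit joins the trajectory's template when
its curve peak reaches `mean + 3 sd` of the curve values over valid bins
(and strictly exceeds the mean, so constant curves never qualify). The
curve-statistics reading of "3 SD above its mean rate" is the default; a
session-wide temporal alternative would be config work for a convention the
package does not need. Left/right ensembles are the unions of a side's two
templates; a unit may sit in both sides' ensembles.

Candidate bursts have >= 4 active template members. Decoding uses the
memoryless Poisson model in 20 ms windows stepped by 10 ms (a trailing
partial window is kept if at least half-length, with its true length used
as the Poisson exposure): under a uniform spatial prior,

    P(x | n) ∝ prod_i (tau f_i(x))^(n_i) exp(-tau f_i(x)),

computed in the log domain and normalised per window with logsumexp; rates
are floored at 0.01 Hz so an empty-looking bin cannot zero a window.
Zero-spike windows carry no sequence information (their posterior reflects
only `exp(-tau f)`) and are excluded from the decoded-position series by
default. The decoded position is the per-window argmax (ties break to the
lowest bin, deterministically).

Significance: Pearson r of decoded positions against window indices versus
1000 permutations of the indices, `p = (1 + hits) / (n + 1)` (never exactly
0). The default is two-sided on |r| because both forward and reverse replay
are of interest; the strictly one-sided variant (tail in the direction of
the observed r) is config-selectable. Events with p < 0.05 are replays,
forward if r > 0. A burst significant for several templates increments each
template's per-trial count; counts are assigned to the trial whose water
period contains the burst peak.

**Known property of the overlapping-window shuffle.** Adjacent 20 ms
windows at a 10 ms step share spikes, so decoded positions are
autocorrelated even for temporally structureless events. The time-bin
permutation null assumes exchangeability, and direct simulation shows the
false-replay rate at p < 0.05 is roughly 0.09-0.12 rather than 0.05. This
is a property of the decoding convention itself, reproduced faithfully
here; with non-overlapping windows (`step = tau`) the same test is
calibrated (~0.05, verified by test). Users who need calibrated type-I
control should decode significance with `step = tau`.

## ACC-CA1 coupling

For every maze-selective ACC cell and the CA1 ensemble on the same or
opposite side of its selectivity label:

- **Delay cross-correlation**: ACC and aggregated-ensemble counts in 200 ms
  bins within each delay period, correlated per trial at lags up to ±5 bins
  (±1 s; with 2 s delays, longer lags leave too few overlapping bins) and
  averaged over trials; the lag-0 value is the cell's statistic. A
  concatenated-bins mode is config-selectable since the per-trial and
  pooled readings both appear in the source conventions.
- **Water-period correlation**: the ACC rate over the entire water period
  vs the ensemble's in-burst rate (ensemble spikes inside the trial's
  bursts / total burst duration), Pearson over trials. Trials without
  bursts are missing values, dropped pairwise.
- **Delay-to-water correlations**: ACC delay rate vs the ensemble in-burst
  rate, vs per-trial replay counts (inbound and outbound templates
  separately), and vs the cell's own water rate (self-continuation).

Population summaries are one-sample t-tests of the per-cell statistics
against 0 — two-sided for the delay cross-correlation and delay-to-burst
analyses, one-sided (positive) for the water and replay-count analyses,
matching how each is reported — and two-sided paired t-tests of same vs
opposite side. Correlations are affine-invariant and pairwise-complete by
construction.

## Synthetic sessions and ground truth

The generator lays out trials sequentially: demonstrator run (choice-point
crossing, maze poke), observer delay (2 s plus an exponential tail of mean
0.5 s, so the delay-window distribution peaks near 2 s), a 10 s water
period, then the observer's out-and-back run on the chosen side (64 s of
self-running per trial by default). Defaults: 40 trials, p(left) = 0.5,
11% errors, 30 CA1 and 20 ACC units.

Geometry: the linearised trajectory is 200 cm, traversed at constant speed
within each half-lap (6.25 cm/s at the default lap duration — above the
5 cm/s stop threshold, as it must be for any running to survive the stop
mask). Position is sampled at 30 Hz; the inbound trajectory has its own
0-200 cm coordinate, and a field at outbound position c sits at 200 - c
inbound.

CA1 cells are inhomogeneous-Poisson place cells (thinning) with Gaussian
fields (sigma = 5 cm, peak 10 Hz over a 0.3 Hz baseline) on one maze side,
stratified centres tiling the track. These values put mean maze rates
inside the 0.4-10 Hz inclusion band and field peaks safely past the 3 SD
template criterion after curve smoothing. ACC cells are piecewise-constant
Poisson: 2 Hz maze rate and 3 Hz delay rate scaled by the selectivity
ratio (default 3) on the preferred side; preferred-side error trials
multiply the delay rate by `acc_error_attenuation` (default 0.5).

Water-period bursts arrive as a Poisson count (mean 2 per trial, >= 0.5 s
apart). Each burst carries a time-compressed (150 ms, ~200-fold) replay of
one trajectory template — the trial's own side with probability
`replay_bias` (default 0.8), forward or reverse with equal probability.
Members fire one ordered, jittered spike each (the planted sequence) plus
Poisson spikes whose rate follows their own field along the virtual
trajectory, so member activity is sequence-consistent; non-members carry a
32 Hz uniform surge so the burst stands out in the multiunit trace.

Trial-wise coupling: each side's CA1 ensemble has a lognormal gain per
trial (sigma 0.6); each ACC cell's delay/water gain shares a latent normal
correlation `coupling_strength` with its side's ensemble gain, so cells are
conditionally independent given the ensemble factor. CA1 in-burst rates
apply a damped affine map of the gain (`gain_mix`, default 0.15): an affine
map leaves the planted Pearson correlation unchanged while keeping burst
amplitudes inside the band the min-max-standardised detector can always
see. One consequence worth knowing: when the coupling plant is on, cells of
a side share a common gain factor, so population t-tests across cells of
*other* effects (e.g. the error-trial DI) see correlated noise; calibration
studies of those analyses should set `coupling_strength = 0`, which is also
the generator's null condition.

All randomness flows from one seeded `numpy.random.Generator`; identical
parameters give byte-identical bundles, and the full pipeline is
deterministic given its config seed.

### What the generator does not emulate

Theta phase precession, interneurons, LFP waveforms, ripple-band content
(bursts are defined purely by spikes), behavioural variability in running
speed within laps, 2-D position noise, and overdispersed (non-Poisson)
spiking. Passing recovery tests therefore demonstrates correctness of the
analysis code under the stated generative model, not robustness to every
property of real recordings.

## Validation study sizes

The test suite runs the recovery studies at sizes chosen to keep the whole
suite fast while retaining power: 100 seeded sessions for DI recovery
(20 ACC cells, 40 trials, 25% errors so most sessions meet the >= 3
error-trial precondition), 100 effect + 100 null sessions for coupling
recovery (30 ACC cells, 40 trials, true gain correlation 0.4), 40 sessions
for replay-bias recovery, a 1000-cell null session and a 200-cell effect
session for selectivity calibration/power, and 1000 structureless events
for shuffle calibration. `oswm calibrate` runs a two-condition
(null/effect) validation and reports recoveries with their pass bands.
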