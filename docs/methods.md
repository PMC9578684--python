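# Methods

`hdmea` analyzes sorted spike trains from high-density micro-electrode
array (HD-MEA) recordings of developing neuronal cultures. This note
documents the models and procedures it implements, the defaults and why,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices that were genuinely open.

## Data model and conventions

Time is in seconds, coordinates in micrometres, culture age in integer days
post induction (dpi). A recording window is half-open `[t_start, t_stop)`,
so a spike exactly at `t_stop` is invalid and every rate denominator is
unambiguous. Spike and tracking tables exchange as CSV; an importer for the
ImageJ Manual Tracking column set (`Track n°, Slice n°, X, Y`) with a
slice-to-dpi map and pixel size is provided, since the exact export dialect
of tracking tools varies. QC attributes (ISI-violation rate, SNR, firing
rate) may be absent at load time and are only required by curation; SNR can
never be derived from spike times alone and must come from the sorter.

## Unit curation

A sorted unit is removed when it fails any of: ISI-violation rate > 0.2,
SNR < 5, or firing rate < 0.1 Hz. The boundary semantics are exactly the
strict inequalities of those phrases; a unit sitting on a threshold is
kept. The ISI-violation rate is defined as the *fraction* of interspike
intervals shorter than a refractory period (default 1.5 ms, configurable).
A rate-style reading of the 0.2 threshold (violations per second) is
conceivable but the value reads naturally as a fraction, and no
rate-corrected estimator (e.g. the common contamination correction) is
applied — curation mirrors a simple post-sorting filter, not a
contamination model. Separately, a unit is *active* when its firing rate
strictly exceeds 0.1 Hz.

## Firing-rate analytics

AP frequency is spike count over recording duration. Instantaneous firing
frequency is the inverse of each interspike interval, timestamped at the
second spike of the pair — an ISI is only known once its closing spike
occurs; the choice affects time-resolved plots only, never fractions.
Units are classified fast-spiking when at least 5% (inclusive) of their
instantaneous-frequency events exceed 150 Hz (strict); events above 600 Hz
still count but are flagged as implausible. The session-level mean
instantaneous frequency averages per-unit means (each neuron weighted
equally); a pooled-event mean is available as an option because the two
conventions differ whenever firing rates are heterogeneous.
Frequency-domain histograms use half-open bins with default edges
{0, 1, 2, 5, 10, ∞} Hz; a unit exactly on an edge falls in the higher bin.

## Poisson-surprise burst detection

For a window of length `T` containing `N` spikes from a unit with mean
rate `λ`, the Poisson surprise is

    S = −log P,   P = Σ_{n≥N} e^{−λT} (λT)^n / n!

the upper-tail probability of `N` or more spikes under a homogeneous
Poisson process. Logarithms are natural by default (so the minimum
surprise of 4 corresponds to P < e⁻⁴ ≈ 0.018); base 10 is configurable.
`S` is dimensionless and invariant under time rescaling (t → ct, λ → λ/c),
which is property-tested.

Numerics: `P` is evaluated through the regularized incomplete gamma
function (the Poisson log-survival function), accurate even when `P`
underflows double precision. When `P` is instead close to 1 (small `N`,
large `λT`), `log(P)` itself loses relative precision, so the
implementation switches to `−log1p(−P(X < N))`; the test oracle is a
direct term-by-term series summation with the same two-sided strategy, and
implementation and oracle agree to better than 1e-9 relative error over
`N ≤ 50`, `λT ∈ [0.01, 20]`.

Detection follows the classic surprise-maximization scan:

1. `λ` is the whole-train mean rate (count / recording duration) and the
   mean ISI is computed once globally; neither is re-estimated during
   scanning (no burst-excluded refinement).
2. A candidate is seeded at the first of three consecutive spikes whose
   two ISIs are both strictly below half the mean ISI (both ISIs of the
   triplet must qualify).
3. Spikes are appended while the next ISI is at most the mean ISI.
4. The surprise is evaluated at every extension length of at least
   `min_spikes`, with `T` the span from the first to the last candidate
   spike; the length maximizing `S` is selected, ties going to the
   shortest (earliest-ending) extension for determinism and parsimony.
5. The burst is emitted iff `S ≥ 4`, duration ≥ 20 ms, and spike count
   ≥ 4 (all configurable); the duration filter applies to the maximized
   burst. Scanning resumes at the spike after an emitted burst, so bursts
   are disjoint and time-ordered. A seeded candidate that fails the
   thresholds advances the scan by one spike only, so overlapping seed
   positions are still explored.
6. Backward start-refinement (dropping leading spikes while that raises
   `S`) exists behind a non-default flag; the default pipeline omits it.

Seed and extension thresholds are expressed as fractions of the mean ISI
(defaults 0.5 and 1.0) and are configurable.

The detector is verified against an exhaustive reference that scores every
admissible window with the series-summation surprise: spike membership and
surprise values are identical on hundreds of random bursty trains.

## Network bursts

No standard criterion exists for when co-occurring single-unit bursts
constitute a network burst, so the definition here is an explicit,
configurable convention: time is binned (default 100 ms); a bin qualifies
when at least `max(5, ⌈0.2 × active units⌉)` units have an ongoing burst;
adjacent qualifying bins merge into one network-burst interval; members
are the units with at least one burst overlapping the interval, and a unit
"participates in network bursting" when it is a member of at least one
event.

## Array model

The electrode grid defaults to 120 × 220 at 17.5 μm pitch (26,400
electrodes). Indexing is 0-based row-major with origin at the top-left and
y increasing downward (image convention, to match microscopy overlays).
The bounding box counts one full pitch cell per electrode
(`n × pitch`, not `(n−1) × pitch`), giving the 3.85 × 2.10 mm sensor area.
An electrode is active when its firing rate exceeds 0.1 Hz *and* its mean
spike amplitude exceeds 20 μV, both strict; the top-1,024 selection sorts
active electrodes by rate descending with ties broken by ascending index.
The full-scan emulation partitions electrodes into `ceil(total/block_size)`
consecutive blocks (default 27 blocks of ≤1,000); vendor firmware uses a
proprietary block geometry with a slightly different block count, so both
block size and dwell time are configurable and the arithmetic partition is
the default. Activity-map rates are stored raw; min–max normalization is
applied per frame at export only, because frames from different days are
not comparable after normalization.

## Soma displacement

Cumulative displacement is reported in two senses that the word
"cumulative" often conflates: total path length (sum of interval
distances) and net displacement (first sample to last). Both are always
computed and labelled; path length ≥ net displacement is property-tested.
Distribution bins are half-open, so the 50–200 μm headline bin is
`[50, 200)`. `displacement_in_pitches` is `floor(mean displacement /
pitch)`, a coarse lower bound on how many electrodes an activity footprint
crosses. Somata that merge into clusters should be tracked as the cluster
centroid upstream; the importer consumes whatever track the table reports.

## Condition comparison

Per-neuron metric values (AP frequency, burst frequency, mean burst
duration, percentage of spikes in bursts) are compared across groups with
a tie-corrected Kruskal–Wallis omnibus test followed by Dunn's pairwise
mean-rank comparisons,

    z_ij = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)],

with two-sided normal p-values adjusted by Bonferroni over all pairs
(Holm available); α = 0.05. Groups are independent — no pairing of the
same neurons across conditions is assumed. The omnibus is backed by
`scipy.stats.kruskal`; the Dunn statistic is implemented here and
cross-checked against an exhaustive rank-permutation oracle at small n.
The full chain's family-wise type-I error under the null is calibrated to
[0.02, 0.08] at α = 0.05 (1,000 simulations, 50 per group).

**Unit-of-analysis caveat.** Treating neurons as independent samples is
only valid when no session-level shock moves all units together. Network
bursts are exactly such a shock: the random number of network events in a
session shifts every member unit's rate, inflating the chain's false-positive
rate when comparing whole sessions of synchronized activity (this is visible
in simulation: with network events enabled, "identical" sessions differ
significantly far more often than α suggests). The statistical tests are
calibrated and tested on data without session-level coupling; conclusions
drawn from single heavily synchronized sessions per condition should be
treated as descriptive, which is equally true of the experimental design
the pipeline mirrors.

## Synthetic data generator

The generator produces sessions with known ground truth so every pipeline
stage is testable without recordings. Per unit, background spikes are
homogeneous Poisson; unit-local bursts arrive as a Poisson process and
network events as a renewal process with a refractory dead time (default
0.5 s) so that injected events never overlap — two overlapping "network
events" would be observationally a single epoch of synchrony and would
make the ground-truth event count meaningless. Each event recruits
`⌈sync_fraction × n_units⌉` members, resampled per event (partial
participation), with Gaussian start jitter (default SD 20 ms). Burst
durations are gamma-distributed (shape 4) about their mean; within-burst
spikes are quasi-regular — evenly spaced with small Gaussian jitter —
rather than Poisson, because real high-rate discharges are far more
regular than a Poisson process and Poisson intra-burst ISIs at 100 Hz
would scatter roughly half of all burst events above the 150 Hz
fast-spiking threshold, poisoning the fast/slow ground-truth labels.
Fast-spiking units (a labelled subpopulation) receive doublets/triplets at
a fixed short ISI (default 4 ms) attached to background spikes. Bursts are
injected additively; the merged train is re-sorted and near-coincident
spikes (< 0.1 ms) collapsed. All randomness flows from one seed through
`numpy.random.SeedSequence` spawning; identical seeds give bit-identical
sessions.

The default stage parameters describe a stylized mature (third-month)
culture: 50 units, 300 s (the 5-minute network assay), 1 Hz background,
0.1 unit-local bursts/s plus 0.25 network events/s at 50% participation
(≈ 0.23 bursts/s per unit combined), 150 ms mean burst duration, 100 Hz
intra-burst rate, 20% fast-spiking units. Presets `sparse`,
`local_bursting` and `synchronized` sketch the developmental progression
from scarce uncorrelated firing to network-wide synchrony; the quantitative
trajectory of these parameters over development is a free modelling choice,
not a measured one. Pharmacology scenarios regenerate the treatment session
with multiplied parameters (`rate`, `burst_rate` — applied to both local
and network burst rates — and `burst_duration`) and interpolate the washout
session by a persistence factor (default 0.5; 1.0 models effects that
persist after washout).

What the generator does *not* emulate: extracellular waveforms and
amplitudes (SNR is drawn uniformly, default range 6–20, i.e. passing
curation), electrode drift, rate nonstationarity within a session,
bursts with internal rate structure (accelerando/decelerando), correlated
background firing outside network events, and the long-tailed unit-rate
distributions of real sorts. Passing recovery tests therefore shows the
analysis chain is correct on data matching its model assumptions, not that
it is robust to every pathology of real recordings.

Soma trajectories are 2-D random walks (per-step Gaussian scale in μm)
with a per-step drift of `attraction_gain` toward the nearest of a set of
random attractors inside the sensor area, emulating migration followed by
cluster formation; positions are clipped to the arena, sampled weekly from
22 dpi by default.

## Problem sizes in tests

The test and acceptance runs use 50-unit, 300 s sessions (20 seeds for
burst recovery, 50 for the pharmacology scenario), 500 random trains of up
to 200 spikes for detector-oracle equivalence, 1,000 simulations at 50 per
group for the statistics calibration, and a 2,500-point grid for the
surprise oracle — sizes chosen so the entire suite completes in a few
minutes while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- SNR must be provided by the sorter; the package cannot validate it.
- Burst-detector behaviour when the source literature is silent (scan
  resumption after a failed candidate, duration filter after
  maximization, global mean ISI) follows the documented choices above;
  other implementations may differ in these corners.
- The network-burst criterion is a declared convention; counts depend on
  its bin width and thresholds.
- `compare_conditions` assumes independent groups; repeated measures of
  the same neurons across conditions are not modelled.
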