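# Methods

`songpulse` extracts a *signal-derived isochronous pulse* from annotated
birdsong — a string of equally spaced timestamps fitted to note onsets —
and provides the statistics needed to decide whether that pulse reflects
real temporal structure: spectral corroboration, tempo clustering,
gesture-transition coincidence, and comparison against randomized null
songs. This note documents the model, its parameters, the numerical
choices, and what the synthetic-data validation does and does not show.

## Input model and segmentation

The unit of analysis is the **song chunk**: a maximal run of notes in which
no silent gap reaches 300 ms. Labels arrive as Audacity-style label tracks
(`start<TAB>end<TAB>label`) or CSV; times are kept as double-precision
seconds internally and written at 1 ms precision, the resolution at which
song annotations are typically measured. Introductory notes and calls are
removed by label membership (default exclusion set `{"i", "call"}`) before
segmentation. Chunks with fewer than 4 notes or fewer than 3 distinct note
types are discarded: a pulse fitted to a tiny or highly repetitive onset
set is a mathematical artifact, not evidence of rhythm. Silent gaps are
associated with the note *preceding* them (note duration covaries more
strongly with the following gap), and the silence after a chunk's final
note is not a gap.

## Pulse matching (GAT)

For each chunk the generate-and-test search scans frequencies from a
per-chunk floor to 100 Hz in 0.01 Hz steps. The floor is
`1 / (1.1 x shortest IOI)`: any slower pulse could not place a distinct
pulse time on every onset, and the 10% margin absorbs onset-measurement
noise. At each frequency the pulse grid — anchored at the chunk's first
onset — is displaced by offsets 0, 1, 2, ... ms across one full period
(half-open `[0, period)`), and the root-mean-square deviation (RMSD) of all
onsets from their nearest pulse time is computed; the minimum over offsets
is that frequency's score.

Raw RMSD trivially favors fast pulses (more pulse times, shorter distances),
so selection uses the frequency-normalized RMSD, **FRMSD = RMSD x
frequency**: deviation as a fraction of the pulse period. FRMSD is bounded
by 0.5 (the nearest pulse is at most half a period away). On pulse-free
onsets the RMSD curve falls roughly like 1/f while the FRMSD curve is flat;
the package's diagnostic compares *relative* trends (least-squares slope
divided by the curve mean), because the two raw slopes carry different
units. A small positive FRMSD drift remains at high frequency where the
1 ms offset grid becomes coarse relative to the period; it is ~1% of the
curve level over the 10–100 Hz band and does not affect selection.

**Tie-breaking.** The goal is the *slowest* pulse consistent with the
onsets, so FRMSD ties resolve to the lowest frequency, then the lowest
offset. Ties are detected with a relative tolerance of 1e-9: onset
sequences commensurate with the measurement grid produce harmonically
related candidates whose FRMSDs are equal in real arithmetic and differ
only by float summation order; a strict `<` would let rounding noise pick
the winner. Genuine FRMSD differences on jittered data are orders of
magnitude above this tolerance.

## Fourier corroboration

Independently of GAT, onsets are binned into a 0/1 point process at 1 ms
resolution, zero-padded so the spectral resolution is at most 0.01 Hz, and
the frequency of maximum power within the same band as the GAT scan is
taken. Near-exact power ties (relative tolerance 1e-9, e.g. exact harmonic
combs) again resolve to the lowest frequency. Method agreement is the
fraction of chunks where |GAT − FFT| < 0.25 Hz, strictly.

## Tempo clustering

Per-bird best-pulse frequencies are clustered agglomeratively with
group-average (UPGMA) linkage on absolute differences of log10-transformed
frequencies, cutting the dendrogram at dissimilarity 0.025 (merges must be
strictly below the threshold; the cut uses `nextafter(0.025, 0)` to get
strict semantics from `scipy.cluster.hierarchy.fcluster`). The log10
transform is not cosmetic: on the raw Hz scale cluster standard deviation
grows with cluster mean (multiplicative tempo noise), so one threshold
would over-merge slow tempi and over-split fast ones. The
`std_vs_mean_regression` diagnostic (OLS of cluster std on cluster mean on
the transform scale, clusters with >= 2 members) quantifies this; the
transform with slope/R² nearest zero is preferred, and log10 is the
default. Cluster means and stds are reported in untransformed Hz.

## Gesture transitions

Complex notes concatenate several neuromuscular gestures; gesture
boundaries appear as amplitude-envelope minima plus frequency-trace
discontinuities. The package accepts a *curated* transition list as the
primary input, because the published workflows verify candidates against
the spectrogram by eye — a step that cannot be reproduced in software. An
automated candidate stage is provided
(`envelope_minima_candidates`: prominence- and separation-filtered local
minima of a uniformly sampled envelope, restricted to note spans), but it
is a proposal mechanism only.

Coincidence with the pulse is the fraction of transitions whose distance to
the nearest pulse time is strictly less than w periods, for windows
w ∈ {1/10, 1/6, 1/4}. Since the window extends to both sides of every
pulse, a uniformly random time lands inside with probability exactly
**2w** — 20%, 33.3% and 50% — which is the chance level against which
per-bird fractions are tested with a two-sided one-sample t-test
(df = n − 1). Boundary events have measure zero on continuous data, so the
strict inequality is inconsequential; it is pinned down for
reproducibility.

## Null models

Two surrogate-song generators ask whether well-fitting pulses arise in any
finch-like duration sequence.

**Model R (random sequence)** redraws every note and gap duration
independently from a Pearson-family distribution matched to the first four
moments (mean, std, skewness, kurtosis) of the pooled observed durations.
Before fitting the gap distribution, per-type Tukey outliers
(Q1/Q3 ∓ 1.5 IQR) are removed, then whole gap types whose remaining values
have mean > 90 ms or std > 30 ms are dropped — these are the long, variable
between-motif silences, which carry no within-motif rhythm information and
would inflate surrogate variability. Both thresholds are configurable; the
defaults bound the filtered gap range near the 6–88 ms band typical of
within-chunk gaps.

The four-moment sampler implements the Pearson system directly (no Python
library provides one): the discriminant of the system's quadratic selects
normal, beta (Type I/II), gamma (Type III), Type IV, inverse-gamma
(Type V, handled by an epsilon nudge), beta-prime (Type VI) or Student-t
(Type VII) branches. Type IV has no closed-form sampler and is drawn by
inverse CDF after the substitution x = λ + a·tanθ, which maps the density
to cos^(2m−2)θ·e^(−νθ) on the compact interval (−π/2, π/2) (16,385-point
grid). Moment recovery is verified by Monte-Carlo in the tests; for
extremely heavy tails (kurtosis ≳ 8) the finite grid slightly truncates the
tails, far outside the range of realistic duration data (kurtosis ~2.5–4).
Specs with kurtosis at or below the feasibility bound skew² + 1 are clamped
just above it with a warning. Durations below 5 ms are rejected and
redrawn (rejection, not clipping, keeps realized moments close to the
spec when sub-threshold mass is small).

**Model C (consistent sequence)** keeps the note sequence. Each note/gap
type receives a fixed set of 100 standard-normal draws affinely retargeted:
the set mean is a uniform draw between the smallest and largest observed
type means, the set std is the mean of the observed type stds. Every
instance of a type draws one element from its set — so repetitions of a
type stay similar (type stds are small), while the type means are
randomized. One `bird_seed` fixes the sets for all chunks of a bird;
a per-(chunk, repetition) seed drives the element draws. Both models are
bit-reproducible under fixed seeds.

**Restricted-range comparison.** FRMSDs of songs with very different best
frequencies are not comparable, so real and surrogate songs are refitted
inside a band centered on the bird's dominant-cluster frequency with
upper bound = 2 x lower bound. The octave width guarantees that every
frequency outside the band has exactly one power-of-two multiple or
fraction inside it. The center is placed geometrically
(lower = center/√2), keeping the band symmetric on the log scale used for
clustering; arithmetic centering would make the band asymmetric in octaves.
Surrogate generation and comparison repeat 50 times per song by default.

## Group statistics

FRMSD grows with the number of notes in a chunk, so group comparisons
(real vs surrogate, or undirected vs directed song) use a linear mixed
model with FRMSD as response, group as fixed effect, and a random intercept
per distinct note count, fitted by maximum likelihood via
`statsmodels.MixedLM`. Significance is the likelihood-ratio test of the
full against the group-free model (χ² with 1 df). Degenerate inputs are
handled explicitly: an all-identical response returns a tie
(χ² = 0, p = 1), and a perfectly separated response (zero residual
variance) returns the test's limit (p = 0) with `converged=False`. The
repetition summary runs one LMM per repetition and reports, per bird and
model, the percentage of repetitions in which the real song had lower
FRMSD (and in which the difference was significant at α = 0.05), in both
directions; exact ties count toward neither and are logged. The null
simulation in the acceptance suite confirms the test holds its nominal
size (type-I error within [0.02, 0.09] at α = 0.05).

## Synthetic songs

The generator produces ground-truth data with the structure of real
zebra finch song: motifs of 4–7 distinct notes repeated 1–10 times per
chunk, note durations 26–256 ms, within-chunk gaps of roughly 6–30 ms, and
onsets on an isochronous 10–60 Hz grid. Notes span whole pulse periods
minus a sub-period gap residue (so consecutive onsets stay on the grid);
gesture transitions sit on the interior pulse times of each note. Gaussian
timing jitter (default sd 2 ms, truncated at ±2 sd to preserve event
order) perturbs every onset, offset and transition independently, and all
times are then quantized to 1 ms, the resolution of real annotation
timestamps. Three structural choices matter:

* the first two note types get consecutive period counts, making the IOI
  period counts coprime — the generating pulse is the unique slowest
  zero-deviation pulse, so "recovery" is well defined;
* every IOI spans at least two periods, mirroring the empirical relation
  between real scan floors and pulse frequencies; a one-period shortest
  IOI would let jitter push the per-chunk scan floor above f0;
* all chunks of one simulated bird share a single motif blueprint
  (real birds sing one stereotyped motif), which keeps within-type duration
  spread at jitter scale — the property that makes Model C's consistent
  sequences behave differently from Model R's random ones.

An arrhythmic control generator draws independent Pearson durations with no
underlying grid; its best-fit FRMSDs stochastically dominate those of
pulse-aligned chunks.

**What passing tests show, and what they do not.** The synthetic songs are
ideal in ways real recordings are not: jitter is i.i.d. Gaussian, there is
no tempo drift within a chunk (real birds slow down slightly), no
amplitude-dependent onset-measurement bias, no motif variants, and gesture
transitions sit exactly on the grid before jitter. Validation on this
ground truth demonstrates the estimators are correct and calibrated, not
that real song is isochronous; conclusions about real birds require real
annotated recordings.

## Problem sizes and runtime choices

The test suite and the acceptance script scale their simulations to desk
size as the package's own defaults: parameter-recovery checks use 50 seeds
per (f0, jitter) condition in the acceptance suite (20 in the acceptance
script's summary), oracle equivalence uses 20 random chunks against a
pure-Python exhaustive scan capped at 50 Hz, null-model comparisons use
10 chunks x 50 repetitions (20 in the script), and the LMM calibration uses
200 null simulations. The full suite runs in a few minutes on one CPU.

## Known limitations

* Constant-tempo model: one frequency per chunk; accelerando/ritardando is
  not modeled.
* The offset search is an exact 1 ms grid by design; sub-millisecond phase
  is not estimated.
* The envelope-minima detector is a simplified candidate stage, not a
  replacement for published envelope-segmentation algorithms or for visual
  curation.
* Whether Model R moments should be fitted per bird or pooled across birds
  is ambiguous in the underlying design; the implementation pools by
  default and accepts per-bird tables.
* Chunks spanning recording-file boundaries are treated as independent
  files; the CLI never merges across files.
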