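# Methods

## Problem setting

Bradykinesia — slowness in preparing, initiating, and executing voluntary
movement — is the cardinal motor sign of Parkinson disease. During a
serious-game session, a glove-mounted gyroscope samples forearm angular
velocity at 250 Hz around the pronation–supination axis. The trace
superimposes two processes: the voluntary movement the player performs to
score (slow, burst-like) and Parkinsonian tremor (a 4–7 Hz oscillation,
typically amplitude-modulated). Two observables quantify slowness:

* **response time (RT)** — the duration of the in-game event from stimulus
  onset to movement completion, i.e. reaction time plus movement time, in
  seconds;
* **angular velocity (AV)** — the peak speed of the voluntary movement in
  deg/s, which requires removing tremor first. AV is computed only for
  game phase 4, the one phase whose scoring movement rotates about the
  measured axis.

## SSA decomposition

The separator uses basic (Broomhead–King/Golyandina-style) singular
spectrum analysis:

1. **Embedding.** The series `x_1..x_N` becomes the `L × K` Hankel
   trajectory matrix with entry `(i, j) = x_{i+j-1}`, `K = N − L + 1`.
2. **Decomposition.** Thin SVD of the trajectory matrix gives eigentriples
   `(σ_i, U_i, V_i)`, σ non-increasing.
3. **Grouping.** Disjoint index sets over `1..d` name components
   ("tremor", residual).
4. **Reconstruction.** Each group's matrix `Σ σ_i U_i V_iᵀ` is mapped back
   to a series by anti-diagonal (diagonal) averaging; for a rank-one term
   this is the linear convolution `σ (U * V)` divided by the anti-diagonal
   multiplicities, which is how it is computed.

Numerical conventions: thin LAPACK SVD (no randomized solver, so results
are bit-reproducible); sign fixed by making the largest-magnitude entry of
each `U_i` positive; ties in σ keep original order; `σ_i < 1e-12 σ_1`
counts as numerical zero; the retained-eigentriple cap defaults to
`min(L, K, 50)`.

**Window length.** `L` defaults to one second of samples (`L = fs`, 250
at the study rate) when the series is at least two seconds long, else
`floor(N/2)`. One second is several tremor periods — enough to isolate the
oscillation — while staying far below `N/2`, so slow voluntary structure
does not mix into the oscillatory pairs. Series shorter than `2 L` are
refused rather than silently decomposed.

**Residual bookkeeping.** The residual component is defined as the input
minus the named components, so every `ComponentSet` sums to the input
exactly, including when the eigentriple cap truncates the decomposition.

## Automatic tremor grouping

The study identified tremor eigentriples by inspecting eigenvalue and
w-correlation plots per recording; a pipeline needs an automated rule. A
sinusoid (AM or not) contributes adjacent eigentriple *pairs* with
near-equal singular values whose elementary components are strongly
w-correlated. A pair `(i, i+1)` joins the tremor group when all of:

* `σ_{i+1}/σ_i ≥ 1 − pair_tol`, default `pair_tol = 0.2`;
* `|w-correlation(i, i+1)| ≥ wcor_min`, default 0.5;
* the dominant Welch-PSD frequency of the pair's reconstructed component
  lies in the tremor band, default [4, 7] Hz inclusive.

Overlapping accepted pairs are unioned (indices counted once); the search
covers the leading `min(d, 30)` eigentriples (manual groupings in this
kind of data use indices well below 20; the cap bounds cost). Both
thresholds are configurable; 0.2 is loose enough that AM tremor — whose σ
pairs are less equal than a pure tone's — is still caught, and 0.5 splits
the observed w-correlation distribution, which is near 1 for true pairs
and near 0 for unrelated components. If no pair qualifies, the recording
is returned untouched with `accepted=False`.

**Spectral estimate.** Welch periodogram, Hann window, segments of
`min(N, 2 fs)` samples with 50% overlap — at most 0.5 Hz resolution for
recordings of ≥ 2 s, stable for the 10–300 s range this pipeline targets.
Band-edge checks treat [4, 7] as inclusive.

## Peak-based AV and event-based RT

Peaks are local maxima of |voluntary| at or above `threshold_rel` times
the recording's maximum absolute amplitude (default 0.5), separated by at
least `min_sep_s` (default 0.5 s — one movement half-cycle cannot complete
faster at game tempo). The threshold is relative because raw recordings
span hundreds of deg/s; taking |·| counts pronation and supination
half-cycles alike and makes AV invariant to the sensor's sign convention.
Per-participant aggregation defaults to the median (robust to occasional
missed/extra peaks); the mean is selectable and the choice is recorded in
output provenance. Empty inputs aggregate to an explicit missing value,
never 0.

RT is simply `end − start` per event interval (half-open `[start, end)`
in seconds), so RT is invariant under uniform time shifts of the log.

ON-vs-OFF change labels per patient: `both_improved` iff RT strictly fell
and AV strictly rose in the ON state; exact ties count as not improved.

## Statistical battery

* Shapiro–Wilk per group at α = 0.05; any rejection routes the analysis
  to the nonparametric branch. Constant groups are non-testable and
  treated as non-normal.
* Kruskal–Wallis H on midranks with tie correction. Effect size is the
  rank eta-squared `η²_H = (H − k + 1)/(n − k)`, the standard rank-based
  analogue on the same scale as classical η²; it can be slightly negative
  under the null and is floored at 0 for binning only. Cohen bins are
  half-open: small [0, 0.06), moderate [0.06, 0.14), large [0.14, ∞).
* Pairwise follow-ups with Bonferroni correction (`p ← min(1, m·p)`):
  Wilcoxon signed-rank for the matched ON/OFF pair (ids must agree
  element-wise), Wilcoxon rank-sum (Mann–Whitney) for control-vs-patient
  pairs, which are independent samples. All-zero paired differences are
  reported as degenerate with p = 1 rather than an error.
* Spearman ρ with strength classes at |ρ| cut points 0.2/0.4/0.6/0.8
  (half-open). Zero-variance inputs yield an explicit undefined marker.
  p-values for ρ are not reported. By default the patient-state rows are
  pooled (n = 30) for the score correlations; per-state analysis is a
  flag.
* One-way ANOVA for the age-homogeneity check only.

All tests are two-sided at α = 0.05 unless configured otherwise.

## Synthetic cohorts

The generator exists so each stage can be validated against ground truth
(the study deposited no raw recordings).

* **Voluntary movement**: `n_pulses = 12` signed raised-cosine velocity
  lobes (width 0.45 s, spacing 0.9 ± 0.15 s, alternating sign — one lobe
  per pronation or supination half-cycle), then zero-phase Butterworth
  low-pass at 2.8 Hz (order 6). The low-pass keeps the voluntary signal
  spectrally below the tremor band; that disjointness is precisely the
  premise under which subtracting in-band components is harmless. Raw
  lobes at this tempo would otherwise carry genuine 4–7 Hz rank structure
  that no spectral criterion could distinguish from tremor. Ground-truth
  pulse amplitudes are measured on the emitted (filtered) series, so
  recovery tests compare like with like.
* **Tremor**: sinusoid at `freq_hz ∈ [4, 7]` (default 5 Hz,
  cohort defaults 5.2 Hz), amplitude-modulated at 0.4 Hz with depth 0.5,
  plus white noise (sd 3 deg/s). Amplitude either absolute (default ON
  15 deg/s, OFF 35 deg/s) or scaled to a target tremor/voluntary RMS
  ratio for benchmarks.
* **Event logs**: per-event duration = lognormal reaction time +
  lognormal movement time (positive support, right skew; component
  medians split 35%/65% of the target RT, log-sd 0.25), placed
  sequentially with 2–4 s gaps. The returned truth equals the parsed
  durations bit-for-bit.
* **Cohorts**: group AV/RT levels are recomputed at run time as the
  column means of the packaged cohort table (AV ≈ 449/290/250 deg/s and
  RT ≈ 1.73/1.94/2.27 s for CG/ON/OFF), preserving the orderings
  CG > ON > OFF (AV) and CG < ON < OFF (RT). Patient AV carries one
  per-participant random effect (sd 70 deg/s) shared by the ON and OFF
  recordings — the paired design — plus a 15 deg/s state jitter, floored
  at 120 deg/s (just below the lowest AV the study observed). The
  clinical bradykinesia score is `round(14.5 − 0.03·AV + N(0, 1.5))`
  clipped to [0, 24], a decreasing affine link targeting a pooled
  Spearman of about −0.7 against AV. All draws come from named
  `SeedSequence` substreams of one root seed, so adding a participant
  never changes another's data.

What the generator does **not** emulate: biomechanics (joint dynamics,
EMG), non-sinusoidal or re-emergent tremor, sensor drift and saturation,
multi-axis cross-talk, game-phase navigation signals, and the
reaction/movement split within an event. Passing recovery tests therefore
demonstrates correctness of the pipeline under band-separated, additive
conditions — not robustness to every artefact of real recordings; in
particular, real voluntary movement with genuine 4–7 Hz content would
partly be removed with the tremor.

## Benchmark problem sizes

Validation suites use 12-pulse recordings (~13.5 s, N ≈ 3400 at 250 Hz),
cohorts of 15 participants per group (45 recordings per draw), 20-seed
repetitions for stochastic properties, and 500 replicates for the
type-I-error calibration of the Kruskal–Wallis test.

## Known limitations and open readings

* The published narrative's list of patients who improved on both metrics
  disagrees with its own printed table for two participants (their ON/OFF
  response times appear swapped in print). The classifier follows the
  printed values; the discrepancy is documented, not reconciled.
* The published correlation table derives from unprinted per-participant
  medians of trial-level data, while the printed cohort table holds
  per-participant averages; pooled correlations recomputed from the
  printed table (ρ_RT ≈ 0.235, ρ_AV ≈ −0.383) therefore differ from the
  published BRADINDEX row (0.147, −0.698) and cannot match it from the
  available data.
* The printed cohort table's clinical-score column spans 2–12 under an
  ambiguous heading; it is exposed as the bradykinesia item sum
  (`brad_score`), flagged here rather than silently assumed.
* Whether SSA ran per phase or on concatenated sessions is not stated;
  this implementation separates per recording (per phase, per state).
* The group-level p-values and trial-level effect sizes of the study are
  not reproducible without the raw recordings; synthetic cohorts
  reproduce the qualitative regime (large AV effect) instead.
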