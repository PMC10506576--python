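# Methods

## Stimuli

A harmonic complex tone with fundamental F0 is the sum of equal-amplitude,
zero-phase sine partials at k·F0. Band-limiting eliminates partials
*strictly below* a low cutoff (250/500/750/1000 Hz) and *strictly above* a
high cutoff (1600 Hz, X series; 1300 Hz, Y series); a partial exactly at a
cutoff is retained. No partial of the default stimulus set lies on a
boundary, so this convention is inert in practice, but it is implemented
with a 1e-9 relative tolerance so that floating-point representations of
a boundary frequency behave as the exact value would.

Experiment-1 pairs fix F0 at 230 Hz (tone A) and 276 Hz (tone B), an
exact 6:5 ratio (1200·log2(6/5) ≈ 315.64 cents, printed as 316). All
eight pairs satisfy the designed crossover — the lower-F0 tone has the
higher lowest partial — and Y4 is the only pair in which both tones are
pure (1150 Hz vs 1104 Hz).

Synthesis parameters (all configurable on `ComplexTone`):

| parameter | default | rationale |
| --- | --- | --- |
| duration | 0.5 s (melody: 0.5 / 1.0 s) | the study's tone lengths |
| rise/fall ramp | 10 ms raised-cosine | the stated ramp time; the raised-cosine (half-Hann) shape is the psychoacoustics standard and avoids spectral splatter — the shape itself is a convention, not a stated fact |
| partial amplitude / phase | equal, zero-start sine | unstated in the source; the simplest convention |
| sample rate / depth | 44.1 kHz / 16-bit PCM | the stated WAV format |
| normalization | per-tone peak to 1 − 2⁻¹⁵ | guarantees quantization cannot clip; loudness equalization across tones is not attempted, since playback level is outside the artifact |
| channels | mono (optional diotic stereo) | stimuli were presented diotically; duplicated channels reproduce that |

Each tone is peak-normalized independently (not per pair).

## Melody

Thirteen notes spell the opening of "Lightly Row"
(G E E | F D D | C D E F | G G G); the phrase-final notes (positions 3, 6,
13) last 1000 ms, the rest 500 ms — the conventional rhythm of the song,
chosen because only the two durations are stated. Notes are rendered
gaplessly; each carries its own ramps.

Note frequencies are not stated anywhere, so the package fixes a
just-intonation C-major table, **anchored at C = 230 Hz**
(C 230, D 258.75, E 287.5, F 306.67, G 345). Two constraints drove the
anchor:

1. the scale's E–G minor third is the exact 6:5 (316-cent) interval of the
   experiment-1 tone pair, keeping the two experiments on the same
   interval; and
2. the third harmonic of G (1035 Hz) is the *only* harmonic of G inside
   both Y passbands, so versions Y3 and Y4 contain pure tones — a
   structural property of the original stimulus set. An anchor placing
   the whole melody at or below 276 Hz cannot satisfy this: any
   f0 ≤ 276 Hz puts at least two harmonics in the 550-Hz-wide Y3 band
   (750–1300 Hz), because consecutive harmonics are only f0 apart.

The scale table and long-note positions are overridable
(`lightly_row_passage(scale_table=…, long_positions=…)`); a note whose
retained-partial set would be empty raises a construction error naming the
note and version rather than silently dropping it.

## Listener model

The response model is this package's own operationalization — the source
study reports human data but no generative model. Participant i has a
latent spectral-listening trait tᵢ ~ Normal(μ, σ²) on the logit scale and
responds spectrally to condition c with probability

    p(tᵢ, c) = logistic(tᵢ + β_low·(k(c) − 1) + β_Y·1[c ∈ Y]),

k(c) ∈ {1..4} the low-cutoff index. The two repetitions of a task are
conditionally independent given the trait, so ambiguous responses
(repetitions disagreeing, SI = 0) arise naturally from intermediate
probabilities rather than being injected. Task-order randomization is not
modeled. Age group is a label with no effect in the default model,
mirroring the absence of age differences in the human cohorts; cohort
sizes default to the study's (experiment 1: 19 young + 20 old;
experiment 2: 18 + 20).

Default population parameters, fixed once: μ = −1.3, σ = 1.2,
β_low = 0.7, β_Y = 0.8. Via the logistic-normal mean approximation these
put cohort-mean SI (= E[2p − 1]) near −0.5 at X1 rising to about +0.3 at
X4, uniformly higher for Y — the direction and rough span of the human
averages. Figure-read values are never treated as ground truth; tests
assert the ordering, not the figure.

`fit_population_model` recovers the four population parameters by
marginal maximum likelihood, integrating the trait out with 31-node
Gauss–Hermite quadrature and optimizing with Nelder–Mead; standard errors
come from a central-difference Hessian. It exists to validate the
simulator (parameter recovery on large cohorts), not to analyze small
human samples.

### What the simulator does and does not emulate

It reproduces the design (8 conditions × 2 repetitions per participant),
stable individual differences, condition-driven shifts toward spectral
listening, and repetition disagreement. It does **not** model the
auditory periphery (no pitch extraction from the waveforms — the
simulator sees condition labels, not audio), order or learning effects,
lapses, or any age effect. Passing tests therefore show that the analysis
stack behaves correctly on data *shaped like* the study's, not that the
model explains human pitch perception.

## Shift Index and summaries

SI = (sp − f0)/(sp + f0) is defined for any repetition count with at
least one response; with two repetitions it takes only {−1, 0, +1}, and
SI = 0 ⇔ ambiguous. Ambiguity is deliberately *undefined* (an error) for
other designs rather than silently generalized. Missing responses are
rejected, not imputed — the design has none. Cohort summaries report mean
SI and the three-way percentage split (ambiguous / unambiguous-spectral /
unambiguous-F0), which partitions each condition.

## Statistics

**Wilcoxon signed-rank** (two-sided): zero differences discarded (the
convention of the R-family defaults, not Pratt's method — documented
because SI differences are zero-rich), mid-ranks for tied |d|. The exact
two-sided p enumerates all 2ⁿ sign assignments via a dynamic program over
the doubled (integer) mid-ranks; p = min(1, 2·min(P(W ≤ w), P(W ≥ w))).
The automatic mode uses the exact path for n_effective ≤ 25 with untied
ranks and otherwise the normal approximation with tie-corrected variance
and a ½ continuity correction — for SI data, ties mean the approximation
is the operative path, which is why the type-I calibration test targets
it. All-zero differences give a flagged degenerate result (p = 1).

**McNemar**: continuity-corrected chi-square (|b − c| − 1)²/(b + c) on
the discordant-pair counts by default (the named test), with the exact
two-sided binomial tail min(1, 2·P(X ≤ min(b, c))), X ~ Bin(b + c, ½),
behind a flag; both are provided because the original analysis software's
variant is unstated.

**Schedule**: ten Wilcoxon SI contrasts — X1 vs {X2, X3, X4}, Y1 vs
{Y2, Y3, Y4} and the four matched X-vs-Y pairs — plus McNemar ambiguity
contrasts of every other condition against Y4, the all-pure baseline
expected to be least ambiguous. Y1-vs-Y2 is included for symmetry even
though the source reports only the Y3/Y4 contrasts. P-values are
unadjusted by default (matching the original report); a Holm column is
available. Age stratification re-runs the whole schedule within each
group.

## Numerical and reproducibility choices

- One global seed fans out through `numpy.random.SeedSequence` into
  per-experiment child seeds, so stages can be re-run independently;
  identical seeds reproduce CSVs value-for-value and WAVs byte-for-byte,
  recorded in a SHA-256 manifest.
- Exact test p-values are computed in closed integer arithmetic (doubled
  ranks), so oracle comparisons can use tight tolerances.
- Spectral validation reads each WAV back, Hann-windows the steady-state
  interior (ramps excluded), and requires every retained partial within
  6 dB of the file's spectral peak and every eliminated harmonic at least
  40 dB below it (±2 FFT bins; harmonics unresolvable from a retained
  partial are skipped, which never occurs in the default set).

## Problem sizes used in the test suite

Calibration and pattern checks are sized to be decisive yet quick: the
null-simulator type-I check uses 1000 cohorts at the study's n = 39
(10 000 Wilcoxon tests); qualitative pattern recovery uses 200 seeded
cohorts of n = 500, where the Monte-Carlo error of a cohort-mean SI
(≈ 0.04) is well below the smallest modeled condition gap; parameter
recovery uses one n = 600 cohort. These sizes are the package's own
choices for stable Monte-Carlo assertions.

## Known limitations

- The melody's true note frequencies, key and rhythm are unknown; the
  documented scale is a convention satisfying the structural constraints
  above, not a recovered fact.
- The response model is phenomenological; its betas are condition-level
  effects, not auditory mechanisms.
- No loudness model, SPL calibration, masking, or playback chain; no
  effect sizes or confidence intervals in the schedule output.
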