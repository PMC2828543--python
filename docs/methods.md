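# Methods

`satlab` implements the Salience Attribution Test (SAT) — a probabilistic
reward-learning game used to quantify *adaptive* and *aberrant* salience
attribution — together with the analysis chain that turns behavioural logs
and (synthetic) BOLD data into group-level statistics. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## The task

Compound cue stimuli vary on colour (blue/red) and shape (animal/household
object). One dimension is task-relevant: its "high" level signals reward on
28/32 = 87.5% of its trials and the other level on 4/32 = 12.5%. The other
dimension is irrelevant: both levels are rewarded on exactly 16/32 = 50% of
trials. Each block presents 64 distinct stimuli (4 cue types × 16 pictures)
once, in random order, at a constant 9.25 s inter-trial interval; three
blocks share identical contingencies, and four counterbalanced versions
move the high-probability feature across blue/red/animal/object. In
information-theoretic terms the relevant features carry outcome entropy
H(0.875) = 0.377 nats and the irrelevant features the maximal
H(0.5) = 0.693 nats.

Subjects respond to a probe whose onset is uniform 3.5–4.5 s after cue
onset and whose duration is calibrated per subject: uniform within ±2 SDF
of the practice mean RT, where SDF is the sample standard deviation
(n−1) of the ten fastest practice trials and the mean is taken over all
valid practice trials. On rewarded trials, a response faster than the
practice mean earns

    X = 10 + 90 · (meanRT − RT) / (3 · SDF)   pence, capped at 100,

rounded half-up to whole pence ("Quick" below 1.5 SDF of advantage, "Very
quick" at or above); slower-than-mean hits earn 10p, misses/omissions and
premature responses (<100 ms after probe onset) earn 5p; non-rewarded
trials always pay 0. Scheduling uses one master seed with independent
named substreams (trial order/reward flags, probe delays, probe durations),
each spawning one child stream per block, so every component is
independently reproducible.

Open points resolved as the package's own choices: the practice mean is
computed over all valid practice trials (SD over the ten fastest only);
the probe delay is timed from cue onset; reward flags are drawn uniformly
without replacement within each cue type per block (the task fixes only
counts).

## Synthetic subjects

The SAT involves no choices, so the generative agent is a Rescorla–Wagner
feature learner driving vigour and ratings. Each feature f ∈ {blue, red,
animal, object} has weight w_f; a compound cue's value is
V = (w_colour + w_shape)/2, and after every trial both presented weights
move by α (r − V) with r ∈ {0, 1} the reward availability. The mean (not
sum) combination keeps V in [0, 1], interpretable as a probability
estimate.

Behaviour:

* RT = base_rt − β_rt · V + Gaussian noise (SD σ_RT), truncated to the
  response window by resampling (≤100 draws, then clamping);
* omissions and premature responses are injected at fixed per-trial rates;
  premature responses occur anywhere from 0.3 s after cue onset to 100 ms
  after probe onset, so some fall under the first-level 1.25 s exclusion;
* end-of-block visual-analogue ratings: 100 · clip(V + δ_level, 0, 1) plus
  rating noise (SD in mm), where δ is the subject's stable aberrant trait —
  a single draw d ~ N(0, κ²) applied as +d/2 to the first irrelevant level
  and −d/2 to the second. Modelling aberrance as a fixed per-subject
  offset (rather than trial-wise noise) matches the construct of a stable
  individual difference that group covariate analyses can pick up.

Defaults (the cohort conditions): n = 19 subjects; α = 0.25; κ = 0.14 —
chosen so the expected explicit aberrant measure, 100·κ·√(2/π) ≈ 11.2 mm,
sits at the magnitude reported for healthy adults; β_rt = 20 ms per unit
value (giving implicit adaptive effects of a few ms); base RT 300 ms,
σ_RT = 30 ms, rating noise 10 mm; omission and premature rates 0.070 and
0.042 per trial (≈4.5 and ≈2.7 events per 64-trial block, the rates seen
in healthy cohorts). Population calibrations: practice mean RT
~ N(300, 30²) ms (floor 150), SDF ~ N(20, 5²) ms (floor 5).

What the generator does *not* emulate: within-block learning curves in the
ratings (ratings probe block-end values only), RT sequential effects,
fatigue, and any coupling between aberrant ratings and RTs (κ acts on the
explicit channel only — matching the empirical finding that explicit and
implicit aberrant measures are uncorrelated). Passing tests therefore
validate the pipeline's statistical machinery, not the claim that this
agent reproduces human group means. Two consequences observed and accepted:
valid responses are forced into the probe window, so simulated earnings run
higher than human earnings; and the bounded 0–100 mm rating scale saturates
the explicit adaptive measure for α ≳ 0.3, so learning-rate monotonicity
holds (and is tested) below that regime.

## Behavioural measures

Per block: explicit adaptive = rating(high relevant feature) − rating(low);
explicit aberrant = |rating(level A) − rating(level B)| across the
irrelevant dimension; implicit adaptive = meanRT(low) − meanRT(high);
implicit aberrant = |meanRT(A) − meanRT(B)|. A feature level's rating is
the mean of the two cue-type ratings containing it; implicit measures use
valid responses only, and a block with no valid RT in a needed condition
yields NaN (the across-block mean is NaN-aware). Subjective relabeling
assigns the irrelevant level with the higher mean rating to
"subjective-high", per block; exact ties break toward canonical order
(animal before object, blue before red) and carry a tie flag into the GLM
stage. Outlier exclusion is leave-one-out: a subject is dropped when its
value lies more than 3.5 SD (configurable) from the mean of the remaining
subjects; by default this is applied to the implicit adaptive measure only.

## First-level GLM

Each block is one run. Six conditions — the four cue types (2 s events,
cues dropped when no response occurred or the response came <1.25 s after
cue onset) and reward outcome (1.5 s events, always modelled, since
feedback is delivered regardless) plus its parametric modulation by payout
(0–100p, mean-centred over all outcomes before convolution to decorrelate
it from the main outcome regressor) — are convolved with a canonical
double-gamma HRF (response peak parameter 6, undershoot 16, ratio 6,
32 s support, peak normalised to 1) and its temporal (1 s onset-shift
finite difference) and dispersion (0.01 dispersion-step finite difference)
derivatives at a microtime resolution of TR/16, then sampled at scan
onsets (TR 2.73 s). Discrete-cosine drift regressors span periods longer
than 128 s; an intercept closes the design (18 task columns + ⌊2·N·TR/128⌋
drifts + 1).

Fitting is two-pass prewhitening: OLS, then a single run-level AR(1)
coefficient pooled over voxels, then whitening of both sides and a refit.
The raw lag-1 residual autocorrelation is biased by the fitting projection
(order −p/n even under white noise), so the estimator solves the trace
fixed point g(ρ) = tr(M A M Σ(ρ)) / tr(M Σ(ρ)) = r₁ for ρ, with M the
residual-forming matrix, A the symmetrised lag operator and Σ(ρ) the AR(1)
correlation matrix (bisection on [−0.95, 0.95], tolerance 1e-4). When the
fit is numerically exact (residual power ≤1e-16 of data power) ρ is set to
0. Grand-mean scaling of each run to 100 is available (`global_scale`,
used by the CLI) but off by default so that noise-free algebra is exact.

Contrasts act on canonical-HRF columns: parametric outcome (+1 on the
modulation column); adaptive (+½ on each cue type bearing the
high-probability relevant feature, −½ on the others); aberrant (same form
but the +/− assignment follows each block's subjective relabeling, so a
level may flip sign between runs; ties warn). Subject-level values average
the per-run contrasts; standard errors combine per-run variances
w'(X'X)⁻¹w·σ².

## Group level

Voxelwise OLS of subject contrast maps on an intercept plus a centred
covariate (a learning measure averaged over blocks), giving the group-mean
t, the covariate t and the equivalent Pearson r (t² = r²(n−2)/(1−r²),
exactly). Familywise error is controlled by max-statistic permutation —
sign-flipping of subject maps for the mean effect, covariate shuffling for
the covariate effect; corrected p = (1 + #{max-null ≥ |t|})/(n_perm + 1) —
chosen over random-field theory because it is exact at any grid size and
needs no smoothness estimation; only voxel-level (not cluster-extent)
inference is provided. Volumes of interest are spheres in mm space
(default radius 8 mm) containing every voxel whose centre lies within the
radius; the grid convention is a 3 mm isotropic affine.

Reported peak correlations from human cohorts (|r| ≈ 0.7–0.8) are peak-voxel
statistics on real subjects; they guide the default synthetic effect sizes
in the end-to-end tests and are not reproduction targets.

## Numerical and problem-size choices

Tests and the verification experiments run at desk scale: 500-scan runs
(the three SAT blocks laid end-to-end at the task ITI, truncated to the
run) for GLM and AR(1) recovery; 16-voxel pools and 100 repeats for AR(1)
calibration; 200 null cohorts (n = 19, 216 voxels, 200 permutations) for
the FWE calibration; 100-subject cohorts for generative-parameter
recovery. Coverage assertions use the exact t-distribution nominal rates
with binomial Monte-Carlo slack.

## Known limitations

No spatial preprocessing (realignment, normalisation, smoothing), no
slice-timing or motion regressors, no cluster-extent or random-field
inference, no RL-model fitting to real data, and a single pooled AR(1)
coefficient per run rather than voxelwise or spatially regularised serial
correlation models.
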