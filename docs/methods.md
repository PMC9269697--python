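# Methods

## Problem setting

`mobiso` operationalises a digital-phenotyping question: can the mobility
patterns of elderly users — where they dwell, how far and how fast they
move, indoors and outdoors — classify their loneliness risk as measured
by two short questionnaires? The package implements the full analysis
chain from raw sensor logs to classifier evaluation, together with a
synthetic trace generator that stands in for participant data (which such
studies typically cannot deposit).

## Sensor models and parsing

**Indoor.** A UWB tag streams one JSON message per line: tag id, epoch
timestamp (seconds, fractional part kept; millisecond epochs are detected
by magnitude and rescaled), a success flag, 3-D local-frame coordinates,
a three-axis accelerometer triplet, the mood-button state (0 neutral /
1 happy / 2 sad) and the zone array. Coordinate units are treated as
millimetres — the platform convention for UWB local frames; the log
itself states no unit, so the conversion lives in one place
(`indoor_feature_rows`) if a deployment differs. Messages whose position
could not be measured (`success: false`) are excluded from positional
analysis but counted, and the parser maintains the invariant
`parsed + skipped + dropped == input lines`, so no record disappears
silently. Transport metadata (message ids, version strings, anchor
diagnostics) is discarded at parse time.

**Outdoor.** A GPS tracker logs `$GPRMC` sentences. The parser requires
the 12-field comma layout of the tracker's output (header, UTC time,
validity letter, lat, N/S, lon, E/W, speed in knots, true course, date,
two empty magnetic-variation fields), tolerates a trailing `*hh` checksum
without verifying it, and maps 2-digit years to 2000–2099. A `V`
(invalid) fix is parsed and retained with `valid=False` rather than
rejected: dropping it silently would distort dwell-time accounting, so
exclusion happens explicitly in the feature stage. Other sentence types
are skipped with a count.

## Geometry

Latitude/longitude arrive as ddmm.mmmm; decimal degrees are
`deg + minutes/60`, negative for S/W. Projection to a local planar frame
is equirectangular about a reference point with mid-latitude scaling
(easting uses the cosine of the mean of the point's and the reference
latitude). On a spherical Earth of radius 6 371 km this stays within
0.1 % of the great-circle distance for offsets up to ~50 km — city scale,
where the study lives — and the tests enforce that bound against a
haversine oracle. Indoor coordinates are already Cartesian and are used
directly; distance defaults to the planar x–y components (a 3-D switch
exists, since whether the vertical axis should contribute is a judgement
call for single-storey facilities). Speed over ground converts at the
international knot, 0.514444 m/s.

## Windowed features

Streams are cut into contiguous, non-overlapping windows anchored at the
first sample: 10 s indoors (16 samples at 1.6 Hz), 40 min outdoors
(4 fixes at the 10-min logging interval). A trailing partial window is
kept only when it holds *strictly more than half* the samples a full
window would — so 35 s of indoor data yields exactly three windows; the
boundary case (exactly half) is dropped, because variance-type statistics
on half-filled windows are the unstable ones.

Nine accelerometer statistics per window: mean, median, population SD,
Fisher (excess) kurtosis and adjusted skewness are computed per axis and
averaged across the three axes into one value each (the per-axis variant
is available by calling `accel_statistics` directly on axis slices);
signal magnitude area, signal energy and average resultant acceleration
are per-sample aggregates of the vector norm / absolute sums as usual in
activity recognition. Zero-variance windows report skewness 0 and
kurtosis 0 rather than NaN. Peaks are local maxima of the resultant
magnitude with prominence ≥ 0.5 × the within-window SD of the resultant —
a scale-free rule, since no absolute threshold suits both quiet and
active windows; the multiplier is configurable.

Window distance is the polyline length of the positions inside the
window, and estimated speed is that distance divided by the window
length. The two are therefore proportional whenever windows are complete
— their Pearson correlation is 1 by construction and ≥ 0.9 under partial
windows — which is precisely the redundancy the correlation-pruning step
removes before classification. Course averaging is circular (vector mean
of unit headings): an arithmetic mean of degrees is wrong across the
0/360 seam. Categorical features (zone/cluster id, mood) take the modal
value of the window, ties broken by earliest occurrence.

## Place discovery and dwell

Outdoor fixes carry no place identity, so frequently visited places are
discovered per user with k-means (10 restarts, fixed seed) on the
projected coordinates. In auto mode the cluster count maximises the
silhouette score over k ∈ [2, 8]; k = 1 is returned only for degenerate
inputs (fewer than 3 points, or all points at one location), because
silhouette is undefined for a single cluster. k_max = 8 reflects the
small number of places an elderly cohort realistically frequents. An
optional speed filter can exclude transit fixes before fitting; it is off
by default. Indoor dwell uses the zone ids recorded in the log and never
invokes clustering.

Dwell time credits each inter-sample interval to the place of its leading
sample — unbiased under uniform sampling — and the last sample of a day
contributes no interval; a single-sample day credits 100 % to its place.
Percentages are normalised per user-day (rows sum to 100) and total
observed time is conserved. Cluster ids are per-user labels; an optional
greedy centroid-distance matcher pairs places across users.

## Questionnaire scoring and labels

LSNS-6: six items each 0–5, total 0–30, higher = more socially engaged;
a total ≤ 12 flags risk of social isolation. UCLA-3: three items each
1–3, total 3–9, higher = lonelier. Both totals are binned into three risk
labels (0 low / 1 medium / 2 high); the scales run in opposite
directions, so the bins invert for LSNS-6. The three-level cutoffs are an
explicit, validated configuration rather than a constant: the only
externally anchored boundary is the LSNS-6 at-risk threshold of 12, which
the defaults place at the high-risk label's upper edge (≤ 12 → 2,
13–17 → 1, ≥ 18 → 0; UCLA 3–4 → 0, 5–6 → 1, 7–9 → 2). Labels are monotone
in both scores by construction, and every in-range score maps to exactly
one label for any valid cutoff set.

## Classification harness

Correlation pruning computes the Pearson matrix over the numeric features
and, for each pair with |r| above the threshold (default 0.9), keeps the
configured preferred member — distance for the indoor pair, GPS speed
over ground for the outdoor pair, the combination that performed best as
features; constant columns (undefined correlation) are flagged and
excluded. Fusion aggregates window rows to user-days (mean of numerics,
mode of categoricals) and inner-joins the two domains, so only user-days
observed in both survive; an empty intersection is an error that names
the one-sided user-days.

Three classifiers: SVM with an RBF kernel (standardised inputs — RBF
kernels are scale-sensitive), random forest and XGBoost at library
defaults apart from the tree count (default 100), plus logistic
regression as an optional fourth that default reports omit. Categorical
features are one-hot encoded. The default split is a stratified 80/20
hold-out with a fixed seed; windows of one user can land in both folds,
which matches the usual protocol of such studies but flatters
generalisation, so a grouped leave-users-out split and a stratified
k-fold are provided as alternatives. Stratification is the only
class-imbalance measure, deliberately. Confusion matrices are normalised
so each true-class row sums to 100 % (a flag switches to column
normalisation); classes absent from a test fold are reported in the
evaluation's warnings, not fatal.

Cross-domain transfer reduces each domain's table to the shared mobility
features (distance, estimated speed), fits XGBoost on one domain and
scores on the other: in regression mode (predicting distance from speed)
RMSE, MAE and R² are reported with R² unclipped — a negative value means
the transferred model fits worse than predicting the test-set mean, the
expected outcome when the two domains' distance scales differ by orders
of magnitude — and in classification mode (identifying the user) accuracy
and per-user recall.

## Synthetic trace generator

The generator emulates the study conditions: a 09:00–17:00 indoor day
sampled at 1.6 Hz and a 24 h outdoor day sampled every 600 s (the logging
hardware's documentation and the analysis spacing disagree between 3 and
10 minutes; 600 s is the default and it is configurable). Each user
profile fixes 1–4 favoured indoor places and a few outdoor places with
visit probabilities, a gait speed (0.6–1.3 m/s, the elderly walking
range), a per-axis accelerometer noise SD, mood probabilities and
ground-truth questionnaire scores.

Movement follows a two-state model: dwell at a place centre with Gaussian
jitter (0.3 m indoors — UWB accuracy plus body sway; 8 m outdoors —
consumer GPS error), and straight-line transit between places at gait
speed. Days are schedule-based rather than i.i.d. per time slice: the day
is cut into fixed segments (10 min indoors, 1 h outdoors), segments are
allocated to places by largest-remainder rounding of the visit
probabilities and shuffled, and consecutive same-place segments merge.
Daily routines are structured in exactly this way, and the construction
makes each day's dwell fractions match the visit probabilities up to
rounding — a 78/20/2 profile reproduces as 77.1/20.8/2.1 at the indoor
segment count — so empirical dwell percentages converge within ±3 points
of the profile well inside five simulated days. Accelerometer synthesis
puts gravity (9.81 m/s²) on the vertical axis, adds a ~2 Hz gait bounce
proportional to walking speed while in transit, and per-axis Gaussian
noise; this makes the nine window statistics discriminative between users
without biomechanical modelling. Mood-button states are redrawn
independently per visit from the profile's mood probabilities — real
button-usage dynamics are unknown, so the simplest exchangeable model is
used. GPS speed over ground is gait speed (plus 5 % noise) in transit and
|N(0, 0.05)| knots at rest; course is the bearing to the next fix in
transit and uniform at rest.

Values are quantised at generation time to the precision the log formats
carry (millimetre coordinates, 10⁻⁴ g accelerations, millisecond
timestamps, 10⁻⁴ arc-minutes, 0.01 kn, 0.1°), so emit→parse round-trips
are exact equalities, and each user draws from an independent child
generator seeded by (seed, user id), so identical inputs reproduce the
emitted logs byte for byte and adding a user never perturbs existing
streams.

The default population (`make_profiles`) alternates home-body profiles
(one dominant place, slow gait, low engagement scores) with mobile
profiles (3–4 places, brisker gait, high engagement scores), with gait
speeds and noise levels spaced across the cohort and dominant rooms
staggered so no two users favour the same room — a deliberately
contrastive cohort, like the behavioural range such studies report.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GPS urban-canyon multipath and dropouts, road
networks (transit is straight-line), circadian structure beyond the fixed
day windows, within-user day-to-day drift, device failures, and any
genuine causal link between mobility and loneliness — profile scores are
assigned, not generated from behaviour. Classifier accuracies on
synthetic cohorts therefore demonstrate that the harness recovers
separable signal, not that real cohorts are separable.

## Problem sizes and numerical choices

The test suite simulates a four-user, two-day cohort once per session
(~370 k indoor samples) and smaller single-user runs per test; the
acceptance script uses one user-day (46 080 indoor samples, 2 880
windows). k-means ties in nearest-centroid assignment resolve to the
lowest cluster id; modal ties to the earliest occurrence; the circular
mean guards the −0.0 mod 360 edge so courses stay in [0, 360). Feature
tables serialise through CSV with an explicit `NA` missing token and
round-trip numerically at 10⁻⁹.

## Known limitations

Auto-k by silhouette cannot return k = 1 for genuinely unimodal but
noisy point clouds (it will split them); use an explicit k when the
ground truth is one place. The per-user hold-out protocol measures
within-cohort separability, not generalisation to unseen users — use the
grouped split for the latter. The LSNS-6/UCLA-3 three-level cutoffs
beyond the at-risk anchor are conventions, not published constants, and
should be reported alongside any result that uses them.
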