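# Methods

## Problem and data model

During the pharyngeal phase of swallowing the hyoid bone is pulled
anteriorly and superiorly; this excursion protects the airway and opens the
upper esophageal sphincter.  Reduced excursion and slower movement are
associated with aspiration (material passing below the vocal folds) and
with post-swallow residue pooling in the pyriform sinuses.  `hyokin`
quantifies hyoid kinematics from per-frame landmark annotations of
lateral-view videofluoroscopic swallow studies (VFSS) and screens the
resulting parameters as predictors of aspiration and pyriform stasis.

The input is not video but a per-recording annotation table: for each frame,
pixel coordinates of six bony points of interest — the anterior–inferior
corners of the C2–C5 vertebral bodies and of the hyoid, plus the most
prominent anterior–inferior mandible point — together with recording
metadata (frame rate, mm-per-pixel calibration, Penetration–Aspiration
Scale score, MBSImP pharyngeal-residue component, bolus consistency).
Recordings in which these landmarks could not be recognized reliably are
excluded: a recording is dropped when more than 20% of frames miss any
landmark or fewer than 10 complete frames remain (both configurable; the
exclusion principle is clinical practice, the numeric thresholds are this
package's documented defaults).

## Anatomical coordinate frame

Each frame is re-expressed in a spine-anchored frame: origin at the C4
corner, superior axis along the C5→C3 direction, anterior axis
perpendicular to it with its sign fixed by the mandible (always anterior to
the spine in lateral view).  Because the axes are rebuilt on every frame,
any rigid motion of the head — rotation plus translation of all landmarks —
cancels exactly; the invariance is enforced by property tests at 1e-9 mm.
Note the working origin is C4 with the C5→C3 *direction* translated there:
a line through C3 and C5 need not pass through the C4 corner, but only the
origin and the axis directions matter for displacements.  Coordinates are
scaled to millimetres with the recording's `mm_per_pixel`; a convenience
(`derive_scale_from_c2c4`) can derive the scale from a known C2–C4 distance
but is off by default.  Axes may optionally be frozen to a reference frame
for sensitivity analysis by smoothing/averaging upstream; the default is
strictly per-frame.

## Kinematic parameters

Six parameters per swallow, in the field's notation: maximal anterior
displacement Dx, maximal superior displacement Dy, maximal Euclidean
displacement Dxy (mm), and the average velocities Vx, Vy, Vxy (mm/s)
obtained by dividing each displacement by the motion duration, so
V·duration = D holds exactly.  Displacements are measured from the hyoid
position at motion onset — the standard excursion convention, which makes a
stationary hyoid score zero — with a `reference="c4_origin"` switch for the
alternative convention of measuring from the C4 origin.  Dy is a signed
superior maximum: posterior or inferior motion does not contribute.

The motion window (recognizable initiation to termination of hyoid motion)
is human-judged in clinical practice; the automatic detector is a documented
operationalization with manual per-recording overrides.  Defaults: the
trajectory is smoothed with a centred 5-frame moving average (shrunken
symmetric windows at the edges, so the filter is zero-phase); onset is the
first run of ≥3 consecutive frame-to-frame speeds above 5 mm/s; later runs
of ≥3 suprathreshold frames are chained into the window while the
sub-threshold hold between them lasts ≤0.5 s (so the peak hold stays inside
the window and the duration includes the return phase); offset is the last
point of the final chained run.  Requiring the minimum run length for
*every* chained run, not just the onset run, keeps isolated jitter spikes
from stretching the window — with 0.5 px annotation noise the smoothed speed
noise is ~2–3 mm/s per axis, so single suprathreshold noise frames are
common while three in a row are rare.  A trajectory with no qualifying run
raises a no-motion error and the recording is logged, never silently zeroed.
Onset/offset land on frames, so durations and velocities are quantized to
1/fps; tests use this as their discretization tolerance.

## Group assignment and statistics

Groups follow the clinical definitions: normal = PAS 1 with residue
component 0–1; aspiration = PAS 6–8; stasis = residue 2–4.  Recordings
meeting both the aspiration and stasis criteria are excluded from analysis
rather than prioritized, and PAS 2–5 with low residue (penetration without
aspiration) is left unclassified; the assignment is total over the 8×5
score grid.

Per group and parameter the package reports n, mean, linear-interpolation
quartiles and a t-based 95% CI of the mean (the CI method is this package's
choice; only mean and CI bounds are conventionally reported).  A
Shapiro–Wilk gate is computed and logged per group; the comparison path is
nonparametric regardless: Kruskal–Wallis (mid-rank, tie-corrected,
chi-square reference) per parameter, with pairwise two-sided Mann–Whitney
post hoc tests run only when the omnibus p < 0.05.  Mann–Whitney uses the
exact null distribution for tie-free pooled samples up to n=30 and the
tie-corrected normal approximation (no continuity correction, so the
two-group case squares to the Kruskal–Wallis H) otherwise.  Post hoc p
values are unadjusted by default, with Bonferroni and Holm available.
Repeated swallows from the same patient are treated as independent
recordings, as in the source study design.

## ROC screening

Impairment presents as *smaller* displacement and velocity, so every
parameter is scored lower-positive: predict the condition when the value is
at or below the threshold (ties count as positive).  Thresholds sit at
midpoints between consecutive distinct values plus ∓∞ sentinels; AUC is the
trapezoidal area and equals the Mann–Whitney concordance probability, which
is verified against a brute-force pairwise oracle.  The operating cutoff
maximizes the Youden index (ties broken toward higher sensitivity, then the
lower threshold), and a parameter is flagged acceptable when AUC > 0.7.
The comparator for "condition present" is target-vs-rest by default (all
other classified recordings), with a normal-only alternative; neither is
asserted to be the source study's choice, which is unstated.

## Synthetic data generator

The study's videos are not deposited, so validation runs on a forward model
that emits landmark-level recordings with known ground truth.

**Value distributions.** Each group/parameter is calibrated to a printed
(mean, q1, q3) triple by a three-parameter shifted log-normal
`shift + LogNormal(mu, sigma)` solved numerically (1-D root in sigma) to
reproduce the triple to ~1e-9 relative error.  Such a fit exists whenever
the mean exceeds the quartile midpoint (right skew, consistent with the
reported non-normality); otherwise a gamma matched to (mean, q3) is used
with a warning.  Draws are floored at a small positive value; for the most
skewed published triples the sub-zero mass is ≤8% but its expected shortfall
is <0.2 mm, so the flooring perturbs means by ≲1%.

**Trajectory.** The hyoid leaves its rest position along a fixed
anterior–superior direction (angle θ drawn uniformly; Dx = Dxy·cosθ,
Dy = Dxy·sinθ), rises with a minimum-jerk profile, pauses at the peak, and
returns with a minimum-jerk profile.  When the drawn duration is long
relative to the amplitude, a plain pause would drop below the 5 mm/s
detection threshold and truncate the window, so the pause is filled with
small re-pump oscillations (≤1.6 mm, ~0.2–0.3 s half-cycles) just below the
peak — partial descents and recoveries as seen in effortful or piecemeal
swallows — keeping the window detectable for arbitrarily slow swallows.
Ground truth is defined operationally: the value the extraction pipeline
measures on the noise-free trajectory.  The generator therefore calibrates
amplitude and segment timing against the same smoothed, frame-discretized
detector the analysis uses (three fixed-point iterations), after which
zero-noise extraction matches ground truth to within one frame step.
Draws whose required amplitude falls below a 2 mm detectability floor are
truncated (for velocity targets the window is stretched up to 8 s first,
preserving the drawn velocity); ground-truth tables record realized values.

**Scene and noise.** Geometry is conventional lateral-view anatomy: C2–C5
corners collinear at 15 mm spacing, mandible 40 mm anterior / 20 mm superior
of C4, hyoid rest 30 mm anterior / 10 mm superior, 0.25 mm/px, 30 fps.
Head motion is a slow rigid sinusoidal translation (≤2 mm) plus rotation
(≤3°, periods 2–5 s) about C4; annotation jitter is i.i.d. Gaussian noise of
0.125 mm (0.5 px) per landmark per frame.  Because head motion is rigid it
cancels in the anatomical frame exactly (verified to 1e-9 mm before
jitter).

**Cohort defaults.** The default cohort is 230 normal / 87 aspiration / 132
stasis recordings.  Each group is Dx-calibrated, with the direction angle
centred where tanθ matches the group's published Dy/Dx mean ratio (≈50°,
60°, 56°; ±5° uniform) so that superior displacement barely separates
groups, and with the duration median set so Dxy/duration matches the
group's published Vxy mean (≈0.94, 1.39, 0.78 s; log-normal with
sigma = 0.3).  Only the calibration target is matched exactly; Dy/Vxy group
means are matched in expectation through the angle/duration model, which is
sufficient for the qualitative checks (ordering of AUCs) but not for
reproducing the published AUCs, which depend on unknown joint distribution
shapes.  PAS/residue labels are drawn uniformly within each group's defining
range, so labels round-trip through group assignment with no doubly-affected
cases; the generator does not model any within-group coupling between
scores and kinematics (none is published).

**What the generator does not emulate.** Real annotation error is likely
autocorrelated and rater-specific rather than i.i.d.; real swallows curve,
vary in speed asymmetrically, and include epiglottic/laryngeal motion that
can confound landmark recognition; bolus consistency is passed through but
does not modulate kinematics; repeated swallows of one patient are
uncorrelated here.  Passing tests therefore demonstrate correctness of the
measurement pipeline and statistical layer under the stated noise model,
not clinical validity on real video.

## Numerical choices and problem sizes

Quartiles: linear interpolation (the common statistical-package default).
Distribution fits: Brent root-finding at 1e-14 tolerance.  Motion-window
discretization: one frame.  Validation batch sizes were chosen to keep
sampling error well inside the tolerances they are checked against:
calibration-recovery runs use n = 2000 recordings per group/parameter
(standard error of the recovered mean ≲1.5%, checked against a ±5% band);
qualitative ROC-ordering checks use the default 449-recording cohort; unit
and property tests use tens to hundreds of samples.  All randomness flows
through `numpy.random.default_rng` seeds, so every simulation, test and the
acceptance script are reproducible bit for bit.

## Known limitations

* The motion-window detector is an operationalization of a human judgement;
  its defaults (5 mm/s, 3 frames, 0.5 s) are package choices, and real
  cohorts may need per-recording manual windows.
* Calibration is per-target: one simulated cohort reproduces one published
  parameter's distribution exactly, the others only through the trajectory
  model.
* Clustered (per-patient) inference is out of scope; the statistics treat
  recordings as independent.
* AUC confidence intervals and multivariable classifiers are not provided.
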