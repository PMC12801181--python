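# Methods

## Model and assumptions

The core quantity is the Poisson linear-quadratic tumor control
probability with repopulation.  Voxels are independent Poisson clonogen
populations; the per-clonogen log-survival after a full schedule is

    log SF_i = −α·n·d_i − (α / (α/β))·n·d_i² + ln2 · T_exp / T_pot

so `β` is always derived as `α/(α/β)` and never an independent parameter.
`SF` is deliberately not clamped at one: at zero dose the repopulation term
gives `SF > 1`, and the Poisson voxel TCP `exp(−N·SF)` handles that
naturally.  The whole-prostate TCP of one radiosensitivity realization is
the product of voxel TCPs, accumulated as `exp(Σ log TCP_i)` to avoid
underflow on large masks.

Inter-patient radiosensitivity heterogeneity enters through `α`, drawn from
a log-normal distribution whose *arithmetic* mean and SD are 0.15 and
0.04 Gy⁻¹; the log-scale parameters are solved analytically
(`σ² = ln(1 + cv²)`, `μ = ln m − σ²/2`).  Draws are restricted to
[0.05, 0.40] Gy⁻¹ by inverse-CDF sampling on the truncated quantile range
rather than rejection: this is exact, handles arbitrarily narrow windows,
and makes the infeasible-window failure mode a clean error (the window's
probability mass underflows double precision) instead of a stalled loop.
The truncated mean is slightly below 0.15 Gy⁻¹ (≈0.14999); this is
documented, not corrected.

By default one `α` is drawn per Monte-Carlo realization and shared by all
sampling voxels — a "virtual patient", matching the population-level
calibration interpretation of the distribution.  Per-voxel independent
sampling is available behind a switch (`per_voxel_sampling`).  The overall
TCP is the mean of whole-prostate TCPs across realizations (not the product
of per-voxel mean TCPs), and the voxel map holds per-voxel mean TCP.
Default 1000 realizations; the seed is required in CLI runs and recorded in
the result.

Schedule timing: `T_pot` defaults to 42 days and `T_exp` is derived from
the fraction count at 5 fractions/week as the elapsed days from first to
last fraction, `7·⌊(n−1)/5⌋ + ((n−1) mod 5)`; both are plain schedule
fields and can be set explicitly.

## Segmentation and histopathology adjustment

Biopsy-style segments are generated geometrically: left/right at the mask
centroid's sagittal plane, base/mid/apex as equal-extent thirds of the
superior-inferior span (base superior), and, for twelve segments, an
anterior/posterior split at the centroid coronal plane.  Plane offsets are
configurable for sensitivity checks.  The partition is validated (every
mask voxel labeled exactly once, no empty segment).

The % adenocarcinoma acts as a voxel-wise multiplicative factor on atlas
cell density, with benign segments floored at 1% to account for
undetected disease; it is not a renormalization of segment totals.  One
consequence worth knowing: with a multiplicative factor ≤ 1 the density
adjustment alone can only raise overall TCP relative to baseline, and the
score-dependent α/β adjustment outweighs it only where segment involvement
is substantial (roughly above the ratio of expected surviving fractions,
~30% at conventional fraction sizes).  Whole-patient TCP reductions under
method 4 therefore require the extensive multifocal involvement typical of
recurrence cohorts, which is how the test patients are constructed.

Method 3 realizes the 75:25 primary:secondary pattern split as two Poisson
subpopulations within each voxel — `TCP_i = exp(−0.75·N_i·SF(α_prim))·
exp(−0.25·N_i·SF(α_sec))` — preserving the Poisson model per
subpopulation; equal patterns collapse to a single component.  Benign
segments receive the least aggressive defaults (`α_GP2` under method 3,
`α/β_GS2+2` under method 4).  The tumor-probability atlas participates
multiplicatively in the clonogen count only behind an explicit flag
(default off), since its role is qualitative (localizing likely tumor)
rather than a calibrated count adjustment.

## Calibration

The cohort forward model evaluates, per patient, `exp(−Σ_g N_g·SF_g(α))`
summed over grade groups, and averages over patients; the expectation over
`α` is computed with 128-node Gauss-Legendre quadrature on the truncated
log-normal density (weights renormalized to one).  A common-random-numbers
Monte-Carlo rule is available (`DEConfig(alpha_rule="monte-carlo")`), but
quadrature is the default because it gives the optimizer a smooth,
deterministic objective with no sampling noise at equal cost.

Ranking constraints are enforced by construction: differential evolution
searches a unit hypercube that a chain of bounded increments maps onto
strictly ordered tuples inside the bounds, so every candidate at every
iteration is feasible (no penalty terms).  The discrepancy metric is
100 × mean |model − observed| across schedules (RMS available by config);
default 500 DE iterations.

The DE stage is followed, for the 4- and 9-parameter fits, by a
multi-start trust-region least-squares refinement on the residual vector
in the natural parameter space (ordering maintained by sort-projection,
bounds by the solver).  This matters because the objective has long,
nearly flat curved valleys when a grade carries few clonogens: DE plus its
default polish lands 0.1–0.4 Gy from the noise-free optimum, while the
refinement recovers synthetic ground truth to better than 0.01 Gy.
Jittered restarts (default 10, SD 3% of the bound width) escape local
valley minima; refinement is on by default and can be disabled.

After fitting, a finite-difference sensitivity of the objective to each
parameter is reported, and parameters with negligible slope are flagged
flat — e.g. the highest-pattern α when the cohort contains no such cells.

Identifiability: each schedule contributes one cohort-mean target, so nine
score-dependent ratios need at least nine schedules with a wide spread of
fraction sizes to separate the quadratic term.  The synthetic recovery
setup uses twelve schedules from 2.0 Gy/fraction conventional courses to
7.25 Gy/fraction SBRT.  Conversely the pattern-specific fit uses fixed
(unsampled) α values, under which curative-dose cohort TCP saturates near
one and carries no signal; its recovery setup therefore uses six
reduced-dose schedules where the fixed-α model leaves mid-range control
probabilities.

## Statistical evaluation

The Wilcoxon signed-rank test drops zero differences, assigns mid-ranks to
tied absolute differences, and takes `W+` as the rank sum of positive
differences.  Exact mode computes the null distribution of `W+` over all
2ⁿ sign assignments by dynamic-programming convolution (doubled ranks keep
the support integral), used up to n = 25; the two-sided p is
`2·min(P(W ≤ w), P(W ≥ w))` capped at one.  With ties present there are
two defensible exact references: the classical unconditional distribution
of the integer ranks 1..n, and the conditional distribution of the
observed mid-rank vector.  The default is unconditional, because tables of
reported summary values are typically rounded and rounding-induced ties
should not perturb the reference null (on the packaged nine-patient table
they would shift the density-only comparison from 0.570 to 0.551); the
conditional null is available as `tie_null="conditional"`.  The normal
approximation uses the tie-corrected variance with continuity correction.

The volume-weighted region comparison computes region overall TCPs as
products of voxel-map values and rescales the nonGTV product to a
GTV-equivalent volume, `TCP_nonGTV^(V_GTV/V_nonGTV)`; the direction is
chosen so a spatially uniform map compares as exactly equal, and only the
volume ratio enters, making the result invariant to voxel-volume
rescaling.  Low-TCP/GTV alignment — a quantitative surrogate for visually
overlaying recurrence contours on maps — reports the fraction of the
lowest-decile TCP voxels (quantile configurable) inside the GTV; a
spatially constant map returns the GTV volume fraction with a warning.
Histograms are descriptive only; no voxel-wise testing or multiplicity
correction is performed.

## Synthetic data

The phantom is an ellipsoidal prostate (default 40×40×30 voxels at 2 mm,
semi-axes 24×20×22 mm) with a posterior outer shell standing in for the
peripheral zone — crude anatomically, but sufficient to exercise the
spatial structure of the atlases.  Cell density is an i.i.d. log-normal
field (median 60 cells/voxel, log-SD 0.4), doubled in the shell and
multiplied inside spherical lesions; these are *effective clonogen*
densities on the scale population TCP calibration yields (whole-prostate
totals of order 10⁵–10⁶), chosen so baseline overall TCP lands in the
high-80s to mid-90s percent at conventional prescriptions.  The
tumor-probability field is piecewise (0.10 base, 0.35 shell, 0.90 lesion).
Reports derived from phantoms assign each segment the most aggressive
intersecting lesion's score and the lesions' voxel share as percent
involvement.

Calibration cohorts draw per-patient totals log-normally (median 3×10⁵,
log-SD 0.6) and partition them over patterns and scores with Dirichlet
weights concentrated on mid grades (extreme grades present but rare,
mirroring surgical-cohort histology).  Outcome targets are forward-model
cohort means under known ground-truth parameters, optionally plus Gaussian
noise.  Every generator is a pure function of its spec and seed.

What passing tests show — and don't: the synthetic fields are spatially
independent (no atlas smoothness or registration error), doses are uniform
up to optional multiplicative noise, reports contain no sampling error,
and targets come from the model's own forward map.  Results therefore
validate the implementation and its statistical machinery, not the
clinical accuracy of the atlases or parameters on real patients.

## Numerical choices and problem sizes

Quadrature: 128 Gauss-Legendre nodes (1e-12 floor on window mass).
Monte-Carlo realizations are chunked to bound memory.  Test and
acceptance-script problem sizes — a ~5500-voxel phantom at 1000
realizations, 27-patient cohorts, DE budgets of 60–150 iterations with
populations of 12–20 — were chosen as the smallest sizes at which the
checked quantities are stable; full-scale defaults (500 iterations,
popsize 15) remain the library defaults.

## Known limitations

* The geometric segmentation is an idealization; real biopsy maps vary by
  center and the anterior/posterior convention for twelve-segment reports
  is a choice.
* One finding per segment: multiple cores within a segment must be
  combined upstream.
* Voxel independence ignores spatial correlation in tumor response;
  segment-wise parameter jumps produce non-smooth maps.
* The multiplicative density adjustment cannot lower baseline TCP on its
  own (see above); published per-patient values in the reference table are
  shipped as a fixture, not recomputed, since the underlying patient and
  atlas data are not public.
* The α/β of the highest scores is weakly identified when cohorts carry
  few cells of those grades; the flat-parameter report surfaces this
  rather than hiding it.
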