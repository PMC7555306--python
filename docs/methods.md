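# Methods

## Scattering conventions

All angular variables use the scattering-vector length
`S = 2 sin(θ)/λ` (Å⁻¹), where `2θ` is the scattering angle and `λ` the
X-ray wavelength. The other common convention, `q = 4π sin(θ)/λ`, is
related by `q = 2πS`; `s_to_q`/`q_to_s` convert explicitly. All closed
forms below carry the `4π²/3` Guinier prefactor that belongs to this
convention — mixing up the two is the most common source of silent
factor-of-2π errors in SAXS code, which is why the package never accepts
a bare "q" anywhere.

Lengths are Å, concentrations mg/mL, molecular weights Da. Intensities
are in arbitrary units throughout; every fitted quantity that depends on
the intensity scale (Mw, A2) is defined relative to a reference or to
the instrument constant `K`.

## Forward model

A particle is an assembly of point scatterers ("dummy residues", DR)
with per-bead zero-angle amplitudes `f_i` (default 1) and a nominal
diameter of 3.8 Å — the Cα–Cα spacing, the standard building block of
low-resolution models. The orientation-averaged intensity is the Debye
sum

    I(S) = Σᵢ Σⱼ f_i f_j sinc(2πS·r_ij),

so `I(0) = (Σf)²` (N² for equal beads) and the profile is invariant
under rigid motion and mirror reflection (enantiomer ambiguity). The
exact double sum is O(N²) per S value; a distance-histogram variant
(0.5 Å bins) evaluates each bin at its weighted mean distance with a
second-order curvature correction from the within-bin variance, which
keeps it within 0.1 % of the exact sum on 500-bead models across the
default grid, including form-factor minima. The annealer (below) uses a
finer 0.1 Å histogram with plain bin centers because its incremental
update requires precomputed sinc rows per bin.

No hydration shell or atomic form factors are modelled: beads carry a
single amplitude. This is adequate for the low-resolution questions the
package addresses (overall shape, domain arrangement) and is the reason
bead counts are not interpretable as residue counts.

## Synthetic specimens

`generate_shape` fills a geometric envelope (sphere, ellipsoid, rod,
tandem multidomain chain, or C2-symmetric dimer of chains) with beads on
a cubic grid whose pitch is calibrated to the requested bead count. The
grid is jittered by only 2 % of the pitch: a quasi-stratified layout.
Heavier jitter or random subsampling makes the model's scattering
deviate from the continuum envelope near form-factor minima by several
percent in a seed-dependent way; with stratification plus a final
rescaling of sphere/ellipsoid/rod clouds to the envelope's closed-form
Rg (√(3/5)·R for a sphere), a ~2000-bead sphere tracks the analytic
form factor to ≲1.5 % up to 95 % of the first minimum. Exactly at the
minimum the relative deviation of any discrete model diverges (the zero
shifts with the effective radius), so oracle comparisons stop short of
it.

The "light state" of a chain is produced by rotating the distal half of
the chain rigidly about a hinge at its midpoint (all intra-segment
distances preserved exactly); for the C2 dimer the bend is applied to
one arm and the second arm is generated by the symmetry operation, so
the two-fold invariant holds to machine precision.

## Dilution series and interparticle interference

Solution SAXS at finite concentration obeys, in the dilute linear
regime,

    K·C / I(0,C) = 1/Mw + 2·A2·C              (forward scattering)
    Rg²(C)       = Rg²(0) − Bif·C             (apparent size)

with `A2` the second virial coefficient and `Bif` an empirical
interference slope. The simulator enforces both laws *by construction*:
the ideal Debye curve is multiplied by
`exp(+(4π²/3)·Bif·C·S²) / (1 + 2·A2·Mw·C)` and rescaled so that
`I(0,C) = K·C·Mw/(1 + 2·A2·Mw·C)`. This is deliberately not a
liquid-state structure factor; it is the weakest assumption that makes
the infinite-dilution extrapolation exactly testable (in the noiseless
limit Guinier analysis recovers the injected Mw, A2, Bif and Rg(0)
identically, because the exponential factor shifts the Guinier slope by
exactly `−(4π²/3)·Bif·C` regardless of the base curve's shape).

Noise is relative Gaussian, `σ(S) = ν·I(S)·(1 + S/S_max)` with
`ν = noise_level` (default 1 %, a typical synchrotron statistic at low
angle); the mild angular ramp mimics the poorer statistics at high
angle. True counting statistics of a beamline reduction chain are not
emulated — the σ model is a labelled stand-in, and tests that depend on
error propagation state their noise model explicitly.

Default study conditions: concentrations (1.0, 2.5, 5.0) mg/mL (a
minimal three-point series, matching the usual "at least three
concentrations" design), Mw 51 kDa (a two-domain sensor-kinase-sized
protein), A2 = 2·10⁻⁷ in the units implied by the forward-scattering
law, Bif = 2 Å²/(mg/mL). These were chosen once as realistic and are
not tuned per test.

## Guinier analysis

`guinier_fit` performs weighted linear least squares of ln I vs S²
(errors propagated onto the log), mapping the slope through
`slope = −(4π²/3)·Rg²`. The fit window is found iteratively: start from
the 10 smallest usable points, estimate Rg, keep all points with
`2πS·Rg ≤ 1.3` (the community q·Rg bound, expressed in this S
convention), re-fit until the window is stable (≤ 20 rounds, minimum 5
points). Intensities must decay at low angle; a rising low-angle curve
(aggregation signature) raises "no Guinier region".

The 1.3 cutoff carries a known systematic for compact globular shapes:
for a homogeneous sphere the quartic term of ln I biases the fitted Rg
by +1.4–1.9 % depending on the point distribution in the window. This
is a property of the Guinier approximation, not of the implementation
(the bias is reproduced on the analytic sphere form factor with no
beads involved) — fitting exact Guinier-form data recovers Rg and I(0)
to machine precision. Consequences: parameter-recovery tests at finite
noise compare against the zero-noise limit of the estimator (so that
noise propagation is tested separately from the deterministic window
bias), and cross-checks between Guinier-Rg and P(r)-Rg are performed on
data whose Guinier representation is exact.

`extrapolate_dilution` fits the two concentration laws by weighted
least squares (errors from per-concentration fit errors), returning
Mw = 1/intercept, A2 = slope/2, Rg²(0) and Bif with standard errors
from the inverse normal matrix. The monodispersity verdict follows the
linearity diagnostic: both concentration fits and every Guinier fit
must reach r² ≥ 0.9. This r² rule is brittle when the true Bif slope
is small relative to the noise in Rg² (three points, weak trend); the
verdict then flags a perfectly monodisperse simulation as suspect. The
reasons list always states which fit failed, and the underlying
parameters remain usable regardless of the verdict.

`estimate_mw` is the standard forward-scattering proportion against a
calibrant of known Mw (default hen egg-white lysozyme, 14 300 Da),
assuming equal contrast and a partial specific volume of 0.74 cm³/g for
both proteins; no contrast correction is applied by default.

## Distance distribution and Dmax

`pr_from_model` histograms all pairwise distances weighted `f_i·f_j`
(1 Å bins by default). Its Rg uses the exact finite-N second moment
`Rg² = Σ w·r² / (Σf)²` rather than the continuum `Σr²P/(2ΣP)` (which
would give d/√2 instead of d/2 for a two-bead system).

`ift_pr` solves the indirect Fourier transform as non-negative least
squares on a radial basis: `I(S) = 4π Σ_k P(r_k)·sinc(2πS·r_k)·Δr`,
100 bins on [0, Dmax_trial], with a second-difference smoothness
penalty whose weight is scaled by the Frobenius norms of the design and
penalty blocks (so the dimensionless `smoothness` is invariant to
intensity units and grid sizes). The default smoothness (3.0) is
calibrated on the noiseless sphere reconstruction; long-tailed
distributions (e.g. the Gaussian-decay curve) are better served by ~1.0
— the parameter is exposed everywhere. Noise-free curves (σ = 0) are
weighted by an effective σ of 1 % relative with a small absolute floor
tied to the maximum intensity, preventing infinite weight at form-factor
minima.

`estimate_dmax` scans trial supports and selects the smallest one whose
fit χ² is within 5 % of the scan minimum *and* whose last radial bin
holds < 1 % of the total mass (the distribution has decayed at the
support edge). Both thresholds are artifact choices, exposed as
arguments; the full scan table is always returned, and the
no-qualifying-trial error carries it as an attribute. The selection is
relative to the scan — it reports the least-bad support even when the
whole range is poor, which is visible in the returned χ² column.

Comparisons between an IFT P(r) and a bead-model histogram are made at
the data's real-space resolution: both curves are normalized to unit
area and blurred with a 3 Å Gaussian before the NRMSD is computed. The
raw 1 Å histogram of a quasi-lattice bead model carries neighbor-shell
peaks that no band-limited transform of the profile can reproduce;
comparing unblurred curves measures lattice artifacts, not IFT quality.

## Shape restoration

`restore_shape` minimizes

    E = χ² + w_connect·(fraction of beads with no neighbor within 5.7 Å)
         + w_pack·max(0, 6 − mean neighbor count)

over configurations of `n_dr` beads, where χ² is the scale-optimized
discrepancy

    χ² = Σⱼ [(I_exp(Sⱼ) − K·I_model(Sⱼ))/σ(Sⱼ)]² / (N − 1),

with K solved in closed form at every evaluation. The compactness terms
are the restraint that scattering alone cannot supply; chain-like
connectivity restraints of the GASBOR type are deliberately not
implemented. Moves relocate one random bead (with C2 symmetry: the bead
and its image, so the two-fold axis holds exactly at every step) to a
random contact position 3.8–5.7 Å from another bead; Metropolis
acceptance with geometric cooling. The initial configuration is drawn
inside an ellipsoid whose long axis is Dmax/2 and whose transverse axes
match the target's Guinier Rg — seeding the right anisotropy lets the
annealing spend its moves on detail rather than on slowly stretching an
isotropic blob.

The schedule is calibrated to the landscape rather than to absolute
energy: T₀ is a multiple (default 1.0) of the median |ΔE| over a
60-move probe batch, cooling 0.90 per level, 40 attempted moves per
bead per level, at most 50 levels, stopping after 8 levels without
best-energy improvement. (A T₀ proportional to the initial objective —
a natural first choice — keeps the system in the random-walk regime for
any plausible level count on this objective; the probe-based start
reaches χ² < 1 on sphere and multidomain benchmarks in tens of
seconds at n_dr = 100–200.) Model intensity is maintained
incrementally through a 0.1 Å distance histogram and recomputed exactly
at every level to cancel floating-point drift; the best-ever
configuration is returned, and the per-level best-energy trace is
non-increasing by construction. Identical inputs and seed give
bit-identical results.

`scan_dr_count` repeats restoration over candidate bead counts with
deterministically derived sub-seeds and reports the count with the
smallest median χ². `enantiomer` reflects through the xy-plane;
because the Debye sum depends only on distances, the mirror fits any
profile identically and restored handedness is never meaningful.

## Ensemble classification

`classify_ensemble` implements the multivariate protocol: all models
are superimposed on the ensemble's best-fitting member through their
principal axes of inertia (all four proper axis-sign combinations, plus
the four mirrored ones, scored by mean nearest-neighbor distance;
near-degenerate inertia spectra fall back to the same exhaustive search
with a fixed lexicographic tie-break), digitized on a common 4×4×4 ų
lattice (half-open boxes; a bead exactly on a boundary goes to the
higher-index voxel on every platform), mean-centered and embedded by
PCA with a deterministic sign convention, clustered by seeded 10-start
K-means on the PC1–PC2 plane, and averaged per class: members aligned
to the class's lowest-χ² member, binary occupancies averaged, voxels at
≥ 0.5 mean occupancy become consensus beads. Classes within 10 % of the
best mean χ² are selected. In auto mode the cluster count maximizes the
silhouette over k = 2..min(8, M−1); a best silhouette below 0.25 is
treated as "no cluster structure" and yields a single class, which is
what a single-shape restoration ensemble should produce.

### What classification can and cannot resolve here

A documented limitation, measured on synthetic two-state experiments:
restorations under the energy above carry large-amplitude centerline
"meander" (tens of Å of slice-centroid deviation on a ~110 Å chain)
that leaves the 1-D profile essentially unchanged. A rigid hinge bend
of 30° — and even 60° — displaces the true centerline by less than
this conformational noise, so mixed straight/bent ensembles do **not**
separate on the PC1–PC2 plane (K-means purity ≈ 0.5–0.6), and even
supervised template matching against the true densities classifies
single models at chance. The per-model bend information is simply not
present in the restored coordinates at this restraint level; protocols
of this kind rely on more strongly regularized (chain-compact) models
to work at such subtle conformational differences. Single-shape
ensembles behave as expected (one dominant class, ≥ 90 % membership),
and two-state *profile-level* analysis (ΔRg(0) sign, low-angle
difference localization) resolves the hinge robustly — which is why
the pipeline reports state differences from the profiles and treats
consensus shapes as per-state descriptions, not as state classifiers.

## Pipeline

`run_pipeline` chains, per state: Guinier fits per concentration →
infinite-dilution extrapolation → Dmax scan and IFT on the
lowest-concentration profile (where interference corrections are
smallest) → seeded multi-replicate restoration → classification. Two
states are compared by ΔRg(0) (with combined fit error) and by the
I(0)-normalized difference profile, summarized inside and outside the
low-angle window (default S < 0.012 Å⁻¹, configurable): a hinge-type
rearrangement concentrates the *absolute* normalized difference at low
angles, while the *relative* difference may keep growing with S where
intensities are small — the report carries the absolute metric.
`reversion_check` declares a reverted state "reversible" when its
low-angle relative difference from the dark state is within tolerance
and |ΔRg(0)| is within twice the combined error; the tolerance must
exceed the noise floor, which the tests demonstrate by failing a
zero-tolerance check on same-generator noisy states.

Every stage failure raises with the stage name; reports are plain JSON
with no timestamps, so a rerun with the same inputs, seed and
configuration is byte-identical.

## Problem sizes used in the shipped tests and acceptance script

Sphere oracles use ~1000–2000 beads; restoration benchmarks 60–200
dummy residues with the default or a lighter schedule; the
classification experiment restores 10 + 10 models at n_dr = 150 with a
reduced schedule (40 levels, 30 moves/bead); pipeline-level tests run
with replicates = 0 (profile-level analysis only). These sizes were
chosen so the full chain demonstrates its properties at desk scale;
all of them are ordinary function arguments, and production use at
larger n_dr, more replicates or longer schedules changes nothing but
wall time.

## Known limitations

- Bead models carry one amplitude per bead: no hydration shell, no
  atomic form factors, no contrast variation; the optimal DR count from
  `scan_dr_count` is an empirical χ² minimum, not a residue count.
- The interference model enforces the linear dilution laws rather than
  deriving them; it cannot represent structure-factor curvature at high
  concentration.
- The monodispersity verdict's r² rule is conservative for weak
  concentration trends (see above).
- Mixed-conformer ensemble classification does not resolve subtle hinge
  bends (see the classification section); state comparisons should use
  the profile-level metrics.
- Dmax selection reports scan-relative quality; a scan placed entirely
  below the true support returns its least-bad trial rather than
  failing, unless the end-decay criterion also fails.
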