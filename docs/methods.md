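# Methods

This note documents the models, conventions and numerical choices behind
seedconn, and what the synthetic validation does and does not establish.

## Streamline-to-region assignment

A streamline is a polyline in world millimetres. Membership in a region
is defined by **traversal**, not endpoint termination: any sample of the
(densified) polyline whose nearest voxel carries the region's label makes
the streamline a member. Traversal matches the semantics of
inclusion/exclusion mask filtering in standard tractography tools, where
seed-to-target bundles pass *through* intermediate structures; an
endpoint-termination criterion would be stricter and is not what
mask-based filtering implements. A strict mode (`require_seed=True`)
additionally requires seed traversal; it is off by default because
tractograms entering this pipeline are already seeded in the seed ROI.

Decision rule, in order of precedence:

1. fewer than 2 vertices or non-finite coordinates → `invalid`
   (counted, never silently dropped);
2. traverses any exclusion label → `touches_exclusion`. Exclusion is
   checked first because regions of avoidance are applied during
   tracking upstream: no excluded streamline can ever be counted;
3. traverses ≥ 2 target labels → `multiple_targets`. This is forced by
   the mutual-exclusion construction — each target acts as inclusion
   mask with all other targets as exclusions, so a two-target streamline
   survives in no target's selection;
4. traverses no target → `no_target`;
5. otherwise assigned to the unique target. Seed traversal never counts
   toward the target tally.

Outcomes always partition the tractogram (assigned + discarded = total).

Numerical conventions:

* **Voxel lookup** is nearest-voxel through the inverse affine (labels
  are categorical; interpolation would be meaningless). Continuous
  indices are rounded half-away-from-zero. Non-axis-aligned affines are
  fully supported — no axis shortcut is ever taken.
* **Densification**: before lookup, each segment is resampled so sample
  spacing is at most half the smallest voxel edge, a Nyquist-style bound
  that prevents skipping one-voxel-thick structures between vertices.
  Extremely acute corner clipping (a path entering and exiting a voxel
  corner over a chord shorter than the sample spacing) can in principle
  still be missed; the fine-sampling oracle tests therefore use
  geometries with clear penetration margins.
* Out-of-bounds samples contribute nothing.

## Density profiles

Per subject, with NOSᵢ the count of streamlines assigned to target i:

* δᵢ = 100 · NOSᵢ / Σⱼ NOSⱼ (percent of total assigned NOS);
* δ_NORMᵢ = 100 · wᵢ / Σⱼ wⱼ with wᵢ = NOSᵢ / ((V_seed + Vᵢ)/2), volumes
  in mm³ from voxel count × |det| of the affine's 3×3 block.

δ_NORM is **renormalized to percent** so each subject's profile sums to
100. This makes the four compartment percentages of a profile cohere
(they sum to 100 up to rounding) and renders the measure invariant under
global volume rescaling, so the volume unit is immaterial. An all-zero
profile (no assigned streamline) is an error distinct from a profile with
some zero entries.

Group summaries use the sample SD (n − 1 denominator), the standard
choice for between-subject variability. COV = SD/mean; an all-zero
pathway is recorded with COV 0 rather than NaN, matching how reference
tables report fully disconnected pathways. The density threshold
(default 1 %) is applied to the **group mean** δ_NORM, not per subject.
Compartment aggregation is a plain sum over member targets, and therefore
commutes with averaging across subjects.

Reported tables round half-away-from-zero to 2 decimals. Note that
published tables rounded this way cannot always satisfy COV = SD/mean at
the printed precision: in the packaged reference table the left
interposed (printed COV 0.84, recomputed 0.83) and left dentate (0.89 vs
0.88) rows break the identity by exactly one unit in the last place.
These are displayed-rounding artifacts, and the tests document rather
than "fix" them.

## Lateralization

LI = (L − R)/(L + R) of the group mean δ_NORM per bilateral pair, with
|LI| > 0.1 as the asymmetry flag. The right-lateralization cutoff is
LI < −0.1 (the mirror of the left cutoff). Midline pathways have no
left/right members and are excluded. LI of a fully disconnected pair
(L + R = 0) is undefined (NaN) and never called lateralized.

Significance uses a paired permutation test on per-subject left−right
δ_NORM differences. Under the null the sign of each subject's difference
vector is exchangeable, so the null is generated by independent
per-subject sign flips of whole difference rows — the Blair–Karniski
construction for paired designs, which preserves the across-pair
correlation structure that the tmax correction exploits. The statistic is
the one-sample t (mean/(SD/√n)); because sign flips preserve Σd², each
permuted t needs only the flipped mean, which makes exhaustive
enumeration cheap. All-zero differences define t = 0; zero SD with
nonzero mean defines t = ±∞, which correctly sorts to the extreme rank of
the permutation distribution.

* n ≤ 20 subjects: all 2ⁿ sign patterns are enumerated; p values are
  exact, p = #{|t_perm| ≥ |t_obs|}/2ⁿ (the identity pattern guarantees
  p > 0).
* n > 20: Monte-Carlo sampling (default 50,000 patterns) with the
  add-one estimator (1 + exceedances)/(1 + draws), which is never zero
  and converges to the exact p.

Two-sided throughout (|t|). The tmax-corrected p compares |t_obs| with
the permutation distribution of maxⱼ |tⱼ| and is therefore never below
the uncorrected p.

## The phantom

The phantom exists to exercise the pipeline's logic with known truth; it
claims no anatomical or biophysical realism.

**Geometry.** Spherical ROIs on a 49³ grid of 1 mm voxels (affine places
the world origin at the grid centre): a midline seed (radius 3 voxels),
bilateral target pairs mirror-symmetric about the midline plane at
distance 15 voxels (x-offset ±9), midline targets on the plane, and one
exclusion sphere (radius 2) between the seed and the −z decoy direction.
Targets occupy the upper (z ≥ 0) hemisphere of directions so the
exclusion region and the −y "background" direction stay clear of valid
bundles. Compartments are assigned round-robin so every compartment
appears. Overlapping or out-of-grid placements raise immediately.

**Counts.** Per subject, realized weights are
true_weightᵢ · exp(εᵢ), εᵢ ~ N(0, σ²) i.i.d. — multiplicative
log-normal variability keeps weights positive and produces the
right-skewed, large-SD densities that real between-subject tables show.
The left member of each pair is further multiplied by a configurable
lateralization shift (1 = symmetric null). Valid streamline counts are
multinomial over targets with probabilities proportional to realized
weights; configured fractions of streamlines (default 5 % each) are
instead constructed to cross the exclusion ROI, traverse two targets, or
end in background.

**Paths.** Straight seed-to-endpoint polylines resampled to 0.2 mm
vertex spacing with i.i.d. per-vertex Gaussian jitter (SD 0.3 × voxel
size). Start points are uniformly drawn seed voxel centres; endpoints are
drawn from the target's interior (≥ 1 voxel inside) so jitter rarely
pushes them out. Candidates are checked by running the assignment stage
itself; any streamline that fails to realize its intended outcome is
regenerated (up to 100 rounds, then an error). The generator therefore
guarantees intent — ground-truth agreement tests verify the pipeline,
not generator luck.

**Defaults as study conditions.** σ = 0.3 and 20,000 streamlines per
subject with 4 bilateral pairs + 2 midline targets are the package's
standard validation conditions (cohorts of 20 subjects in the recovery
study). Default true weights are symmetric within pairs and decay
geometrically across pathways (12/2ʲ for pairs, 10/1.5ᵏ for midline),
spanning the order-of-magnitude density spread real profiles show.

**Determinism.** Subject k draws from a child seed sequence spawned as
(seed, k) — platform-stable, so cohorts are bit-reproducible and a
subject's data do not depend on cohort size.

**What the phantom does not emulate:** curved bundles, fibre
orientation modelling, partial-volume effects, spatially correlated
noise, registration error, or any property of the tracking algorithm.
Passing phantom tests shows the *post-processing* is correct; it says
nothing about upstream tractography fidelity on real data.

## Statistical validation sizes

The permutation test's operating characteristics are studied on the
phantom's weight model directly (realized weights + multinomial counts,
skipping polyline rasterization, since the group-level statistics depend
only on the per-subject profiles): family-wise type-I error over 500
symmetric replicates of 12 subjects × 4 pairs (exhaustive enumeration),
uniformity of uncorrected p over 250 replicates, and power over 100
replicates of 30 subjects with a 1.5× shift on one pair (Monte-Carlo,
2,000 permutations). Full-rasterization cohorts are used for
ground-truth recovery (20 subjects × 20,000 streamlines) and for the
null lateralization check.

## Known limitations

* TCK is the only tractogram dialect (Float32 vertices); TRK/VTK are out
  of scope, as are 4D or probability-map (non-integer) atlases.
* δ_NORM corrects ROI-volume bias only; no streamline-count bias
  correction (SIFT-like filtering) is applied.
* The exhaustive permutation path materializes 2ⁿ × n sign matrices;
  beyond n = 20 it would be memory-hungry, hence the Monte-Carlo
  switch-over.
* Exact oracle-agreement guarantees hold for paths with clear ROI
  penetration; grazing-incidence corner clips below the densification
  spacing are not guaranteed to be detected (see above).
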