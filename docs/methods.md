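# Methods

## The statistical model

At every voxel of the analysis mask the subject's FA value `x` is compared
to the control sample (mean `x̄_c`, standard deviation `s_c`, size `n`)
with the single-case t statistic

    t = (x − x̄_c) / (s_c · sqrt(1 + 1/n)),   df = n − 1.

This is the Crawford–Howell form — algebraically the pooled two-sample t
with one group of size one — and is the only well-defined t for one
observation against a normative sample; the source study says only
"voxelwise t test", so the choice is pinned here and in the configuration.
Testing is one-tailed in the low-FA direction (`p = P(T_df ≤ t)`), because
the question is abnormally *low* anisotropy. Voxels where the controls have
zero variance are flagged invalid and excluded rather than raising; they
occur on synthetic mask borders where every control holds the fill value.

Suprathreshold voxels (`p < α`, default α = 0.005) are grouped into
connected components; components of at least `min_size` voxels (default
100, inclusive) are reported as clusters. Connectivity defaults to 26
(full 3×3×3 neighbourhood), the common convention in neuroimaging cluster
software; 6 and 18 are available because the original analysis does not
state its choice. Ties in the cluster ordering are broken by size, then
most negative peak t, then first voxel in lexicographic order, so outputs
are reproducible bit for bit.

The paired Wilcoxon signed-rank statistic W is the sum of the ranks of
positive differences after dropping zero pairs, with average ranks for
ties. The tail probability is exact — a dynamic program equivalent to full
sign-assignment enumeration — when N ≤ 20 and the absolute differences are
tie-free, and otherwise a normal approximation with tie and continuity
corrections. On the packaged cluster-count table all 18 nonzero differences
are positive, giving W = 171 = 18·19/2; the tied counts force the normal
path, whose one-tailed p (≈1.0·10⁻⁴) is slightly conservative relative to
the exact tail (2⁻¹⁸ ≈ 3.8·10⁻⁶).

Table-style percentages are rounded to one decimal, half away from zero
(3.85 → 3.9), matching the fixtures' formatting. The misregistration
percentage uses the **template** WM voxel count as denominator — the
reading verified by recomputing the fixture rows (75859/607633 = 12.5%).
The "percent more voxels" summary is implemented as the mean of the
per-subject ratios 100·(aBR voxels / sBR voxels) over subjects with a
nonzero sBR count; exact recomputation gives 383.4% / 405.4% against the
published 383.3% / 405.5% — the published figures are not exactly
recoverable from the published per-patient counts under any rounding
convention we tried, so the 0.1-point discrepancy is noted here rather
than hidden. Two further published summaries ("76.8% fewer clusters" and
the W = 34 comparison between the two atlas analyses) are likewise not
reproducible from the tables and are deliberately not used as oracles.

## Transforms and simulated registration

Displacement fields are stored in millimetres on the image grid and applied
in the pull (backward-sampling) convention: the output voxel at index `v`
takes the input value at `v + d(v)/spacing`. FA and structural volumes are
resampled trilinearly; binary masks strictly nearest-neighbour, which pulls
all three tissue masks from the same source voxel and so preserves binarity
and pairwise disjointness by construction. Composition is
`c(v) = outer(v) + inner(v + outer(v))` with the inner field linearly
interpolated (clamped at the grid edge so the extension stays smooth).

Inversion uses an under-relaxed Picard iteration
`g ← (1−ω)·g − ω·d(v + g(v))` with ω = 0.5; the damping keeps the iteration
contractive for fields whose local gradients approach one voxel per voxel,
where the plain fixed point oscillates. Convergence is measured as the
maximum residual of `compose(d, g)` in voxel units, by default over the
whole grid (tol 0.05 voxel, 50 iterations) and over a dilated brain mask in
the pipeline (tol 0.1 voxel, 100 iterations): near the grid boundary the
true preimage can lie off-grid, where no discrete inverse can drive the
residual to zero. The achievable accuracy is limited by trilinear
interpolation of the field itself — about 0.04 voxel for the default
anatomical-variability fields — and this residual behaves as one more small
source of registration imperfection shared identically by both analysis
modes.

Real deformable registration is deliberately not implemented. In a phantom
cohort every individual `I` is generated from the template `T` as
`I = apply(u_I, T)` with known `u_I`, so the exact moving→target map is
`compose(u_target, invert(u_moving))`, and an *imperfect* registration is
modelled as that exact map composed with a fresh random smooth residual
field of stated RMS amplitude. This gives full experimental control over
the quantity whose consequences the package measures; an external engine
can be plugged in by supplying its displacement field to
`apply_displacement` directly.

## The phantom generator

The phantom emulates the study conditions, not brain realism: nested
ellipsoids on a 64³ grid at 2 mm — an outer 3-voxel cortical GM shell, a WM
interior of ≈50k voxels (so that a 100-voxel cluster is a small fraction of
the mask, as in the real analysis), and two CSF ventricles. These are the
three tissue interfaces whose misregistration the method quantifies. FA is
a frozen per-voxel tissue "texture" (WM 0.50±0.05, GM 0.15±0.03, CSF
0.05±0.02 — plausible contrast, configurable) plus fresh per-acquisition
voxel noise (sd 0.02) added after warping, so each individual has its own
measurement noise at full variance.

Anatomical variability is i.i.d. Gaussian vector noise smoothed by a
Gaussian kernel and rescaled to a target RMS magnitude — default 2 mm RMS
at a 10 mm correlation scale. The amplitude is a modeling choice (no
quantitative inter-subject variability model exists to copy) and is
reported with every result; the 10 mm smoothness reflects that gross
anatomical differences are large-scale, and keeps the deformations
comfortably diffeomorphic and invertible to ~0.04 voxel. The Gaussian model
has unbounded tails, so the cohort generator rejection-resamples the rare
draw that folds the grid (deterministically, from spawned child seeds);
`sample_individual` itself raises on a folding field, naming the amplitude.

What the phantom does **not** emulate: cortical folding, anisotropic voxel
sizes, spatially structured noise, multi-compartment diffusion, EPI
distortion, or real registration error statistics. Passing tests therefore
demonstrate the *logic* of the bias and its quantification — not
performance on real mTBI data, whose raw images are not available.

## Calibration, interpolation, and the null experiments

"Perfect registration" in the null-calibration experiment means zero
anatomical variability **and** zero residual error, i.e. no resampling
occurs anywhere. In that limit the single-case t is exactly calibrated and
the voxelwise rejection rate converges to α. With nonzero variability the
pipeline necessarily interpolates control FA during registration; trilinear
interpolation shrinks control noise variance (by (2/3)³ at generic
fractional offsets) while the sBR subject keeps full-variance noise, which
inflates the statistic and can assemble spurious suprathreshold clusters
even at zero residual error — an interpolation artifact of any such
pipeline, shared with the original analysis scheme and studied separately
by the `interpolation_impact` experiment (an identity-warp nearest resample
changes nothing, bit for bit; a half-voxel there-and-back linear resample
isolates pure smoothing). The bias experiments are therefore paired: aBR
and sBR runs share cohort, controls, parameters and seeds, and differ only
in the registration target, so the directional comparison is unaffected.

Desk-scale problem sizes, stated as the package's own choices: the source
study's 48 controls where nothing is resampled (null calibration); 20
controls for the repeated-seed bias experiments (the size of that study's
base-rate reference group); 12 for lesion recovery; 8 leave-one-out
pseudo-subjects
for the threshold-calibration curve, run atlas-based with 1 mm subject-side
residual — the operating point at which the 64³ phantom produces a
non-degenerate base-rate curve (at 0 mm the curve is identically zero, at
2 mm saturated at one). Truth-field inverses and exact pairwise maps are
cached per cohort, so repeated seeds recompute only the random residual.

## Known limitations

* Misregistration is quantified only as GM/CSF onto template WM; WM-to-WM
  misregistration has no defined metric here (or in the source analyses).
* The simulated residual error is a stationary smooth random field; real
  registration error correlates with anatomy.
* The atlas stand-in for aBR mode is the cohort's template phantom — a
  brain none of the individuals equals — mirroring the role, not the
  content, of a population atlas.
* The optional "volume adjustment" of aBR voxel counts (rescaling by
  subject-native / template WM volume) is one plausible reading of an
  underspecified adjustment; it is off by default and labelled as such.
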