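# Methods

## The measurement model

A colonic crypt is treated as a test-tube-shaped epithelial invagination
with an orientable luminal axis.  All operations work in micrometre
coordinates; image volumes are `(channel, z, y, x)` grids of cubic voxels
(anisotropy is supported by overriding the voxel size but every shipped
workflow uses isotropic voxels).

**Length** is the arc length of the annotated axis polyline in 3D.
**Basal width** is either the length of an annotated chord or, in automatic
mode, the maximal chord of the crypt cross-section in a one-voxel slab at
`height_fraction × L` above the base (`height_fraction` defaults to 0.20).
**Rectangular area** `L × W` is the crypt-size proxy used for regional
comparisons.

**Budding stage** is a function of the developing-front height `h` — the
arc position of the parent/daughter division point above the parent base —
normalized as `f = h/L`: stage 0 with no bud, stage 1 for `f < 0.25`,
stage 2 for `0.25 ≤ f < 0.5`, stage 3 for `f ≥ 0.5`.  The `0.5` boundary is
fixed by the staging definition (the front reaching the parent's top half);
the `0.25` stage-1/2 boundary is an operational choice and both are
configurable (`stage1_boundary`, `stage3_boundary`).

**Asymmetry index.**  A budding crypt has two branches below the division
point (parent side, daughter side).  `AI = 100 · mean(|Lᵢ − L̄|)/L̄`
generalizes the two-branch percentage deviation `100·|L₁−L₂|/(L₁+L₂)` to
any branch count; only two-branch crypts occur in practice, and the two
forms agree there (property-tested).  `AI > 1 %` scores an event
asymmetric.  AI is scale-invariant and order-invariant.

**Tables.**  Stage percentages per (age, region) are computed from raw
counts and rounded to one decimal only on output; the budding rate is
`(n₁+n₂)/n`, again from raw counts, so table rows stay internally
consistent (e.g. a row whose rounded stage percentages are 13.2 + 12.8 may
still show 25.9 % budding).  Group comparisons use classical one-way ANOVA
(`scipy.stats.f_oneway` behind the module surface); no multiple-testing
correction is applied because only single planned comparisons are reported.

## Compartment masks and regional quantitation

Per crypt stack: the **nuclear mask** is the segmented DAPI channel; the
**membrane mask** is `segment(β-catenin) OR segment(E-cadherin)` (the OR
enhances membranes bright in either junctional channel) with nuclear voxels
removed; the **whole-cell mask** is `nuclei OR segment(E-cadherin)` with
holes filled per 2D slice and then in 3D; the **cytosol** is the whole cell
minus nuclei and membrane.  The builder additionally unions the membrane
and nuclear masks into the whole-cell mask so the containment invariant
(nucleus ∪ membrane ∪ cytosol ⊆ whole cell) holds even where β-catenin-only
membrane lies outside the E-cadherin-derived cell body.

Segmentation is Otsu thresholding after Gaussian smoothing with σ = 0.5
voxel.  The σ was chosen because the membrane compartment is about one
voxel thick: at σ = 1 the walls blur below Otsu's bimodal separation and
the membrane mask dilates badly (Jaccard ≈ 0.4 against truth, with
spurious basal "high clusters" appearing in homogeneous crypts), while at
σ = 0.5 the mask is essentially exact (Jaccard ≈ 0.99).  Nuclear masks are
hole-filled and cleaned of objects below 30 µm³ (a volume threshold rather
than a voxel count, so behaviour is resolution-independent; at the default
1 µm voxel it equals 30 voxels).

**Axial regions.**  Every in-crypt voxel gets the arc-length position of
its nearest point on the densely resampled axis polyline (annotation axis
when present, else the principal axis of the mask oriented to increasing
z — stacks are acquired base-down).  The axis is divided into `k = 5`
equal-length half-open bins `[start, end)` named bottom, middle1, middle2,
top1, top2.  Integrated intensity is the plain voxel sum per
(region × compartment), reported together with voxel counts; any
normalization onto a "relative intensity" axis is left to the caller, since
only ratios and trends are analyzed downstream.

**Nuclear background subtraction** (E-cadherin only): no E-cadherin is
expected in the nucleus, so each region's nuclear mean intensity per voxel
is used as that region's background; membrane and cytosol integrals are
reduced by `background × voxel_count` and clamped at zero (clamping is
flagged with a warning).  The background is per-region, not global.

**Depth projections** are per-(row, column) means over z of in-mask voxel
values, 0 where a column has no mask.

## HE/HO phenotype rule

The published HE/HO distinction is qualitative; the operational rule here
is the module's central specification:

* **low band** — a maximal run of ≥ 3 bins of the 40-bin axial membrane
  E-cadherin profile (per-bin median), restricted to the bottom half of the
  axis, below `θ_low = 0.6` times the profile median;
* **basal high cluster** — a connected component of ≥ 8 membrane voxels in
  the bottom axial fifth exceeding `θ_high = 1.5` times the crypt-wide
  membrane median in *both* E-cadherin and β-catenin (co-expression is
  required because the banding phenotype always co-occurs with high
  β-catenin);
* **HE iff ≥ 1 band AND ≥ 1 cluster**, HO otherwise.  A band without a
  cluster (or vice versa) is called HO with the ambiguity recorded in the
  call's evidence.  Thresholds are configurable and echoed in every call so
  results are reproducible.

The defaults separate the generator's HE/HO presets with wide margin (band
voxels sit at ≈ 0.3× the median, clusters at ≈ 2.2×), and calls are robust
at the generator's default noise.

## The synthetic generator

The generator emulates what the analysis consumes — isolated whole-mount
crypts imaged in three channels — not the optics of a confocal microscope
(no PSF, optical sectioning artifacts, or calibration microspheres;
intensities are already in common arbitrary units across channels).

**Geometry.**  A crypt is a capped cylinder: a capsule of outer radius
`W/2` with a single-cell epithelial wall (default 16 µm) around a narrow
lumen, closed by the hemispherical cap at the base and cut open at the top.
Cells are wedge prisms around the lumen (≈ 8 µm angular sectors × 8 µm
axial bands), each with one ellipsoidal nucleus (semi-axes 3 × 2.5 × 3 µm);
the membrane is the one-voxel sheet on every cell boundary (inner/outer
surfaces plus lateral and horizontal cell-cell interfaces).  Cells clipped
at the cap or rim can produce sliver nuclei of a few voxels; fragments
below a quarter of the nominal nucleus volume revert to cytosol so the
ground-truth nucleus count refers to whole nuclei.  A budding daughter is a
second, 0.7-scaled capsule branching downward-and-outward (35°) from the
division point at height `f·L` on the parent axis; the two branch lengths
below the division point, `(h, d)`, are the AI inputs.

**Channels** (arbitrary units on the 16-bit scale): DAPI 200 in nuclei;
β-catenin 150 membrane / 20 cytosol / 10 nucleus; E-cadherin 160 membrane /
15 cytosol / 0 nucleus.  HE crypts get (i) a contiguous low-E-cadherin band
(×0.3) at 2–22 % of crypt height, (ii) two 2-cell basal clusters at ×2.2 in
both membrane channels on well-separated sectors, (iii) basal nuclear
β-catenin raised to 60 in the bottom fifth, and (iv) an E-cadherin gradient
0.7→1.3 from base to top of membrane and cytosol.  The band defaults to the
bottom fifth (rather than, say, 25–45 % height) because a band straddling
the bottom/middle1 boundary would break the monotone base-to-top E-cadherin
trend that the five-region analysis is expected to recover; band placement
is configurable, and tests exercise a 30–45 % band explicitly.  HO crypts
are uniform.  Noise is Gaussian read noise (σ = 2) plus signal-scaled
Poisson-like variance (scale 1), then rounding to uint16; zero-noise
phantoms are exactly deterministic, and all generation is bit-reproducible
from `(spec, seed)`.

**Populations.**  Region/age presets encode the published study
conditions: lengths are positive-truncated normals with (mean, sd) =
(133, 28), (160, 32), (154, 21) µm for proximal/middle/distal (the mean ±
sd admits no negative support), and stage frequencies follow the per-age,
per-region frequency table (normalized where printed rows sum to 100.1 from
rounding).  The pooled "total" presets have no printed length statistics;
they use the mean of the three regions (149 ± 27 µm) — only their stage
composition matters for the worked examples.  An exact-count mode fixes the
per-stage composition at `round(n × frequency)` (residual, if any, to the
most frequent stage).  Basal widths are drawn at 40 ± 5 µm with wall
thickness 0.4 × width.  Per-stage front heights are uniform within each
stage's `f`-interval (with small guard margins so float rounding cannot
cross a boundary), and branch ratios come from the asymmetric-budding
mixture below.  60 % of population crypts are HE, matching the quantified
cohort fraction.

**Asymmetric-budding branch preset.**  Branch-length pairs are a mixture:
with weight 0.902 an asymmetric event (ratio uniform in [1.15, 2.5], AI
≥ 6.9 %), else a near-symmetric fission-like event (ratio within 1.5 % of
unity, AI ≤ 0.76 %).  The weight is the mean of the two published cohort
values (89.9 % and 90.4 % of budding crypts above the 1 % cutoff).

**The 32-crypt cohort** (20 HE, 12 HO, non-budding, 150 ± 25 µm) is
rendered at 2 µm voxels: the cell-scale patterning survives comfortably at
that sampling and a full cohort renders in a couple of seconds.  The
10000-crypt parameter-recovery populations are annotation-level only (no
volumes), which is also how the corresponding measurements were made in
practice — lengths are read off annotated polylines, not segmentations.

**What passing tests do and do not show.**  The phantoms have crisp
bimodal intensity distributions, perfectly known geometry, and noise far
milder than real confocal stacks (no depth attenuation, bleed-through,
debris, or touching crypts).  Recovery results (e.g. ≥ 95 % nuclear voxel
recovery, membrane Jaccard ≈ 0.99, 100 % phenotype accuracy) therefore
validate the *correctness of the algebra and the decision rules*, not
segmentation robustness on real microscopy; on real data the thresholds
(`θ_low`, `θ_high`, σ, minimum object sizes) would need tuning against
expert annotation.

## Numerical choices and degenerate inputs

* Coordinates are 0-based voxel indices, axis order (z, y, x); voxel
  centers sit at `(i + 0.5) × voxel_size`; region bins are `[start, end)`.
* Zero-length polyline segments contribute nothing to length; annotations
  need ≥ 2 points; a division point must lie within 1 µm of the axis.
* Stage-3 pairs with exactly equal members are labelled mature/mature with
  a warning; the daughter is otherwise the smaller-width (preferred) or
  shorter member.
* Empty channels segment to empty masks with a warning; empty (age,
  region) groups are omitted from tables with a warning; background
  exceeding signal clamps to zero with a warning.
* `ANOVA` with equal group means returns exactly F = 0, p = 1.
* One master seed drives everything through `numpy` `SeedSequence`
  substreams keyed by crypt index, so per-crypt outputs are stable under
  population-size changes.

## Known limitations

* The generator's crypt wall is a single abstract cell layer; no goblet
  cells, no cell-size gradients along the axis, no curvature of the crypt
  axis (annotations are jittered polylines, volumes are straight).
* Whole-cell hole filling also fills the crypt lumen on tube-like slices;
  with the default narrow lumen (wall 0.4 × width) this inflates the cell
  body by < 10 %, and tests bound it, but wide-lumen crypts would need a
  lumen-aware fill.
* HE/HO thresholds are validated against the generator's phenotype
  contrast, which is stronger than the biological one; the 60/40 HE/HO
  population split is an input, not a discovery.
* Budding outcome is not linked statistically to HE/HO status (the
  quantified cohort contains too few budding crypts for that analysis).
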