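# Methods

## Scientific setting

The package quantifies how two medial prefrontal cortex (mPFC) projection
populations divide their output between the nucleus accumbens (NAc) and the
ventral tegmental area (VTA) in mouse. Two kinds of raw material feed the
analyses:

1. **High-magnification confocal z-stacks** of fluorescently labeled axons
   in the two target regions. The quantity of interest is total axon
   centerline length per stack, aggregated into a relative axon density
   (RAD, mm of axon per mm³ of tissue) per region and animal, and the
   per-animal ratio RAD_VTA/RAD_NAc (1 = equal innervation of the two
   targets).
2. **Cell tables** from retrograde tracing: one row per counted neuron with
   its animal, Bregma level, mPFC subregion, cortical layer, tracer flags
   (NAc and/or VTA) and tri-state molecular marker calls (Calb1, Ctip2,
   FoxP2; positive / negative / untested).

No imaging data accompany the study being modeled, so a synthetic-data
module generates both kinds of input with exact ground truth, and a bundled
reference dataset of published per-animal counts and densities supports a
full reproduction of every published summary statistic.

## Axon length measurement

**Model.** An axon in a stack is a sparse tubular structure a few hundred
nanometres wide, imaged with anisotropic voxels (z-step coarser than the
in-plane pixel). Its length is the length of its centerline.

**Pipeline.** `binarize_stack` → `skeletonize_stack` → `skeleton_length`:

* *Segmentation.* Gaussian pre-smoothing with σ = 1 voxel in-plane (0 in z)
  suppresses shot noise without bridging neighbouring axons; the threshold
  is Otsu's (maximizing between-class intensity variance) by default, or a
  fixed value; connected components under 27 voxels (a 3×3×3 cube,
  26-connectivity) are discarded as specks. A constant-intensity stack
  segments to an empty mask, not an error. The threshold and all parameters
  are recorded on the returned mask.
* *Skeletonization.* 3D thinning (Lee's method, via scikit-image) on the
  native voxel grid. The grid is never resampled to isotropy: resampling
  interpolates intensities and blurs topology, whereas anisotropy is exact
  arithmetic at the length step.
* *Length.* A graph is built with one node per skeleton voxel and one edge
  per 26-adjacent voxel pair, each undirected adjacency counted once. Edge
  length is √((Δz·dz)² + (Δy·dy)² + (Δx·dx)²); total length is the sum over
  unique edges, reported in mm.

**Volume and density.** When a region-of-interest specification is given,
analyzed volume is ROI area × slice count × z-step, overriding the stack's
own extent; otherwise the full physical extent is used. Regional RAD sums
lengths and volumes over that region's stacks before dividing — it is a
ratio of totals, not a mean of per-stack densities.

**Known biases.** The skeleton loses roughly a tube radius plus a PSF width
at every axon endpoint (thinning erosion), biasing length down; the digital
26-adjacency path overestimates the length of lines at oblique angles by up
to ~8%, and corner staircases can contribute a spurious triangle edge,
biasing length up. On the synthetic phantoms these effects partially cancel;
the median recovery error over 20 phantom stacks at signal/background 6 is
about 4–6%, and the test suite requires ≤ 15%.

## Synthetic phantoms

Centerlines are piecewise-linear random walks: step length 0.5 µm, the
direction rotated after each step by a uniform angle in [0, tortuosity]
(default 20°) about a random perpendicular axis — the simplest model with
an exact analytic length. Walks start inside a one-tube-radius margin and
are clipped where they exit the stack; the ground truth records the clipped
polylines, i.e. exactly what is measurable inside the stack. A voxel is
foreground when its centre lies within the tube radius (default 0.4 µm) of
a centerline, distances in physical µm so the tube respects anisotropy.
The indicator volume is blurred with an anisotropic Gaussian PSF (default
σ = 0.35/0.13/0.13 µm in z/y/x, appropriate for a high-NA oil objective),
scaled between a background of 20 and a peak of 120 intensity units
(signal/background 6), and corrupted with Poisson noise by default
(Gaussian optional). Default spacing is (0.27, 0.2, 0.2) µm (dz, dy, dx):
the z-step matches 63× confocal sectioning; the in-plane pixel size is a
typical value for that magnification chosen here, since the emulated
acquisitions recorded only the z-step. The default 64×400×400 voxel shape
gives ≈ 1.1 × 10⁻⁴ mm³, a desk-scale stand-in for a real field of view.

Each axon consumes an independent child RNG stream spawned from the spec
seed, so generation is bit-reproducible and the first *k* axons are
identical across specs differing only in axon count — which makes total
ground-truth length monotone in `n_axons`.

What the phantoms do *not* emulate: uneven staining or immunoenhancement,
channel bleed-through, tissue deformation, axon varicosities, and densely
crossing arbors. Passing recovery tests therefore demonstrate the
measurement chain's correctness on sparse tubular signal, not performance
on every real-tissue pathology.

A practical note on noise: recovery error is flat — even very slightly
improved — between zero and mild sensor noise, because moderate noise
smooths the intensity histogram Otsu operates on; once the noise scale
approaches the signal amplitude the threshold collapses into the background
and error grows by orders of magnitude. The noise-degradation test samples
the clean, moderate and collapse regimes accordingly.

## Cell-count statistics

Percentages are computed per animal and summarized as mean ± SD across
animals with the sample (n−1) SD — the convention verified by exact
reproduction of more than ten published SDs from published per-animal
counts.

* **Distributions.** For a tracer population and an axis (Bregma bin,
  subregion, layer), per-animal percentage = stratum count / animal total;
  strata percentages sum to 100 per animal; pooled counts are sums across
  animals. Animals with zero cells in the population are excluded with a
  warning. Bregma bins are closed at both printed endpoints; values are
  rounded to 2 decimals (the precision of the printed edges) before
  binning, and a value falling in the 0.01-wide gap between adjacent
  printed edges joins the more rostral bin.
* **Marker co-labeling.** Within each layer group and in total: numerator =
  tracer⁺ marker⁺ cells, denominator = tracer⁺ cells tested for the marker;
  untested cells enter neither. A group's summary is *suppressed* (reported
  without a percentage) when the pooled marker-positive count is below 10
  or any contributing animal's denominator is below 10 — percentages over
  so few cells are noise. This combined rule reproduces every suppressed
  and every reported cell of the reference tables; a rule based on
  denominators alone does not (one reference row is suppressed despite
  per-animal denominators in the hundreds, because only 7 marker-positive
  cells were found).
* **Double-tracer overlap.** Per animal: NAc-only, VTA-only and
  double-labeled counts. Ratios reported: double/VTA-only, double/NAc-only,
  and double/total with total = singles + doubles. The reference data's
  independently tallied total column differs slightly from the component
  sum; `overlap_from_counts` therefore accepts explicit totals, and the
  reproduction uses the published totals as data.

## Group comparison

Per-animal RAD ratios (or percentages) are compared with a one-way
fixed-effects ANOVA (F = MS_between/MS_within, p from the F distribution)
followed by Fisher's LSD post hoc: for each pair,
t = (m_i − m_j)/√(MSE·(1/n_i + 1/n_j)) with the within-group df, two-sided
p, *unadjusted* — no multiple-comparison correction is part of the LSD
procedure by definition. Under the global null each pairwise test is an
exact t test, and a 10,000-replicate simulation in the 4×3 design confirms
the per-comparison type-I error sits at nominal α. Homogeneity of variances
is checked with Levene's test (mean-centered — chosen because no specific
test was named for this step); it is reported alongside the ANOVA and never
gates it. Zero within-group variance with unequal means yields an infinite
F flagged `degenerate` with p reported as 0.

## Reference dataset and its quirks

`projdense.refdata` bundles the published per-animal measurements and
materializes cell tables from them. Only marginal counts were published
(per-animal × subregion, per-animal × layer, pooled × Bregma bin), so the
materialized tables pair the expanded attribute lists in a fixed order:
every published marginal is preserved exactly, while the joint
subregion×layer assignment is arbitrary and must not be interpreted.
Two source-data quirks are consumed as-is rather than "fixed":

* per-animal densities do not equal published length / published
  same-region volume (the volume columns appear transposed between regions
  and all values are rounded) — the density columns are taken as the
  authoritative per-animal values, and the per-animal VTA/NAc ratios are
  recomputed from them (this, and only this, reproduces all four group
  means ± SD at published rounding);
* the ANOVA/LSD is run on the published per-animal relative-density column,
  which reproduces all six published p-values at their printed precision.
  The resulting F is 55.53; the published F of 55.56 is not reproducible
  from any printed-precision input and is documented as a likely
  transcription error in the source (the acceptance test for it is left
  failing rather than loosened).

## Numerical and design choices

* Lengths in mm, volumes in mm³, densities in mm/mm³ throughout.
* Voxel indices are 0-based; the physical position of a voxel centre is
  index × spacing. Spacing priority on read: explicit override > YAML
  sidecar > TIFF tags; a stack without any spacing source is an error
  (isotropy is never assumed silently).
* Reported statistics are rounded to 2 decimals only at the reporting
  surface; full precision is kept internally.
* Problem sizes in the test and acceptance runs (20 phantom stacks of
  40×128×128 voxels, 4 axons of 20–60 µm each; 10,000 LSD replicates) are
  chosen so the whole suite runs in well under a minute per family on one
  CPU while keeping the binomial/median estimates stable.

## Limitations

Segmentation is global-threshold based and will fail under strong
intensity gradients or out-of-focus haze; no branch/endpoint
classification, bouton detection, or axon–soma discrimination is
attempted; cell tables are consumed as given (the input contract assumes
cells were counted only when visible in two sections with a visible
nucleus); no nonparametric or mixed-model alternatives to the ANOVA are
provided.
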