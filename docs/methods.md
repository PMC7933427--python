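# Methods

This note documents the models, conventions and design choices behind
`dorsalcode`, in the order the pipeline runs.

## Coordinate convention

Pixel coordinates throughout: origin at the top-left, x to the right
(columns), y downwards (rows), 0-based, with positions referring to pixel
centers. Images are indexed `img[y, x]`. Shapely geometries use (x, y).

## Tissue template

The default template is one half of the dorsal grey matter: a lens-like
outline attached to the midline (x = 0), lateral border bulging to the
configured width at mid-depth, with five stacked laminar bands I–V at depth
fractions 0.09 / 0.15 / 0.18 / 0.24 / 0.34 (lamina I a thin superficial
sheet, lamina V the deepest band). Laminae are the intersections of the
outline with horizontal bands, so they are simple polygons, mutually
disjoint, contained in the outline, and ordered dorsal to ventral. Users can
supply any template as GeoJSON (an `outline` feature plus one feature per
lamina). The default pixel scale is 1 µm/px; it is metadata only — nothing
downstream converts units.

## Synthetic tissue model

A section is generated in three stages, all driven by one
`numpy.random.Generator` seeded from `(seed, animal, section, stream)`, so
identical configurations are bit-reproducible.

**Placement.** Each cell draws a population from the mixture weights, a
lamina from the population's placement weights (once per cell, so the lamina
marginal is exactly multinomial), and a nucleus radius from a truncated
normal (default mean 5 px, SD 1 px, floor 2 px). The centroid is
rejection-sampled uniformly inside the lamina polygon subject to nucleus
non-overlap: centroid distance > r_i + r_j (+ an optional placement margin).
Somata are discs of radius nucleus + expansion (default 4 px). Placement
raises after a bounded retry budget; the shipped configurations keep nucleus
packing ≤ ~30% of the available area, where rejection sampling is reliable.

**Expression.** Per gene, a cell expresses with its population's probability
p_g; conditional on expressing, the dot count is negative binomial with the
population's (mean, dispersion), variance = μ + αμ². Dispersion 0 means
Poisson. Within a population, genes are independent; co-expression structure
arises from the mixture. The implied pairwise co-expression fraction is
closed-form, `F[g,h] = Σ_k w_k p_kg p_kh / Σ_k w_k p_kg`, and is what the
recovery studies compare against.

**Rendering.** Spots are placed uniformly in the soma disc and rendered as
additive Gaussians (σ = 1 px, amplitude 200 by default); the nuclear channel
paints the nucleus discs and smooths them; Gaussian camera noise (SD 5) is
added and clipped at zero. Background dots are a Poisson process over the
whole image with density `rate / mean_soma_area`, so the *expected number of
stray dots inside an average soma equals the configured rate* (default 0.5
dots per cell per channel). Background falls inside and outside somata —
which is exactly why a negative-control threshold is needed downstream.
Negative controls use the same placement and rendering but contain only
background dots.

Two placement options exist for validation configurations and default to
off: `min_spot_separation_px` keeps same-cell, same-channel spots at least
that far apart (and their rounded pixel ≥ 2 px inside the soma radius and
≥ 8 px from the image border), and `placement_margin_px` adds extra centroid
spacing so somata stay disjoint. With separation on, an infeasible spot
packing truncates the drawn count to the spots actually placed, keeping
ground truth and rendering consistent. By default spots may overlap freely
and the detector's merge behavior is tested explicitly.

**What the simulator does not model:** optics-accurate PSFs, 3-D stacks,
tissue autofluorescence, irregular nucleus shapes, intensity variation
between transcripts, or segmentation-confounding debris. Passing tests
therefore demonstrate correctness of the quantification logic under the
stated generative model, not robustness to every real-tissue artifact.

## Segmentation

Nuclei: Gaussian smoothing (σ = 1), global Otsu threshold × correction
factor clipped to `[lower, upper]` (mirroring the correction-factor/bounds
semantics of the CellProfiler modules this follows), hole filling, and
optional declumping by watershed on a smoothed distance transform with peak
seeds at least `min_diameter` apart within each connected clump. Objects
outside the equivalent-diameter range are removed and labels are contiguous
1..N. Raising the correction factor can only shrink the foreground, which
the tests assert as a monotonicity property. Border objects are kept by
default; an exclusion flag exists.

Somata: nearest-nucleus Euclidean expansion up to `max_distance_px`
(default 10 px — a value to review per dataset, since the original soma
expansion is not a published constant). Implementation: a cKDTree over
labeled pixels, k-nearest queries, exact integer squared-distance
comparisons for tie detection, and min-label resolution (with an exhaustive
radius query for the rare ≥ k-way tie). A brute-force nearest-nucleus scan
is the test oracle. Nucleus pixels are never overwritten, so each soma
contains its nucleus.

## Spot detection and relation

The band-pass response is a scale-normalised negative Laplacian of Gaussian
at `scale_px` (default 1 px, matched to the rendered spot σ). Spots are
local maxima above `clip(otsu × correction, lower, upper)`, non-maximum
suppressed at `min_separation_px`; positions are refined to the 3×3
intensity-weighted centroid of the response, but cell assignment uses the
rounded pixel — a plain label lookup, reproducible and order-free. Two true
spots closer than the suppression radius yield one detection; that merge
behavior is documented and tested, not hidden. Note the suppression footprint
is square, so a radius of 2 can merge peaks up to ~2.8 px apart Euclidean;
the exact-recovery validation pairs a 4 px generator separation guarantee
with suppression radius 1.

Dots/cell tables include every soma label, zeros included; spots over
background (label 0) are excluded from all counts but never dropped from
the spot table.

## Positivity and co-expression

Background thresholds use the **nearest-rank (type-1) percentile** of the
negative-control dots/cell distribution: rank ⌈p/100·n⌉ of the sorted
values, default p = 90. On integer count data this yields attainable integer
thresholds; interpolating definitions would not. Positive means dots
strictly above the background threshold; high means dots strictly above 20
*and* positive (the high rule combines with, rather than replaces, the
background rule — with default thresholds the former subsumes the latter).

Pairwise fractions are computed only from cells measured for both genes of
the pair (probe combinations hybridise up to three genes; unmeasured genes
carry NaN counts). At the stringent level the > 20 rule applies to both
genes of the pair by default — the symmetric definition keeps the
reciprocity identity meaningful; a flag restricts it to the denominator
gene. Fractions are per animal (hemisections pooled first), then averaged
unweighted across animals; SDs are across animals, with SD = 0 by convention
for a single animal. Pairs never co-hybridised are reported as missing, not
as zero.

A deliberate property of this procedure, quantified during design: with a
background rate of 0.5 dots/cell the calibrated threshold is 1, so a
non-expressing gene is falsely called positive with probability
P(Poisson(0.5) ≥ 2) ≈ 9%. At the permissive level this inflates low
co-expression fractions by far more than the sampling error. The recovery
studies therefore assert the stringent matrix against the generative
fractions (where the Poisson background cannot reach 20 dots), and assert
the permissive matrix against the background-aware closed form of the full
generative process — both to ±5 percentage points.

## Laminar mapping

Alignment is landmark-based least-squares affine (≥ 3 non-collinear pairs;
collinearity detected by design-matrix rank). Intensity-based registration
was deliberately avoided: landmarks (dorsomedial/ventromedial corners,
lateral apex, centroid) are reproducible and sufficient for affine section
placement. Lamina assignment is boundary-inclusive point-in-polygon in
dorsal-to-ventral template order, so boundary points go dorsal and every
cell receives exactly one label (`outside` if in no lamina); mixed
"I–II border" assignments are out of scope.

## Translatome filtering

Normalized counts are reads per kilobase per million:
`raw / (library/10⁶) / (length/10³)`. The named thresholds — 10 for
"expressed", 100 for "detectable by in situ hybridisation" — are interpreted
on this scale and applied strictly to group means (a per-sample-minimum
variant is available). Enrichment filtering is inclusive at both boundaries:
FDR ≤ 0.05 and fold ≥ 2 (or ≤ ½ for the opposite direction). FDR values are
an input column in normal use; the built-in two-group test — a
fixed-dispersion negative-binomial likelihood ratio with library-size
offsets, χ²(1) reference and Benjamini–Hochberg correction — exists as a
test oracle for simulated matrices and is explicitly not a replacement for
a dedicated DGEA package.

## Validation studies and problem sizes

The studies in `dorsalcode.studies`/`dorsalcode.validation` fix the
conditions once:

- **Noiseless exact recovery:** 1 section, 200 cells, 3 genes, dot means
  2.5, zero noise and background, 4 px spot separation, disjoint somata.
  Measured dots/cell must equal ground truth exactly, and Venn counts must
  equal a brute-force enumeration.
- **Threshold oracle:** 1,000 random integer count vectors × percentiles
  {50, 90, 95, 100} against an independent sort-and-index oracle.
- **Co-expression recovery:** 20 seeds × (2 animals × 2 hemisections × 400
  cells), three populations (weights 0.30/0.25/0.45; one A-only population,
  one A∧B population, one C population with 20% B), background 0.5
  dots/cell calibrated from simulated negative controls; ≥ 95% of ordered
  pair estimates within ±5 pp of the closed form.
- **Laminar recovery:** 500 cells at 90%/10% in laminae II/III on a
  double-size template (small nuclei, so superficial laminae hold them at
  ~20% packing), section displaced by a known rotation-scale-shift affine;
  transform recovered to 1e-6 relative error, lamina distribution within 3
  multinomial SDs.
- **Translatome:** two 400-gene comparisons, 3 vs 3 replicates, dispersion
  0.15, 60 planted genes at fold 4 in the first and the same 60 + 20 in the
  second; recovery and congruence are reported.

These sizes make the full suite run in well under a minute while keeping
every statistical tolerance at ≥ 3σ margins.

## Known limitations

- Dense expressors (tens of dots in a ~250 px² soma) render as overlapping
  signal; peak detection then undercounts absolute dots, as any
  local-maximum detector must. Positivity calling is robust to this (it
  needs thresholds, not exact counts at the high end), but absolute
  dots/cell from images is only faithful in the resolvable regime.
- The declumping variant (smoothed distance transform, peak seeds) is one
  reasonable choice among several; exact agreement with any particular
  CellProfiler version is not claimed.
- Soma expansion assumes convex-ish nuclei; Voronoi-style expansion from
  highly concave nuclei could produce disconnected somata.
- The NB test oracle assumes the dispersion is known — true for simulated
  matrices, false for real data.
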