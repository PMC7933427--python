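# dorsalcode

Quantification pipeline for multiplex single-molecule FISH (RNAscope-style)
experiments in the mouse spinal dorsal horn, built around the question of how
neuropeptide genes partition excitatory neurons into laminar subtypes. It
re-implements, as a tested and reusable library, the complete quantification
chain from raw multi-channel section images to co-expression matrices and
laminar distributions — together with the count-level filtering logic used to
screen translatome (TRAP-seq) matrices for enriched genes — and ships a
synthetic dorsal-horn tissue simulator with exhaustive ground truth so every
stage can be validated without any external data.

## Who it is for

Groups quantifying multiplex smFISH in tissue sections who want the standard
CellProfiler-style workflow (primary/secondary object identification, spot
detection with per-slide threshold correction, spot-to-cell relation) as a
scriptable, fully tested Python pipeline, with the negative-control
calibration and per-animal statistics done the same way every time.

## The quantification model

For each section image (one nuclear channel, up to three probe channels):

1. **Segmentation.** Nuclei are primary objects: smoothing, a global Otsu
   threshold scaled by a *threshold correction factor* and clipped to lower
   and upper bounds, distance-transform watershed declumping and a diameter
   filter. Somata ("cells") are secondary objects: every background pixel
   within a maximum Euclidean distance of its nearest nucleus inherits that
   nucleus's label (ties to the lower label).
2. **Spot counting.** Signal dots are local maxima of a Laplacian-of-Gaussian
   band-pass response above `clip(otsu × correction, lower, upper)`; each dot
   is assigned to the soma label under its rounded pixel position, giving
   integer *dots per cell* `d_gc` for gene g and cell c.
3. **Positivity.** Per channel, a matched negative-control section defines
   background: the threshold `t_g` is the 90th nearest-rank percentile of its
   dots/cell distribution, and a cell is *positive* iff `d_gc > t_g`
   (strict). A cell is a *high expressor* iff additionally `d_gc > 20`.
4. **Co-expression.** For every gene pair (g, h) hybridised together, the
   fraction `F[g,h] = 100 · N_gh / N_g` of g-expressing cells that also
   express h is computed per animal (hemisections pooled) and averaged
   unweighted across animals; `100·N_gh = F[g,h]·N_g = F[h,g]·N_h` holds on
   the unrounded counts. Triple-probe Venn region counts are reported per
   animal.
5. **Laminar mapping.** Sections are aligned to a lamina template (polygons
   I–V) by a landmark-based least-squares affine; cell centroids are binned
   by point-in-polygon with dorsal-to-ventral priority, giving counts of
   expressing cells per lamina and hemisection.
6. **Translatome filtering.** Gene × sample count matrices are normalized to
   reads per kilobase per million; *expressed* genes exceed 10 normalized
   counts and in-situ-detectable genes exceed 100 (group means, strict);
   enriched gene sets require FDR ≤ 0.05 and fold ratio ≥ 2 (inclusive), and
   two comparisons are summarised by their congruence |A ∩ B| / |A|.

The simulator (`dorsalcode.simulate`) generates all of the above from a known
generative model: nuclei placed without overlap in laminar bands of a
half-dorsal-horn template, per-cell dot counts from a configurable
mixture-of-populations co-expression model, Gaussian spot rendering, diffuse
background dots at a negative-control rate, and matched negative controls —
with per-cell and per-spot ground truth tables.

## Worked example

The numbered drivers under `analysis/` run a complete simulated experiment
(2 animals × 2 hemisections, 400 cells each, three genes A/B/C from a fixed
three-population mixture, 0.5 background dots per cell):

```bash
python analysis/01_simulate_tissue.py --seed 1
python analysis/03_coexpression.py --seed 1
```

prints (abridged):

```
background thresholds (dots/cell): {'A': 1.0, 'B': 2.0, 'C': 1.0}

co-expression matrix, level=high (% of row gene also expressing column):
       A      B      C
A  100.0   42.6    0.0
B   73.9  100.0   26.0
C    0.0   18.1  100.0
vs generative matrix: max |error| 2.81 pp, mean 0.92 pp over 6 ordered pairs
```

Reading the matrix: 42.6% of A-high cells are also B-high, while 73.9% of
B-high cells are A-high — the nested-population motif (B-cells largely a
subset of A-cells) planted in the generative mixture, recovered to within
about 3 percentage points. `analysis/02_segment_and_count.py` runs the image
pipeline on a rendered section, `04` the laminar mapping and `05` the
translatome filtering (which reports, e.g., ~83% congruence between two
simulated enrichment comparisons sharing 60 of 80 planted genes). Tables land
under `results/`, large rendered images under `scratch/`.

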