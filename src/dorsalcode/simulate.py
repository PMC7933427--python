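"""Synthetic dorsal-horn tissue with exhaustive ground truth.

The generator emulates the raw material of a multiplex smFISH (RNAscope)
experiment: roughly circular nuclei placed without overlap inside laminar
bands of a half-dorsal-horn template, somata as expanded discs, per-cell probe
dot counts drawn from a mixture-of-populations co-expression model, diffuse
background dots at a configurable negative-control rate, and matched
negative-control sections that contain background dots only. Every cell and
every spot is recorded in ground-truth tables so downstream segmentation,
spot detection, classification and laminar mapping can be validated exactly.

A second generator produces gene x sample count matrices with planted
enriched gene sets for the translatome module.

Determinism: all draws flow from ``numpy.random.Generator`` seeded from
``(config.seed, animal_id, section_id, stream)``, so identical configs and
seeds give bit-identical images and tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from scipy import ndimage as ndi

from .template import TissueTemplate, default_template

# id of the negative-control pseudo-section stream (keeps it distinct from the
# tissue stream of the same animal/section)
_STREAM_TISSUE = 0
_STREAM_NEGCTRL = 1


@dataclass
class GeneExpression:
    """Per-gene expression law inside one population.

    ``prob`` is the probability that a cell of the population expresses the
    gene at all; conditional on expressing, the dot count is negative binomial
    with the given mean and dispersion (variance = mean + dispersion * mean^2;
    dispersion 0 degenerates to Poisson).
    """

    prob: float
    mean_dots: float = 60.0
    dispersion: float = 0.05

    def validate(self, gene: str) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError(f"{gene}: expression probability must be in [0, 1]")
        if self.mean_dots <= 0:
            raise ValueError(f"{gene}: mean_dots must be > 0")
        if self.dispersion < 0:
            raise ValueError(f"{gene}: dispersion must be >= 0")


@dataclass
class PopulationSpec:
    """One neuronal population of the co-expression mixture."""

    name: str
    weight: float
    expression: dict[str, GeneExpression]
    lamina_weights: dict[str, float]

    def validate(self, lamina_names: list[str]) -> None:
        if self.weight < 0:
            raise ValueError("population weight must be >= 0")
        for gene, law in self.expression.items():
            law.validate(gene)
        total = sum(self.lamina_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"population {self.name!r}: lamina weights sum to {total}, not 1"
            )
        unknown = set(self.lamina_weights) - set(lamina_names)
        if unknown:
            raise ValueError(f"population {self.name!r}: unknown laminae {unknown}")


@dataclass
class SimulationConfig:
    """Study design plus imaging/rendering parameters for one experiment.

    Defaults mirror the study design quantified downstream: 3 animals with
    2 hemisections per animal, a matched negative control per combination,
    and a background rate of 0.5 stray dots per cell-equivalent area.
    """

    template: TissueTemplate = field(default_factory=default_template)
    populations: list[PopulationSpec] = field(default_factory=list)
    n_cells: int = 300
    nucleus_radius_mean: float = 5.0
    nucleus_radius_sd: float = 1.0
    nucleus_radius_min: float = 2.0  # truncation floor of the radius draw
    soma_expansion_px: float = 4.0
    spot_sigma_px: float = 1.0
    spot_amplitude: float = 200.0
    nuclear_amplitude: float = 150.0
    noise_sd: float = 5.0
    background_dot_rate: float = 0.5
    n_animals: int = 3
    hemisections_per_animal: int = 2
    seed: int = 0
    # Optional placement constraints used by noiseless exact-recovery
    # configurations; 0 disables them (spots may then overlap freely).
    min_spot_separation_px: float = 0.0
    placement_margin_px: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be > 0")
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("nucleus radius parameters must be positive")
        if not 0 < self.nucleus_radius_min <= self.nucleus_radius_mean:
            raise ValueError("nucleus_radius_min must be in (0, mean]")
        if self.soma_expansion_px < 0:
            raise ValueError("soma_expansion_px must be >= 0")
        if self.background_dot_rate < 0:
            raise ValueError("background_dot_rate must be >= 0")
        if self.hemisections_per_animal < 1:
            raise ValueError("hemisections_per_animal must be >= 1")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.populations:
            w = sum(p.weight for p in self.populations)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"population weights sum to {w}, not 1")
            for pop in self.populations:
                pop.validate(self.template.lamina_names)

    @property
    def genes(self) -> list[str]:
        """Ordered union of genes over populations (first-appearance order)."""
        seen: list[str] = []
        for pop in self.populations:
            for g in pop.expression:
                if g not in seen:
                    seen.append(g)
        return seen

    @property
    def mean_soma_area(self) -> float:
        r = self.nucleus_radius_mean + self.soma_expansion_px
        return float(np.pi * r * r)


@dataclass
class ImageStack:
    """Registered multi-channel 2-D image with channel roles."""

    data: np.ndarray  # (C, H, W) float32
    channel_names: list[str]
    channel_roles: list[str]  # "nuclear" or "probe"

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("image stack must be (C, H, W)")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channel_names.index(name)]

    @property
    def probe_channels(self) -> list[str]:
        return [
            n for n, r in zip(self.channel_names, self.channel_roles) if r == "probe"
        ]


@dataclass
class GroundTruth:
    """Per-cell and per-spot truth tables for one simulated section."""

    cells: pd.DataFrame
    spots: pd.DataFrame

    def validate(self, genes: list[str]) -> None:
        """Conservation: per-cell counts equal the number of owned spots."""
        known = set(self.cells["cell_id"])
        parents = set(self.spots.loc[self.spots["cell_id"] != 0, "cell_id"])
        if not parents <= known:
            raise AssertionError("spot parents missing from cell table")
        for gene in genes:
            per_cell = (
                self.spots[(self.spots["gene"] == gene) & (self.spots["cell_id"] != 0)]
                .groupby("cell_id")
                .size()
            )
            counts = self.cells.set_index("cell_id")[f"true_{gene}"]
            expected = per_cell.reindex(counts.index, fill_value=0)
            if not (expected == counts).all():
                raise AssertionError(f"spot conservation violated for {gene}")


def _rng(config: SimulationConfig, animal_id: int, section_id: int, stream: int):
    return np.random.default_rng(
        [int(config.seed) & 0x7FFFFFFF, int(animal_id), int(section_id), stream]
    )


def _draw_counts(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# --------------------------------------------------------------------------
# cell placement + expression
# --------------------------------------------------------------------------

def sample_cells(
    config: SimulationConfig,
    animal_id: int,
    section_id: int,
    rng=None,
    max_tries_per_cell: int = 4000,
) -> pd.DataFrame:
    """Place cells and draw their expression state for one hemisection.

    Placement: the population is sampled from the mixture weights, a lamina
    from the population's placement weights, and the centroid rejection-
    sampled uniformly inside that lamina polygon subject to nucleus
    non-overlap (centroid distance > r_i + r_j + placement_margin_px).
    Raises if a cell cannot be placed within the retry budget.
    """
    if not config.populations:
        raise ValueError("config.populations is empty")
    if rng is None:
        rng = _rng(config, animal_id, section_id, _STREAM_TISSUE)
    genes = config.genes
    weights = np.array([p.weight for p in config.populations])
    lam_polys = dict(config.template.laminae)

    xs = np.empty(config.n_cells)
    ys = np.empty(config.n_cells)
    radii = np.empty(config.n_cells)
    pop_idx = np.empty(config.n_cells, dtype=int)
    laminae: list[str] = []

    for i in range(config.n_cells):
        k = int(rng.choice(len(weights), p=weights))
        pop = config.populations[k]
        lam_names = list(pop.lamina_weights)
        lam_probs = np.array([pop.lamina_weights[n] for n in lam_names])
        # truncated normal radius
        r = -1.0
        while r < config.nucleus_radius_min:
            r = rng.normal(config.nucleus_radius_mean, config.nucleus_radius_sd)
        # lamina drawn once per cell so the lamina marginal is exactly the
        # multinomial of the placement weights; retries only move the centroid
        lam = lam_names[int(rng.choice(len(lam_names), p=lam_probs))]
        poly = lam_polys[lam]
        minx, miny, maxx, maxy = poly.bounds
        placed = False
        for _ in range(max_tries_per_cell):
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if not shapely.contains_xy(poly, x, y):
                continue
            if i > 0:
                d2 = (xs[:i] - x) ** 2 + (ys[:i] - y) ** 2
                lim = radii[:i] + r + config.placement_margin_px
                if np.any(d2 <= lim * lim):
                    continue
            xs[i], ys[i], radii[i], pop_idx[i] = x, y, r, k
            laminae.append(lam)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{config.n_cells} without nucleus "
                "overlap; reduce n_cells or radii"
            )

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, config.n_cells + 1),
            "animal_id": animal_id,
            "section_id": section_id,
            "x": xs,
            "y": ys,
            "nucleus_radius": radii,
            "soma_radius": radii + config.soma_expansion_px,
            "population": [config.populations[k].name for k in pop_idx],
            "lamina": laminae,
        }
    )
    for gene in genes:
        probs = np.array(
            [
                config.populations[k].expression.get(gene, GeneExpression(0.0)).prob
                for k in pop_idx
            ]
        )
        expressed = rng.random(config.n_cells) < probs
        counts = np.zeros(config.n_cells, dtype=int)
        for k, pop in enumerate(config.populations):
            law = pop.expression.get(gene)
            if law is None:
                continue
            sel = expressed & (pop_idx == k)
            if sel.any():
                counts[sel] = _draw_counts(rng, law.mean_dots, law.dispersion, sel.sum())
        cells[f"expr_{gene}"] = expressed
        cells[f"true_{gene}"] = counts
    return cells


def _place_cell_spots(rng, cx, cy, r_soma, n, config: SimulationConfig, shape):
    """Spot positions uniform in the soma disc, clipped to the image.

    With ``min_spot_separation_px > 0`` the positions additionally keep that
    distance from each other (same cell, same channel) and their rounded pixel
    stays >= 2 px inside the soma radius and >= 8 px inside the image border,
    which guarantees a local-maximum detector can recover them exactly.
    Returns possibly fewer than ``n`` points if the packing is infeasible.
    """
    H, W = shape
    sep = config.min_spot_separation_px
    pts: list[tuple[float, float]] = []
    for _ in range(n):
        ok = False
        for _ in range(2000):
            rad = (r_soma if sep <= 0 else max(r_soma - 2.0, 0.5)) * np.sqrt(
                rng.random()
            )
            th = rng.uniform(0, 2 * np.pi)
            x = cx + rad * np.cos(th)
            y = cy + rad * np.sin(th)
            if sep > 0:
                px, py = round(x), round(y)
                if not (8 <= px < W - 8 and 8 <= py < H - 8):
                    continue
                if (px - cx) ** 2 + (py - cy) ** 2 > (r_soma - 2.0) ** 2:
                    continue
                if any((x - u) ** 2 + (y - v) ** 2 < sep * sep for u, v in pts):
                    continue
            else:
                if not (-0.5 <= x < W - 0.5 and -0.5 <= y < H - 0.5):
                    continue
            pts.append((x, y))
            ok = True
            break
        if not ok:
            break  # infeasible packing: truncate, caller fixes the count
    return pts


def sample_spots(
    cells: pd.DataFrame, config: SimulationConfig, rng, shape=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw ground-truth spot positions for every cell and gene.

    Returns ``(spots, cells)`` where cells is updated in the rare case a
    drawn count had to be truncated to a feasible packing.
    """
    if shape is None:
        shape = config.template.image_shape
    genes = config.genes
    cells = cells.copy()
    recs: list[tuple[float, float, str, int]] = []
    for row in cells.itertuples():
        for gene in genes:
            n = getattr(row, f"true_{gene}")
            if n == 0:
                continue
            pts = _place_cell_spots(
                rng, row.x, row.y, row.soma_radius, int(n), config, shape
            )
            if len(pts) != n:
                cells.loc[cells["cell_id"] == row.cell_id, f"true_{gene}"] = len(pts)
            recs += [(x, y, gene, row.cell_id) for x, y in pts]
    spots = pd.DataFrame(recs, columns=["x", "y", "gene", "cell_id"])

    # diffuse background: Poisson process over the full image, one process per
    # probe channel, at background_dot_rate stray dots per cell-equivalent area
    H, W = shape
    density = config.background_dot_rate / config.mean_soma_area
    bg_recs = []
    for gene in genes:
        n_bg = rng.poisson(density * H * W)
        bx = rng.uniform(-0.5, W - 0.5, size=n_bg)
        by = rng.uniform(-0.5, H - 0.5, size=n_bg)
        bg_recs.append(pd.DataFrame({"x": bx, "y": by, "gene": gene, "cell_id": 0}))
    frames = [f for f in [spots] + bg_recs if len(f)]
    if frames:
        spots = pd.concat(frames, ignore_index=True)
    else:
        spots = pd.DataFrame(
            {
                "x": pd.Series(dtype=float),
                "y": pd.Series(dtype=float),
                "gene": pd.Series(dtype=object),
                "cell_id": pd.Series(dtype=int),
            }
        )
    return spots, cells


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _paint_discs(shape, xs, ys, radii, value) -> np.ndarray:
    img = np.zeros(shape, dtype=np.float32)
    H, W = shape
    for x, y, r in zip(xs, ys, radii):
        x0, x1 = max(0, int(np.floor(x - r - 1))), min(W, int(np.ceil(x + r + 2)))
        y0, y1 = max(0, int(np.floor(y - r - 1))), min(H, int(np.ceil(y + r + 2)))
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] = value
    return img


def _render_spots(shape, spots: pd.DataFrame, sigma: float, amplitude: float):
    img = np.zeros(shape, dtype=np.float32)
    H, W = shape
    w = int(np.ceil(4 * sigma))
    for x, y in zip(spots["x"].to_numpy(), spots["y"].to_numpy()):
        x0, x1 = max(0, int(np.floor(x)) - w), min(W, int(np.floor(x)) + w + 2)
        y0, y1 = max(0, int(np.floor(y)) - w), min(H, int(np.floor(y)) + w + 2)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        img[y0:y1, x0:x1] += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma * sigma)
        )
    return img


def render_section(
    cells: pd.DataFrame, spots: pd.DataFrame, config: SimulationConfig, rng
) -> ImageStack:
    """Render nuclear + probe channels; spots add up where they overlap."""
    shape = config.template.image_shape
    genes = config.genes
    nuclear = _paint_discs(
        shape,
        cells["x"].to_numpy(),
        cells["y"].to_numpy(),
        cells["nucleus_radius"].to_numpy(),
        config.nuclear_amplitude,
    )
    nuclear = ndi.gaussian_filter(nuclear, 1.0)
    channels = [nuclear]
    for gene in genes:
        sub = spots[spots["gene"] == gene]
        channels.append(
            _render_spots(shape, sub, config.spot_sigma_px, config.spot_amplitude)
        )
    data = np.stack(channels)
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
        data = np.clip(data, 0.0, None)
    return ImageStack(
        data=data.astype(np.float32),
        channel_names=["nuclear"] + genes,
        channel_roles=["nuclear"] + ["probe"] * len(genes),
    )


def generate_tissue(
    config: SimulationConfig, animal_id: int, section_id: int
) -> tuple[ImageStack, GroundTruth]:
    """One simulated hemisection: image stack plus full ground truth."""
    rng = _rng(config, animal_id, section_id, _STREAM_TISSUE)
    cells = sample_cells(config, animal_id, section_id, rng=rng)
    spots, cells = sample_spots(cells, config, rng)
    image = render_section(cells, spots, config, rng)
    return image, GroundTruth(cells=cells, spots=spots)


def generate_negative_control(
    config: SimulationConfig, animal_id: int = 0, section_id: int = 0
) -> tuple[ImageStack, GroundTruth]:
    """Matched negative control: same placement process, background dots only."""
    rng = _rng(config, animal_id, section_id, _STREAM_NEGCTRL)
    cells = sample_cells(config, animal_id, section_id, rng=rng)
    for gene in config.genes:
        cells[f"expr_{gene}"] = False
        cells[f"true_{gene}"] = 0
    spots, cells = sample_spots(cells, config, rng)
    image = render_section(cells, spots, config, rng)
    return image, GroundTruth(cells=cells, spots=spots)


def ground_truth_label_maps(
    cells: pd.DataFrame, shape
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize ground-truth nuclei and soma discs as label images.

    Discs are painted in cell order; configurations meant for exact recovery
    keep somata disjoint so painting order never matters.
    """
    H, W = shape
    nuclei = np.zeros((H, W), dtype=np.int32)
    soma = np.zeros((H, W), dtype=np.int32)
    for row in cells.itertuples():
        for img, r in ((nuclei, row.nucleus_radius), (soma, row.soma_radius)):
            x0, x1 = max(0, int(np.floor(row.x - r - 1))), min(
                W, int(np.ceil(row.x + r + 2))
            )
            y0, y1 = max(0, int(np.floor(row.y - r - 1))), min(
                H, int(np.ceil(row.y + r + 2))
            )
            yy, xx = np.mgrid[y0:y1, x0:x1]
            mask = (xx - row.x) ** 2 + (yy - row.y) ** 2 <= r * r
            img[y0:y1, x0:x1][mask] = row.cell_id
    return nuclei, soma


# --------------------------------------------------------------------------
# count-level interface (tables without rasterisation)
# --------------------------------------------------------------------------

def measured_cell_table(
    cells: pd.DataFrame, config: SimulationConfig, rng
) -> pd.DataFrame:
    """Measured dots/cell at the count level: true dots + in-soma background.

    The number of stray dots falling inside a soma is Poisson with mean
    ``background_dot_rate * soma_area / mean_soma_area``, i.e. the configured
    rate for an average-sized soma. This is the table the full image pipeline
    converges to, without rendering and re-detecting.
    """
    out = cells.copy()
    area_ratio = (np.pi * out["soma_radius"] ** 2 / config.mean_soma_area).to_numpy()
    for gene in config.genes:
        bg = rng.poisson(config.background_dot_rate * area_ratio)
        out[f"count_{gene}"] = out[f"true_{gene}"].to_numpy() + bg
    return out


def simulate_cell_tables(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count-level experiment: (cells, negative-control cells) tables.

    Cells from all ``n_animals`` x ``hemisections_per_animal`` hemisections
    are concatenated; one matched negative-control hemisection is generated
    per animal, mirroring the one-control-per-combination design.
    """
    tissues = []
    controls = []
    for a in range(1, config.n_animals + 1):
        for s in range(1, config.hemisections_per_animal + 1):
            rng = _rng(config, a, s, _STREAM_TISSUE)
            cells = sample_cells(config, a, s, rng=rng)
            tissues.append(measured_cell_table(cells, config, rng))
        rng = _rng(config, a, 0, _STREAM_NEGCTRL)
        nc = sample_cells(config, a, 0, rng=rng)
        for gene in config.genes:
            nc[f"expr_{gene}"] = False
            nc[f"true_{gene}"] = 0
        controls.append(measured_cell_table(nc, config, rng))
    return (
        pd.concat(tissues, ignore_index=True),
        pd.concat(controls, ignore_index=True),
    )


# --------------------------------------------------------------------------
# translatome count matrices
# --------------------------------------------------------------------------

def generate_count_matrix(
    n_genes: int,
    groups: dict[str, int],
    enriched_sets: dict[str, list[str]] | None = None,
    fold_changes: float | dict[str, float] = 4.0,
    library_sizes: dict[str, float] | None = None,
    gene_lengths: np.ndarray | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    base_mean: float = 50.0,
):
    """Gene x sample NB count matrix with planted enriched gene sets.

    Expected raw count of gene g in sample s is
    ``base_g * (length_g / 1e3) * (library_s / 1e6) * fold``, where ``fold``
    applies only in the group the gene is planted in. ``dispersion == 0`` is
    the deterministic limit: counts equal the rounded expectations.

    Returns ``(counts, samples, genes, truth)`` where truth maps each group
    name to the set of genes planted as enriched in it.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if len(groups) < 1 or any(n < 2 for n in groups.values()):
        raise ValueError("need >= 2 replicates per group")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    if gene_lengths is None:
        gene_lengths = rng.integers(500, 5000, size=n_genes).astype(float)
    sample_ids, sample_groups = [], []
    for gname, n in groups.items():
        for r in range(1, n + 1):
            sample_ids.append(f"{gname}_{r}")
            sample_groups.append(gname)
    if library_sizes is None:
        library_sizes = {s: 1e6 for s in sample_ids}
    libs = np.array([library_sizes[s] for s in sample_ids], dtype=float)

    enriched_sets = enriched_sets or {}
    if np.isscalar(fold_changes):
        fold_map = {
            g: float(fold_changes) for gs in enriched_sets.values() for g in gs
        }
    else:
        fold_map = {g: float(f) for g, f in fold_changes.items()}
    if any(f < 1.0 for f in fold_map.values()):
        raise ValueError("planted fold changes must be >= 1")

    base = rng.lognormal(mean=np.log(base_mean), sigma=0.8, size=n_genes)
    mu = np.outer(base * gene_lengths / 1e3, libs / 1e6)
    truth: dict[str, set[str]] = {gname: set() for gname in groups}
    for gname, genes_in in enriched_sets.items():
        cols = [i for i, sg in enumerate(sample_groups) if sg == gname]
        for g in genes_in:
            f = fold_map.get(g, 1.0)
            gi = gene_ids.index(g)
            mu[gi, cols] *= f
            if f > 1.0:
                truth[gname].add(g)

    if dispersion == 0:
        counts = np.rint(mu).astype(int)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    samples_df = pd.DataFrame(
        {"sample": sample_ids, "group": sample_groups, "library_size": libs}
    )
    genes_df = pd.DataFrame({"gene": gene_ids, "length": gene_lengths})
    return counts_df, samples_df, genes_df, truth


# --------------------------------------------------------------------------
# config (de)serialisation
# --------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("template")
    d["template"] = "default"
    d["populations"] = [
        {
            "name": p.name,
            "weight": p.weight,
            "expression": {
                g: {"prob": e.prob, "mean_dots": e.mean_dots, "dispersion": e.dispersion}
                for g, e in p.expression.items()
            },
            "lamina_weights": dict(p.lamina_weights),
        }
        for p in config.populations
    ]
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    tmpl = d.pop("template", "default")
    if tmpl == "default":
        template = default_template()
    else:
        template = TissueTemplate.from_geojson(tmpl)
    pops = [
        PopulationSpec(
            name=p["name"],
            weight=p["weight"],
            expression={
                g: GeneExpression(**law) for g, law in p["expression"].items()
            },
            lamina_weights=p["lamina_weights"],
        )
        for p in d.pop("populations", [])
    ]
    return SimulationConfig(template=template, populations=pops, **d)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))
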