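"""Synthetic landscape-genetics studies with planted, recoverable structure.

The generator emulates the shape of a multi-species cpDNA meta-analysis:
10-20 species, each with a pool of aligned haplotypes (random substitutions
from a root sequence) and 5-60 georeferenced populations of >= 5 sampled
individuals.  Haplotype frequencies are drawn from a symmetric Dirichlet
whose concentration increases along a configurable spatial gradient, so
expected haplotype diversity rises in a known direction — the planted
signal the downstream pipeline must recover.  Environmental rasters come
in the three analysis categories with known structure (climatic variables
are affine in latitude, creating a known climate-topography overlap;
anthropogenic variables are independent smooth noise), and protected-area
polygons cover a configurable, exactly-known fraction of target cells.

Everything is driven by one master seed; identical seeds give identical
bytes on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import box

from . import landscape as _land
from . import popgen as _pg
from .geo import write_geojson_polygons
from .hotspots import detect_hotspots
from .landscape import (
    GridSpec,
    Surface,
    cell_areas,
    combine_surfaces,
    make_grid,
    species_diversity_surface,
    write_ascii_grid,
)

__all__ = [
    "StudyConfig",
    "LRGR_BBOX",
    "simulate_species_dataset",
    "simulate_environment_rasters",
    "simulate_protected_areas",
    "simulate_study",
    "planted_response_surface",
]

#: study-region bounding box (west, south, east, north) of the default
#: fixture: the Longitudinal Range Gorge Region of southwest China
LRGR_BBOX = (95.79, 21.15, 106.12, 30.60)

_BASES = np.array(list("ACGT"))


@dataclass
class StudyConfig:
    """Parameters of one synthetic study; defaults emulate the real design."""

    bbox: tuple[float, float, float, float] = LRGR_BBOX
    n_species: int = 15
    pops_per_species: tuple[int, int] = (5, 60)
    n_per_pop: tuple[int, int] = (5, 30)
    pool_size: int = 12
    seq_length: int = 600
    max_mutations: int = 8
    #: gradient direction as a (d_lon, d_lat) vector; default northward
    gradient_direction: tuple[float, float] = (0.0, 1.0)
    #: 0 = no gradient (uniform mid concentration), 1 = full planted gradient
    gradient_strength: float = 1.0
    #: Dirichlet concentration per haplotype at the low/high gradient ends
    alpha_range: tuple[float, float] = (0.06, 1.5)
    resolution: float = _land.DEFAULT_RESOLUTION_DEG
    #: fraction of populations given N < 5 to exercise the sample-size filter
    contaminate_fraction: float = 0.0
    protected_coverage: float = 0.3
    #: 'hotspots' plants PA coverage over detected hotspot cells,
    #: 'region' over the whole study region
    protected_target: str = "hotspots"
    climate_noise_sd: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 <= self.protected_coverage <= 1.0:
            raise ValueError("protected_coverage must be in [0, 1]")
        if self.pool_size < 2 and self.gradient_strength > 0:
            raise ValueError("a diversity gradient needs a haplotype pool of >= 2")
        if min(self.pops_per_species) < 1 or min(self.n_per_pop) < 1:
            raise ValueError("population and sample-size ranges must be positive")
        if not 0.0 <= self.contaminate_fraction <= 1.0:
            raise ValueError("contaminate_fraction must be in [0, 1]")


def _species_rng(config: StudyConfig, species_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
        config.n_species + 8)[species_index])


def _gradient_position(config: StudyConfig, lon: float, lat: float) -> float:
    """Position in [0, 1] along the gradient direction across the bbox."""
    w, s, e, n = config.bbox
    dx, dy = config.gradient_direction
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 0.5
    dx, dy = dx / norm, dy / norm
    # project normalized coordinates onto the direction, rescale to [0, 1]
    u = dx * (lon - w) / (e - w) + dy * (lat - s) / (n - s)
    lo = min(0.0, dx) + min(0.0, dy)
    hi = max(0.0, dx) + max(0.0, dy)
    return float((u - lo) / (hi - lo))


def expected_haplotype_diversity(alpha: float, pool_size: int) -> float:
    """Expected population heterozygosity under a symmetric Dirichlet.

    Two individuals drawn from Dirichlet(alpha, ..., alpha) frequencies
    carry the same haplotype with probability (1 + alpha)/(1 + K alpha).
    """
    k = pool_size
    return alpha * (k - 1) / (1.0 + k * alpha)


def simulate_species_dataset(
    config: StudyConfig, species_index: int
) -> tuple[_pg.SpeciesDataset, dict]:
    """One species' haplotype pool and populations, plus ground truth.

    Haplotypes are built by seeded random substitutions from a random root
    sequence; per-population haplotype counts are multinomial draws from
    Dirichlet frequencies whose concentration grows along the planted
    gradient, so expected haplotype diversity does too.
    """
    rng = _species_rng(config, species_index)
    species = f"species_{species_index + 1:02d}"

    root = rng.choice(_BASES, size=config.seq_length)
    haplotypes = [_pg.Haplotype(id="h01", sequence="".join(root))]
    for h in range(1, config.pool_size):
        seq = root.copy()
        n_mut = int(rng.integers(1, config.max_mutations + 1))
        sites = rng.choice(config.seq_length, size=n_mut, replace=False)
        for s in sites:
            seq[s] = rng.choice(_BASES[_BASES != seq[s]])
        haplotypes.append(_pg.Haplotype(id=f"h{h + 1:02d}", sequence="".join(seq)))

    w, s, e, n = config.bbox
    n_pops = int(rng.integers(config.pops_per_species[0], config.pops_per_species[1] + 1))
    a_lo, a_hi = config.alpha_range
    populations = []
    truth_pops = []
    contaminated = rng.random(n_pops) < config.contaminate_fraction
    for p in range(n_pops):
        lon = float(rng.uniform(w, e))
        lat = float(rng.uniform(s, n))
        t = _gradient_position(config, lon, lat)
        t_eff = config.gradient_strength * t + (1.0 - config.gradient_strength) * 0.5
        alpha = a_lo * (a_hi / a_lo) ** t_eff
        theta = rng.dirichlet(np.full(config.pool_size, alpha))
        if contaminated[p]:
            n_ind = int(rng.integers(1, 5))
        else:
            n_ind = int(rng.integers(config.n_per_pop[0], config.n_per_pop[1] + 1))
        counts_vec = rng.multinomial(n_ind, theta)
        counts = {
            haplotypes[i].id: int(c) for i, c in enumerate(counts_vec) if c > 0
        }
        pop_id = f"{species}_p{p + 1:03d}"
        populations.append(_pg.PopulationSample(pop_id, lon, lat, counts))
        truth_pops.append(
            {
                "pop_id": pop_id,
                "lon": lon,
                "lat": lat,
                "N": n_ind,
                "gradient_position": t,
                "alpha": alpha,
                "expected_H_D": expected_haplotype_diversity(alpha, config.pool_size),
                "contaminated": bool(contaminated[p]),
            }
        )

    dataset = _pg.SpeciesDataset(species, haplotypes, populations)
    truth = {
        "species": species,
        "gradient_direction": list(config.gradient_direction),
        "gradient_strength": config.gradient_strength,
        "populations": truth_pops,
    }
    return dataset, truth


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float = 6.0) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def simulate_environment_rasters(
    config: StudyConfig, grid: GridSpec
) -> tuple[list[tuple[str, str, Surface]], pd.DataFrame]:
    """Category-tagged variable rasters with known structure.

    Topographic: the coordinate fields ``lat``/``long`` plus two smooth
    random fields (``elev``, ``tri``).  Climatic: affine functions of
    latitude plus smooth noise (``wet`` increases, ``cld`` decreases
    northward), including one pair (``wet``/``pre``) planted collinear at
    r ~ 0.9 to exercise the collinearity filter.  Anthropogenic: two
    independent smooth fields (``ahf``, ``hfp``).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
        config.n_species + 8)[config.n_species])
    lon, lat = grid.cell_centers()
    w, s, e, n = config.bbox
    lat_norm = (lat - s) / (n - s)
    lon_norm = (lon - w) / (e - w)
    sd = config.climate_noise_sd

    def smooth() -> np.ndarray:
        return _smooth_field(rng, grid.shape)

    wet = lat_norm + sd * smooth()
    rasters = [
        ("lat", "topographic", lat),
        ("long", "topographic", lon),
        ("elev", "topographic", smooth()),
        ("tri", "topographic", smooth()),
        ("wet", "climatic", wet),
        ("pre", "climatic", wet + 0.5 * sd * smooth()),  # planted collinear pair
        ("cld", "climatic", -lat_norm + sd * smooth()),
        ("tmp", "climatic", -lat_norm + 2.0 * sd * smooth()),
        ("frs", "climatic", lat_norm * lon_norm + sd * smooth()),
        ("vap", "climatic", smooth()),
        ("ahf", "anthropogenic", smooth()),
        ("hfp", "anthropogenic", smooth()),
    ]
    out = [
        (name, cat, Surface(grid=grid, values=np.asarray(vals, float), layer_name=name))
        for name, cat, vals in rasters
    ]
    manifest = pd.DataFrame(
        [(name, cat) for name, cat, _ in out], columns=["name", "category"]
    )
    return out, manifest


def simulate_protected_areas(
    config: StudyConfig,
    grid: GridSpec,
    hotspot_cells: list[tuple[int, int]] | None = None,
) -> tuple[object, float]:
    """Protected-area polygons covering a known fraction of target cells.

    Returns ``(geometry, achieved_fraction)``.  With target cells given,
    whole cell rectangles are accumulated (in the given order) until the
    configured area fraction is reached, so the protected fraction is known
    to within one cell's area.  Without target cells, a single rectangle
    covers the western ``coverage`` share of the study region.
    """
    f = config.protected_coverage
    if f == 0.0:
        return box(0, 0, 0, 0).buffer(0), 0.0  # empty polygon
    w, s, e, n = config.bbox
    if hotspot_cells is None:
        return box(w, s, w + f * (e - w), n), f

    areas = cell_areas(grid)
    cell_area = np.array([areas[r, c] for r, c in hotspot_cells])
    total = cell_area.sum()
    take = []
    acc = 0.0
    for (r, c), a in zip(hotspot_cells, cell_area):
        if acc >= f * total:
            break
        take.append((r, c))
        acc += a
    res = grid.resolution
    boxes = [
        box(
            grid.west + c * res,
            grid.north - (r + 1) * res,
            grid.west + (c + 1) * res,
            grid.north - r * res,
        )
        for r, c in take
    ]
    from shapely.ops import unary_union

    return unary_union(boxes), float(acc / total)


@dataclass
class StudyBundle:
    """Paths of one simulated study written to disk."""

    out_dir: Path
    fasta_paths: dict[str, Path]
    population_table: Path
    boundary: Path
    protected_areas: Path
    raster_dir: Path
    manifest: Path
    ground_truth: Path
    species: list[str] = field(default_factory=list)


def simulate_study(config: StudyConfig, out_dir) -> StudyBundle:
    """Write a complete synthetic study bundle plus its ground-truth file.

    Produces per-species aligned FASTA, the population CSV, boundary and
    protected-area GeoJSON, the environmental raster stack with its
    category manifest, and a JSON ground-truth record (planted gradient,
    per-population expected diversity, protected coverage) sufficient for
    recovery tests.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raster_dir = out_dir / "rasters"
    raster_dir.mkdir(exist_ok=True)

    datasets, truths = [], []
    for i in range(config.n_species):
        ds, truth = simulate_species_dataset(config, i)
        datasets.append(ds)
        truths.append(truth)

    fasta_paths: dict[str, Path] = {}
    pop_rows = []
    for ds in datasets:
        fp = out_dir / f"{ds.species}.fasta"
        with open(fp, "w") as fh:
            for h in ds.haplotypes:
                fh.write(f">{h.id}\n{h.sequence}\n")
        fasta_paths[ds.species] = fp
        for pop in ds.populations:
            for hap_id in sorted(pop.counts):
                pop_rows.append(
                    (ds.species, pop.pop_id, pop.longitude, pop.latitude, hap_id, pop.counts[hap_id])
                )
    pop_table = out_dir / "populations.csv"
    pd.DataFrame(pop_rows, columns=_pg.POPULATION_TABLE_COLUMNS).to_csv(pop_table, index=False)

    w, s, e, n = config.bbox
    boundary_geom = box(w, s, e, n)
    boundary_path = out_dir / "boundary.geojson"
    write_geojson_polygons(boundary_path, boundary_geom, [{"name": "study_region"}])

    grid = make_grid(boundary_geom, config.resolution)
    rasters, manifest = simulate_environment_rasters(config, grid)
    for name, _cat, surf in rasters:
        write_ascii_grid(raster_dir / f"{name}.asc", surf)
    manifest = manifest.assign(path=[f"rasters/{name}.asc" for name, _, _ in rasters])
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)

    # plant protected-area coverage over the hotspots of the combined
    # diversity surface (or over the region as a fallback)
    hotspot_cells = None
    if config.protected_target == "hotspots":
        surfaces = []
        for ds in datasets:
            filtered = _pg.filter_min_sample(ds, 5)
            pops_ok = [p for p in filtered.populations if p.n >= 2]
            if len(pops_ok) == 0:
                continue
            filtered = _pg.SpeciesDataset(ds.species, ds.haplotypes, pops_ok)
            div = _pg.diversity_table(filtered)
            surfaces.append(species_diversity_surface(filtered, div, grid))
        combined = combine_surfaces(surfaces, layer_name="combined_H_D")
        spots = detect_hotspots(combined)
        if spots:
            hotspot_cells = [cell for h in spots for cell in h.cells]
    pa_geom, achieved = simulate_protected_areas(config, grid, hotspot_cells)
    pa_path = out_dir / "protected_areas.geojson"
    polys = [] if pa_geom.is_empty else [pa_geom]
    write_geojson_polygons(pa_path, polys, [{"name": "protected"}] * len(polys))

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "species": truths,
        "protected_coverage_target": config.protected_coverage,
        "protected_coverage_achieved": achieved,
        "n_low_sample_populations": int(
            sum(1 for t in truths for p in t["populations"] if p["N"] < 5)
        ),
    }
    truth_path = out_dir / "ground_truth.json"
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=1)

    return StudyBundle(
        out_dir=out_dir,
        fasta_paths=fasta_paths,
        population_table=pop_table,
        boundary=boundary_path,
        protected_areas=pa_path,
        raster_dir=raster_dir,
        manifest=manifest_path,
        ground_truth=truth_path,
        species=[ds.species for ds in datasets],
    )


def planted_response_surface(
    rasters: list[tuple[str, str, Surface]],
    grid: GridSpec,
    effects: dict[str, float],
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Surface:
    """Response surface that is a known linear function of chosen rasters.

    ``effects`` maps raster names to coefficients applied to the z-scored
    raster; independent Gaussian noise is added on top.  Used to plant
    attribution ground truth (e.g. a purely topographic response).
    """
    rng = np.random.default_rng(seed)
    by_name = {name: surf for name, _cat, surf in rasters}
    vals = np.zeros(grid.shape)
    for name, beta in effects.items():
        v = by_name[name].values
        mu = np.nanmean(v)
        sd = np.nanstd(v)
        vals = vals + beta * (v - mu) / (sd if sd > 0 else 1.0)
    vals = vals + noise_sd * rng.standard_normal(grid.shape)
    return Surface(grid=grid, values=vals, layer_name="planted_response")
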