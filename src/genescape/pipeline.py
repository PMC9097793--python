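"""End-to-end orchestration: haplotype data to variance attribution.

One config drives the whole analysis in order: read and filter species
data, per-population statistics, per-species diversity/divergence surfaces,
the combined multi-species landscape, hotspot delineation with
protected-area overlap, per-species isolation-by-distance, and the
environmental attribution chain (variable extraction, collinearity filter,
importance selection, GAMs, variation partitioning).  Every intermediate
artifact is written to the results directory; identical configs and seeds
give identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import attribution as _attr
from . import popgen as _pg
from .geo import read_geojson_polygons, write_geojson_polygons
from .hotspots import detect_hotspots, hotspot_polygon, protected_overlap, threshold_value
from .ibd import geodesic_distance_matrix, mantel_test
from .landscape import (
    DEFAULT_RESOLUTION_DEG,
    combine_surfaces,
    make_grid,
    read_ascii_grid,
    species_diversity_surface,
    species_divergence_surface,
    write_ascii_grid,
)
from .simulate import StudyConfig, simulate_study

logger = logging.getLogger("genescape")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (YAML-serializable)."""

    out_dir: str = "results"
    # either a simulation spec ...
    simulate: StudyConfig | None = None
    # ... or explicit input paths
    fasta_dir: str | None = None
    population_table: str | None = None
    boundary: str | None = None
    protected_areas: str | None = None
    raster_manifest: str | None = None

    min_n: int = 5
    resolution: float = DEFAULT_RESOLUTION_DEG
    idw_power: float = 2.0
    pair_mode: str = "all_pairs"
    truncate_negative: bool = True
    z_threshold: float = 1.5
    connectivity: int = 8
    n_perm: int = 999
    collinearity_threshold: float = 0.7
    top_k: int = 2
    gam_basis_dim: int = 10
    gam_subsample: int = 2000
    rf_subsample: int = 4000
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw["simulate"]
            for key in ("bbox", "pops_per_species", "n_per_pop", "gradient_direction", "alpha_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = StudyConfig(**sim)
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles to the main pipeline outputs."""

    out_dir: Path
    diversity: pd.DataFrame
    fst: dict[str, _pg.PairwiseFstMatrix]
    combined_diversity: object
    combined_divergence: object
    hotspots: list
    outside_fraction: float | None
    ibd: pd.DataFrame
    retained_variables: list[str]
    selected_variables: dict[str, list[str]]
    gam_results: list
    partition: object
    manifest: dict
    n_dropped_populations: int = 0


def _stage(name: str):
    logger.info("stage: %s", name)
    return name


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    for sub in ("stats", "surfaces", "hotspots", "ibd", "attribution"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = _stage("inputs")
        if config.simulate is not None:
            bundle = simulate_study(config.simulate, out / "inputs")
            fasta_paths = bundle.fasta_paths
            pop_table = bundle.population_table
            boundary_path = bundle.boundary
            pa_path = bundle.protected_areas
            manifest_path = bundle.manifest
            raster_root = bundle.out_dir
        else:
            if not (config.fasta_dir and config.population_table and config.boundary):
                raise ValueError("need fasta_dir, population_table and boundary (or a simulate spec)")
            table = pd.read_csv(config.population_table)
            species_names = list(dict.fromkeys(table["species"]))
            fasta_dir = Path(config.fasta_dir)
            fasta_paths = {sp: fasta_dir / f"{sp}.fasta" for sp in species_names}
            pop_table = Path(config.population_table)
            boundary_path = Path(config.boundary)
            pa_path = Path(config.protected_areas) if config.protected_areas else None
            manifest_path = Path(config.raster_manifest) if config.raster_manifest else None
            raster_root = manifest_path.parent if manifest_path else None
        manifest["stages"]["inputs"] = {"population_table": str(pop_table)}

        # ------------------------------------------------------- read/filter
        stage = _stage("read_filter")
        datasets = []
        n_dropped = 0
        for sp, fp in fasta_paths.items():
            ds = _pg.read_species_dataset(fp, pop_table, sp)
            before = len(ds.populations)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = _pg.filter_min_sample(ds, config.min_n)
            n_dropped += before - len(ds.populations)
            if len(ds.populations) >= 2:
                datasets.append(ds)
            else:
                logger.warning("%s: < 2 populations after filtering; species skipped", sp)
        if not datasets:
            raise ValueError("no species with >= 2 retained populations")

        # ------------------------------------------------------------- stats
        stage = _stage("stats")
        diversity = pd.concat([_pg.diversity_table(ds) for ds in datasets], ignore_index=True)
        diversity.to_csv(out / "stats" / "diversity.csv", index=False)
        fst: dict[str, _pg.PairwiseFstMatrix] = {}
        for ds in datasets:
            m = _pg.fst_matrix(ds)
            fst[ds.species] = m
            m.to_long().to_csv(out / "stats" / f"fst_{ds.species}_long.csv", index=False)
            m.to_square().to_csv(out / "stats" / f"fst_{ds.species}_square.csv")
        r_hd_pi, p_hd_pi = _pg.index_correlation(diversity["H_D"], diversity["pi"])
        manifest["stages"]["stats"] = {
            "n_populations": int(len(diversity)),
            "n_dropped_populations": int(n_dropped),
            "HD_pi_pearson_r": r_hd_pi,
            "HD_pi_p": p_hd_pi,
        }

        # --------------------------------------------------------- landscape
        stage = _stage("landscape")
        boundary = read_geojson_polygons(boundary_path)
        grid = make_grid(boundary, config.resolution)
        div_surfaces, fst_surfaces = [], []
        for ds in datasets:
            s = species_diversity_surface(ds, diversity, grid, power=config.idw_power)
            div_surfaces.append(s)
            write_ascii_grid(out / "surfaces" / f"diversity_{ds.species}.asc", s)
            s2 = species_divergence_surface(
                ds, fst[ds.species], grid,
                pair_mode=config.pair_mode,
                truncate_negative=config.truncate_negative,
                power=config.idw_power,
            )
            fst_surfaces.append(s2)
            write_ascii_grid(out / "surfaces" / f"divergence_{ds.species}.asc", s2)
        combined_div = combine_surfaces(div_surfaces, layer_name="combined_H_D")
        combined_fst = combine_surfaces(fst_surfaces, layer_name="combined_PhiST")
        write_ascii_grid(out / "surfaces" / "combined_diversity.asc", combined_div)
        write_ascii_grid(out / "surfaces" / "combined_divergence.asc", combined_fst)
        vals = combined_div.masked_values()
        manifest["stages"]["landscape"] = {
            "grid": {"n_rows": grid.n_rows, "n_cols": grid.n_cols, "resolution": grid.resolution},
            "combined_H_D_range": [float(np.nanmin(vals)), float(np.nanmax(vals))],
            "combined_PhiST_range": [
                float(np.nanmin(combined_fst.masked_values())),
                float(np.nanmax(combined_fst.masked_values())),
            ],
        }

        # ---------------------------------------------------------- hotspots
        stage = _stage("hotspots")
        spots = detect_hotspots(combined_div, config.z_threshold, config.connectivity)
        outside = None
        if spots:
            thr = threshold_value(combined_div, config.z_threshold)
            pa_geom = read_geojson_polygons(pa_path) if pa_path else None
            outside, per_hotspot = protected_overlap(spots, pa_geom, grid)
            per_hotspot.to_csv(out / "hotspots" / "hotspots.csv", index=False)
            write_geojson_polygons(
                out / "hotspots" / "hotspots.geojson",
                [hotspot_polygon(h, grid) for h in spots],
                [{"label": h.label, "area_km2": h.area_km2} for h in spots],
            )
            manifest["stages"]["hotspots"] = {
                "n_hotspots": len(spots),
                "total_area_km2": float(sum(h.area_km2 for h in spots)),
                "threshold_H_D": thr,
                "outside_protected_fraction": outside,
            }
        else:
            manifest["stages"]["hotspots"] = {"n_hotspots": 0}

        # --------------------------------------------------------------- IBD
        stage = _stage("ibd")
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
        ibd_rows = []
        for ds in datasets:
            if len(ds.populations) < 4:
                continue
            coords = [(p.longitude, p.latitude) for p in ds.populations]
            d_geo = geodesic_distance_matrix(coords, labels=[p.pop_id for p in ds.populations])
            from .ibd import DistanceMatrix

            # raw (untruncated) Phi_ST as the genetic distance
            gen = DistanceMatrix(list(fst[ds.species].pop_ids), fst[ds.species].values.copy())
            try:
                r, p = mantel_test(d_geo, gen, n_perm=config.n_perm, seed=int(rng.integers(2**31)))
            except ValueError:
                continue  # zero-variance genetic triangle (all pops identical)
            ibd_rows.append({"species": ds.species, "n_pops": len(ds.populations), "r": r, "p": p})
        ibd = pd.DataFrame(ibd_rows, columns=["species", "n_pops", "r", "p"])
        ibd.to_csv(out / "ibd" / "ibd.csv", index=False)
        manifest["stages"]["ibd"] = {
            "n_species_tested": int(len(ibd)),
            "n_significant": int((ibd["p"] < 0.05).sum()) if len(ibd) else 0,
        }

        # --------------------------------------------------------- attribute
        stage = _stage("attribution")
        partition = None
        gam_results: list = []
        retained: list[str] = []
        selected: dict[str, list[str]] = {}
        if manifest_path is not None:
            man = pd.read_csv(manifest_path)
            rasters = []
            for _, row in man.iterrows():
                surf = read_ascii_grid(
                    raster_root / row["path"], boundary_mask=grid.boundary_mask, layer_name=row["name"]
                )
                rasters.append((row["name"], row["category"], surf))
            table = _attr.extract_variable_table(rasters, combined_div)
            retained = _attr.collinearity_filter(table, config.collinearity_threshold)
            table = _attr.VariableTable(
                table.data[["cell_id", "row", "col", "response"] + retained],
                {k: v for k, v in table.categories.items() if k in retained},
                table.n_dropped,
            )
            seeds = np.random.SeedSequence(config.seed).spawn(8)
            sel_seed = int(np.random.default_rng(seeds[1]).integers(2**31))
            for short, cat in (("C", "climatic"), ("T", "topographic"), ("A", "anthropogenic")):
                names = table.variables(cat)
                k = min(config.top_k, len(names))
                selected[short] = _attr.importance_select(
                    table, cat, k=k, seed=sel_seed, max_cells=config.rf_subsample
                ) if names else []
            # GAM per selected variable on a seeded subsample of cells
            gam_rng = np.random.default_rng(seeds[2])
            df = table.data
            if len(df) > config.gam_subsample:
                idx = np.sort(gam_rng.choice(len(df), size=config.gam_subsample, replace=False))
                df = df.iloc[idx]
            for name in [v for vs in selected.values() for v in vs]:
                gam_results.append(
                    _attr.fit_gam(
                        df[name].to_numpy(), df["response"].to_numpy(),
                        basis_dim=config.gam_basis_dim, variable=name,
                    )
                )
            pd.DataFrame(
                [
                    {"variable": g.variable, "r2_adj": g.r2_adj, "p_value": g.p_value,
                     "trend": g.trend, "edf": g.edf}
                    for g in gam_results
                ]
            ).to_csv(out / "attribution" / "gam_summary.csv", index=False)
            if all(selected.get(k) for k in ("C", "T", "A")):
                partition = _attr.variation_partition(table, selected)
                rows = [{"component": k, "adj_r2": v} for k, v in partition.adj_r2.items()]
                rows += [{"component": f"fraction_{k}", "adj_r2": v} for k, v in partition.fractions.items()]
                rows.append({"component": "residual", "adj_r2": partition.residual})
                pd.DataFrame(rows).to_csv(out / "attribution" / "partition.csv", index=False)
            pd.Series(retained, name="variable").to_csv(
                out / "attribution" / "retained_variables.csv", index=False
            )
            manifest["stages"]["attribution"] = {
                "n_variables_retained": len(retained),
                "selected": selected,
                "partition_fractions": partition.fractions if partition else None,
                "total_explained_adj_r2": partition.adj_r2["CTA"] if partition else None,
            }

        manifest["seed"] = config.seed
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return PipelineResult(
            out_dir=out,
            diversity=diversity,
            fst=fst,
            combined_diversity=combined_div,
            combined_divergence=combined_fst,
            hotspots=spots,
            outside_fraction=outside,
            ibd=ibd,
            retained_variables=retained,
            selected_variables=selected,
            gam_results=gam_results,
            partition=partition,
            manifest=manifest,
            n_dropped_populations=n_dropped,
        )
    except Exception as err:  # preserve artifact state, name the stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
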