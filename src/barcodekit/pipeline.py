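"""End-to-end orchestration: library (real or simulated) in, report bundle out.

The bundle mirrors the tables of a barcode-library evaluation study: locus
profiles, per-combination distance summaries and gap reports, best-match /
best-close-match success rates, NJ trees with bootstrap supports, a ranked
combination table, diagnostic blocks for the closest species pairs, and a
geographic-region clustering report.
"""

from __future__ import annotations

import json
import logging
import math
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__
from .combinations import combinations_table, evaluate_combinations
from .distance import DEFAULT_MIN_OVERLAP, distance_matrix, summarize_pairwise
from .errors import BarcodekitError, InsufficientDataError
from .library import BarcodeLibrary, read_library
from .matching import (
    MatchParameters,
    best_close_match,
    best_match,
    intraspecific_threshold,
    outcomes_table,
)
from .profile import profiles_table
from .diagnostics import blocks_table, find_diagnostic_blocks
from .simulate import SimulationConfig, default_config, simulate_to_dir
from .trees import bootstrap_support, label_clusters, write_newick

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs: input source, models, thresholds,
    seeds, output directory."""

    outdir: Path
    simulation: Optional[SimulationConfig] = None
    metadata_path: Optional[Path] = None
    locus_paths: dict[str, Path] = field(default_factory=dict)
    cutoff: float = 0.05
    percentile: float = 95.0
    match_model: str = "K2P"
    tree_model: str = "p"
    min_overlap: int = DEFAULT_MIN_OVERLAP
    min_support: float = 0.0
    bootstrap_reps: int = 100
    seed: int = 0
    pad_missing: bool = False
    # (locus, species_a, species_b) triples; None = closest pair per locus
    diagnostic_pairs: Optional[list[tuple[str, str, str]]] = None

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.simulation is None and (
            self.metadata_path is None or not self.locus_paths
        ):
            raise ValueError(
                "config needs either a simulation recipe or metadata + locus paths"
            )


def _closest_pair(library: BarcodeLibrary, locus_name: str, config: PipelineConfig):
    """Species pair with the smallest mean interspecific distance — the
    hardest pair, and the natural mini-barcode question."""
    locus = library.locus(locus_name)
    matrix = distance_matrix(locus, config.match_model, config.min_overlap)  # type: ignore[arg-type]
    species_of = library.species_of
    sums: dict[tuple[str, str], list[float]] = {}
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            d = matrix.values[i, j]
            if math.isnan(d):
                continue
            a, b = sorted((species_of[matrix.ids[i]], species_of[matrix.ids[j]]))
            if a != b:
                sums.setdefault((a, b), []).append(float(d))
    if not sums:
        return None
    return min(sums, key=lambda p: sum(sums[p]) / len(sums[p]))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns a dict of output paths plus the in-memory combination results.
    Per-combination failures are recorded in the tables; only unusable
    input raises.
    """
    t_start = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"barcodekit {__version__} | python {platform.python_version()}",
        f"seed={config.seed} cutoff={config.cutoff} percentile={config.percentile} "
        f"match_model={config.match_model} tree_model={config.tree_model} "
        f"bootstrap_reps={config.bootstrap_reps} min_support={config.min_support}",
    ]

    def stage(name: str, t0: float, detail: str = "") -> None:
        log_lines.append(f"stage={name} elapsed={time.perf_counter() - t0:.2f}s {detail}")

    # --- input ---
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim = config.simulation
        sim_dir = outdir / "library"
        simulate_to_dir(sim, sim_dir)
        library = read_library(
            sim_dir / "specimens.tsv",
            {l.name: sim_dir / f"{l.name}.fasta" for l in sim.loci},
        )
        stage("simulate", t0, f"n_specimens={len(library.specimens)} n_loci={len(library.loci)}")
    else:
        library = read_library(config.metadata_path, config.locus_paths)
        stage("load", t0, f"n_specimens={len(library.specimens)} n_loci={len(library.loci)}")
    paths: dict[str, object] = {}

    # --- locus profiles (Table 1 analog) ---
    t0 = time.perf_counter()
    profiles = profiles_table(library.loci, library.specimens)
    p = outdir / "locus_profiles.tsv"
    profiles.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["profiles"] = p
    stage("profile", t0)

    # --- per-locus distances, matching, gap, trees ---
    trees_dir = outdir / "trees"
    trees_dir.mkdir(exist_ok=True)
    dist_dir = outdir / "distances"
    dist_dir.mkdir(exist_ok=True)
    region_rows = []
    for idx, locus in enumerate(library.loci):
        t0 = time.perf_counter()
        matrix = distance_matrix(locus, config.match_model, config.min_overlap)  # type: ignore[arg-type]
        matrix.write_tsv(dist_dir / f"{locus.name}.{config.match_model}.tsv")
        summary = summarize_pairwise(matrix, library.specimens)
        bm = best_match(matrix, library.specimens)
        try:
            thr = intraspecific_threshold(summary, config.percentile)
        except InsufficientDataError:
            thr = math.inf
        bcm = best_close_match(matrix, library.specimens, MatchParameters(threshold=thr))
        outcomes_table(bm).to_csv(
            outdir / f"best_match.{locus.name}.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        outcomes_table(bcm).to_csv(
            outdir / f"best_close_match.{locus.name}.tsv", sep="\t", index=False,
            lineterminator="\n",
        )
        try:
            tree = bootstrap_support(
                locus, config.tree_model, max(config.bootstrap_reps, 1),  # type: ignore[arg-type]
                seed=config.seed + 17 * (idx + 1), min_overlap=config.min_overlap,
            )
            write_newick(tree, trees_dir / f"{locus.name}.nwk")
            region = label_clusters(tree, library.specimens, "region", config.min_support)
            region_rows.append(
                {"locus": locus.name, "region_cluster_rate_pct": region.overall_rate}
            )
        except BarcodekitError as exc:
            logger.warning("locus %s: tree stage skipped: %s", locus.name, exc)
            region_rows.append({"locus": locus.name, "region_cluster_rate_pct": math.nan})
        stage(f"locus:{locus.name}", t0, f"bcm_threshold={thr:.4f}")
    if region_rows:
        import pandas as pd

        rp = outdir / "region_clusters.tsv"
        pd.DataFrame(region_rows).to_csv(rp, sep="\t", index=False, lineterminator="\n")
        paths["region_clusters"] = rp

    # --- all combinations (Table 2 / Fig. 3 / Fig. 5 analogs) ---
    t0 = time.perf_counter()
    results = evaluate_combinations(
        library,
        cutoff=config.cutoff,
        percentile=config.percentile,
        match_model=config.match_model,
        tree_model=config.tree_model,
        min_overlap=config.min_overlap,
        min_support=config.min_support,
        pad_missing=config.pad_missing,
    )
    combo_path = outdir / "combinations.tsv"
    combinations_table(results).to_csv(
        combo_path, sep="\t", index=False, float_format="%.4f", lineterminator="\n"
    )
    paths["combinations"] = combo_path
    stage("combinations", t0, f"n={len(results)}")

    # --- diagnostic blocks (mini-barcode analog) ---
    t0 = time.perf_counter()
    pairs = config.diagnostic_pairs
    if pairs is None:
        pairs = []
        for locus in library.loci:
            best = _closest_pair(library, locus.name, config)
            if best is not None:
                pairs.append((locus.name, best[0], best[1]))
    blocks = []
    for locus_name, sp_a, sp_b in pairs:
        try:
            blocks.extend(
                find_diagnostic_blocks(
                    library.locus(locus_name), library.specimens, sp_a, sp_b
                )
            )
        except BarcodekitError as exc:
            logger.warning(
                "diagnostics %s %s/%s skipped: %s", locus_name, sp_a, sp_b, exc
            )
    diag_path = outdir / "diagnostic_blocks.tsv"
    blocks_table(blocks).to_csv(diag_path, sep="\t", index=False, lineterminator="\n")
    paths["diagnostics"] = diag_path
    stage("diagnostics", t0, f"n_blocks={len(blocks)}")

    log_lines.append(f"total_elapsed={time.perf_counter() - t_start:.2f}s")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    paths["run_log"] = outdir / "run_log.txt"
    paths["results"] = results
    paths["library"] = library
    return paths


def demo_config(outdir: Path, seed: int = 0, bootstrap_reps: int = 100) -> PipelineConfig:
    """Built-in demo: the default six-species simulation through the full
    pipeline."""
    return PipelineConfig(
        outdir=Path(outdir),
        simulation=default_config(seed=seed),
        seed=seed,
        bootstrap_reps=bootstrap_reps,
    )


def config_from_yaml(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from YAML (keys mirror PipelineConfig;
    ``simulation`` may be inline or a path to a simulation YAML)."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    sim = data.get("simulation")
    if isinstance(sim, str):
        data["simulation"] = SimulationConfig.from_yaml(sim)
    elif isinstance(sim, dict):
        from .simulate import LocusConfig

        sim["loci"] = tuple(LocusConfig(**l) for l in sim["loci"])
        sim["samples_per_species"] = tuple(sim["samples_per_species"])
        sim["linked_loci"] = tuple(sim.get("linked_loci", ()))
        data["simulation"] = SimulationConfig(**sim)
    if "metadata_path" in data and data["metadata_path"]:
        data["metadata_path"] = Path(data["metadata_path"])
    if "locus_paths" in data:
        data["locus_paths"] = {k: Path(v) for k, v in data["locus_paths"].items()}
    if "diagnostic_pairs" in data and data["diagnostic_pairs"]:
        data["diagnostic_pairs"] = [tuple(t) for t in data["diagnostic_pairs"]]
    data["outdir"] = Path(data["outdir"])
    return PipelineConfig(**data)


def write_summary_json(paths: dict, out: Path) -> None:
    """Condense the bundle's headline numbers into one JSON file."""
    results = paths.get("results", [])
    best = results[0] if results else None
    payload = {
        "n_combinations": len(results),
        "best_combination": best.label if best else None,
        "best_combination_bcm_pct": best.best_close_match_success if best else None,
    }
    Path(out).write_text(json.dumps(payload, indent=2) + "\n")
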