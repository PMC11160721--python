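"""Benchmark orchestration: simulate → assign → evaluate (→ reconstruct).

A :class:`BenchmarkConfig` spans a grid of SHM rates × mean leaf counts; for
every configuration × replicate a repertoire is simulated and every
configured assignment method is run and scored, producing one long-format
row per (configuration, replicate, method).  Per-cell random substreams are
derived from the master seed by (configuration index, replicate index), so
cells are independent and individually reproducible.  Failures inside a
cell are recorded as data rather than aborting the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import assign as _assign
from .ancestral import evaluate_reconstruction
from .assign import Partition, annotate_sequences, partition_from_records
from .evaluate import MetricsSummary, median_family_size, summarize
from .germline import GermlineReference, generate_synthetic_germline
from .io import repertoire_to_records
from .ptp import assign_ptp
from .simulate import Repertoire, simulate_repertoire

logger = logging.getLogger("clonefam")

#: SHM rates studied throughout: per-position expected substitutions on a
#: root-to-tip path.
DEFAULT_SHM_RATES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.2)
#: Mean leaves per clonal family (geometric); the grid size matches the
#: four-value design but the specific values are this package's defaults.
DEFAULT_MEAN_LEAVES = (2.0, 5.0, 10.0, 25.0)

DEFAULT_METHODS = ("identical-junction", "junction-threshold", "cdr3-fuzzy", "ptp")


@dataclass(frozen=True)
class BenchmarkConfig:
    shm_rates: tuple[float, ...] = DEFAULT_SHM_RATES
    mean_leaves: tuple[float, ...] = DEFAULT_MEAN_LEAVES
    n_clones: int = 16
    replicates: int = 5
    methods: tuple[str, ...] = DEFAULT_METHODS
    threshold: float = 0.15
    max_mismatch: int = 1
    annotation: str = "oracle"  # or "align"
    region: str = "whole"
    drop_singletons: bool = True
    reconstruct: bool = False
    rooting: str = "midpoint"
    seed: int = 0
    germline_seed: int | None = None
    germline: GermlineReference | None = None

    def __post_init__(self) -> None:
        if not self.shm_rates or not self.mean_leaves:
            raise ValueError("parameter grids must be nonempty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def enumerate_configurations(config: BenchmarkConfig) -> list[tuple[float, float]]:
    """Cartesian product of SHM rates × mean leaves, row-major."""
    return [(r, m) for r in config.shm_rates for m in config.mean_leaves]


def _cell_seed(master: int, config_index: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=(config_index, replicate))


def run_method(method: str, records: pd.DataFrame, config: BenchmarkConfig) -> Partition:
    if method == "identical-junction":
        return _assign.cluster_identical_junction(records)
    if method == "junction-threshold":
        return _assign.cluster_junction_threshold(records, threshold=config.threshold)
    if method == "cdr3-fuzzy":
        return _assign.cluster_cdr3_fuzzy(records, max_mismatch=config.max_mismatch)
    if method == "ptp":
        return assign_ptp(records)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(config: BenchmarkConfig) -> pd.DataFrame:
    """Run the full grid and return the long-format report."""
    germline = config.germline or generate_synthetic_germline(
        seed=config.germline_seed if config.germline_seed is not None else config.seed)
    rows: list[dict] = []
    for ci, (shm_rate, mean_leaves) in enumerate(enumerate_configurations(config)):
        for rep_i in range(config.replicates):
            cell = _cell_seed(config.seed, ci, rep_i)
            sim_seed = int(cell.generate_state(1)[0] % (2 ** 31))
            rep = simulate_repertoire(
                germline, n_clones=config.n_clones, mean_leaves=mean_leaves,
                shm_rate=shm_rate, region=config.region, seed=sim_seed)
            records = repertoire_to_records(rep)
            truth = partition_from_records(records)
            if config.annotation == "align":
                annotated = annotate_sequences(records, germline, mode="align")
            else:
                annotated = annotate_sequences(records, mode="oracle")
            for method in config.methods:
                row = {
                    "shm_rate": shm_rate, "mean_leaves": mean_leaves,
                    "replicate": rep_i, "method": method, "seed": sim_seed,
                    "n_clones_true": config.n_clones,
                    "error": None,
                }
                try:
                    inferred = run_method(method, annotated, config)
                    metrics = summarize(truth, inferred,
                                        drop_inferred_singletons=config.drop_singletons)
                    row.update(dataclasses.asdict(metrics))
                    row["median_size_true"] = median_family_size(
                        truth, drop_singletons=config.drop_singletons)
                    try:
                        row["median_size_inferred"] = median_family_size(
                            inferred, drop_singletons=config.drop_singletons)
                    except Exception:
                        row["median_size_inferred"] = float("nan")
                    if config.reconstruct:
                        recon = evaluate_reconstruction(rep, inferred,
                                                        rooting=config.rooting)
                        dists = [r.normalized_distance for r in recon
                                 if r.normalized_distance is not None]
                        row["mean_reconstruction_distance"] = (
                            float(np.mean(dists)) if dists else float("nan"))
                        row["n_reconstructed"] = len(dists)
                except Exception as exc:  # failures are data, not crashes
                    logger.warning("cell failed (%s, %s, rep %d, %s): %s",
                                   shm_rate, mean_leaves, rep_i, method, exc)
                    row["error"] = str(exc)
                rows.append(row)
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, out_dir: str | Path,
                 config: BenchmarkConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv", index=False)
    if config is not None:
        echo = {k: v for k, v in dataclasses.asdict(config).items() if k != "germline"}
        (out / "config.json").write_text(json.dumps(echo, indent=2, default=str))
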