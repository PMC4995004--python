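"""End-to-end orchestration: normalise -> estimate -> cluster -> compare.

The pipeline reads a cells x genes matrix (Ct values or integer counts;
CSV or TSV, header row of gene names, first column of cell IDs), converts
Ct to counts if needed, fits per-population kinetics, optionally runs
SABEC consensus clustering over a K sweep with outlier pruning, and runs
the differential-kinetics test on requested population pairs — on both
the pruned and unpruned cell sets when pruning is enabled, reporting the
parameters consistently called under both.

Every stage writes its outputs under the run directory and records them,
with all seeds, in ``manifest.json``; outputs are a pure function of
(config, seeds), and existing stage outputs are reused unless
``force=True``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import epik as _epik
from .estimation import fit_populations
from .model_core import GridSpec, LookupTable, build_lookup_table, \
    load_lookup_table
from .normalization import ct_to_counts
from .sabec import (corrected_rand, pac_score, prune_outliers,
                    sabec_consensus, variation_of_information)

__all__ = ["RunConfig", "run_pipeline", "read_matrix", "parse_axis_spec"]


def read_matrix(path) -> pd.DataFrame:
    """Read a cells x genes CSV/TSV matrix (cell IDs in the first column)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise ValueError(f"missing values in matrix {path}")
    return df


def parse_axis_spec(spec: str) -> np.ndarray:
    """Parse 'start:stop:step' into an inclusive grid axis."""
    start, stop, step = (float(s) for s in spec.split(":"))
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    return np.round(start + step * np.arange(n), 10)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML/JSON loadable)."""

    out_dir: str
    counts: str | None = None          # pre-scaled integer counts
    ct: str | None = None              # or normalised Ct values
    sentinel: float | None = None      # Ct value meaning "not expressed"
    labels: str | None = None          # CSV: cell_id,population
    table: str | None = None           # prebuilt lookup table (HDF5)
    grid_k_on: str = "0.1:5:0.1"
    grid_k_off: str = "0.4:20:0.4"
    grid_k_t: str = "5:200:5"
    x_max: int = 200
    k_values: list[int] = field(default_factory=lambda: [5])
    k_final: int | None = None         # K used for pruning (default: first)
    n_runs: int = 50
    tau: float = 10.0
    seed: int = 0
    run_sabec: bool = True
    pruning: bool = True
    prune_threshold: float | None = None
    pairs: list[list[str]] | None = None  # population pairs for EPiK
    min_cells: int = 10
    subsample_frac: float = 0.25
    subsample_reps: int = 100

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _get_table(cfg: RunConfig, out: Path, manifest: dict) -> LookupTable:
    if cfg.table:
        manifest["table"] = str(cfg.table)
        return load_lookup_table(cfg.table)
    cache = out / "table.h5"
    if cache.exists():
        manifest["table"] = str(cache) + " (cached)"
        return load_lookup_table(cache)
    grid = GridSpec(parse_axis_spec(cfg.grid_k_on),
                    parse_axis_spec(cfg.grid_k_off),
                    parse_axis_spec(cfg.grid_k_t), cfg.x_max)
    table = build_lookup_table(grid)
    table.save(cache)
    manifest["table"] = str(cache)
    return table


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute all configured stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "stages": {}}

    # --- stage: counts -----------------------------------------------------
    counts_path = out / "counts.csv"
    if cfg.counts:
        counts = read_matrix(cfg.counts).astype(np.int64)
    elif cfg.ct:
        if counts_path.exists() and not force:
            counts = read_matrix(counts_path)
        else:
            counts = ct_to_counts(read_matrix(cfg.ct), x_max=cfg.x_max,
                                  sentinel=cfg.sentinel)
            counts.to_csv(counts_path)
        manifest["stages"]["normalize"] = str(counts_path)
    else:
        raise ValueError("config must set either 'counts' or 'ct'")

    if cfg.labels:
        lab = pd.read_csv(cfg.labels, index_col=0).iloc[:, 0]
        labels = lab.reindex(counts.index).to_numpy()
        if pd.isna(labels).any():
            raise ValueError("labels missing for some cells")
    else:
        labels = np.zeros(len(counts), dtype=int)

    table = _get_table(cfg, out, manifest)

    # --- stage: per-population fits ---------------------------------------
    fits_path = out / "fits.csv"
    if not (fits_path.exists() and not force):
        fits = fit_populations(counts, labels, table,
                               min_expressing=cfg.min_cells)
        fits.to_csv(fits_path, index=False)
    manifest["stages"]["estimate"] = str(fits_path)

    # --- stage: SABEC sweep + pruning --------------------------------------
    kept_mask = np.ones(len(counts), dtype=bool)
    if cfg.run_sabec:
        metrics = []
        consensus_by_k = {}
        for K in cfg.k_values:
            res = sabec_consensus(counts.to_numpy(), K, table,
                                  n_runs=cfg.n_runs, tau=cfg.tau,
                                  seed=cfg.seed + 1000 * K)
            cm = res["consensus"]
            consensus_by_k[K] = cm
            freq = pd.DataFrame(cm.frequency, index=counts.index,
                                columns=counts.index)
            freq.to_csv(out / f"consensus_K{K}.csv")
            pd.Series(res["partition"], index=counts.index,
                      name="cluster").to_csv(out / f"partition_K{K}.csv")
            row = dict(K=K, pac=res["pac"])
            if cfg.labels:
                row["vi"] = variation_of_information(res["partition"], labels)
                row["rand"] = corrected_rand(res["partition"], labels)
            metrics.append(row)
        pd.DataFrame(metrics).to_csv(out / "sabec_metrics.csv", index=False)
        manifest["stages"]["sabec"] = str(out / "sabec_metrics.csv")

        if cfg.pruning:
            k_final = cfg.k_final or cfg.k_values[0]
            cm = consensus_by_k[k_final]
            kept_mask, match = prune_outliers(cm, labels,
                                              threshold=cfg.prune_threshold)
            pd.DataFrame({"match_fraction": match, "kept": kept_mask},
                         index=counts.index).to_csv(out / "pruning.csv")
            manifest["stages"]["prune"] = str(out / "pruning.csv")

    # --- stage: EPiK --------------------------------------------------------
    if cfg.pairs:
        calls = []
        for pop_a, pop_b in cfg.pairs:
            for gene in counts.columns:
                variants = {"unpruned": np.ones(len(counts), dtype=bool)}
                if cfg.pruning and cfg.run_sabec:
                    variants["pruned"] = kept_mask
                per_variant = {}
                for name, mask in variants.items():
                    a = counts.loc[mask & (labels == pop_a), gene].to_numpy()
                    b = counts.loc[mask & (labels == pop_b), gene].to_numpy()
                    try:
                        per_variant[name] = _epik.epik_test_pair(
                            a, b, table, frac=cfg.subsample_frac,
                            reps=cfg.subsample_reps,
                            seed=cfg.seed + (zlib.crc32(
                                f"{gene}|{pop_a}|{pop_b}|{name}".encode())
                                & 0x3FFFFFFF), min_cells=cfg.min_cells)
                    except ValueError:
                        # e.g. pruning left too few cells to subsample
                        per_variant[name] = _epik.EpikCall(testable=False)
                u = per_variant["unpruned"]
                consistent = u.intersection
                if "pruned" in per_variant and per_variant["pruned"].testable:
                    consistent = consistent & per_variant["pruned"].intersection
                calls.append(dict(
                    gene=gene, pop_a=pop_a, pop_b=pop_b,
                    testable=u.testable, regime=u.regime,
                    bic_set="+".join(sorted(u.bic_set)),
                    mp_kon=u.mp.get("k_on"), mp_koff=u.mp.get("k_off"),
                    mp_kt=u.mp.get("k_t"),
                    ks_kon=u.ks.get("k_on"), ks_koff=u.ks.get("k_off"),
                    ks_kt=u.ks.get("k_t"),
                    intersection_call="+".join(sorted(u.intersection)),
                    union_call="+".join(sorted(u.union_mp_ks)),
                    consistent_call="+".join(sorted(consistent)),
                    direction=u.direction,
                ))
        pd.DataFrame(calls).to_csv(out / "epik_calls.csv", index=False)
        manifest["stages"]["epik"] = str(out / "epik_calls.csv")

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest
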