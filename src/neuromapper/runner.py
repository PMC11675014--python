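"""Parameter-grid batch execution over a cohort of input matrices.

A JSON grid config describes each pipeline stage; any list-valued field is
swept, and the Cartesian product (in a fixed field order) yields the
individual :class:`~neuromapper.pipeline.MapperConfig` runs.  A cohort CSV
lists the inputs.  Results land in a deterministic layout::

    out_dir/<input_id>/<config_hash>/{graph.json, graph.graphml,
                                      membership.csv, stats.csv}

with a run manifest recording config hashes, seeds, and failures.  Results
are independent of the parallel pool size because every task's seed is
derived from the master seed and the task's identity, never from
execution order.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .data import DataMatrix
from .pipeline import MapperConfig, MapperResult, evaluate_result, run_mapper
from .shapegraph import compute_tcm, normalized_degree
from .synthdata import StateLabels

__all__ = ["GridConfig", "CohortTable", "expand_grid", "run_cohort",
           "aggregate_stats", "config_hash"]

# canonical sweep order: (section, field); expansion is the Cartesian
# product of list-valued fields in exactly this order
_GRID_FIELDS = [
    ("dist", "type"), ("dist", "k"),
    ("embed", "type"), ("embed", "dims"),
    ("bin", "type"), ("bin", "resolution"), ("bin", "gain"), ("bin", "sides"),
    ("cluster", "type"), ("cluster", "bins"), ("cluster", "eps"),
    ("preprocess", None),
]
_KNOWN = {
    "dist": {"type", "k"},
    "embed": {"type", "dims", "params"},
    "bin": {"type", "resolution", "gain", "sides"},
    "cluster": {"type", "bins", "eps", "min_pts"},
}
_TOP_KEYS = {"dist", "embed", "bin", "cluster", "preprocess", "analyses"}


@dataclass
class GridConfig:
    """Validated parameter-grid specification (the JSON dialect)."""

    spec: dict[str, Any]

    @classmethod
    def from_json(cls, path: str | Path) -> "GridConfig":
        return cls(json.loads(Path(path).read_text()))

    def __post_init__(self) -> None:
        for key in self.spec:
            if key not in _TOP_KEYS:
                raise ValueError(f"unknown config section {key!r}; "
                                 f"expected one of {sorted(_TOP_KEYS)}")
        for section, allowed in _KNOWN.items():
            for field in self.spec.get(section, {}):
                if field not in allowed:
                    raise ValueError(
                        f"unknown field {section}.{field!r}; "
                        f"allowed: {sorted(allowed)}")

    @property
    def analyses(self) -> list[dict]:
        return self.spec.get("analyses", [{"type": "stats"}])


@dataclass
class CohortTable:
    """Input listing: unique ids and paths relative to a data root."""

    table: pd.DataFrame

    @classmethod
    def from_csv(cls, path: str | Path) -> "CohortTable":
        df = pd.read_csv(path)
        if "id" not in df.columns or "path" not in df.columns:
            raise ValueError("cohort CSV needs 'id' and 'path' columns")
        if df["id"].duplicated().any():
            raise ValueError("cohort ids must be unique")
        return cls(df)

    def __len__(self) -> int:
        return len(self.table)


def _as_list(v: Any) -> list:
    return v if isinstance(v, list) else [v]


def _single_config(choice: dict[tuple[str, str | None], Any],
                   spec: dict[str, Any]) -> MapperConfig:
    dist_type = choice[("dist", "type")]
    geodesic = dist_type.startswith("geodesic")
    metric = dist_type.removeprefix("geodesic_") if geodesic else dist_type
    embed_type = choice[("embed", "type")]
    bin_type = choice[("bin", "type")]
    bin_kind = ("intrinsic" if bin_type in ("intrinsic", "landmark")
                else "extrinsic")
    cluster_type = choice[("cluster", "type")]
    return MapperConfig(
        metric=metric, geodesic=geodesic, k=int(choice[("dist", "k")]),
        lens_algorithm=embed_type, lens_dim=int(choice[("embed", "dims")]),
        lens_params=dict(spec.get("embed", {}).get("params", {})),
        bin_kind=bin_kind, resolution=int(choice[("bin", "resolution")]),
        gain=float(choice[("bin", "gain")]), sides=int(choice[("bin", "sides")]),
        cluster_method=("linkage" if cluster_type == "linkage" else "dbscan"),
        hist_bins=int(choice[("cluster", "bins")]),
        eps=(None if choice[("cluster", "eps")] is None
             else float(choice[("cluster", "eps")])),
        min_pts=int(spec.get("cluster", {}).get("min_pts", 3)),
        preprocess=choice[("preprocess", None)],
    )


def expand_grid(config: GridConfig) -> list[MapperConfig]:
    """Cartesian product of all list-valued fields, in the canonical
    (section, field) order, as single Mapper configurations."""
    spec = config.spec
    defaults = {
        ("dist", "type"): "geodesic_euclidean", ("dist", "k"): 12,
        ("embed", "type"): "CMDS", ("embed", "dims"): 2,
        ("bin", "type"): "cube", ("bin", "resolution"): 20,
        ("bin", "gain"): 70, ("bin", "sides"): 4,
        ("cluster", "type"): "linkage", ("cluster", "bins"): 10,
        ("cluster", "eps"): None,
        ("preprocess", None): "none",
    }
    axes = []
    for section, field in _GRID_FIELDS:
        if field is None:
            raw = spec.get(section, defaults[(section, field)])
        else:
            raw = spec.get(section, {}).get(field, defaults[(section, field)])
        axes.append([(section, field, v) for v in _as_list(raw)])
    configs = []
    for combo in itertools.product(*axes):
        choice = {(s, f): v for s, f, v in combo}
        configs.append(_single_config(choice, spec))
    return configs


def config_hash(config: MapperConfig) -> str:
    """Stable digest of the canonicalized single-config JSON (the per-task
    seed is not part of the configuration's identity)."""
    doc = config.to_dict()
    doc.pop("seed")
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:12]


def _expected_from_labels(labels: np.ndarray, tr: float) -> np.ndarray:
    """Transition times = samples where the label changes."""
    labels = np.asarray(labels)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    return change * tr


def stats_row(result: MapperResult) -> dict[str, Any]:
    v, g = result.validation, result.gof
    c = result.config
    return {
        "metric": c.metric, "geodesic": c.geodesic, "k": c.k,
        "embed": c.lens_algorithm, "resolution": c.resolution, "gain": c.gain,
        "clusterer": c.cluster_method,
        "n_nodes": result.graph.n_nodes, "n_edges": len(result.graph.edges),
        "alpha": v.alpha if v else np.nan, "beta": v.beta if v else np.nan,
        "entropy": v.entropy if v else np.nan,
        "valid": bool(v.valid) if v else False,
        "circleness": (g.circleness if g else None),
        "n_transitions": len(g.transitions) if g else 0,
        "average_delay": g.average_delay if g else np.nan,
        "pass_12s": bool(g and np.isfinite(g.average_delay)
                         and g.average_delay <= 12.0),
        "pass_20s": bool(g and np.isfinite(g.average_delay)
                         and g.average_delay <= 20.0),
    }


def _task_seed(master_seed: int, input_id: str, chash: str) -> int:
    h = hashlib.sha256(f"{master_seed}:{input_id}:{chash}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _run_one(input_id: str, path: Path, labels_path: Path | None, tr: float,
             config: MapperConfig, analyses: list[dict], out_dir: Path,
             master_seed: int) -> dict[str, Any]:
    from dataclasses import replace as dc_replace
    chash = config_hash(config)
    try:
        data = DataMatrix.from_tsv(path, tr=tr,
                                   labels_path=labels_path)
        config = dc_replace(config,
                            seed=_task_seed(master_seed, input_id, chash))
        result = run_mapper(data, config)
        tau = delta = None
        for a in analyses:
            if a.get("type") == "stats":
                tau, delta = a.get("tau", 11.0), a.get("delta", 12.0)
        expected = None
        n_change = None
        if data.labels is not None:
            expected = _expected_from_labels(data.labels, data.tr)
            n_change = len(expected) if len(expected) else None
        evaluate_result(result, data,
                        expected_transitions=expected if n_change else None,
                        n_change=n_change,
                        tau=tau if tau is not None else 11.0,
                        delta=delta if delta is not None else 12.0)
        dest = out_dir / input_id / chash
        dest.mkdir(parents=True, exist_ok=True)
        wanted = {a.get("type") for a in analyses}
        if "graph" in wanted or "stats" in wanted:
            result.graph.to_json(dest / "graph.json")
            result.graph.to_graphml(dest / "graph.graphml")
            result.graph.membership_frame().to_csv(dest / "membership.csv",
                                                   index=False)
        row = stats_row(result)
        pd.DataFrame([row]).to_csv(dest / "stats.csv", index=False)
        if "plot" in wanted:
            _plot_degree(result, dest / "degree.csv")
        (dest / "config.json").write_text(
            json.dumps(config.to_dict(), sort_keys=True, indent=1))
        return {"input": input_id, "config": chash, "status": "ok",
                "seed": config.seed, **row}
    except Exception as exc:  # recorded, run continues
        return {"input": input_id, "config": chash, "status": "failed",
                "error": f"{type(exc).__name__}: {exc}"}


def _plot_degree(result: MapperResult, csv_path: Path) -> None:
    """Persist the normalized-degree series (and a PNG next to it when
    matplotlib is importable)."""
    deg = normalized_degree(compute_tcm(result.graph))
    pd.DataFrame({"t": np.arange(deg.size), "normalized_degree": deg}).to_csv(
        csv_path, index=False)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.plot(deg)
        ax.set_xlabel("time point")
        ax.set_ylabel("normalized degree")
        fig.tight_layout()
        fig.savefig(csv_path.with_suffix(".png"), dpi=100)
        plt.close(fig)
    except Exception:
        pass


def run_cohort(cohort: CohortTable, config: GridConfig, data_root: str | Path,
               out_dir: str | Path, poolsize: int = 1,
               master_seed: int = 0) -> pd.DataFrame:
    """Run every (input x config) task; returns the manifest frame.

    Unreadable inputs are recorded as failures without aborting the rest;
    an invalid grid config aborts before any execution (validated at
    construction).  Reruns with identical inputs are idempotent.
    """
    data_root, out_dir = Path(data_root), Path(out_dir)
    if poolsize < 1:
        raise ValueError("poolsize must be >= 1")
    configs = expand_grid(config)
    tasks = []
    for _, row in cohort.table.iterrows():
        path = data_root / row["path"]
        labels_path = (data_root / row["labels"]
                       if "labels" in row and pd.notna(row.get("labels")) else None)
        tr = float(row["tr"]) if "tr" in row and pd.notna(row.get("tr")) else 1.0
        for cfg in configs:
            tasks.append((str(row["id"]), path, labels_path, tr, cfg))
    results = Parallel(n_jobs=poolsize)(
        delayed(_run_one)(iid, path, lp, tr, cfg, config.analyses, out_dir,
                          master_seed)
        for iid, path, lp, tr, cfg in tasks)
    manifest = pd.DataFrame(results)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    meta = {"master_seed": master_seed, "n_inputs": len(cohort),
            "n_configs": len(configs),
            "config_hashes": [config_hash(c) for c in configs]}
    (out_dir / "manifest.json").write_text(json.dumps(meta, indent=1))
    return manifest


def aggregate_stats(out_dir: str | Path) -> pd.DataFrame:
    """Collect every per-graph stats.csv under ``out_dir`` into one
    long-format table (input, pipeline parameters, metrics, pass flags)."""
    out_dir = Path(out_dir)
    frames = []
    for stats in sorted(out_dir.glob("*/*/stats.csv")):
        df = pd.read_csv(stats)
        df.insert(0, "input", stats.parent.parent.name)
        df.insert(1, "config", stats.parent.name)
        frames.append(df)
    if not frames:
        warnings.warn(f"no stats files found under {out_dir}")
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def pass_count_matrix(stats: pd.DataFrame, flag: str = "valid") -> pd.DataFrame:
    """Per-(resolution x gain) pass counts, the heatmap summary."""
    if stats.empty:
        return pd.DataFrame()
    return (stats.pivot_table(index="resolution", columns="gain", values=flag,
                              aggfunc="sum", fill_value=0))
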