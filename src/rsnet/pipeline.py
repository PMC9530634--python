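"""End-to-end orchestration: simulate -> connectivity -> metrics -> stats.

A run is fully determined by a :class:`RunConfig` and writes a self-contained
output directory::

    out/
      cohort/manifest.csv, cohort/timeseries/*.tsv
      fc/<subject>_<session>.tsv
      metrics.tsv                       # tidy long format
      screens/local_screen.tsv
      screens/global_anova.tsv, global_glm.tsv, global_fisher_z.tsv
      bundle.json                       # config echo, seed, version, row counts
      run.log

Stages are cached by a content hash of their inputs plus the relevant
configuration, so an unchanged re-run reuses intermediates; pass
``force=True`` to recompute everything.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    CohortConfig,
    default_effects,
    default_score_models,
    generate_cohort,
    null_score_models,
)
from .connectivity import (
    DEFAULT_K_GRID,
    ConnectivityMatrix,
    binarize_top_k,
    pearson_fc,
)
from .io import (
    read_fc,
    read_manifest,
    read_timeseries,
    write_cohort,
    write_fc,
    write_table,
)
from .metrics import (
    LOCAL_METRICS,
    auc_aggregate,
    global_metrics,
    nodal_metrics,
    small_worldness,
)
from .stats import global_metric_screen, local_metric_screen

__all__ = ["RunConfig", "ResultBundle", "compute_metric_table", "run_pipeline"]

logger = logging.getLogger("rsnet")

GLOBAL_CHOICES = ("global_efficiency", "char_path_length", "small_worldness")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``planted`` switches between the study-condition cohort (hub-edge
    perturbation plus LSAS slope change) and a fully null cohort.  The
    ``atlas_label`` is a free-text tag recorded in outputs.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    planted: bool = True
    local_metrics: tuple[str, ...] = LOCAL_METRICS
    global_metrics: tuple[str, ...] = ("global_efficiency", "char_path_length", "small_worldness")
    n_nulls: int = 100
    fdr_q: float = 0.05
    family: str = "per-threshold"
    absolute: bool = False
    seed: int = 0
    atlas_label: str = "desk-30"

    def __post_init__(self) -> None:
        unknown = set(self.local_metrics) - set(LOCAL_METRICS)
        if unknown:
            raise ValueError(f"unknown local metrics: {sorted(unknown)}")
        unknown = set(self.global_metrics) - set(GLOBAL_CHOICES)
        if unknown:
            raise ValueError(f"unknown global metrics: {sorted(unknown)}")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must lie in (0, 1)")
        # the master seed drives the cohort unless one was set explicitly
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort.to_dict(),
            "planted": self.planted,
            "local_metrics": list(self.local_metrics),
            "global_metrics": list(self.global_metrics),
            "n_nulls": self.n_nulls,
            "fdr_q": self.fdr_q,
            "family": self.family,
            "absolute": self.absolute,
            "seed": self.seed,
            "atlas_label": self.atlas_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = {
                **cohort,
                "group_sizes": tuple(cohort.get("group_sizes", (28, 24))),
                "dropout": tuple(cohort.get("dropout", (8, 3))),
                "k_grid": tuple(cohort.get("k_grid", DEFAULT_K_GRID)),
            }
            cohort = CohortConfig(**cohort)
        for key in ("local_metrics", "global_metrics"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(cohort=cohort, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ResultBundle:
    """In-memory handles to a finished run's tables and paths."""

    manifest: pd.DataFrame
    metric_table: pd.DataFrame
    local_screen: pd.DataFrame
    global_screens: dict[str, pd.DataFrame]
    config: RunConfig
    out_dir: Path
    meta: dict


def compute_metric_table(
    fcs: dict[tuple[str, str], ConnectivityMatrix],
    k_grid=DEFAULT_K_GRID,
    local_metrics: tuple[str, ...] = LOCAL_METRICS,
    global_metric_set: tuple[str, ...] = ("global_efficiency", "char_path_length"),
    n_nulls: int = 100,
    seed=None,
    absolute: bool = False,
) -> pd.DataFrame:
    """Tidy long-format metric table over subjects, regions and thresholds.

    Columns: ``subject_id, session, region, metric, threshold, value`` with
    ``region="GLOBAL"`` for whole-network metrics and ``threshold="AUC"`` for
    the grid aggregate.  Small-worldness nulls are seeded per subject-session
    so the table is reproducible.
    """
    k_grid = tuple(float(k) for k in k_grid)
    want_full_nodal = bool(set(local_metrics) - {"degree"})
    want_sigma = "small_worldness" in global_metric_set
    want_eff = "global_efficiency" in global_metric_set
    want_cpl = "char_path_length" in global_metric_set
    ss = np.random.SeedSequence(seed)
    keys = sorted(fcs)
    sigma_seeds = dict(zip(keys, ss.spawn(len(keys)))) if want_sigma else {}

    rows = []
    for key in keys:
        sid, session = key
        fc = fcs[key]
        labels = fc.roi_labels
        local_curves = {m: {lab: {} for lab in labels} for m in local_metrics}
        global_curves: dict[str, dict] = {m: {} for m in ("global_efficiency", "char_path_length", "small_worldness")}
        for k in k_grid:
            net = binarize_top_k(fc, k, absolute=absolute)
            if want_full_nodal:
                nm = nodal_metrics(net)
                per_metric = {m: getattr(nm, m) for m in local_metrics}
            elif local_metrics:
                per_metric = {"degree": net.adjacency.sum(axis=1).astype(float)}
            else:
                per_metric = {}
            for m, vec in per_metric.items():
                for lab, v in zip(labels, vec):
                    local_curves[m][lab][k] = float(v)
            if want_eff or want_cpl:
                g = global_metrics(net)
                global_curves["global_efficiency"][k] = g.global_efficiency
                global_curves["char_path_length"][k] = g.char_path_length
            if want_sigma:
                sw = small_worldness(net, n_nulls=n_nulls, seed=sigma_seeds[key])
                global_curves["small_worldness"][k] = sw.sigma

        for m in local_metrics:
            for lab in labels:
                curve = local_curves[m][lab]
                for k, v in curve.items():
                    rows.append((sid, session, lab, m, str(k), v))
                auc, _ = auc_aggregate(curve) if len(curve) >= 2 else (np.nan, 0)
                rows.append((sid, session, lab, m, "AUC", auc))
        for m in global_metric_set:
            curve = global_curves[m]
            for k, v in curve.items():
                rows.append((sid, session, "GLOBAL", m, str(k), v))
            auc, _ = auc_aggregate(curve) if len(curve) >= 2 else (np.nan, 0)
            rows.append((sid, session, "GLOBAL", m, "AUC", auc))
    return pd.DataFrame(
        rows, columns=["subject_id", "session", "region", "metric", "threshold", "value"]
    )


def _hash_inputs(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, Path):
            h.update(part.read_bytes())
        else:
            h.update(str(part).encode())
        h.update(b"\x00")
    return h.hexdigest()


class _StageCache:
    def __init__(self, out_dir: Path, force: bool):
        self.path = out_dir / ".stage_hashes.json"
        self.force = force
        self.hashes = {}
        if self.path.exists() and not force:
            try:
                self.hashes = json.loads(self.path.read_text())
            except json.JSONDecodeError:
                self.hashes = {}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        return (
            not self.force
            and self.hashes.get(stage) == digest
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, digest: str) -> None:
        self.hashes[stage] = digest
        self.path.write_text(json.dumps(self.hashes, indent=0, sort_keys=True))


def _setup_logging(out_dir: Path, level: str = "INFO") -> None:
    logger.setLevel(level)
    have_file = any(
        isinstance(h, logging.FileHandler)
        and Path(getattr(h, "baseFilename", "")) == out_dir / "run.log"
        for h in logger.handlers
    )
    if not have_file:
        fh = logging.FileHandler(out_dir / "run.log")
        fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(fh)


def run_pipeline(config: RunConfig, out_dir, force: bool = False) -> ResultBundle:
    """Execute all stages, reusing cached intermediates when inputs match."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    cache = _StageCache(out_dir, force)
    cfg = config.to_dict()
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    t_all = time.perf_counter()

    # ---- stage 1: simulate -------------------------------------------------
    manifest_path = out_dir / "cohort" / "manifest.csv"
    digest = _hash_inputs("simulate", json.dumps(cfg["cohort"], sort_keys=True), config.planted)
    if cache.fresh("simulate", digest, [manifest_path]):
        logger.info("simulate: cached")
    else:
        t0 = time.perf_counter()
        effects = default_effects(config.cohort.n_regions) if config.planted else ()
        models = default_score_models() if config.planted else null_score_models()
        cohort = generate_cohort(config.cohort, effects=effects, score_models=models)
        write_cohort(cohort, out_dir / "cohort")
        cache.record("simulate", digest)
        logger.info(
            "simulate: %d manifest rows in %.1fs",
            len(cohort.manifest),
            time.perf_counter() - t0,
        )

    manifest, echo = read_manifest(manifest_path)

    # ---- stage 2: connectivity --------------------------------------------
    fc_dir = out_dir / "fc"
    ts_paths = sorted((out_dir / "cohort" / "timeseries").glob("*.tsv"))
    digest = _hash_inputs("fc", config.absolute, *ts_paths)
    fc_paths = [fc_dir / p.name for p in ts_paths]
    if cache.fresh("fc", digest, fc_paths):
        logger.info("fc: cached")
    else:
        t0 = time.perf_counter()
        for _, row in manifest.iterrows():
            ts = read_timeseries(
                out_dir / "cohort" / row["file"],
                subject_id=row["subject_id"],
                session=row["session"],
            )
            write_fc(pearson_fc(ts), fc_dir / f"{row['subject_id']}_{row['session']}.tsv")
        cache.record("fc", digest)
        logger.info("fc: %d matrices in %.1fs", len(manifest), time.perf_counter() - t0)

    # ---- stage 3: metrics --------------------------------------------------
    metrics_path = out_dir / "metrics.tsv"
    digest = _hash_inputs(
        "metrics",
        json.dumps(
            {
                "k_grid": list(config.cohort.k_grid),
                "local": list(config.local_metrics),
                "global": list(config.global_metrics),
                "n_nulls": config.n_nulls,
                "seed": config.seed,
                "absolute": config.absolute,
            },
            sort_keys=True,
        ),
        *sorted(fc_dir.glob("*.tsv")),
    )
    if cache.fresh("metrics", digest, [metrics_path]):
        logger.info("metrics: cached")
        metric_table = pd.read_csv(
            metrics_path, sep="\t", dtype={"threshold": str}, float_precision="round_trip"
        )
    else:
        t0 = time.perf_counter()
        fcs = {
            (row["subject_id"], row["session"]): read_fc(
                fc_dir / f"{row['subject_id']}_{row['session']}.tsv"
            )
            for _, row in manifest.iterrows()
        }
        metric_table = compute_metric_table(
            fcs,
            k_grid=config.cohort.k_grid,
            local_metrics=config.local_metrics,
            global_metric_set=config.global_metrics,
            n_nulls=config.n_nulls,
            seed=config.seed,
            absolute=config.absolute,
        )
        write_table(metric_table, metrics_path)
        cache.record("metrics", digest)
        logger.info(
            "metrics: %d rows in %.1fs", len(metric_table), time.perf_counter() - t0
        )

    # ---- stage 4: stats ----------------------------------------------------
    t0 = time.perf_counter()
    local_screen = local_metric_screen(
        metric_table, manifest, q=config.fdr_q, family=config.family
    )
    global_screens = global_metric_screen(metric_table, manifest)
    screens_dir = out_dir / "screens"
    write_table(local_screen, screens_dir / "local_screen.tsv")
    write_table(global_screens["anova"], screens_dir / "global_anova.tsv")
    write_table(global_screens["glm"], screens_dir / "global_glm.tsv")
    write_table(global_screens["fisher_z"], screens_dir / "global_fisher_z.tsv")
    logger.info("stats: %d local rows in %.1fs", len(local_screen), time.perf_counter() - t0)

    meta = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg,
        "config_echo": echo,
        "row_counts": {
            "manifest": len(manifest),
            "metric_table": len(metric_table),
            "local_screen": len(local_screen),
            "global_anova": len(global_screens["anova"]),
            "global_glm": len(global_screens["glm"]),
            "global_fisher_z": len(global_screens["fisher_z"]),
        },
    }
    (out_dir / "bundle.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_all)
    return ResultBundle(
        manifest=manifest,
        metric_table=metric_table,
        local_screen=local_screen,
        global_screens=global_screens,
        config=config,
        out_dir=out_dir,
        meta=meta,
    )
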