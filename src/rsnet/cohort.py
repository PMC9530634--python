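"""Synthetic two-group, two-session resting-state cohort generator.

Emulates a randomized waitlist-controlled design: a control arm (n = 28 at
baseline, 8 drop out) and an experimental arm (n = 24 at baseline, 3 drop
out), each with a baseline and a follow-up recording of N regional
BOLD-like timeseries, plus psychometric scores (LSAS, BFNE, SIAS, RSES,
HADS anxiety/depression subscales), age, and gender.

The generative model is deliberately the simplest structure exhibiting every
feature the inference layer tests:

* a block-structured population correlation matrix (modular resting-state
  organization: within-module correlation ``rho_in``, between-module
  ``rho_out``), repaired to positive definiteness by eigenvalue clipping;
* an additive, cell-specific edge perturbation (the planted group-by-time
  effect), by default +0.4 on five "hub" edges in the experimental group at
  follow-up;
* frames drawn as a first-order autoregressive process driven by correlated
  innovations, so that the lag-0 inter-regional correlation equals the
  target matrix while each channel carries BOLD-like temporal smoothness;
* social-anxiety scores generated conditionally on each subject's *own*
  realized global network metric (AUC over the density grid), with a
  cell-specific slope — so a planted slope change is exactly the quantity
  the correlation-trend GLM downstream estimates.

Everything is reproducible from a single seed; dropout is completely at
random and non-completers keep their baseline session, flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import metrics as gm
from .connectivity import DEFAULT_K_GRID, RoiTimeseries, pearson_fc, threshold_series

__all__ = [
    "CorrelationStructure",
    "EffectSpec",
    "ScoreModel",
    "CohortConfig",
    "Cohort",
    "make_base_correlation",
    "apply_effect",
    "sample_timeseries",
    "generate_scores",
    "generate_cohort",
    "default_effects",
    "default_score_models",
    "null_score_models",
]

GROUPS = ("control", "experimental")
SESSIONS = ("baseline", "followup")

#: Demographic cell parameters: group -> (age mean, age sd, P(female)).
DEMOGRAPHICS = {
    "control": (23.18, 2.04, 10 / 28),
    "experimental": (23.75, 2.64, 10 / 24),
}

#: Ancillary scales drawn as plain cell-mean normals, (mean, sd) per cell.
ANCILLARY_SCALES = {
    "RSES": {
        ("control", "baseline"): (16.50, 5.18),
        ("control", "followup"): (16.50, 4.95),
        ("experimental", "baseline"): (14.92, 5.83),
        ("experimental", "followup"): (17.86, 6.52),
    },
    "HADS_A": {
        ("control", "baseline"): (8.82, 2.89),
        ("control", "followup"): (8.25, 3.01),
        ("experimental", "baseline"): (10.21, 4.22),
        ("experimental", "followup"): (8.29, 3.95),
    },
    "HADS_D": {
        ("control", "baseline"): (8.54, 3.67),
        ("control", "followup"): (7.70, 3.54),
        ("experimental", "baseline"): (8.17, 4.74),
        ("experimental", "followup"): (6.33, 3.85),
    },
}

_PD_EPS = 1e-6


@dataclass
class CorrelationStructure:
    """Population inter-regional correlation matrix with module labels.

    ``repair_perturbation`` records the largest absolute entry change made by
    the positive-definiteness repair (0 when no repair was needed).
    """

    matrix: np.ndarray
    block_assignment: np.ndarray
    repair_perturbation: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = m.shape[0]
        if m.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        off = m[~np.eye(n, dtype=bool)]
        if off.size and np.max(np.abs(off)) >= 1:
            raise ValueError("off-diagonal correlations must satisfy |r| < 1")
        self.matrix = m
        self.block_assignment = np.asarray(self.block_assignment, dtype=int)
        if self.block_assignment.shape != (n,):
            raise ValueError("block assignment must have one entry per region")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class EffectSpec:
    """Additive correlation change on selected edges in one design cell."""

    edges: tuple[tuple[int, int], ...]
    delta: float
    group: str = "experimental"
    session: str = "followup"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"effect edge ({i}, {j}) is a self-loop")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.group, self.session)


@dataclass
class ScoreModel:
    """Linear score model: score = intercept(cell) + slope(cell) * metric + noise.

    ``intercept`` may be a scalar or a per-cell mapping; ``slope_by_cell``
    maps every (group, session) cell to the slope of the score on the
    (cohort-standardized) target global metric AUC.  ``clamp`` optionally
    restricts scores to an instrument range (off by default).
    """

    name: str
    intercept: float | Mapping[tuple[str, str], float]
    slope_by_cell: Mapping[tuple[str, str], float]
    noise_sd: float
    target_metric: str = "char_path_length"
    clamp: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for cell, slope in dict(self.slope_by_cell).items():
            if not np.isfinite(slope):
                raise ValueError(f"slope for cell {cell} is not finite")

    def intercept_for(self, cell: tuple[str, str]) -> float:
        if isinstance(self.intercept, Mapping):
            if cell not in self.intercept:
                raise KeyError(f"unknown design cell {cell!r}")
            return float(self.intercept[cell])
        return float(self.intercept)

    def slope_for(self, cell: tuple[str, str]) -> float:
        if cell not in self.slope_by_cell:
            raise KeyError(f"unknown design cell {cell!r}")
        return float(self.slope_by_cell[cell])


@dataclass
class CohortConfig:
    """Study-scale parameters of the synthetic cohort.

    Defaults mirror the emulated design (28 control / 24 experimental at
    baseline with 8 / 3 dropouts, two sessions) at a desk-scale parcellation
    of 30 regions and a 5-minute-like recording of 150 frames.
    """

    n_regions: int = 30
    n_frames: int = 150
    group_sizes: tuple[int, int] = (28, 24)  # (control, experimental)
    dropout: tuple[int, int] = (8, 3)
    n_blocks: int = 5
    rho_in: float = 0.4
    rho_out: float = 0.1
    phi: float = 0.3
    k_grid: tuple[float, ...] = DEFAULT_K_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1 < self.phi < 1:
            raise ValueError("AR coefficient phi must lie in (-1, 1)")
        for g, (size, drop) in enumerate(zip(self.group_sizes, self.dropout)):
            if size - drop < 2:
                raise ValueError(
                    f"group {GROUPS[g]}: fewer than 2 completers "
                    f"({size} enrolled, {drop} dropouts)"
                )
        if self.n_frames <= self.n_regions:
            warnings.warn(
                "n_frames <= n_regions: sample correlation matrices will be "
                "rank-deficient",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "n_frames": self.n_frames,
            "group_sizes": list(self.group_sizes),
            "dropout": list(self.dropout),
            "n_blocks": self.n_blocks,
            "rho_in": self.rho_in,
            "rho_out": self.rho_out,
            "phi": self.phi,
            "k_grid": list(self.k_grid),
            "seed": self.seed,
        }


@dataclass
class Cohort:
    """Generated cohort: manifest, timeseries, and realized global metrics.

    ``realized_metrics`` holds each subject-session's AUC-aggregated global
    efficiency and average shortest path length, computed with the package's
    own connectivity and metric stages — the very values the score models
    conditioned on.
    """

    manifest: pd.DataFrame
    timeseries: dict[tuple[str, str], RoiTimeseries]
    config: CohortConfig
    base: CorrelationStructure
    realized_metrics: pd.DataFrame


def _repair_positive_definite(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at a small floor, reconstruct, rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(m)
    if vals.min() > _PD_EPS:
        return m, 0.0
    clipped = np.clip(vals, _PD_EPS, None)
    rebuilt = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.diag(rebuilt))
    rebuilt = rebuilt / np.outer(d, d)
    rebuilt = (rebuilt + rebuilt.T) / 2.0
    np.fill_diagonal(rebuilt, 1.0)
    if np.linalg.eigvalsh(rebuilt).min() <= 0:
        raise RuntimeError("correlation matrix not positive definite after repair")
    return rebuilt, float(np.max(np.abs(rebuilt - m)))


def make_base_correlation(
    n_regions: int, n_blocks: int, rho_in: float, rho_out: float
) -> CorrelationStructure:
    """Block-modular population correlation matrix.

    Regions are split into ``n_blocks`` contiguous modules; off-diagonals are
    ``rho_in`` within a module and ``rho_out`` across modules (requires
    0 <= rho_out < rho_in < 1).  The result is repaired to positive
    definiteness if necessary.
    """
    if not 0 <= rho_out < rho_in < 1:
        raise ValueError("need 0 <= rho_out < rho_in < 1")
    if not 1 <= n_blocks <= n_regions:
        raise ValueError("need 1 <= n_blocks <= n_regions")
    assignment = np.concatenate(
        [np.full(len(b), i) for i, b in enumerate(np.array_split(np.arange(n_regions), n_blocks))]
    )
    same = assignment[:, None] == assignment[None, :]
    m = np.where(same, rho_in, rho_out)
    np.fill_diagonal(m, 1.0)
    m, pert = _repair_positive_definite(m)
    return CorrelationStructure(
        matrix=m, block_assignment=assignment, repair_perturbation=pert
    )


def apply_effect(base: CorrelationStructure, effect: EffectSpec) -> CorrelationStructure:
    """Shift the targeted edges' correlations by ``delta`` (symmetrically).

    Raises if a target leaves (-1, 1); re-checks positive definiteness and
    records the repair perturbation on the returned structure.
    """
    m = base.matrix.copy()
    n = base.n_regions
    for i, j in effect.edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"effect edge ({i}, {j}) outside 0..{n - 1}")
        new = m[i, j] + effect.delta
        if abs(new) >= 1:
            raise ValueError(
                f"effect on edge ({i}, {j}) drives correlation to {new:.3f}, "
                "outside (-1, 1)"
            )
        m[i, j] = new
        m[j, i] = new
    m, pert = _repair_positive_definite(m)
    return CorrelationStructure(
        matrix=m,
        block_assignment=base.block_assignment.copy(),
        repair_perturbation=pert,
    )


def sample_timeseries(
    R: CorrelationStructure,
    n_frames: int,
    phi: float,
    seed,
    roi_labels=None,
    subject_id: str = "",
    session: str = "baseline",
    burn_in: int = 100,
) -> RoiTimeseries:
    """Draw an AR(1)-filtered multivariate-normal recording.

    Innovations are jointly normal with covariance ``R`` and the shared AR
    filter x_t = phi * x_{t-1} + eps_t is applied channel-wise, so the
    stationary lag-0 inter-regional correlation equals ``R`` while each
    channel gains temporal autocorrelation phi.  ``burn_in`` initial frames
    are discarded to reach stationarity.  Deterministic given ``seed``.
    """
    if n_frames < 10:
        raise ValueError("need at least 10 frames")
    if not -1 < phi < 1:
        raise ValueError("AR coefficient phi must lie in (-1, 1)")
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(R.matrix)
    eps = rng.standard_normal((burn_in + n_frames, R.n_regions)) @ chol.T
    x = lfilter([1.0], [1.0, -phi], eps, axis=0)[burn_in:]
    return RoiTimeseries(
        values=x, roi_labels=roi_labels, subject_id=subject_id, session=session
    )


def generate_scores(
    global_metric_value: float,
    cell: tuple[str, str],
    model: ScoreModel,
    seed=None,
    rng: np.random.Generator | None = None,
) -> float:
    """One subject-session score from the linear score model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    score = (
        model.intercept_for(cell)
        + model.slope_for(cell) * global_metric_value
        + rng.normal(0.0, model.noise_sd)
    )
    if model.clamp is not None:
        score = float(np.clip(score, *model.clamp))
    return float(score)


def default_effects(n_regions: int = 30, delta: float = 0.4, n_edges: int = 5) -> tuple[EffectSpec, ...]:
    """Planted group-by-time effect: a hub star in the experimental follow-up.

    ``n_edges`` cross-module edges from hub region 0 to the last ``n_edges``
    regions gain ``delta`` correlation, concentrating the effect on a small
    set of regions so degree-centrality screens can recover it.
    """
    if n_edges >= n_regions:
        raise ValueError("n_edges must be < n_regions")
    targets = tuple((0, n_regions - 1 - m) for m in range(n_edges))
    return (EffectSpec(edges=targets, delta=delta),)


def _slopes(base: float, experimental_followup: float | None = None):
    slopes = {(g, s): base for g in GROUPS for s in SESSIONS}
    if experimental_followup is not None:
        slopes[("experimental", "followup")] = experimental_followup
    return slopes


def default_score_models(trend_delta: float = 15.0) -> tuple[ScoreModel, ...]:
    """Score models at study conditions.

    LSAS carries the planted correlation-trend change: its slope on the
    standardized average-shortest-path-length AUC rises from 5 to
    ``5 + trend_delta`` in the experimental group at follow-up.  BFNE and
    SIAS keep cell-constant slopes (no planted trend).  Cell intercepts
    reproduce the emulated study's observed scale means.
    """
    lsas_intercepts = {
        ("control", "baseline"): 68.11,
        ("control", "followup"): 68.85,
        ("experimental", "baseline"): 73.50,
        ("experimental", "followup"): 53.0,
    }
    bfne_intercepts = {
        ("control", "baseline"): 45.11,
        ("control", "followup"): 43.10,
        ("experimental", "baseline"): 45.63,
        ("experimental", "followup"): 38.62,
    }
    sias_intercepts = {
        ("control", "baseline"): 43.0,
        ("control", "followup"): 40.75,
        ("experimental", "baseline"): 47.71,
        ("experimental", "followup"): 35.48,
    }
    return (
        ScoreModel(
            name="LSAS",
            intercept=lsas_intercepts,
            slope_by_cell=_slopes(5.0, 5.0 + trend_delta),
            noise_sd=10.0,
        ),
        ScoreModel(
            name="BFNE",
            intercept=bfne_intercepts,
            slope_by_cell=_slopes(3.0),
            noise_sd=7.0,
        ),
        ScoreModel(
            name="SIAS",
            intercept=sias_intercepts,
            slope_by_cell=_slopes(4.0),
            noise_sd=12.0,
        ),
    )


def null_score_models() -> tuple[ScoreModel, ...]:
    """Score models with no slope change anywhere (trend null)."""
    return tuple(
        replace(m, slope_by_cell=_slopes(next(iter(m.slope_by_cell.values()))))
        for m in default_score_models(trend_delta=0.0)
    )


def _roi_labels(n: int) -> tuple[str, ...]:
    # bilateral-style naming: R01_L, R01_R, R02_L, ...
    return tuple(f"R{i // 2 + 1:02d}_{'LR'[i % 2]}" for i in range(n))


def _global_auc(ts: RoiTimeseries, k_grid) -> dict[str, float]:
    fc = pearson_fc(ts)
    eff, cpl = {}, {}
    for net in threshold_series(fc, k_grid):
        g = gm.global_metrics(net)
        eff[net.sparsity] = g.global_efficiency
        cpl[net.sparsity] = g.char_path_length
    return {
        "global_efficiency": gm.auc_aggregate(eff)[0],
        "char_path_length": gm.auc_aggregate(cpl)[0],
    }


def generate_cohort(
    config: CohortConfig,
    base: CorrelationStructure | None = None,
    effects: tuple[EffectSpec, ...] | None = None,
    score_models: tuple[ScoreModel, ...] | None = None,
) -> Cohort:
    """Generate the full cohort (timeseries, demographics, scores).

    ``effects`` defaults to the planted hub-star perturbation and
    ``score_models`` to the study-condition models; pass ``effects=()`` and
    :func:`null_score_models` for a fully null cohort.  Dropout is applied
    after baseline: non-completers keep only their baseline session and are
    flagged ``completer=False`` in the manifest.  Byte-reproducible from
    ``config.seed``.
    """
    if base is None:
        base = make_base_correlation(
            config.n_regions, config.n_blocks, config.rho_in, config.rho_out
        )
    if base.n_regions != config.n_regions:
        raise ValueError("base correlation size does not match config.n_regions")
    if effects is None:
        effects = default_effects(config.n_regions)
    if score_models is None:
        score_models = default_score_models()

    # per-cell correlation structures
    cell_R: dict[tuple[str, str], CorrelationStructure] = {}
    for g in GROUPS:
        for s in SESSIONS:
            R = base
            for eff in effects:
                if eff.cell == (g, s):
                    R = apply_effect(R, eff)
            cell_R[(g, s)] = R

    ss = np.random.SeedSequence(config.seed)
    demo_rng = np.random.default_rng(ss.spawn(1)[0])
    ts_seeds = iter(ss.spawn(2 * sum(config.group_sizes)))
    score_rng = np.random.default_rng(ss.spawn(1)[0])

    labels = _roi_labels(config.n_regions)
    subjects = []
    for gi, g in enumerate(GROUPS):
        size, drop = config.group_sizes[gi], config.dropout[gi]
        age_mean, age_sd, p_female = DEMOGRAPHICS[g]
        ages = demo_rng.normal(age_mean, age_sd, size)
        genders = np.where(demo_rng.random(size) < p_female, "F", "M")
        dropped = set(demo_rng.choice(size, size=drop, replace=False).tolist())
        for i in range(size):
            subjects.append(
                {
                    "subject_id": f"{'C' if g == 'control' else 'E'}{i + 1:03d}",
                    "group": g,
                    "age": float(ages[i]),
                    "gender": str(genders[i]),
                    "completer": i not in dropped,
                }
            )

    timeseries: dict[tuple[str, str], RoiTimeseries] = {}
    realized_rows = []
    for subj in subjects:
        sessions = SESSIONS if subj["completer"] else SESSIONS[:1]
        for s in sessions:
            seed = next(ts_seeds)
            ts = sample_timeseries(
                cell_R[(subj["group"], s)],
                config.n_frames,
                config.phi,
                seed,
                roi_labels=labels,
                subject_id=subj["subject_id"],
                session=s,
            )
            timeseries[(subj["subject_id"], s)] = ts
            realized_rows.append(
                {"subject_id": subj["subject_id"], "session": s, **_global_auc(ts, config.k_grid)}
            )
    realized = pd.DataFrame(realized_rows)

    # scores conditioned on the cohort-standardized realized target metric
    manifest_rows = []
    z_cache = {}
    for model in score_models:
        col = realized[model.target_metric]
        z_cache[model.target_metric] = (col - col.mean()) / col.std(ddof=0)
    for subj in subjects:
        sessions = SESSIONS if subj["completer"] else SESSIONS[:1]
        for s in sessions:
            cell = (subj["group"], s)
            row_idx = realized.index[
                (realized["subject_id"] == subj["subject_id"])
                & (realized["session"] == s)
            ][0]
            row = {
                "subject_id": subj["subject_id"],
                "group": subj["group"],
                "session": s,
                "file": f"timeseries/{subj['subject_id']}_{s}.tsv",
                "age": round(subj["age"], 2),
                "gender": subj["gender"],
            }
            for model in score_models:
                z = float(z_cache[model.target_metric].iloc[row_idx])
                row[model.name] = round(
                    generate_scores(z, cell, model, rng=score_rng), 2
                )
            for scale, cells in ANCILLARY_SCALES.items():
                mean, sd = cells[cell]
                row[scale] = round(float(score_rng.normal(mean, sd)), 2)
            row["completer"] = subj["completer"]
            manifest_rows.append(row)

    manifest = pd.DataFrame(manifest_rows)[
        [
            "subject_id", "group", "session", "file", "age", "gender",
            "LSAS", "BFNE", "SIAS", "RSES", "HADS_A", "HADS_D", "completer",
        ]
    ]
    return Cohort(
        manifest=manifest,
        timeseries=timeseries,
        config=config,
        base=base,
        realized_metrics=realized,
    )
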