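"""CSV input/output, configuration and end-to-end pipeline orchestration.

Two CSV interfaces define the pipeline's inputs:

* the wide survey file — one row per user with paired 13-item activation
  responses (``pam1_b..pam13_b``, ``pam1_f..pam13_f``), paired
  health-status items (``eq_<dimension>_b/f``), utilization categories
  (``gp_b`` ...) and demographics;
* the long engagement file — one row per (user, day) with the seven daily
  activity counts; days with no row count as zero activity.

Missing survey values are empty cells; sentinel tokens are rejected rather
than silently coerced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pam as pam_mod
from .cohort import build_tables, kruskal_wallis, paired_t
from .eq5d import DIMENSIONS, load_value_set, toy_value_set, utility
from .mixture import (
    MEASURES,
    EngagementSeries,
    MarkovChainMixture,
    assign_clusters,
    binarize_frame,
    select_k_elbow,
    summarize_clusters,
)
from .synthetic import (
    VISIT_CATEGORIES,
    GeneratorConfig,
    SyntheticCohort,
    default_scenario,
    generate_cohort,
)

__all__ = [
    "ValidationError",
    "PipelineError",
    "RunConfig",
    "read_survey",
    "read_engagement",
    "write_cohort",
    "load_run_config",
    "run_pipeline",
]

_SENTINELS = {"NA", "N/A", "null", "NULL", "missing", "-"}


class ValidationError(ValueError):
    pass


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclasses.dataclass
class RunConfig:
    """Settings for an end-to-end run.

    Either point ``survey_path``/``engagement_path`` at existing CSVs or set
    ``generate`` true to synthesize a cohort first.  ``n_components=None``
    triggers elbow selection over ``candidate_K``.
    """

    out_dir: str
    survey_path: str | None = None
    engagement_path: str | None = None
    generate: bool = False
    n_users: int = 200
    horizon_days: int = 91
    n_components: int | None = 4
    candidate_K: tuple = (1, 2, 3, 4, 5, 6, 7, 8)
    tol: float = 1e-6
    max_iter: int = 300
    n_init: int = 5
    seed: int = 0
    pam_conversion_path: str | None = None
    value_set_path: str | None = None
    meaningful_threshold: float = 5.0

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.candidate_K is not None:
            cfg.candidate_K = tuple(int(k) for k in cfg.candidate_K)
        return cfg


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_mapping(data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_survey(path) -> pd.DataFrame:
    """Read and validate the wide survey CSV.

    Checks for duplicate user ids, out-of-range activation items (1..4),
    health-status items (1..5), unknown utilization category tokens and
    sentinel missing-value tokens; empty cells are the only valid encoding
    of missingness.  Returns the validated frame; per-field missingness is
    attached as ``frame.attrs['missingness']``.
    """
    # empty cells are the only missing-value encoding; tokens like "N/A"
    # must survive parsing as strings so they can be rejected
    df = pd.read_csv(path, dtype={"user_id": str}, keep_default_na=False, na_values=[""])
    if "user_id" not in df.columns:
        raise ValidationError("survey file must have a user_id column")
    dup = df["user_id"][df["user_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate user_id {dup.iloc[0]!r}")
    for col in df.columns:
        if df[col].dtype == object:
            bad = df[col].dropna().isin(_SENTINELS)
            if bad.any():
                raise ValidationError(
                    f"column {col}: sentinel missing token "
                    f"{df[col].dropna()[bad].iloc[0]!r}; use empty cells"
                )
    for i in range(1, 14):
        for suffix in ("b", "f"):
            col = f"pam{i}_{suffix}"
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[(vals < 1) | (vals > 4)]
                if len(bad):
                    raise ValidationError(
                        f"column {col}: value {bad.iloc[0]} outside the 1..4 range"
                    )
    for dim in DIMENSIONS:
        for suffix in ("b", "f"):
            col = f"eq_{dim}_{suffix}"
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[(vals < 1) | (vals > 5)]
                if len(bad):
                    raise ValidationError(
                        f"column {col}: value {bad.iloc[0]} outside the 1..5 range"
                    )
    for svc in ("gp", "nurse", "outpatient", "ae"):
        for suffix in ("b", "f"):
            col = f"{svc}_{suffix}"
            if col in df.columns:
                vals = df[col].dropna()
                bad = vals[~vals.isin(VISIT_CATEGORIES)]
                if len(bad):
                    raise ValidationError(
                        f"column {col}: unknown category token {bad.iloc[0]!r}"
                    )
    df.attrs["missingness"] = {c: int(df[c].isna().sum()) for c in df.columns}
    return df


def read_engagement(path, horizon_days: int = 91) -> list:
    """Read the long engagement CSV into per-user day-indexed series.

    Absent days are zero-filled up to the horizon.  Negative counts or day
    indices outside 1..horizon are validation errors.
    """
    df = pd.read_csv(path, dtype={"user_id": str})
    if df.empty:
        import warnings

        warnings.warn("engagement file is empty", stacklevel=2)
        return []
    need = {"user_id", "day_index", *MEASURES}
    missing = need - set(df.columns)
    if missing:
        raise ValidationError(f"engagement file missing columns {sorted(missing)}")
    if (df["day_index"] < 1).any() or (df["day_index"] > horizon_days).any():
        bad = df.loc[(df["day_index"] < 1) | (df["day_index"] > horizon_days)].iloc[0]
        raise ValidationError(
            f"user {bad['user_id']!r}: day index {int(bad['day_index'])} "
            f"outside 1..{horizon_days}"
        )
    for m in MEASURES:
        if (df[m] < 0).any():
            bad = df.loc[df[m] < 0].iloc[0]
            raise ValidationError(
                f"user {bad['user_id']!r}: negative {m} count on day "
                f"{int(bad['day_index'])}"
            )
    series = []
    full_index = pd.RangeIndex(1, horizon_days + 1, name="day_index")
    for uid, grp in df.groupby("user_id", sort=True):
        counts = (
            grp.set_index("day_index")[list(MEASURES)]
            .groupby(level=0)
            .sum()
            .reindex(full_index, fill_value=0)
            .astype(int)
        )
        series.append(EngagementSeries(user_id=uid, counts=counts, horizon_days=horizon_days))
    return series


def write_cohort(cohort: SyntheticCohort, out_dir) -> dict:
    """Write a synthetic cohort to the standard CSV interfaces.

    Produces survey.csv (wide), engagement.csv (long, engaged days only)
    and truth.csv (user_id, true_component).  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": out / "survey.csv",
        "engagement": out / "engagement.csv",
        "truth": out / "truth.csv",
    }
    cohort.surveys.to_csv(paths["survey"], index=False)
    cohort.engagement.to_csv(paths["engagement"], index=False)
    pd.DataFrame(
        {"user_id": cohort.user_ids, "true_component": cohort.true_component}
    ).to_csv(paths["truth"], index=False)
    return paths


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run generate -> cluster -> score -> analyze end to end.

    Every output file is rewritten from scratch; with a fixed seed the run
    is deterministic.  Returns a dict of artifact paths.  Stage failures
    raise :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"seed: {config.seed}",
        f"tol: {config.tol}",
        f"n_init: {config.n_init}",
    ]
    artifacts = {}

    if config.generate:
        gen = _stage("generate")(lambda: generate_cohort(
            default_scenario(n_users=config.n_users, seed=config.seed)
        ))
        cohort = gen()
        paths = write_cohort(cohort, out_dir)
        artifacts.update({f"input_{k}": str(v) for k, v in paths.items()})
        survey_path, engagement_path = paths["survey"], paths["engagement"]
    else:
        if config.engagement_path is None or config.survey_path is None:
            raise PipelineError(
                "stage 'configure' failed: survey_path and engagement_path are "
                "required when generate is false"
            )
        survey_path, engagement_path = config.survey_path, config.engagement_path

    surveys = _stage("read_survey")(read_survey)(survey_path)
    series = _stage("read_engagement")(read_engagement)(
        engagement_path, config.horizon_days
    )
    user_ids, X = _stage("binarize")(binarize_frame)(series)

    @_stage("cluster")
    def _cluster():
        kwargs = dict(
            tol=config.tol,
            max_iter=config.max_iter,
            n_init=config.n_init,
            random_state=config.seed,
        )
        if config.n_components is None:
            sel = select_k_elbow(X, list(config.candidate_K), **kwargs)
            log_lines.append(f"elbow candidates: {sel.candidate_K}")
            log_lines.append(f"elbow logliks: {[round(v, 2) for v in sel.logliks]}")
            K = sel.chosen_K
            pd.DataFrame(
                {"K": sel.candidate_K, "loglik": sel.logliks}
            ).to_csv(out_dir / "elbow.csv", index=False)
            artifacts["elbow"] = str(out_dir / "elbow.csv")
        else:
            K = config.n_components
        log_lines.append(f"chosen K: {K}")
        est = MarkovChainMixture(n_components=K, **kwargs)
        est.fit(X)
        return est

    est = _cluster()
    assignments = assign_clusters(est.responsibilities_, user_ids)
    assignments.to_csv(out_dir / "assignments.csv", index=False)
    artifacts["assignments"] = str(out_dir / "assignments.csv")

    with open(out_dir / "model_params.txt", "w") as fh:
        fh.write(f"n_components: {len(est.weights_)}\n")
        fh.write(f"weights: {np.array2string(est.weights_, precision=6)}\n")
        fh.write(f"emissions: {np.array2string(est.emissions_, precision=6)}\n")
        for k, A in enumerate(est.transitions_):
            fh.write(f"transition[{k}]:\n{np.array2string(A, precision=6)}\n")
    artifacts["model_params"] = str(out_dir / "model_params.txt")

    summary = summarize_clusters(est.labels_, X, n_clusters=len(est.weights_))
    summary.to_csv(out_dir / "cluster_summary.csv", index=False)
    artifacts["cluster_summary"] = str(out_dir / "cluster_summary.csv")

    @_stage("score")
    def _score():
        conversion = (
            pam_mod.load_conversion_table(config.pam_conversion_path)
            if config.pam_conversion_path
            else None
        )
        vs = (
            load_value_set(config.value_set_path)
            if config.value_set_path
            else toy_value_set()
        )
        pam_cols_b = [f"pam{i}_b" for i in range(1, 14)]
        pam_cols_f = [f"pam{i}_f" for i in range(1, 14)]
        rows = []
        n_missing = 0
        for _, r in surveys.iterrows():
            try:
                sb = pam_mod.score(r[pam_cols_b], conversion)
                sf = pam_mod.score(r[pam_cols_f], conversion)
            except pam_mod.ScoringError:
                n_missing += 1
                continue
            row = {
                "user_id": r["user_id"],
                "pam_baseline": sb.scaled,
                "pam_followup": sf.scaled,
                "pam_level_baseline": sb.level,
                "pam_level_followup": sf.level,
                "ceiling": sb.excluded_ceiling or sf.excluded_ceiling,
            }
            eq_b = [r.get(f"eq_{d}_b") for d in DIMENSIONS]
            eq_f = [r.get(f"eq_{d}_f") for d in DIMENSIONS]
            if all(pd.notna(v) for v in eq_b):
                row["eq5d_baseline"] = utility(eq_b, vs)
            if all(pd.notna(v) for v in eq_f):
                row["eq5d_followup"] = utility(eq_f, vs)
            rows.append(row)
        log_lines.append(f"unscorable activation responses: {n_missing}")
        return pd.DataFrame(rows)

    scores = _score()
    scores.to_csv(out_dir / "scores.csv", index=False)
    artifacts["scores"] = str(out_dir / "scores.csv")

    @_stage("analyze")
    def _analyze():
        merged = scores.merge(assignments[["user_id", "cluster"]], on="user_id")
        kept = merged[~merged["ceiling"]]
        n_excluded = int(merged["ceiling"].sum())
        log_lines.append(f"ceiling exclusions: {n_excluded}")
        lines = []
        if len(kept) >= 2:
            res = paired_t(kept["pam_baseline"], kept["pam_followup"])
            lines.append(
                f"activation change: mean={res['mean_diff']:.2f} "
                f"sd={res['sd_diff']:.2f} t={res['t']:.3f} p={res['p_value']:.4g} "
                f"n={res['n']}"
            )
            groups = [
                g["pam_baseline"].to_numpy()
                for _, g in kept.groupby("cluster")
                if len(g)
            ]
            if len(groups) >= 2:
                kw = kruskal_wallis(*groups)
                lines.append(
                    f"baseline activation across clusters: H={kw['statistic']:.3f} "
                    f"p={kw['p_value']:.4g}"
                )
            eq = kept.dropna(subset=["eq5d_baseline", "eq5d_followup"]) \
                if {"eq5d_baseline", "eq5d_followup"}.issubset(kept.columns) else None
            if eq is not None and len(eq) >= 2:
                res = paired_t(eq["eq5d_baseline"], eq["eq5d_followup"])
                lines.append(
                    f"health-status change: mean={res['mean_diff']:.3f} "
                    f"p={res['p_value']:.4g} n={res['n']}"
                )
        tables = build_tables(surveys, assignments, X)
        for name, df in tables.items():
            df.to_csv(out_dir / f"table_{name}.csv", index=False)
            artifacts[f"table_{name}"] = str(out_dir / f"table_{name}.csv")
        return lines

    log_lines.extend(_analyze())
    log_lines.append(f"missingness: {surveys.attrs.get('missingness', {})}")
    with open(out_dir / "analysis_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    artifacts["log"] = str(out_dir / "analysis_log.txt")
    return artifacts
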