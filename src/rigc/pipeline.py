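"""End-to-end pipeline: simulate (or load) -> validate -> score -> analyze.

A run is fully determined by a :class:`RunConfig` (serializable to YAML or
JSON): the config plus its seed reproduces every output byte of the
deterministic stages and the distribution of the stochastic ones.  Each run
directory receives a manifest with the config hash, seeds, CTM-table
provenance, row counts and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import plots
from .cohort import (
    Cohort,
    BiasProfile,
    CovariateEffects,
    LifespanCurve,
    read_cohort,
    sample_cohort,
    write_cohort,
)
from .ctm import read_table
from .scoring import score_cohort
from .tables import builtin_table
from .tasks import TASK_ORDER, TASKS
from .trajectory import (
    age_window_correlation,
    fit_glm,
    fit_trajectory,
    reliability_alpha,
    speed_accuracy_path,
)

__all__ = ["RunConfig", "PipelineError", "validate_cohort", "run_pipeline", "load_tables"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage that raised it."""


@dataclass
class RunConfig:
    n: int = 200
    seed: int = 1
    cohort_path: str | None = None  # load instead of simulate when set
    tables: str = "builtin"  # "builtin" or a directory of <ref>.tsv files
    spline_df: float = 7
    bootstrap_reps: int = 200
    curve: dict = field(default_factory=dict)  # LifespanCurve overrides
    effects: dict = field(default_factory=dict)  # CovariateEffects overrides
    biases: dict = field(default_factory=dict)  # BiasProfile strength overrides
    make_plots: bool = True
    version: str = "rigc-0.1.0"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_tables(config: RunConfig) -> dict:
    """Resolve the CTM table for each task from the config."""
    tables = {}
    for tid in TASK_ORDER:
        ref = TASKS[tid].table_ref
        if config.tables == "builtin":
            tables[tid] = builtin_table(ref)
        else:
            path = Path(config.tables) / f"{ref}.tsv"
            if not path.exists():
                raise FileNotFoundError(f"CTM table {ref!r} not found at {path}")
            tables[tid] = read_table(path)
    return tables


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------

_SEXES = {"male", "female", ""}
_FIELDS = {"humanities", "science", "other", ""}


def _check_row(row) -> list[str]:
    errs = []
    age = row.get("age")
    try:
        if not 4 <= float(age) <= 91:
            errs.append(f"age: value {age} outside [4, 91]")
    except (TypeError, ValueError):
        errs.append(f"age: not a number ({age!r})")
    if str(row.get("sex", "")) not in _SEXES:
        errs.append(f"sex: invalid value {row.get('sex')!r}")
    if str(row.get("field", "") or "") not in _FIELDS:
        errs.append(f"field: invalid value {row.get('field')!r}")
    for col, lo, hi in (("education", 1, 7), ("paranormal_belief", 1, 6)):
        v = row.get(col)
        if v is not None and not (isinstance(v, float) and np.isnan(v)):
            try:
                if not lo <= int(v) <= hi:
                    errs.append(f"{col}: value {v} outside [{lo}, {hi}]")
            except (TypeError, ValueError):
                errs.append(f"{col}: not an integer ({v!r})")
    for tid in TASK_ORDER:
        spec = TASKS[tid]
        col = f"{tid}_response"
        resp = row.get(col)
        if resp is None or (isinstance(resp, float) and np.isnan(resp)) or resp == "":
            continue
        resp = str(resp)
        if len(resp) != spec.length:
            errs.append(f"{col}: length {len(resp)} != {spec.length}")
        for i, ch in enumerate(resp):
            if not ch.isdigit() or int(ch) >= spec.alphabet_size:
                errs.append(
                    f"{col}: symbol {ch!r} at position {i} outside alphabet "
                    f"of size {spec.alphabet_size}"
                )
                break
        ct = row.get(f"{tid}_ct_seconds")
        if ct is not None and not (isinstance(ct, float) and np.isnan(ct)):
            if float(ct) <= 0:
                errs.append(f"{tid}_ct_seconds: non-positive value {ct}")
    return errs


def validate_cohort(path) -> tuple[Cohort, pd.DataFrame]:
    """Load and validate a cohort CSV.

    Returns the cohort restricted to valid rows plus a per-row error report
    (columns: participant_id, row, error).  Global problems — unreadable or
    empty file, duplicated participant ids — raise immediately.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cohort = read_cohort(path)
    if cohort.table.empty:
        raise ValueError(f"{path}: empty cohort file")
    if "participant_id" not in cohort.table.columns:
        raise ValueError(f"{path}: missing participant_id column")
    dup = cohort.table["participant_id"][cohort.table["participant_id"].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate participant_id values: {sorted(set(dup))[:5]}")
    report_rows = []
    bad_idx = []
    for idx, row in cohort.table.iterrows():
        errs = _check_row(row)
        if errs:
            bad_idx.append(idx)
            for e in errs:
                report_rows.append(
                    {"participant_id": row["participant_id"], "row": int(idx), "error": e}
                )
    report = pd.DataFrame(report_rows, columns=["participant_id", "row", "error"])
    valid = Cohort(cohort.table.drop(index=bad_idx).reset_index(drop=True), cohort.config)
    return valid, report


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapped

    return deco


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the configured run; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"config": asdict(config), "config_hash": config.config_hash()}

    t0 = time.perf_counter()
    tables = _stage("tables")(load_tables)(config)
    manifest["tables"] = {tid: t.source for tid, t in tables.items()}
    timings["tables"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    if config.cohort_path:
        cohort, report = _stage("load")(validate_cohort)(config.cohort_path)
        if len(report):
            report.to_csv(outdir / "validation_errors.csv", index=False)
    else:
        cohort = _stage("simulate")(sample_cohort)(
            config.n,
            curve=LifespanCurve(**config.curve),
            effects=CovariateEffects(**config.effects),
            biases=BiasProfile(**config.biases),
            seed=config.seed,
        )
    write_cohort(cohort, outdir / "cohort.csv")
    manifest["n_participants"] = len(cohort.table)
    timings["cohort"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    scores = _stage("score")(score_cohort)(cohort.table, tables)
    scores.to_csv(outdir / "scores.csv", index=False)
    manifest["n_scored"] = int(scores["n_tasks"].gt(0).sum())
    timings["score"] = round(time.perf_counter() - t0, 3)

    t0 = time.perf_counter()
    analyze = _stage("analyze")
    variables = [f"z_{t}" for t in TASK_ORDER] + [f"ct_{t}" for t in TASK_ORDER]
    variables += ["mean_z", "total_ct"]
    fits = {}
    traj_rows = []
    for var in variables:
        fit = analyze(fit_trajectory)(
            scores, var, config.spline_df, config.bootstrap_reps, seed=config.seed
        )
        fits[var] = fit
        for a, f, lo, hi in zip(fit.age_grid, fit.fitted, fit.ci_lower, fit.ci_upper):
            traj_rows.append(
                {"variable": var, "age": a, "fit": f, "ci_lower": lo, "ci_upper": hi}
            )
    pd.DataFrame(traj_rows).to_csv(outdir / "trajectories.csv", index=False)
    manifest["peak_age_mean_z"] = fits["mean_z"].peak_age

    glm_rows = []
    glm_skipped = {}
    for dv in [f"z_{t}" for t in TASK_ORDER] + [f"ct_{t}" for t in TASK_ORDER] + [
        "mean_z",
        "total_ct",
    ]:
        try:
            res = fit_glm(scores, dv)
        except ValueError as e:  # e.g. too few complete cases at small n
            glm_skipped[dv] = str(e)
            continue
        for t in res.terms:
            glm_rows.append(
                {
                    "dv": dv,
                    "term": t.name,
                    "estimate": t.coefficient,
                    "p": t.p_value,
                    "partial_eta_sq": t.partial_eta_sq,
                    "holm_p": res.holm_adjusted[t.name],
                    "n": res.n_used,
                }
            )
    pd.DataFrame(
        glm_rows,
        columns=["dv", "term", "estimate", "p", "partial_eta_sq", "holm_p", "n"],
    ).to_csv(outdir / "glm.csv", index=False)
    if glm_skipped:
        manifest["glm_skipped"] = glm_skipped

    rel_rows = []
    for name, cols in (
        ("completion_times", [f"ct_{t}" for t in TASK_ORDER]),
        ("complexities", [f"z_{t}" for t in TASK_ORDER]),
    ):
        rel = analyze(reliability_alpha)(scores, cols)
        rel_rows.append(
            {"set": name, "alpha": rel.alpha, "n_complete_cases": rel.n_complete_cases}
        )
    pd.DataFrame(rel_rows).to_csv(outdir / "reliability.csv", index=False)

    try:
        r, p = age_window_correlation(scores, ("total_ct", "mean_z"), (25, 60))
        manifest["ct_z_corr_25_60"] = {"r": r, "p": p}
    except ValueError:
        manifest["ct_z_corr_25_60"] = None
    timings["analyze"] = round(time.perf_counter() - t0, 3)

    if config.make_plots:
        t0 = time.perf_counter()
        analyze(plots.plot_task_trajectories)(fits, outdir / "fig_tasks.png")
        analyze(plots.plot_mean_trajectories)(
            fits["total_ct"], fits["mean_z"], outdir / "fig_mean.png"
        )
        path_df = speed_accuracy_path(fits["total_ct"], fits["mean_z"])
        analyze(plots.plot_speed_accuracy)(path_df, scores, outdir / "fig_speed_accuracy.png")
        timings["plots"] = round(time.perf_counter() - t0, 3)

    manifest["timings_s"] = timings
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir
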