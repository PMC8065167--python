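"""End-to-end pipeline: simulate → morphometrics → thickness → statistics.

Every artifact (cohort CSV, per-eye metrics CSV, statistics tables,
exclusion log) is a deterministic function of the run configuration and
seed; logging goes to stderr, results never do.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SECTOR_NAMES
from .io import RunConfig, load_cohort_spec
from .morphometrics import compute_bmo_morphometrics, crossval_tilt
from .stats import fit_lmm, group_comparison
from .synthetic import default_cohort_spec, simulate_cohort_geometry
from .thickness import compute_mrw, compute_pct, compute_rnfl_thickness, quality_filter

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("onhmorph")

MORPH_OUTCOMES = ("ovality_index", "tilt_deg", "rotation_deg", "bmo_area_mm2")
THICKNESS_METRICS = ("mrw", "rnfl", "pct")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and eye."""


def _metric_columns(prefix: str, summary) -> dict[str, float]:
    d = {f"{prefix}_global": summary.global_um}
    d.update({f"{prefix}_{s}": summary[s] for s in SECTOR_NAMES})
    return d


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic-cohort analysis and write its artifacts.

    Output directory contents: ``cohort.csv`` (one row per included eye
    with covariates and measured metrics), ``exclusions.csv`` (one row per
    excluded eye with the reason), ``summary_groups.csv`` (mean (95% CI)
    per myopia group per outcome with overall/pairwise p-values), and
    ``assoc_al.csv`` (mixed-model slopes of each outcome on axial length,
    univariate and age+VF-MD adjusted, with Edwards semi-partial R²).
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = (
        load_cohort_spec(config.cohort_spec)
        if config.cohort_spec
        else default_cohort_spec()
    )
    logger.info("pipeline start: seed=%d out=%s", config.seed, out)

    rows, exclusions = [], []
    stage = "simulate"
    try:
        for row, scans, profile, truth in simulate_cohort_geometry(spec, seed=config.seed):
            eye_id = str(row["eye_id"])
            include, reason = quality_filter(
                scans.quality_score_db, config.quality_threshold_db
            )
            if not include:
                exclusions.append({"eye_id": eye_id, "reason": reason})
                continue
            stage = "morphometrics"
            rec = {
                "eye_id": eye_id,
                "patient_id": row["patient_id"],
                "laterality": row["laterality"],
                "myopia_group": row["myopia_group"],
                "al_mm": row["al_mm"],
                "age_yr": row["age_yr"],
                "vf_md_db": row["vf_md_db"],
            }
            try:
                morph = compute_bmo_morphometrics(scans)
                rec.update(
                    ovality_index=morph.ovality_index,
                    tilt_deg=morph.tilt_deg,
                    rotation_deg=morph.rotation_deg,
                    bmo_area_mm2=morph.bmo_area_mm2,
                )
                if config.crossval_ring_um:
                    try:
                        rec["crossval_tilt_deg"] = crossval_tilt(
                            scans, config.crossval_ring_um
                        )
                    except ValueError:
                        rec["crossval_tilt_deg"] = np.nan
                stage = "thickness"
                _, mrw = compute_mrw(scans)
                rnfl = compute_rnfl_thickness(profile)
                pct = compute_pct(profile, mode=config.pct_mode)
                rec.update(_metric_columns("mrw", mrw))
                rec.update(_metric_columns("rnfl", rnfl))
                rec.update(_metric_columns("pct", pct))
            except ValueError as err:
                exclusions.append(
                    {"eye_id": eye_id, "reason": f"{stage} failure: {err}"}
                )
                continue
            rows.append(rec)
    except Exception as err:
        raise PipelineError(f"stage {stage!r} failed: {err}") from err

    cohort = pd.DataFrame(rows)
    cohort.to_csv(out / "cohort.csv", index=False)
    pd.DataFrame(exclusions, columns=["eye_id", "reason"]).to_csv(
        out / "exclusions.csv", index=False
    )
    logger.info(
        "simulate+measure done: %d eyes included, %d excluded (%.1fs)",
        len(cohort),
        len(exclusions),
        time.time() - t0,
    )

    stage = "statistics"
    if cohort.empty:
        raise PipelineError(
            "stage 'statistics' failed: empty cohort (all eyes excluded)"
        )
    try:
        _write_stats(cohort, out)
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage 'statistics' failed: {err}") from err
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return out


def _write_stats(cohort: pd.DataFrame, out: Path) -> None:
    outcomes = [
        c
        for c in list(MORPH_OUTCOMES)
        + [f"{m}_global" for m in THICKNESS_METRICS]
        + [f"{m}_{s}" for m in THICKNESS_METRICS for s in SECTOR_NAMES]
        if c in cohort.columns
    ]
    n_groups = cohort["myopia_group"].nunique()
    summary_rows, assoc_rows = [], []
    for outcome in outcomes:
        # per-group mean (95% CI) from intercept-only mixed models
        srow: dict[str, object] = {"outcome": outcome}
        for g, sub in cohort.groupby("myopia_group"):
            if sub["patient_id"].nunique() < 2:
                srow[g] = f"{sub[outcome].mean():.2f} (n<2 patients)"
                continue
            res = fit_lmm(sub, outcome, [])
            lo, hi = res.conf_int.iloc[0]
            srow[g] = f"{res.params.iloc[0]:.2f} ({lo:.2f}, {hi:.2f})"
        if n_groups >= 2:
            cmp_ = group_comparison(cohort, outcome)
            srow["overall_p"] = cmp_.overall_p
            for (a, b), p in cmp_.pairwise_p.items():
                srow[f"p_{a}_vs_{b}"] = p
        summary_rows.append(srow)

        for label, adjust in (("univariate", []), ("age_vfmd_adjusted", ["age_yr", "vf_md_db"])):
            res = fit_lmm(cohort, outcome, ["al_mm"] + adjust)
            lo, hi = res.conf_int.loc["al_mm"]
            assoc_rows.append(
                {
                    "outcome": outcome,
                    "model": label,
                    "estimate_per_mm": res.params["al_mm"],
                    "ci_lower": lo,
                    "ci_upper": hi,
                    "semi_partial_r2": res.ftests.loc["al_mm", "r2"],
                    "pvalue": res.ftests.loc["al_mm", "pvalue"],
                    "n_patients": res.n_patients,
                    "n_eyes": res.n_eyes,
                }
            )
    pd.DataFrame(summary_rows).to_csv(out / "summary_groups.csv", index=False)
    pd.DataFrame(assoc_rows).to_csv(out / "assoc_al.csv", index=False)
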