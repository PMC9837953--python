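"""Long-format CSV readers/writers and result serialization.

The on-disk layout is one row per episode plus exactly one ``final_gap`` row
per subject:

====================  =======================================================
column                meaning
====================  =======================================================
subject_id            subject identifier
record_type           ``episode`` or ``final_gap``
episode_index         1-based episode number (empty for final_gap rows)
between_gap           exacerbation-free time preceding the episode / the
                      censored final exacerbation-free time (days)
within_gap            episode duration in days (episode rows only)
severity              0/1 (episode rows only)
censored              0/1; within-gap censoring on episode rows, always 1 on
                      final_gap rows
<covariates>          one column per baseline covariate
====================  =======================================================

Times are accepted in days, weeks or years (``config.time_unit``) and stored
internally in days.  Subjects with missing covariate values are dropped with
a logged count; structural problems (non-positive gaps, duplicate final_gap
rows, non-binary severity) are hard errors naming the offending rows.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TIME_UNITS, ModelConfig
from .model_core import MIN_GAP, ExacerbationEpisode, SubjectHistory

__all__ = ["read_dataset", "write_dataset", "dataset_to_frame",
           "frame_to_dataset", "write_results", "write_predictions"]

log = logging.getLogger(__name__)

_CORE_COLUMNS = ["subject_id", "record_type", "episode_index", "between_gap",
                 "within_gap", "severity", "censored"]


def dataset_to_frame(dataset, covariate_names=None) -> pd.DataFrame:
    """Long-format frame from a list of :class:`SubjectHistory`."""
    if covariate_names is None:
        covariate_names = sorted({k for s in dataset for k in s.covariates})
    rows = []
    for s in dataset:
        cov = {k: s.covariates.get(k, np.nan) for k in covariate_names}
        prev = 0.0
        for j, ep in enumerate(s.episodes, start=1):
            rows.append({
                "subject_id": s.subject_id, "record_type": "episode",
                "episode_index": j, "between_gap": ep.onset_time - prev,
                "within_gap": ep.duration, "severity": ep.severity,
                "censored": ep.within_censored, **cov,
            })
            prev = ep.termination_time
        rows.append({
            "subject_id": s.subject_id, "record_type": "final_gap",
            "episode_index": np.nan, "between_gap": s.final_gap,
            "within_gap": np.nan, "severity": np.nan,
            "censored": s.final_gap_censored, **cov,
        })
    return pd.DataFrame(rows, columns=_CORE_COLUMNS + list(covariate_names))


def write_dataset(dataset, path, covariate_names=None) -> None:
    dataset_to_frame(dataset, covariate_names).to_csv(path, index=False)


def frame_to_dataset(df: pd.DataFrame, config: ModelConfig | None = None,
                     covariate_names=None):
    """Validated list of :class:`SubjectHistory` from a long-format frame."""
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if covariate_names is None:
        covariate_names = (config.baseline_covariate_names() if config is not None
                           else [c for c in df.columns if c not in _CORE_COLUMNS])
    absent = [c for c in covariate_names if c not in df.columns]
    if absent:
        raise ValueError(f"missing covariate columns: {absent}")
    scale = TIME_UNITS[config.time_unit] if config is not None else 1.0

    problems = []
    subjects = []
    n_dropped = 0
    for sid, g in df.groupby("subject_id", sort=False):
        fin = g[g.record_type == "final_gap"]
        eps = g[g.record_type == "episode"].copy()
        rows = g.index + 2  # 1-based with header, for error messages
        if len(fin) != 1:
            problems.append(f"subject {sid}: {len(fin)} final_gap rows (need 1)")
            continue
        unknown = g[~g.record_type.isin(["episode", "final_gap"])]
        if len(unknown):
            problems.append(f"subject {sid}: unknown record_type at rows "
                            f"{list(unknown.index + 2)}")
            continue
        idx = eps.episode_index.to_numpy()
        if len(eps) and (np.any(np.sort(idx) != np.arange(1, len(eps) + 1))):
            problems.append(f"subject {sid}: episode indices not contiguous from 1")
            continue
        eps = eps.sort_values("episode_index")
        bad = eps[(eps.between_gap <= MIN_GAP) | (eps.within_gap <= MIN_GAP)]
        if len(bad):
            problems.append(f"subject {sid}: non-positive gap at rows "
                            f"{list(bad.index + 2)}")
            continue
        if len(eps) and not eps.severity.isin([0, 1]).all():
            problems.append(f"subject {sid}: non-binary severity")
            continue
        if float(fin.between_gap.iloc[0]) < 0:
            problems.append(f"subject {sid}: negative final gap at row "
                            f"{fin.index[0] + 2}")
            continue
        cov = {c: fin[c].iloc[0] for c in covariate_names}
        if any(pd.isna(v) for v in cov.values()):
            n_dropped += 1
            continue
        episodes, t = [], 0.0
        for _, r in eps.iterrows():
            onset = t + float(r.between_gap) * scale
            term = onset + float(r.within_gap) * scale
            episodes.append(ExacerbationEpisode(onset, term, int(r.severity),
                                                int(r.censored)))
            t = term
        final_gap = float(fin.between_gap.iloc[0]) * scale
        subjects.append(SubjectHistory(
            subject_id=sid, follow_up=t + final_gap, episodes=episodes,
            final_gap=final_gap, final_gap_censored=int(fin.censored.iloc[0]),
            covariates={k: float(v) for k, v in cov.items()},
        ))
    if problems:
        raise ValueError("invalid long-format data:\n  " + "\n  ".join(problems))
    if n_dropped:
        log.warning("dropped %d subject(s) with missing covariate values "
                    "(complete-case analysis)", n_dropped)
    if not subjects:
        raise ValueError("no valid subjects in file")
    for s in subjects:
        s.validate()
    return subjects


def read_dataset(path, config: ModelConfig | None = None, covariate_names=None):
    """Read and validate a long-format CSV."""
    return frame_to_dataset(pd.read_csv(path), config, covariate_names)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(fit_result, out_dir, seed=None, extra_log=None) -> None:
    """Write estimates.csv (coefficient tables), random_effects.csv,
    fit.json (loglik/AIC/convergence) and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tabs = []
    for name, tab in fit_result.report.items():
        t = tab.copy()
        t.insert(0, "submodel", name)
        t = t.rename(columns={"AFT factor": "exp_coef", "OR": "exp_coef"})
        tabs.append(t)
    pd.concat(tabs, ignore_index=True).to_csv(out / "estimates.csv", index=False)
    if fit_result.re_report is not None:
        fit_result.re_report.to_csv(out / "random_effects.csv", index=False)
    summary = {
        "loglik": fit_result.loglik,
        "aic": fit_result.aic,
        "n_free_parameters": fit_result.n_free,
        "n_subjects": fit_result.n_subjects,
        "convergence": fit_result.convergence,
        "config": fit_result.config.to_dict(),
    }
    with open(out / "fit.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    lines = [
        f"python {platform.python_version()}, numpy {np.__version__}, "
        f"pandas {pd.__version__}",
        f"seed: {seed}",
        f"config: {fit_result.config.to_dict()}",
        f"converged: {fit_result.converged}",
    ]
    if extra_log:
        lines.extend(str(x) for x in extra_log)
    (out / "run.log").write_text("\n".join(lines) + "\n")


def write_predictions(predictions: pd.DataFrame, out_dir,
                      curves: dict | None = None) -> None:
    """Write per-subject predictions and optional tidy CDF-curve frames."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    predictions.to_csv(out / "predictions.csv")
    for name, frame in (curves or {}).items():
        frame.to_csv(out / f"curve_{name}.csv", index=False)
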