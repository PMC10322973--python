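"""Trial-level reaction times -> per-subject indicators and reliability.

Each subject performs verbal and visuospatial working-memory (filled-delay)
tasks and a number-Stroop distractor task, in two scanning sessions.  The
verbal/spatial tasks contribute 24 trials per session (48 total); the Stroop
task runs alongside both working-memory tasks, so it contributes 48 trials
per session (96 total).  Session means feed a test-retest intraclass
correlation; the grand mean per task becomes the subject's RT indicator for
the latent behavioral construct.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TASKS",
    "TRIALS_PER_SESSION",
    "TrialTableError",
    "validate_trials",
    "session_means",
    "subject_indicator",
    "icc_test_retest",
    "IccResult",
]

TASKS = ("verbal", "spatial", "stroop")
SESSIONS = (1, 2)
#: complete-block sizes per task and session
TRIALS_PER_SESSION = {"verbal": 24, "spatial": 24, "stroop": 48}

REQUIRED_COLUMNS = ["subject_id", "task", "session", "trial_index", "rt"]


class TrialTableError(ValueError):
    """Raised for malformed or incomplete trial tables."""


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Check a trial table for completeness; returns the validated frame.

    Every subject x task x session cell must hold exactly the full trial
    block (24 for the working-memory tasks, 48 for Stroop) with positive RTs.
    """
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing_cols:
        raise TrialTableError(f"trial table lacks columns {missing_cols}")
    bad_task = set(trials["task"].unique()) - set(TASKS)
    if bad_task:
        raise TrialTableError(f"unknown task(s) {sorted(bad_task)}")
    if not trials["session"].isin(SESSIONS).all():
        raise TrialTableError("session must be 1 or 2")
    if (trials["rt"] <= 0).any() or not np.isfinite(trials["rt"]).all():
        raise TrialTableError("reaction times must be positive and finite")
    counts = trials.groupby(["subject_id", "task", "session"], sort=False).size()
    for (subj, task, sess), n in counts.items():
        expect = TRIALS_PER_SESSION[task]
        if n != expect:
            raise TrialTableError(
                f"subject {subj!r} task {task!r} session {sess}: "
                f"{n} trials, expected {expect}"
            )
    # both sessions present for every subject x task
    per_cell = trials.groupby(["subject_id", "task"], sort=False)["session"].nunique()
    incomplete = per_cell[per_cell < 2]
    if len(incomplete):
        subj, task = incomplete.index[0]
        raise TrialTableError(f"subject {subj!r} task {task!r}: one session missing")
    return trials


def session_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean RT per subject x task x session (complete blocks enforced)."""
    validate_trials(trials)
    out = (
        trials.groupby(["subject_id", "task", "session"], sort=False)["rt"]
        .mean()
        .rename("mean_rt")
        .reset_index()
    )
    return out


def subject_indicator(trials: pd.DataFrame) -> pd.DataFrame:
    """Grand mean RT per subject x task, pooled over both sessions.

    For balanced blocks this equals the mean of the two session means; the
    pooled form is used because it is also exact if block sizes ever differ.
    Returns a wide frame with columns rt_verbal, rt_visuospatial, rt_stroop
    (tasks absent from the input are omitted).
    """
    validate_trials(trials)
    grand = trials.groupby(["subject_id", "task"], sort=False)["rt"].mean()
    wide = grand.unstack("task")
    wide = wide.rename(
        columns={"verbal": "rt_verbal", "spatial": "rt_visuospatial",
                 "stroop": "rt_stroop"}
    )
    wide.columns.name = None
    return wide.reset_index()


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation with its variance decomposition."""

    icc: float
    form: str           # "ICC3" (consistency) or "ICC2" (absolute agreement)
    ms_subjects: float  # between-subject mean square
    ms_error: float     # residual mean square
    ms_sessions: float  # between-session mean square
    n_subjects: int


def icc_test_retest(session1_means: np.ndarray, session2_means: np.ndarray,
                    form: str = "ICC3") -> IccResult:
    """Single-measure test-retest ICC of paired session means.

    The default is the two-way mixed, consistency form ICC(3,1) =
    (MS_subjects - MS_error) / (MS_subjects + MS_error), treating the two
    sessions as fixed; ``form="ICC2"`` gives the two-way random,
    absolute-agreement form instead.  The underlying estimates come from
    :func:`pingouin.intraclass_corr`.
    """
    s1 = np.asarray(session1_means, dtype=float)
    s2 = np.asarray(session2_means, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise TrialTableError("session mean vectors must be 1-D and equal length")
    n = s1.size
    if n < 3:
        raise TrialTableError(f"need at least 3 subjects for an ICC, got {n}")
    if not (np.isfinite(s1).all() and np.isfinite(s2).all()):
        raise TrialTableError("session means must be finite")
    if form not in ("ICC2", "ICC3"):
        raise TrialTableError(f"form must be 'ICC2' or 'ICC3', got {form!r}")

    grand = (s1.mean() + s2.mean()) / 2.0
    subj_mean = (s1 + s2) / 2.0
    ms_subjects = 2.0 * np.sum((subj_mean - grand) ** 2) / (n - 1)
    ms_sessions = n * ((s1.mean() - grand) ** 2 + (s2.mean() - grand) ** 2)
    ss_total = np.sum((s1 - grand) ** 2) + np.sum((s2 - grand) ** 2)
    ss_error = ss_total - (n - 1) * ms_subjects - ms_sessions
    ms_error = ss_error / (n - 1)

    if ms_subjects <= 0 or (ms_subjects == 0 and ms_error == 0):
        raise TrialTableError("zero between-subject variance: ICC undefined")

    import pingouin as pg

    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "session": np.repeat([1, 2], n),
        "score": np.concatenate([s1, s2]),
    })
    with np.errstate(divide="ignore"), warnings.catch_warnings():
        # degenerate (error-free) data put a zero in pingouin's F denominator
        warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(long, targets="subject", raters="session",
                                   ratings="score")
    pg_type = {"ICC3": "ICC(C,1)", "ICC2": "ICC(A,1)"}[form]
    icc = float(table.set_index("Type").loc[pg_type, "ICC"])
    return IccResult(icc=icc, form=form, ms_subjects=float(ms_subjects),
                     ms_error=float(ms_error), ms_sessions=float(ms_sessions),
                     n_subjects=n)
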