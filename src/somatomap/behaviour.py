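"""Compensatory-behaviour indices from bout-coded video data.

Each participant performs up to 15 bimanual everyday tasks; raters code
bouts of active use (start/end seconds) of six body parts: the intact or
dominant hand, the residual or non-dominant limb, torso, lower face, legs
and feet. From these we compute the percentage of task time each part is
used, a co-use index (the effective number of body parts reliably engaged
per task, an exponential-entropy / Hill order-1 number), and a per-pair
co-use count matrix. Mouth/chin use is analysed separately (chi-square on
user counts; bootstrap on usage scores).

Bout tables travel as tidy DataFrames with columns ``participant_id``,
``group``, ``task_id``, ``body_part``, ``bout_start_s``, ``bout_end_s``;
task durations as ``participant_id``, ``task_id``, ``duration_s``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BEHAVIOUR_PARTS",
    "CO_USE_PARTS",
    "merge_bouts",
    "percentage_of_use",
    "co_use_index",
    "co_use_matrix",
    "mouth_use_chi_square",
    "two_sample_bootstrap",
    "BootstrapResult",
]

#: All coded body parts, in reporting order.
BEHAVIOUR_PARTS = ("hand", "residual_arm", "torso", "lower_face", "legs", "feet")

#: The five compensatory parts entering the co-use matrix (the intact /
#: dominant hand is universally engaged and excluded).
CO_USE_PARTS = ("residual_arm", "torso", "lower_face", "legs", "feet")

BOUT_COLUMNS = ("participant_id", "task_id", "body_part", "bout_start_s", "bout_end_s")


def merge_bouts(starts: np.ndarray, ends: np.ndarray) -> float:
    """Total covered time of a set of intervals, overlaps merged."""
    starts = np.asarray(starts, dtype=float)
    ends = np.asarray(ends, dtype=float)
    if np.any(ends <= starts):
        raise ValueError("every bout must have bout_end_s > bout_start_s")
    order = np.argsort(starts)
    total = 0.0
    current_start, current_end = None, None
    for s, e in zip(starts[order], ends[order]):
        if current_end is None or s > current_end:
            if current_end is not None:
                total += current_end - current_start
            current_start, current_end = s, e
        else:
            current_end = max(current_end, e)
    if current_end is not None:
        total += current_end - current_start
    return total


def _usage_seconds(bouts: pd.DataFrame) -> pd.DataFrame:
    """Merged usage seconds per participant x task x body part."""
    missing = set(BOUT_COLUMNS) - set(bouts.columns)
    if missing:
        raise ValueError(f"bout table missing columns: {sorted(missing)}")
    rows = [
        {
            "participant_id": pid,
            "task_id": task,
            "body_part": part,
            "seconds": merge_bouts(
                chunk["bout_start_s"].to_numpy(), chunk["bout_end_s"].to_numpy()
            ),
        }
        for (pid, task, part), chunk in bouts.groupby(
            ["participant_id", "task_id", "body_part"], sort=False
        )
    ]
    return pd.DataFrame(rows, columns=["participant_id", "task_id", "body_part", "seconds"])


def percentage_of_use(
    bouts: pd.DataFrame,
    durations: pd.DataFrame,
    body_parts: tuple[str, ...] = BEHAVIOUR_PARTS,
) -> pd.DataFrame:
    """Percent of task time each body part is used, averaged over tasks.

    Per sub-task, bout durations of a part are merged and expressed as a
    percentage of the task duration; the participant's value is the mean
    over their completed tasks. Unused parts are kept at 0% so group means
    stay unbiased. Returns a long table (participant_id, body_part, pct).
    """
    if (durations["duration_s"] <= 0).any():
        raise ValueError("task durations must be positive")
    usage = _usage_seconds(bouts)

    per_task = durations[["participant_id", "task_id", "duration_s"]].merge(
        usage, on=["participant_id", "task_id"], how="left"
    )
    records = []
    for pid, chunk in per_task.groupby("participant_id", sort=False):
        tasks = chunk[["task_id", "duration_s"]].drop_duplicates()
        pivot = (
            chunk.dropna(subset=["body_part"])
            .pivot_table(
                index="task_id", columns="body_part", values="seconds", aggfunc="sum"
            )
            .reindex(index=tasks["task_id"], columns=list(body_parts))
            .fillna(0.0)
        )
        pct = 100.0 * pivot.div(tasks.set_index("task_id")["duration_s"], axis=0)
        if (pct.to_numpy() > 100.0 + 1e-9).any():
            raise ValueError(f"bouts exceed task duration for participant {pid!r}")
        means = pct.mean(axis=0)
        records.extend(
            {"participant_id": pid, "body_part": part, "pct": float(means[part])}
            for part in body_parts
        )
    return pd.DataFrame(records)


def co_use_index(
    bouts: pd.DataFrame,
    durations: pd.DataFrame,
    body_parts: tuple[str, ...] = BEHAVIOUR_PARTS,
) -> pd.Series:
    """Effective number of co-used body parts per participant.

    Per sub-task, merged usage times are normalised to proportions q over
    the parts actually used and the index is exp(-sum q ln q) — the Hill
    order-1 effective number. It equals the part count under perfectly even
    usage and drops when usage is uneven; the participant's value is the
    mean over sub-tasks. Tasks with zero total usage are skipped with a
    warning.
    """
    usage = _usage_seconds(bouts)
    usage = usage[usage["body_part"].isin(body_parts)]
    values: dict[str, float] = {}
    for pid in durations["participant_id"].unique():
        tasks = durations.loc[durations["participant_id"] == pid, "task_id"]
        indices = []
        for task in tasks:
            secs = usage.loc[
                (usage["participant_id"] == pid) & (usage["task_id"] == task),
                "seconds",
            ].to_numpy()
            total = secs.sum()
            if total <= 0:
                warnings.warn(
                    f"participant {pid!r} task {task!r} has no coded usage; skipped",
                    stacklevel=2,
                )
                continue
            q = secs[secs > 0] / total
            indices.append(float(np.exp(-(q * np.log(q)).sum())))
        values[pid] = float(np.mean(indices)) if indices else np.nan
    return pd.Series(values, name="co_use_index")


def co_use_matrix(
    bouts: pd.DataFrame,
    body_parts: tuple[str, ...] = CO_USE_PARTS,
) -> dict[str, pd.DataFrame]:
    """Per participant, the symmetric matrix of pairwise co-use counts.

    Cell (a, b) counts the sub-tasks in which both parts have positive
    usage time; the diagonal counts sub-tasks in which the part was used.
    """
    usage = _usage_seconds(bouts)
    usage = usage[(usage["body_part"].isin(body_parts)) & (usage["seconds"] > 0)]
    out: dict[str, pd.DataFrame] = {}
    for pid, chunk in usage.groupby("participant_id", sort=False):
        used = (
            chunk.assign(used=1)
            .pivot_table(index="task_id", columns="body_part", values="used", fill_value=0)
            .reindex(columns=list(body_parts), fill_value=0)
            .to_numpy()
        )
        counts = used.T @ used
        out[pid] = pd.DataFrame(counts, index=body_parts, columns=body_parts, dtype=int)
    return out


def mouth_use_chi_square(
    user_counts: np.ndarray, group_sizes: np.ndarray
) -> tuple[float, int, float]:
    """Pearson chi-square of independence on the users/non-users x group table.

    No continuity correction; df = n_groups - 1.
    """
    users = np.asarray(user_counts, dtype=float)
    sizes = np.asarray(group_sizes, dtype=float)
    if users.shape != sizes.shape:
        raise ValueError("user counts and group sizes must align")
    if np.any(sizes <= 0):
        raise ValueError("every group must be non-empty")
    if np.any(users > sizes) or np.any(users < 0):
        raise ValueError("user counts must lie in [0, group size]")
    table = np.vstack([users, sizes - users])
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class BootstrapResult:
    observed: float
    p: float
    null_values: np.ndarray
    n_iter: int
    seed: int | None


def two_sample_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    n_iter: int = 5000,
    seed: int | None = None,
) -> BootstrapResult:
    """Two-sided bootstrap test of a mean difference under pooled resampling.

    Each iteration resamples the pooled values with replacement into two
    groups of the original sizes; p is the add-one-smoothed proportion of
    null |mean differences| at least as extreme as the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    observed = float(x.mean() - y.mean())
    pool = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    draws = rng.choice(pool, size=(n_iter, pool.size), replace=True)
    null = draws[:, : x.size].mean(axis=1) - draws[:, x.size :].mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (1.0 + n_iter)
    return BootstrapResult(
        observed=observed, p=float(p), null_values=null, n_iter=n_iter, seed=seed
    )
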