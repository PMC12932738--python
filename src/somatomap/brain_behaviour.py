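"""Deviance-based brain-behaviour correlation and its permutation tests.

For each participant with congenital limb difference (CLD) we pair, over
five body parts (feet, legs, torso, residual arm, lower face), a
behavioural deviance (percentage-of-use minus the age-matched peer-group
mean, in percentage points) with a brain position deviance (the ratio of
the participant's peak-to-hand bin distance to the control peer mean; < 1
means shifted toward the hand). A Spearman rho over the five pairs gives a
participant-level coupling measure. Group inference uses permutation:

* within-participant shuffling of the brain-behaviour pairing builds the
  null for the group-mean rho (one-sided, greater);
* group-label shuffling builds the null for the child-adult difference in
  mean rho (Welch t statistic, one-sided).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEVIANCE_PARTS",
    "USAGE_TO_BRAIN_PART",
    "DevianceRecord",
    "PermutationResult",
    "behavioural_deviance",
    "brain_position_deviance",
    "participant_spearman",
    "group_mean_rho_permutation",
    "group_difference_permutation",
    "build_deviance_records",
]

#: Usage-table part names entering the analysis, and the corresponding
#: stimulated body part in the imaging tables.
USAGE_TO_BRAIN_PART = {
    "feet": "foot",
    "legs": "leg",
    "torso": "torso",
    "residual_arm": "arm",
    "lower_face": "lower_face",
}
DEVIANCE_PARTS = tuple(USAGE_TO_BRAIN_PART)


@dataclass
class DevianceRecord:
    """One CLD participant's five paired deviance values and their rho."""

    participant_id: str
    group: str
    parts: tuple[str, ...]
    behav: np.ndarray
    brain: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        self.behav = np.asarray(self.behav, dtype=float)
        self.brain = np.asarray(self.brain, dtype=float)
        if self.behav.shape != self.brain.shape or self.behav.ndim != 1:
            raise ValueError("behav and brain deviances must be aligned 1-D vectors")


@dataclass
class PermutationResult:
    observed: float
    null_values: np.ndarray
    p: float
    n_iter: int
    seed: int | None
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)


def behavioural_deviance(
    participant_pct: Mapping[str, float] | pd.Series,
    peer_pct: pd.DataFrame,
    participant_id: str | None = None,
    leave_self_out: bool = True,
) -> pd.Series:
    """Participant-minus-peer-mean usage, in percentage points.

    ``peer_pct`` is a participants x body-parts table of usage percentages.
    If the participant appears in it and ``leave_self_out`` is set, their
    own row is excluded from the peer mean (they are usually not a member:
    the peer group is the age-matched controls).
    """
    participant = pd.Series(participant_pct, dtype=float)
    peers = peer_pct
    if leave_self_out and participant_id is not None and participant_id in peers.index:
        peers = peers.drop(index=participant_id)
    missing = [p for p in participant.index if p not in peers.columns]
    if missing:
        raise KeyError(f"peer table lacks body part(s): {missing}")
    return participant - peers[participant.index].mean(axis=0)


def brain_position_deviance(
    participant_dist: Mapping[str, float] | pd.Series,
    ctr_peer_mean_dist: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """Peak-to-hand distance relative to the control peer mean, per part.

    A ratio below 1 means the body part's peak sits closer to the hand
    than is typical. Parts whose control mean distance is zero yield NaN
    with a warning (dropped pairwise downstream).
    """
    dist = pd.Series(participant_dist, dtype=float)
    peer = pd.Series(ctr_peer_mean_dist, dtype=float)
    missing = [p for p in dist.index if p not in peer.index]
    if missing:
        raise KeyError(f"control means lack body part(s): {missing}")
    peer = peer[dist.index]
    if (dist < 0).any() or (peer < 0).any():
        raise ValueError("distances must be non-negative")
    zero = peer.index[peer == 0]
    if len(zero):
        warnings.warn(
            f"control mean distance is zero for {list(zero)}; ratio undefined",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = dist / peer
    out[zero] = np.nan
    return out


def participant_spearman(behav: np.ndarray, brain: np.ndarray) -> float:
    """Spearman rho over the paired deviances (average ranks for ties).

    Returns NaN when either vector has zero variance (the participant is
    flagged and excluded pairwise by the group tests).
    """
    behav = np.asarray(behav, dtype=float)
    brain = np.asarray(brain, dtype=float)
    keep = np.isfinite(behav) & np.isfinite(brain)
    if keep.sum() < 2:
        return float("nan")
    b, r = behav[keep], brain[keep]
    if np.ptp(b) == 0 or np.ptp(r) == 0:
        return float("nan")
    return float(stats.spearmanr(b, r).statistic)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equal-shape matrices."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=-1) * (b**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return (a * b).sum(axis=-1) / denom


def _usable_records(records: Sequence[DevianceRecord]) -> tuple[list[DevianceRecord], int]:
    usable, excluded = [], 0
    for rec in records:
        finite = np.isfinite(rec.behav) & np.isfinite(rec.brain)
        if finite.sum() < 3 or np.ptp(rec.behav[finite]) == 0 or np.ptp(rec.brain[finite]) == 0:
            excluded += 1
            continue
        usable.append(rec)
    if excluded:
        warnings.warn(
            f"{excluded} participant(s) with undefined rho excluded", stacklevel=3
        )
    return usable, excluded


def group_mean_rho_permutation(
    records: Sequence[DevianceRecord],
    n_iter: int = 5000,
    seed: int | None = None,
) -> PermutationResult:
    """Is the group-mean Spearman rho greater than chance?

    Each iteration independently re-pairs, within every participant, the
    brain deviances with the behavioural deviances (a random permutation of
    one margin), recomputes all rhos and stores the group mean. The
    one-sided p is the add-one-smoothed proportion of null means at least
    as large as the observed mean.
    """
    if n_iter < 100:
        warnings.warn("fewer than 100 iterations gives a coarse p-value", stacklevel=2)
    usable, excluded = _usable_records(records)
    if len(usable) < 2:
        raise ValueError("need at least 2 participants with defined rho")

    rng = np.random.default_rng(seed)
    null_sum = np.zeros(n_iter)
    observed_sum = 0.0
    for rec in usable:
        finite = np.isfinite(rec.behav) & np.isfinite(rec.brain)
        behav_ranks = stats.rankdata(rec.behav[finite])
        brain_ranks = stats.rankdata(rec.brain[finite])
        observed_sum += _pearson_rows(
            behav_ranks[None, :], brain_ranks[None, :]
        )[0]
        permuted = rng.permuted(
            np.broadcast_to(brain_ranks, (n_iter, brain_ranks.size)).copy(), axis=1
        )
        null_sum += _pearson_rows(
            np.broadcast_to(behav_ranks, permuted.shape), permuted
        )
    observed = observed_sum / len(usable)
    null = null_sum / len(usable)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    return PermutationResult(
        observed=float(observed),
        null_values=null,
        p=float(p),
        n_iter=n_iter,
        seed=seed,
        n_excluded=excluded,
        meta={"n_participants": len(usable)},
    )


def group_difference_permutation(
    children: Sequence[DevianceRecord],
    adults: Sequence[DevianceRecord],
    n_iter: int = 5000,
    seed: int | None = None,
) -> PermutationResult:
    """Is the children's mean rho larger than the adults'?

    Observed statistic: Welch two-sample t on participant rhos (children
    minus adults). The null shuffles group labels over the pooled
    participants; one-sided p = add-one-smoothed proportion of null t at
    least as large as observed.
    """
    kids, exc_k = _usable_records(children)
    grown, exc_a = _usable_records(adults)
    if len(kids) < 2 or len(grown) < 2:
        raise ValueError("each group needs at least 2 participants with defined rho")

    rho_k = np.array([participant_spearman(r.behav, r.brain) for r in kids])
    rho_a = np.array([participant_spearman(r.behav, r.brain) for r in grown])

    def welch_t(x: np.ndarray, y: np.ndarray) -> float:
        return float(stats.ttest_ind(x, y, equal_var=False).statistic)

    observed = welch_t(rho_k, rho_a)
    pooled = np.concatenate([rho_k, rho_a])
    rng = np.random.default_rng(seed)
    null = np.empty(n_iter)
    n_k = rho_k.size
    for it in range(n_iter):
        perm = rng.permutation(pooled)
        null[it] = welch_t(perm[:n_k], perm[n_k:])
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_iter)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p=float(p),
        n_iter=n_iter,
        seed=seed,
        n_excluded=exc_k + exc_a,
        meta={"n_children": len(kids), "n_adults": len(grown)},
    )


def build_deviance_records(
    usage_pct: pd.DataFrame,
    peaks: pd.DataFrame,
    thumb_anchor: Mapping[str, int],
    cld_group: str,
    ctr_group: str,
    behav_peer_group: str | None = None,
) -> list[DevianceRecord]:
    """Assemble DevianceRecords from the behaviour and topography outputs.

    Parameters
    ----------
    usage_pct:
        Long table (participant_id, group, body_part, pct) of usage
        percentages covering both the CLD group and its behavioural peer
        group.
    peaks:
        Peak table (participant_id, group, body_part, peak_bin, status)
        from :func:`somatomap.topography.peak_shift_table`, covering the CLD
        group and the control peer group.
    thumb_anchor:
        Per participant_id, the mirrored functional thumb bin anchoring
        their hand position.
    cld_group, ctr_group:
        Group labels of the CLD cohort and its age-matched control cohort.
    behav_peer_group:
        Group whose usage forms the behavioural norm; defaults to
        ``ctr_group`` (the age-matched peers).
    """
    behav_peer_group = behav_peer_group or ctr_group
    usage_parts = list(DEVIANCE_PARTS)
    brain_parts = [USAGE_TO_BRAIN_PART[p] for p in usage_parts]

    usage_wide = usage_pct.pivot_table(
        index=["group", "participant_id"], columns="body_part", values="pct"
    )
    peer_table = usage_wide.loc[behav_peer_group][usage_parts]

    usable_peaks = peaks[peaks["status"] != "excluded_nonpositive"]

    def distances(group: str) -> pd.DataFrame:
        rows = {}
        for pid, chunk in usable_peaks[usable_peaks["group"] == group].groupby(
            "participant_id", sort=False
        ):
            anchor = thumb_anchor[pid]
            series = chunk.set_index("body_part")["peak_bin"]
            rows[pid] = {
                part: abs(int(series[part]) - int(anchor))
                for part in brain_parts
                if part in series.index
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    ctr_mean_dist = distances(ctr_group).mean(axis=0)
    cld_dist = distances(cld_group)

    records = []
    for pid, dist_row in cld_dist.iterrows():
        if (cld_group, pid) not in usage_wide.index:
            continue
        behav = behavioural_deviance(
            usage_wide.loc[(cld_group, pid)][usage_parts],
            peer_table,
            participant_id=pid,
        )
        brain = brain_position_deviance(
            dist_row.reindex(brain_parts), ctr_mean_dist.reindex(brain_parts)
        )
        rho = participant_spearman(behav.to_numpy(), brain.to_numpy())
        records.append(
            DevianceRecord(
                participant_id=pid,
                group=cld_group,
                parts=tuple(usage_parts),
                behav=behav.to_numpy(),
                brain=brain.to_numpy(),
                rho=rho,
            )
        )
    return records
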