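"""Synthetic cohorts with the statistical structure the analyses assume.

Generates (1) bin-wise S1 activity profiles with group-dependent Gaussian
bumps — congenital limb difference (CLD) peaks shifted toward the hand and
higher than controls; (2) bout-coded usage tables whose per-part usage
fractions differ by group (CLD children use more parts, more evenly); (3)
multivoxel pattern sets with known noise covariance and known true
crossnobis distances; and (4) coupled cohorts in which a participant-level
latent drives both usage deviance and peak-position deviance, so the
brain-behaviour pipeline has a recovery target. Every generator is a pure
function of its spec and seed.

Group sizes default to the study skeleton: 15/16/20/15 (CLD child / CLD
adult / CTR child / CTR adult) for imaging and 16/15/17/16 for behaviour.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .behaviour import BEHAVIOUR_PARTS
from .brain_behaviour import DEVIANCE_PARTS, USAGE_TO_BRAIN_PART, DevianceRecord
from .rsa import PatternSet

__all__ = [
    "CohortSpec",
    "GROUPS",
    "gen_bin_profiles",
    "gen_usage_tables",
    "gen_pattern_sets",
    "gen_coupled_cohort",
    "gen_deviance_records",
    "coupling_for_target_rho",
    "CoupledCohort",
]

GROUPS = ("CLD_child", "CLD_adult", "CTR_child", "CTR_adult")

#: Stimulated body parts, medial to lateral; the thumb is mapped in the
#: hemisphere opposite to all the others (intact/dominant hand).
PROFILE_PARTS = ("foot", "leg", "torso", "arm", "thumb", "upper_face", "lower_face")


def _default_usage_fractions() -> dict[str, dict[str, float]]:
    # Mean per-task usage fraction per body part. The intact/dominant hand is
    # near-universal; controls are essentially bimanual (hand + other hand
    # coded as residual_arm); CLD children recruit legs, feet and torso the
    # most, CLD adults less so.
    return {
        "CTR_adult": dict(hand=0.92, residual_arm=0.82, torso=0.01,
                          lower_face=0.0, legs=0.01, feet=0.0),
        "CTR_child": dict(hand=0.90, residual_arm=0.70, torso=0.04,
                          lower_face=0.01, legs=0.06, feet=0.02),
        "CLD_adult": dict(hand=0.92, residual_arm=0.36, torso=0.05,
                          lower_face=0.01, legs=0.09, feet=0.02),
        "CLD_child": dict(hand=0.90, residual_arm=0.34, torso=0.12,
                          lower_face=0.03, legs=0.22, feet=0.08),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {
            "CLD_child": 15, "CLD_adult": 16, "CTR_child": 20, "CTR_adult": 15
        }
    )
    n_behaviour: Mapping[str, int] = field(
        default_factory=lambda: {
            "CLD_child": 16, "CLD_adult": 15, "CTR_child": 17, "CTR_adult": 16
        }
    )
    n_bins: int = 49
    peak_centers_ctr: Mapping[str, float] = field(
        default_factory=lambda: {
            "foot": 5.0, "leg": 10.0, "torso": 16.0, "arm": 23.0,
            "thumb": 39.0, "upper_face": 43.0, "lower_face": 46.0,
        }
    )
    #: Bins each part's peak moves toward the hand anchor in CLD.
    cld_shift: Mapping[str, float] = field(
        default_factory=lambda: {
            "foot": 3.0, "leg": 3.0, "torso": 2.0, "arm": 4.0,
            "thumb": 0.0, "upper_face": 2.0, "lower_face": 2.0,
        }
    )
    amp_ctr: float = 3.0
    amp_cld: float = 4.0
    bump_width: float = 3.0  # bins
    profile_noise_sd: float = 0.25  # z units
    #: AR(1) coefficient of the bin noise (0 -> i.i.d.). Real bin profiles
    #: are spatially smooth (smoothed z-maps averaged within bins), and the
    #: default keeps spurious double-peak flags at the few-percent level.
    profile_noise_ar: float = 0.9
    participant_jitter_sd: float = 0.8  # bins
    n_tasks: int = 15
    usage_fractions: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_usage_fractions
    )
    usage_task_sd: float = 0.03
    #: Participant-level latent coupling between usage deviance and
    #: peak-position deviance, in [0, 1].
    coupling: float = 0.0
    behav_dev_sd: float = 8.0  # percentage points of usage
    shift_dev_sd: float = 2.5  # bins of participant-level peak displacement

    def __post_init__(self) -> None:
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        if self.profile_noise_sd <= 0:
            raise ValueError("profile noise sd must be positive")
        anchor = self.peak_centers_ctr["thumb"]
        for part, shift in self.cld_shift.items():
            center = self.peak_centers_ctr[part]
            towards = np.sign(anchor - center)
            shifted = center + towards * shift
            if (center - anchor) * (shifted - anchor) < 0:
                raise ValueError(f"cld shift pushes {part!r} past the hand anchor")
            if not 0 <= shifted < self.n_bins:
                raise ValueError(f"cld shift pushes {part!r} off the strip")

    def hand_anchor(self) -> float:
        return float(self.peak_centers_ctr["thumb"])

    def participant_ids(self, imaging: bool = True) -> dict[str, list[str]]:
        sizes = self.n_per_group if imaging else self.n_behaviour
        return {g: [f"{g}_{i:02d}" for i in range(sizes[g])] for g in GROUPS}


def _mni_x(bin_index: np.ndarray, hemisphere: str) -> np.ndarray:
    # Medial bin 0 sits near the midline; magnitude grows laterally.
    magnitude = 10.0 + 1.0 * bin_index
    return -magnitude if hemisphere == "deprived" else magnitude


def _bin_noise(rng: np.random.Generator, n_bins: int, sd: float, ar: float) -> np.ndarray:
    """Stationary AR(1) noise over bins with marginal standard deviation sd."""
    eps = rng.standard_normal(n_bins)
    if ar == 0:
        return sd * eps
    noise = np.empty(n_bins)
    noise[0] = eps[0]
    innovation = np.sqrt(1.0 - ar**2)
    for k in range(1, n_bins):
        noise[k] = ar * noise[k - 1] + innovation * eps[k]
    return sd * noise


def _true_center(
    spec: CohortSpec, group: str, part: str, extra_shift_away: float = 0.0
) -> float:
    center = spec.peak_centers_ctr[part]
    anchor = spec.hand_anchor()
    towards = np.sign(anchor - center)
    if group.startswith("CLD"):
        center = center + towards * spec.cld_shift[part]
    # positive extra displacement moves the peak away from the hand
    center = center - towards * extra_shift_away
    return float(np.clip(center, 0, spec.n_bins - 1))


def gen_bin_profiles(
    spec: CohortSpec,
    seed: int,
    extra_shifts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort of bin profiles plus the ground-truth peak table.

    Each profile is a Gaussian bump (amplitude by group, centre by group
    and body part, plus participant jitter) over ``n_bins`` bins with
    i.i.d. Gaussian noise. Thumb profiles are placed in the opposite
    hemisphere (positive MNI-x) for ROI anchoring. ``extra_shifts`` is an
    optional participants x brain-parts table of additional displacement
    away from the hand (bins), used by the coupled generator.
    """
    rng = np.random.default_rng(seed)
    bins = np.arange(spec.n_bins)
    rows, truth = [], []
    for group, pids in spec.participant_ids().items():
        amp = spec.amp_cld if group.startswith("CLD") else spec.amp_ctr
        for pid in pids:
            for part in PROFILE_PARTS:
                extra = 0.0
                if (
                    extra_shifts is not None
                    and pid in extra_shifts.index
                    and part in extra_shifts.columns
                ):
                    extra = float(extra_shifts.loc[pid, part])
                center = _true_center(spec, group, part, extra)
                center = float(
                    np.clip(
                        center + rng.normal(0.0, spec.participant_jitter_sd),
                        0,
                        spec.n_bins - 1,
                    )
                )
                part_amp = spec.amp_ctr if part == "thumb" else amp
                z = part_amp * np.exp(
                    -((bins - center) ** 2) / (2.0 * spec.bump_width**2)
                ) + _bin_noise(
                    rng, spec.n_bins, spec.profile_noise_sd, spec.profile_noise_ar
                )
                hemisphere = "intact" if part == "thumb" else "deprived"
                x = _mni_x(bins, hemisphere)
                rows.extend(
                    {
                        "participant_id": pid,
                        "group": group,
                        "body_part": part,
                        "bin_index": int(b),
                        "mni_x": float(xv),
                        "z": float(zv),
                    }
                    for b, xv, zv in zip(bins, x, z)
                )
                truth.append(
                    {
                        "participant_id": pid,
                        "group": group,
                        "body_part": part,
                        "true_center": center,
                        "true_amplitude": part_amp,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def gen_usage_tables(
    spec: CohortSpec,
    seed: int,
    usage_offsets: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Bout table, task durations and ground-truth usage fractions.

    Per participant and task, each body part's usage time is a clipped
    Gaussian around the group's mean usage fraction (plus an optional
    participant offset from the coupled generator), realised as a single
    bout placed uniformly within the task.
    """
    rng = np.random.default_rng(seed)
    bout_rows, duration_rows, truth_rows = [], [], []
    for group, pids in spec.participant_ids(imaging=False).items():
        fractions = spec.usage_fractions[group]
        for pid in pids:
            offsets = (
                usage_offsets.loc[pid]
                if usage_offsets is not None and pid in usage_offsets.index
                else None
            )
            for task in range(1, spec.n_tasks + 1):
                duration = float(rng.uniform(20.0, 60.0))
                duration_rows.append(
                    {"participant_id": pid, "task_id": task, "duration_s": duration}
                )
                for part in BEHAVIOUR_PARTS:
                    mean = fractions.get(part, 0.0)
                    if offsets is not None and part in offsets.index:
                        mean = mean + float(offsets[part])
                    frac = float(
                        np.clip(rng.normal(mean, spec.usage_task_sd), 0.0, 1.0)
                    )
                    if frac <= 0.005:
                        continue
                    length = frac * duration
                    start = float(rng.uniform(0.0, duration - length))
                    bout_rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "task_id": task,
                            "body_part": part,
                            "bout_start_s": start,
                            "bout_end_s": start + length,
                        }
                    )
            truth_rows.extend(
                {
                    "participant_id": pid,
                    "group": group,
                    "body_part": part,
                    "mean_fraction": fractions.get(part, 0.0)
                    + (float(offsets[part]) if offsets is not None and part in offsets.index else 0.0),
                }
                for part in BEHAVIOUR_PARTS
            )
    return pd.DataFrame(bout_rows), pd.DataFrame(duration_rows), pd.DataFrame(truth_rows)


def _embed_means(true_distances: np.ndarray, n_conditions: int, n_voxels: int) -> np.ndarray:
    """Condition means whose pairwise Mahalanobis distances match the target.

    Classical multidimensional scaling of the (distance x voxel-count)
    matrix; requires the targets to be Euclidean-embeddable.
    """
    expected = n_conditions * (n_conditions - 1) // 2
    if true_distances.size != expected:
        raise ValueError(f"need {expected} pairwise distances")
    if np.any(true_distances < 0):
        raise ValueError("true distances must be non-negative")
    d2 = np.zeros((n_conditions, n_conditions))
    for (i, j), d in zip(itertools.combinations(range(n_conditions), 2), true_distances):
        d2[i, j] = d2[j, i] = d * n_voxels
    centering = np.eye(n_conditions) - 1.0 / n_conditions
    gram = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh(gram)
    if eigval.min() < -1e-8 * max(eigval.max(), 1.0):
        raise ValueError("true_distances are not Euclidean-embeddable")
    eigval = np.clip(eigval, 0.0, None)
    coords = eigvec * np.sqrt(eigval)  # (conditions, conditions)
    if coords.shape[1] > n_voxels:
        raise ValueError("need n_voxels >= n_conditions to embed the distances")
    means = np.zeros((n_conditions, n_voxels))
    means[:, : coords.shape[1]] = coords
    return means


def gen_pattern_sets(
    n_runs: int = 3,
    n_conditions: int = 5,
    n_voxels: int = 20,
    true_distances: np.ndarray | float = 0.0,
    noise_cov: np.ndarray | None = None,
    noise_sd: float = 1.0,
    n_residual_samples: int = 40,
    n_sets: int = 1,
    seed: int = 0,
    conditions: tuple[str, ...] | None = None,
) -> list[PatternSet]:
    """Pattern sets with known noise covariance and known true distances.

    Condition means are embedded so the expected crossnobis distances equal
    ``true_distances`` (scalar -> all pairs equal); run-wise beta noise and
    the residual streams share ``noise_cov`` (default: ``noise_sd**2 * I``).
    """
    n_pairs = n_conditions * (n_conditions - 1) // 2
    targets = np.asarray(true_distances, dtype=float)
    if targets.ndim == 0:
        targets = np.full(n_pairs, float(targets))
    if noise_cov is None:
        noise_cov = noise_sd**2 * np.eye(n_voxels)
    noise_cov = np.asarray(noise_cov, dtype=float)
    try:
        chol = np.linalg.cholesky(noise_cov)
    except np.linalg.LinAlgError as err:
        raise ValueError("noise covariance must be positive-definite") from err

    base = _embed_means(targets, n_conditions, n_voxels)
    means = base @ chol.T  # Mahalanobis geometry w.r.t. noise_cov
    if conditions is None:
        conditions = tuple(f"cond{i}" for i in range(n_conditions))

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sets):
        beta_noise = rng.standard_normal((n_runs, n_conditions, n_voxels)) @ chol.T
        patterns = means[None, :, :] + beta_noise
        residuals = [
            rng.standard_normal((n_residual_samples, n_voxels)) @ chol.T
            for _ in range(n_runs)
        ]
        out.append(
            PatternSet(patterns=patterns, conditions=conditions, residuals=residuals)
        )
    return out


def coupling_for_target_rho(target_rho: float, n_parts: int = 5) -> float:
    """Latent correlation whose expected sample Spearman rho hits the target.

    With only ``n_parts`` pairs per participant the sample Spearman is
    attenuated relative to its population value; for bivariate-normal pairs
    E[r_S] = 6 / (pi (n+1)) * (asin c + (n-2) asin(c/2)) (Moran), which is
    inverted numerically here.
    """
    if not -1 < target_rho < 1:
        raise ValueError("target rho must lie in (-1, 1)")
    if n_parts < 3:
        raise ValueError("need at least 3 pairs")

    def expected(c: float) -> float:
        return (
            6.0
            / (np.pi * (n_parts + 1))
            * (np.arcsin(c) + (n_parts - 2) * np.arcsin(c / 2.0))
        )

    from scipy.optimize import brentq

    return float(brentq(lambda c: expected(c) - target_rho, -0.999999, 0.999999))


def gen_deviance_records(
    n_participants: int,
    coupling: float,
    seed: int,
    group: str = "CLD_child",
    n_parts: int = len(DEVIANCE_PARTS),
    behav_sd: float = 8.0,
    brain_sd: float = 0.25,
) -> list[DevianceRecord]:
    """Deviance records drawn directly at the record level.

    Behavioural deviances are Gaussian (percentage points); brain deviance
    ratios are 1 + correlated Gaussian noise, with latent correlation
    ``coupling``. Used for permutation-test calibration, where thousands of
    cohorts are needed and only the record structure matters.
    """
    from .brain_behaviour import participant_spearman

    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_participants):
        z_behav = rng.standard_normal(n_parts)
        z_noise = rng.standard_normal(n_parts)
        z_brain = coupling * z_behav + np.sqrt(1.0 - coupling**2) * z_noise
        behav = behav_sd * z_behav
        brain = 1.0 + brain_sd * z_brain
        records.append(
            DevianceRecord(
                participant_id=f"{group}_{i:02d}",
                group=group,
                parts=tuple(DEVIANCE_PARTS),
                behav=behav,
                brain=brain,
                rho=participant_spearman(behav, brain),
            )
        )
    return records


@dataclass
class CoupledCohort:
    """A full synthetic cohort with an injected brain-behaviour coupling."""

    bouts: pd.DataFrame
    durations: pd.DataFrame
    profiles: pd.DataFrame
    profile_truth: pd.DataFrame
    usage_truth: pd.DataFrame
    latents: pd.DataFrame  # per CLD participant x part: behavioural + brain deltas


def gen_coupled_cohort(spec: CohortSpec, seed: int) -> CoupledCohort:
    """Cohort in which a participant-level latent couples usage and position.

    For every CLD participant, a per-part behavioural deviation (percentage
    points, sd ``behav_dev_sd``) perturbs their usage fractions, and a
    correlated per-part displacement (bins, sd ``shift_dev_sd``, latent
    correlation ``coupling``) moves their peaks away from the hand. With
    positive coupling, parts a participant over-uses sit farther from the
    hand than the group norm, so the expected participant Spearman rho
    between behavioural deviance and the distance ratio is a positive,
    monotone function of the coupling.
    """
    rng = np.random.default_rng(seed)
    usage_ids = spec.participant_ids(imaging=False)
    imaging_ids = spec.participant_ids(imaging=True)

    latent_rows = []
    usage_offsets = {}
    extra_shifts = {}
    for group in ("CLD_child", "CLD_adult"):
        # couple the participants present in both sessions
        pids = sorted(set(usage_ids[group]) | set(imaging_ids[group]))
        for pid in pids:
            z_behav = rng.standard_normal(len(DEVIANCE_PARTS))
            z_noise = rng.standard_normal(len(DEVIANCE_PARTS))
            z_brain = (
                spec.coupling * z_behav
                + np.sqrt(1.0 - spec.coupling**2) * z_noise
            )
            behav_delta = spec.behav_dev_sd * z_behav  # percentage points
            shift_away = spec.shift_dev_sd * z_brain  # bins, away from hand
            usage_offsets[pid] = pd.Series(
                behav_delta / 100.0, index=list(DEVIANCE_PARTS)
            )
            extra_shifts[pid] = pd.Series(
                shift_away,
                index=[USAGE_TO_BRAIN_PART[p] for p in DEVIANCE_PARTS],
            )
            latent_rows.extend(
                {
                    "participant_id": pid,
                    "group": group,
                    "body_part": part,
                    "behav_delta_pct": float(bd),
                    "shift_away_bins": float(sa),
                }
                for part, bd, sa in zip(DEVIANCE_PARTS, behav_delta, shift_away)
            )

    seeds = rng.integers(0, 2**31 - 1, size=2)
    bouts, durations, usage_truth = gen_usage_tables(
        spec, int(seeds[0]), usage_offsets=pd.DataFrame(usage_offsets).T
    )
    profiles, profile_truth = gen_bin_profiles(
        spec, int(seeds[1]), extra_shifts=pd.DataFrame(extra_shifts).T
    )
    return CoupledCohort(
        bouts=bouts,
        durations=durations,
        profiles=profiles,
        profile_truth=profile_truth,
        usage_truth=usage_truth,
        latents=pd.DataFrame(latent_rows),
    )
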