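"""Bin-wise S1 topography: peak extraction, mirrored-thumb hand ROI, ROI means.

Empirical activity profiles are z-statistics sampled along ~49 equally
spaced medial-to-lateral bins of the postcentral strip, one profile per
participant and body part. Peak positions (bins) quantify topographic
remapping; a participant-specific 10-bin hand ROI is anchored at the
mirror-projection of the intact-hand thumb peak.

Profiles travel as tidy DataFrames with columns ``participant_id``,
``group``, ``body_part``, ``bin_index``, ``mni_x``, ``z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "PeakResult",
    "HandROI",
    "extract_peak",
    "mirror_thumb_peak",
    "define_hand_roi",
    "roi_mean_activity",
    "peak_shift_table",
    "PROFILE_COLUMNS",
]

PROFILE_COLUMNS = ("participant_id", "group", "body_part", "bin_index", "mni_x", "z")

#: A candidate local maximum counts as a genuine (double) peak only if its
#: prominence reaches this fraction of the profile's global maximum.
DOUBLE_PEAK_PROMINENCE_FRAC = 0.2


@dataclass
class PeakResult:
    bin_index: int
    mni_x: float | None
    amplitude: float
    status: str  # "ok" | "excluded_nonpositive" | "double_peak_resolved"

    @property
    def usable(self) -> bool:
        return self.status != "excluded_nonpositive"


@dataclass
class HandROI:
    """Ten contiguous bins: one lateral and eight medial of the anchor."""

    bin_indices: np.ndarray
    anchor: int


def _local_maxima(z: np.ndarray) -> np.ndarray:
    """Indices of local maxima, plateau -> most medial bin, edges included."""
    padded = np.concatenate(([-np.inf], z, [-np.inf]))
    peaks, props = signal.find_peaks(padded, plateau_size=1)
    # plateau left edge is the most medial plateau bin
    return props["left_edges"] - 1


def _prominences(z: np.ndarray, maxima: np.ndarray) -> np.ndarray:
    """Prominence of each local maximum, with edge bins handled explicitly.

    The prominence of a maximum is its height above the higher of the two
    valley floors separating it from larger terrain (or from the strip end).
    """
    out = np.empty(maxima.size)
    for k, m in enumerate(maxima):
        height = z[m]
        bases = []
        for segment in (z[:m][::-1], z[m + 1 :]):
            higher = np.flatnonzero(segment > height)
            stop = higher[0] if higher.size else segment.size
            if stop > 0:
                bases.append(segment[:stop].min())
        out[k] = height - max(bases) if bases else height
    return out


def extract_peak(
    z: np.ndarray,
    mni_x: np.ndarray | None = None,
    group_reference_bin: int | None = None,
    prominence_frac: float = DOUBLE_PEAK_PROMINENCE_FRAC,
) -> PeakResult:
    """Locate the governing activity peak of one bin profile.

    Profiles with no positive activation anywhere are flagged
    ``excluded_nonpositive``. When more than one local maximum is prominent
    (prominence at least ``prominence_frac`` of the global maximum) and a
    group-reference peak bin is supplied, the maximum nearest the reference
    is chosen and flagged ``double_peak_resolved`` — a mechanised version of
    choosing the peak closest to the group average. Otherwise the global
    argmax wins (ties -> most medial bin).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size < 3:
        raise ValueError("profile must be a 1-D array with at least 3 bins")
    if mni_x is not None:
        mni_x = np.asarray(mni_x, dtype=float)
        if mni_x.shape != z.shape:
            raise ValueError("mni_x must match the profile length")

    def coord(bin_index: int) -> float | None:
        return None if mni_x is None else float(mni_x[bin_index])

    global_argmax = int(np.argmax(z))
    if z[global_argmax] <= 0:
        return PeakResult(
            bin_index=global_argmax,
            mni_x=coord(global_argmax),
            amplitude=float(z[global_argmax]),
            status="excluded_nonpositive",
        )

    maxima = _local_maxima(z)
    if maxima.size > 1:
        prominences = _prominences(z, maxima)
        prominent = maxima[prominences >= prominence_frac * z[global_argmax]]
        # the global maximum is always a candidate, whatever its prominence
        # (a peak riding the strip edge has no lateral valley to earn any)
        if global_argmax not in prominent:
            prominent = np.sort(np.append(prominent, global_argmax))
    else:
        prominent = maxima

    if prominent.size > 1 and group_reference_bin is not None:
        order = np.lexsort((prominent, np.abs(prominent - group_reference_bin)))
        chosen = int(prominent[order[0]])
        return PeakResult(
            bin_index=chosen,
            mni_x=coord(chosen),
            amplitude=float(z[chosen]),
            status="double_peak_resolved",
        )

    return PeakResult(
        bin_index=global_argmax,
        mni_x=coord(global_argmax),
        amplitude=float(z[global_argmax]),
        status="ok",
    )


def mirror_thumb_peak(thumb_peak_mni_x: float, target_mni_x: np.ndarray) -> int:
    """Homologous bin in the other hemisphere for an intact-thumb peak.

    The match is by medial-to-lateral coordinate magnitude: the target bin
    whose \\|MNI-x\\| is nearest the source peak's (the hemispheres may have
    unequal bin counts). Ties resolve to the more medial bin.
    """
    target = np.abs(np.asarray(target_mni_x, dtype=float))
    source = abs(float(thumb_peak_mni_x))
    if source > target.max() + np.diff(np.sort(target)).max():
        raise ValueError("thumb peak lies outside the target strip")
    deltas = np.abs(target - source)
    return int(np.lexsort((np.arange(target.size), deltas))[0])


def define_hand_roi(anchor: int, n_bins: int) -> HandROI:
    """Hand ROI: the anchor bin, eight bins medial and one lateral of it.

    Bins are clipped to the strip; a warning is emitted when the ROI is
    truncated at an edge and therefore smaller than 10 bins.
    """
    if not 0 <= anchor < n_bins:
        raise ValueError(f"anchor {anchor} outside strip of {n_bins} bins")
    lo, hi = anchor - 8, anchor + 2
    clipped_lo, clipped_hi = max(lo, 0), min(hi, n_bins)
    if (clipped_lo, clipped_hi) != (lo, hi):
        warnings.warn(
            f"hand ROI truncated at strip edge: {clipped_hi - clipped_lo} bins "
            f"instead of 10 (anchor {anchor}, {n_bins} bins)",
            stacklevel=2,
        )
    return HandROI(bin_indices=np.arange(clipped_lo, clipped_hi), anchor=anchor)


def roi_mean_activity(profile: pd.DataFrame | np.ndarray, roi: HandROI) -> float:
    """Mean z over the ROI bins of one profile."""
    if isinstance(profile, pd.DataFrame):
        sel = profile[profile["bin_index"].isin(roi.bin_indices)]["z"]
        if sel.empty:
            raise ValueError("ROI does not overlap the profile's bins")
        return float(sel.mean())
    z = np.asarray(profile, dtype=float)
    inside = roi.bin_indices[(roi.bin_indices >= 0) & (roi.bin_indices < z.size)]
    if inside.size == 0:
        raise ValueError("ROI does not overlap the profile's bins")
    return float(z[inside].mean())


def peak_shift_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Per participant x body part peak table with group-mean references.

    For every (group, body part) cell the reference peak is the global
    argmax of the across-participant mean profile; individual profiles are
    then peak-extracted against that reference so double peaks resolve
    toward the group's typical location. Excluded profiles stay in the
    table, flagged, so the audit trail is complete.
    """
    if profiles.empty:
        raise ValueError("empty cohort")
    missing = set(PROFILE_COLUMNS) - set(profiles.columns)
    if missing:
        raise ValueError(f"profiles table missing columns: {sorted(missing)}")

    rows = []
    for (group, part), chunk in profiles.groupby(["group", "body_part"], sort=False):
        mean_profile = (
            chunk.groupby("bin_index", sort=True)["z"].mean().sort_index()
        )
        reference_bin = int(mean_profile.idxmax())
        for pid, prof in chunk.groupby("participant_id", sort=False):
            prof = prof.sort_values("bin_index")
            result = extract_peak(
                prof["z"].to_numpy(),
                prof["mni_x"].to_numpy(),
                group_reference_bin=reference_bin,
            )
            rows.append(
                {
                    "participant_id": pid,
                    "group": group,
                    "body_part": part,
                    "peak_bin": result.bin_index,
                    "peak_mni_x": result.mni_x,
                    "amplitude": result.amplitude,
                    "status": result.status,
                }
            )
    return pd.DataFrame(rows)
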