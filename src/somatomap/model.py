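"""Homeostatic synaptic-scaling model of the S1 homunculus.

A shallow network: 10 body-part inputs project to ``n_neurons`` internal
nodes laid out medially to laterally along the postcentral strip. Initial
connection weights are bell-shaped tuning curves over the strip, offset by a
small constant so every body part is weakly connected to every node. Each
node's mean neural activity (MNA) is the stimulation-probability-weighted
sum of its input weights; homeostatic plasticity multiplicatively rescales
every node's weights so its MNA equals a common target (``mna_hom``),
preserving within-node weight ratios.

Two group configurations are supported. Controls (``CTR``) have strong hand
(palm/finger) connections. Congenital limb difference (``CLD``) attenuates
the palm/finger bells (residual nerves connect weakly but are not removed),
and during evaluation arm stimulation co-activates the residual palm/finger
nerves (peripheral reorganisation). A ``rudimentary`` variant strips
peripheral reorganisation and all input inhomogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BODY_PARTS",
    "HAND_PARTS",
    "EVALUATED_PARTS",
    "ModelConfig",
    "WeightMatrix",
    "ActivationProfile",
    "ObservationReport",
    "build_initial_weights",
    "compute_mna",
    "apply_synaptic_scaling",
    "simulate_stimulation",
    "run_group_simulation",
    "check_observations",
    "hand_center",
]

#: The ten modelled inputs in medial-to-lateral homuncular order.
BODY_PARTS: tuple[str, ...] = (
    "genitals",
    "foot",
    "leg",
    "torso",
    "arm",
    "palm",
    "fingers",
    "upper_face",
    "lower_face",
    "throat",
)

HAND_PARTS: tuple[str, ...] = ("palm", "fingers")

#: Body parts whose activation profiles are evaluated against the
#: empirical observations (the six stimulated in the fMRI protocol).
EVALUATED_PARTS: tuple[str, ...] = (
    "foot",
    "leg",
    "torso",
    "arm",
    "upper_face",
    "lower_face",
)


class ConfigurationError(ValueError):
    """Raised for invalid model configurations."""


def _default_peak_positions(n_neurons: int) -> tuple[float, ...]:
    # Ten peaks uniformly spread over the strip: node = spacing * (rank - 1/2).
    spacing = n_neurons / len(BODY_PARTS)
    return tuple(spacing * (rank - 0.5) for rank in range(1, len(BODY_PARTS) + 1))


@dataclass(frozen=True)
class ModelConfig:
    """Parameters of one group's homunculus simulation.

    Parameters
    ----------
    n_neurons:
        Number of internal S1 nodes (>= 10).
    group:
        ``"CTR"`` or ``"CLD"``.
    variant:
        ``"main"`` (peripheral reorganisation, hand gain, inhomogeneous
        stimulation probabilities) or ``"rudimentary"`` (none of those).
    peak_positions:
        Bell-curve centre per body part, strictly increasing in homuncular
        order. Defaults to uniform spacing.
    bell_width:
        Gaussian standard deviation of the tuning curves, in nodes.
    offset:
        Constant added to every weight so all connections stay positive.
    hand_gain:
        Multiplier on the palm/finger bells (controls' dense hand
        innervation). Forced to 1 in the rudimentary variant.
    cld_attenuation:
        Multiplier on the palm/finger bells for the CLD group (residual
        nerves are reduced, not removed). The offset floor is not attenuated.
    mna_hom:
        Homeostatic target mean neural activity.
    stim_probabilities:
        Optional per-part stimulation probabilities; defaults to 0.05
        everywhere with 0.15 for palm and fingers (uniform 0.05 in the
        rudimentary variant).
    mna_costimulation:
        Alternative reading of peripheral reorganisation during homeostasis:
        for CLD, everyday arm stimulation also fires the residual
        palm/finger nerves, adding the arm probability to theirs when the
        MNA is computed. Default off (independent probabilities).
    """

    n_neurons: int = 50
    group: str = "CTR"
    variant: str = "main"
    peak_positions: tuple[float, ...] | None = None
    bell_width: float = 4.0
    offset: float = 0.05
    hand_gain: float = 3.0
    cld_attenuation: float = 0.15
    mna_hom: float = 0.5
    stim_probabilities: Mapping[str, float] | None = None
    mna_costimulation: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("CTR", "CLD"):
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.variant not in ("main", "rudimentary"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.n_neurons < len(BODY_PARTS):
            raise ConfigurationError("n_neurons must be >= 10")
        if self.offset <= 0:
            raise ConfigurationError("offset must be positive")
        if not 0 < self.cld_attenuation <= 1:
            raise ConfigurationError("cld_attenuation must lie in (0, 1]")
        if self.mna_hom <= 0:
            raise ConfigurationError("mna_hom must be positive")
        if self.bell_width <= 0:
            raise ConfigurationError("bell_width must be positive")
        peaks = np.asarray(self.peaks)
        if peaks.shape != (len(BODY_PARTS),):
            raise ConfigurationError("need one peak position per body part")
        if np.any(peaks < 0) or np.any(peaks >= self.n_neurons):
            raise ConfigurationError("peak positions must lie within [0, n_neurons)")
        if np.any(np.diff(peaks) <= 0):
            raise ConfigurationError(
                "peak positions must be strictly increasing in homuncular order"
            )
        probs = self.probabilities
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("stimulation probabilities must lie in [0, 1]")

    @property
    def peaks(self) -> tuple[float, ...]:
        if self.peak_positions is not None:
            return tuple(self.peak_positions)
        return _default_peak_positions(self.n_neurons)

    @property
    def probabilities(self) -> np.ndarray:
        """Stimulation probability per body part, in homuncular order."""
        if self.stim_probabilities is not None:
            return np.array([self.stim_probabilities[p] for p in BODY_PARTS])
        if self.variant == "rudimentary":
            return np.full(len(BODY_PARTS), 0.05)
        probs = np.full(len(BODY_PARTS), 0.05)
        for part in HAND_PARTS:
            probs[BODY_PARTS.index(part)] = 0.15
        return probs

    def effective_probabilities(self) -> np.ndarray:
        """Probabilities entering the MNA, honouring ``mna_costimulation``."""
        probs = self.probabilities.copy()
        if (
            self.mna_costimulation
            and self.group == "CLD"
            and self.variant == "main"
        ):
            arm_p = probs[BODY_PARTS.index("arm")]
            for part in HAND_PARTS:
                probs[BODY_PARTS.index(part)] += arm_p
        return probs


@dataclass
class WeightMatrix:
    """Connection strengths from the 10 body-part inputs to the S1 nodes."""

    values: np.ndarray  # (n_neurons, 10), strictly positive
    stage: str  # "initial" | "homeostatic"
    body_parts: tuple[str, ...] = BODY_PARTS

    def column(self, body_part: str) -> np.ndarray:
        try:
            idx = self.body_parts.index(body_part)
        except ValueError:
            raise KeyError(f"unknown body part {body_part!r}") from None
        return self.values[:, idx]


@dataclass
class ActivationProfile:
    """Node activities elicited by stimulating one body part."""

    body_part: str
    values: np.ndarray
    peak_node: int  # integer argmax, ties resolved to the most medial node
    peak_value: float
    peak_position: float  # sub-node (parabolic) peak location


@dataclass
class ObservationReport:
    """Whether the two groups' profiles replicate the four empirical findings."""

    obs1: bool  # CLD arm peak higher and laterally shifted toward the hand
    obs2: bool  # all other peaks closer to the hand in CLD
    obs3: bool  # all CLD peaks higher than CTR peaks
    obs4: bool  # foot > leg > torso and upper < lower face, in both groups
    obs4_per_group: dict = field(default_factory=dict)
    peaks: dict = field(default_factory=dict)

    def all_replicated(self) -> bool:
        return self.obs1 and self.obs2 and self.obs3 and self.obs4


def build_initial_weights(config: ModelConfig) -> WeightMatrix:
    """Construct the genetically pre-determined (seed) weight matrix.

    Each body part's column is a Gaussian bump over the nodes, centred at
    its configured peak, scaled by ``hand_gain`` for palm/fingers, plus the
    constant offset. For the CLD group the palm/finger bells are attenuated
    by ``cld_attenuation`` (rudimentary variant: removed entirely); the
    offset floor is kept so residual nerves stay weakly connected everywhere.
    """
    nodes = np.arange(config.n_neurons)[:, None]
    peaks = np.asarray(config.peaks)[None, :]
    bells = np.exp(-((nodes - peaks) ** 2) / (2.0 * config.bell_width**2))

    hand_cols = [BODY_PARTS.index(p) for p in HAND_PARTS]
    if config.variant == "main":
        bells[:, hand_cols] *= config.hand_gain
        if config.group == "CLD":
            bells[:, hand_cols] *= config.cld_attenuation
    elif config.group == "CLD":
        bells[:, hand_cols] = 0.0

    return WeightMatrix(values=bells + config.offset, stage="initial")


def compute_mna(weights: WeightMatrix | np.ndarray, probabilities: Sequence[float]) -> np.ndarray:
    """Mean neural activity per node: MNA_j = sum_i W[j, i] * P[i]."""
    values = weights.values if isinstance(weights, WeightMatrix) else np.asarray(weights)
    probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (values.shape[1],):
        raise ValueError(
            f"probability vector length {probs.shape} does not match "
            f"{values.shape[1]} inputs"
        )
    return values @ probs


def apply_synaptic_scaling(
    weights: WeightMatrix,
    probabilities: Sequence[float],
    mna_hom: float,
) -> WeightMatrix:
    """Multiplicatively rescale every node's weights to hit ``mna_hom``.

    W_hom[j, i] = mna_hom * W_init[j, i] / MNA_init[j]. Within-node weight
    ratios are unchanged; recomputing the MNA afterwards yields ``mna_hom``
    for every node.
    """
    mna = compute_mna(weights, probabilities)
    zero = np.flatnonzero(mna == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"initial MNA is zero for neuron(s) {zero.tolist()}; cannot scale"
        )
    scaled = mna_hom * weights.values / mna[:, None]
    return WeightMatrix(values=scaled, stage="homeostatic", body_parts=weights.body_parts)


def _refine_peak(values: np.ndarray) -> tuple[int, float, float]:
    """Integer argmax (tie -> most medial) plus a parabolic sub-node position.

    Peak shifts of body parts distant from the hand are far smaller than one
    node, so position comparisons use the interpolated location.
    """
    node = int(np.argmax(values))
    peak = float(values[node])
    if node == 0 or node == len(values) - 1:
        return node, peak, float(node)
    left, mid, right = values[node - 1], values[node], values[node + 1]
    denom = left - 2.0 * mid + right
    shift = 0.0 if denom == 0 else 0.5 * (left - right) / denom
    return node, peak, node + float(shift)


def simulate_stimulation(
    weights: WeightMatrix,
    body_part: str,
    group: str = "CTR",
    variant: str = "main",
) -> ActivationProfile:
    """Node activities when one body part is stimulated (X = 1).

    For the CLD main model, arm stimulation also fires the residual
    palm/finger nerves, so Y_j = W[j, arm] + W[j, palm] + W[j, fingers];
    every other case activates the stimulated column alone.
    """
    if body_part not in weights.body_parts:
        raise KeyError(f"unknown body part {body_part!r}")
    if body_part == "arm" and group == "CLD" and variant == "main":
        values = (
            weights.column("arm") + weights.column("palm") + weights.column("fingers")
        )
    else:
        values = weights.column(body_part).copy()
    node, peak, position = _refine_peak(values)
    return ActivationProfile(
        body_part=body_part,
        values=values,
        peak_node=node,
        peak_value=peak,
        peak_position=position,
    )


def run_group_simulation(config: ModelConfig) -> dict[str, ActivationProfile]:
    """Build, equilibrate and evaluate one group's model.

    Returns the activation profile for each of the six evaluated body parts
    after a single homeostatic equilibration.
    """
    initial = build_initial_weights(config)
    homeostatic = apply_synaptic_scaling(
        initial, config.effective_probabilities(), config.mna_hom
    )
    return {
        part: simulate_stimulation(homeostatic, part, config.group, config.variant)
        for part in EVALUATED_PARTS
    }


def hand_center(config: ModelConfig) -> float:
    """Centre of the hand representation: midpoint of palm/finger peaks."""
    peaks = config.peaks
    return 0.5 * (
        peaks[BODY_PARTS.index("palm")] + peaks[BODY_PARTS.index("fingers")]
    )


def check_observations(
    ctr: Mapping[str, ActivationProfile],
    cld: Mapping[str, ActivationProfile],
    hand_center: float,
) -> ObservationReport:
    """Evaluate the four empirical findings on the two groups' profiles.

    1. CLD arm peak is higher and shifted laterally, toward the hand.
    2. Foot, leg, torso and both face peaks are closer to the hand in CLD.
    3. Every compared CLD peak is higher than its CTR counterpart.
    4. Within each group, peak magnitude falls foot > leg > torso and rises
       from upper to lower face.
    """
    missing = [p for p in EVALUATED_PARTS if p not in ctr or p not in cld]
    if missing:
        raise KeyError(f"missing body part profile(s): {missing}")

    def pos(profiles: Mapping[str, ActivationProfile], part: str) -> float:
        return profiles[part].peak_position

    def amp(profiles: Mapping[str, ActivationProfile], part: str) -> float:
        return profiles[part].peak_value

    obs1 = (
        amp(cld, "arm") > amp(ctr, "arm")
        and pos(cld, "arm") > pos(ctr, "arm")
        and abs(pos(cld, "arm") - hand_center) < abs(pos(ctr, "arm") - hand_center)
    )

    shifted_parts = ("foot", "leg", "torso", "upper_face", "lower_face")
    obs2 = all(
        abs(pos(cld, p) - hand_center) < abs(pos(ctr, p) - hand_center)
        for p in shifted_parts
    )

    obs3 = all(amp(cld, p) > amp(ctr, p) for p in EVALUATED_PARTS)

    def gradient_holds(profiles: Mapping[str, ActivationProfile]) -> bool:
        return (
            amp(profiles, "foot") > amp(profiles, "leg") > amp(profiles, "torso")
            and amp(profiles, "upper_face") < amp(profiles, "lower_face")
        )

    obs4_per_group = {"CTR": gradient_holds(ctr), "CLD": gradient_holds(cld)}
    peaks = {
        group: {
            p: {"node": prof[p].peak_node, "position": pos(prof, p), "value": amp(prof, p)}
            for p in EVALUATED_PARTS
        }
        for group, prof in (("CTR", ctr), ("CLD", cld))
    }
    return ObservationReport(
        obs1=bool(obs1),
        obs2=bool(obs2),
        obs3=bool(obs3),
        obs4=bool(all(obs4_per_group.values())),
        obs4_per_group=obs4_per_group,
        peaks=peaks,
    )


def compare_groups(
    variant: str = "main", **overrides
) -> tuple[dict[str, ActivationProfile], dict[str, ActivationProfile], ObservationReport]:
    """Run CTR and CLD simulations with shared settings and check observations."""
    ctr_cfg = ModelConfig(group="CTR", variant=variant, **overrides)
    cld_cfg = replace(ctr_cfg, group="CLD")
    ctr = run_group_simulation(ctr_cfg)
    cld = run_group_simulation(cld_cfg)
    report = check_observations(ctr, cld, hand_center(ctr_cfg))
    return ctr, cld, report
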