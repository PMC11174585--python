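"""Synthetic pathological-gait skeleton sequences and data augmentation.

The generator is phenomenological, not biomechanical: each gait class is a
parametric recipe (cadence, limb swing amplitudes, left/right asymmetry,
walking-speed drift, tremor, trunk lean) layered as sinusoids on a static
rest pose.  That is exactly the structure a frequency-domain gait classifier
exploits — class identity lives in the fundamental step frequency, its
spatial distribution over joints, and left/right amplitude ratios — so the
generated data exercises the method without claiming clinical realism.

Kinematic conventions (3-D): channel 0 is lateral x, channel 1 vertical y,
channel 2 forward z (walking direction).  Limb joints swing along z with
phase-opposed left/right sinusoids at the step frequency; arms counter-swing
their ipsilateral leg.  With ``channels=2`` the lateral axis is dropped
(sagittal view: forward, vertical).

Pose-estimation noise is modelled as i.i.d. Gaussian jitter plus per-joint
per-frame dropout, filled either by holding the last observed position
(tracker-like, the default) or with zeros.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .graphs import Layout, load_layout

__all__ = [
    "GaitClassSpec",
    "NoiseSpec",
    "SkeletonSequence",
    "generate_sequence",
    "generate_dataset",
    "mirror_augment",
    "channel_flip_augment",
    "noise_augment",
    "random_crop_augment",
    "default_class_specs",
    "fft_magnitude_features",
]


@dataclass
class GaitClassSpec:
    """Parametric description of one synthetic gait phenotype.

    Amplitudes are in rest-pose coordinate units (metres); ``cadence_hz`` is
    steps per second; ``left_right_asymmetry`` scales every left-side
    amplitude (1.0 = symmetric); ``speed_drift`` sinusoidally modulates the
    instantaneous cadence by the given fraction over the sequence.
    """

    class_id: int
    name: str
    cadence_hz: float
    arm_swing: float = 0.12
    leg_swing: float = 0.25
    step_height: float = 0.05
    body_sway: float = 0.0
    left_right_asymmetry: float = 1.0
    speed_drift: float = 0.0
    tremor_hz: float = 0.0
    tremor_amplitude: float = 0.0
    trunk_lean: float = 0.0

    def __post_init__(self):
        if self.cadence_hz <= 0:
            raise ValueError("cadence_hz must be positive")
        if not 0.0 < self.left_right_asymmetry <= 1.0:
            raise ValueError("left_right_asymmetry must be in (0, 1]")


@dataclass
class NoiseSpec:
    """Pose-estimation noise: Gaussian jitter + joint dropout."""

    jitter_sd: float = 0.0
    dropout_prob: float = 0.0
    dropout_fill: str = "hold"  # 'hold' last observed position, or 'zero'

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.dropout_fill not in ("hold", "zero"):
            raise ValueError("dropout_fill must be 'hold' or 'zero'")


@dataclass
class SkeletonSequence:
    """A (C, T, V) joint-coordinate sequence with label and provenance."""

    values: np.ndarray
    fps: float
    label: int
    subject_id: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be (C, T, V)")
        c, t, _ = self.values.shape
        if c not in (2, 3):
            raise ValueError("channels must be 2 or 3")
        if t < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite coordinates")

    @property
    def shape(self):
        return self.values.shape

    def replace(self, **kw) -> "SkeletonSequence":
        return dataclasses.replace(self, **kw)


def _side_factors(layout: Layout, asymmetry: float):
    sides = np.asarray(layout.sides)
    amp = np.where(sides == "L", asymmetry, 1.0)
    phase = np.where(sides == "R", np.pi, 0.0)  # left leg leads at phase 0
    return amp, phase


def generate_sequence(
    spec: GaitClassSpec,
    noise: NoiseSpec,
    T: int,
    fps: float,
    layout="kinect25",
    seed: int = 0,
    channels: int = 3,
    subject_id: str = "",
) -> SkeletonSequence:
    """Deterministically synthesize one labelled gait sequence."""
    if isinstance(layout, str):
        layout = load_layout(layout)
    if T < 2:
        raise ValueError("T must be >= 2")
    nyquist = fps / 2.0
    if spec.cadence_hz >= nyquist:
        raise ValueError(f"cadence {spec.cadence_hz} Hz at/above Nyquist ({nyquist} Hz)")
    if spec.tremor_hz >= nyquist:
        raise ValueError(f"tremor {spec.tremor_hz} Hz at/above Nyquist ({nyquist} Hz)")
    if layout.rest_pose is None or not layout.swing_weight:
        raise ValueError(f"layout {layout.name!r} lacks a rest pose / gait metadata")

    v = layout.n_joints
    t_sec = np.arange(T) / fps
    duration = T / fps
    # instantaneous cadence, sinusoidally modulated over the sequence
    inst = spec.cadence_hz * (1.0 + spec.speed_drift * np.sin(2 * np.pi * t_sec / duration))
    phase = 2 * np.pi * np.concatenate([[0.0], np.cumsum(inst[:-1])]) / fps

    groups = np.asarray(layout.groups)
    weight = np.asarray(layout.swing_weight)
    amp_side, phase_side = _side_factors(layout, spec.left_right_asymmetry)
    is_arm, is_leg = groups == "arm", groups == "leg"

    pose = np.repeat(layout.rest_pose[None, :, :], T, axis=0)  # (T, V, 3)
    ph = phase[:, None] + phase_side[None, :]
    # forward swing: legs at the step phase, arms in counter-phase
    swing = np.where(is_leg, spec.leg_swing, 0.0) * np.sin(ph) + np.where(
        is_arm, spec.arm_swing, 0.0
    ) * np.sin(ph + np.pi)
    pose[:, :, 2] += amp_side[None, :] * weight[None, :] * swing
    # vertical step lift (legs only), one lift per step
    lift = 0.5 * spec.step_height * (1.0 - np.cos(ph))
    pose[:, :, 1] += amp_side[None, :] * weight[None, :] * np.where(is_leg, lift, 0.0)
    # lateral body sway at the stride frequency (half the step frequency)
    pose[:, :, 0] += spec.body_sway * np.sin(phase / 2.0)[:, None]
    # tremor overlay on the limbs
    if spec.tremor_amplitude > 0.0 and spec.tremor_hz > 0.0:
        trem = spec.tremor_amplitude * np.sin(2 * np.pi * spec.tremor_hz * t_sec)
        pose[:, :, 2] += trem[:, None] * weight[None, :] * (is_arm | is_leg)
    # static forward trunk lean, increasing with height above the pelvis
    if spec.trunk_lean != 0.0:
        y0 = layout.rest_pose[list(layout.center_joints), 1].mean()
        height = np.clip(layout.rest_pose[:, 1] - y0, 0.0, None)
        pose[:, :, 2] += np.sin(spec.trunk_lean) * height[None, :]

    rng = np.random.default_rng(seed)
    if noise.jitter_sd > 0:
        pose = pose + rng.normal(0.0, noise.jitter_sd, size=pose.shape)
    if noise.dropout_prob > 0:
        lost = rng.random((T, v)) < noise.dropout_prob
        if noise.dropout_fill == "zero":
            pose[lost] = 0.0
        else:  # hold last observed position (rest pose if dropped at frame 0)
            fallback = np.repeat(layout.rest_pose[None], T, axis=0)
            last = np.where(lost[:, :, None], np.nan, pose)
            for k in range(T):
                if k == 0:
                    last[0] = np.where(lost[0, :, None], fallback[0], pose[0])
                else:
                    last[k] = np.where(lost[k, :, None], last[k - 1], pose[k])
            pose = last

    values = pose.transpose(2, 0, 1)  # (3, T, V)
    if channels == 2:
        values = values[[2, 1]]  # sagittal view: forward, vertical
    elif channels != 3:
        raise ValueError("channels must be 2 or 3")
    return SkeletonSequence(
        values=values,
        fps=fps,
        label=spec.class_id,
        subject_id=subject_id,
        provenance={
            "generator": "gaitfreq.synthetic",
            "layout": layout.name,
            "seed": int(seed),
            "spec": dataclasses.asdict(spec),
            "noise": dataclasses.asdict(noise),
        },
    )


def generate_dataset(
    class_specs,
    n_per_class: int,
    noise: NoiseSpec,
    T: int,
    fps: float,
    layout="kinect25",
    seed: int = 0,
    channels: int = 3,
) -> list[SkeletonSequence]:
    """Balanced, label-complete, seed-reproducible dataset (class-major order)."""
    class_specs = list(class_specs)
    if len(class_specs) < 2:
        raise ValueError("need at least 2 classes")
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if isinstance(layout, str):
        layout = load_layout(layout)
    child_seeds = np.random.SeedSequence(seed).generate_state(
        len(class_specs) * n_per_class
    )
    out = []
    k = 0
    for spec in class_specs:
        for rep in range(n_per_class):
            out.append(
                generate_sequence(
                    spec,
                    noise,
                    T,
                    fps,
                    layout=layout,
                    seed=int(child_seeds[k]),
                    channels=channels,
                    subject_id=f"{spec.name}_{rep:03d}",
                )
            )
            k += 1
    return out


# -- augmentations ---------------------------------------------------------


def _mirror_channel(seq: SkeletonSequence, layout: Layout) -> int:
    # 3-D data mirrors across the sagittal plane (negate lateral x); 2-D
    # sagittal data mirrors the walking direction (negate forward, channel 0)
    return layout.lateral_channel if seq.shape[0] == 3 else 0


def mirror_augment(seq: SkeletonSequence, layout="kinect25") -> SkeletonSequence:
    """Swap left/right joints and negate the mirror axis; label preserved."""
    if isinstance(layout, str):
        layout = load_layout(layout)
    if not layout.mirror:
        raise ValueError(f"layout {layout.name!r} defines no left/right mirror map")
    perm = layout.mirror_permutation()
    values = seq.values[:, :, perm].copy()
    values[_mirror_channel(seq, layout)] *= -1.0
    return seq.replace(values=values)


def channel_flip_augment(seq: SkeletonSequence, permutation=None) -> SkeletonSequence:
    """Permute coordinate channels (default: reverse order); label preserved."""
    c = seq.shape[0]
    perm = np.arange(c)[::-1] if permutation is None else np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(c)):
        raise ValueError(f"invalid channel permutation {perm} for C={c}")
    return seq.replace(values=seq.values[perm].copy())


def noise_augment(seq: SkeletonSequence, sd: float, seed: int = 0) -> SkeletonSequence:
    """Additive i.i.d. Gaussian jitter; sd = 0 is the identity."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return seq.replace(values=seq.values.copy())
    rng = np.random.default_rng(seed)
    return seq.replace(values=seq.values + rng.normal(0.0, sd, size=seq.shape))


def random_crop_augment(seq: SkeletonSequence, T_out: int, seed: int = 0) -> SkeletonSequence:
    """Contiguous window of T_out frames at a seeded offset; label preserved."""
    t = seq.shape[1]
    if not 2 <= T_out <= t:
        raise ValueError(f"T_out must be in [2, {t}], got {T_out}")
    offset = int(np.random.default_rng(seed).integers(0, t - T_out + 1))
    return seq.replace(values=seq.values[:, offset : offset + T_out].copy())


# -- shipped class recipes -------------------------------------------------


def default_class_specs() -> dict[str, GaitClassSpec]:
    """Nine illustrative gait phenotypes (one normal, eight pathological).

    Parameter choices encode the textbook phenomenology of each gait —
    festinating is fast and shuffling with forward lean, hemiplegic is
    strongly left/right asymmetric, ataxic is irregular (large speed drift),
    waddling rocks laterally, steppage lifts the foot high, chorea overlays
    a fast tremor — they are discriminable test material, not clinically
    validated models.
    """
    recipes = dict(
        normal=dict(cadence_hz=0.9, arm_swing=0.12, leg_swing=0.25, step_height=0.05,
                    body_sway=0.01, speed_drift=0.02),
        steppage=dict(cadence_hz=0.8, arm_swing=0.10, leg_swing=0.28, step_height=0.14,
                      body_sway=0.02, speed_drift=0.03),
        wadding=dict(cadence_hz=0.75, arm_swing=0.08, leg_swing=0.22, step_height=0.05,
                     body_sway=0.10, speed_drift=0.03),
        ataxic=dict(cadence_hz=1.0, arm_swing=0.10, leg_swing=0.24, step_height=0.06,
                    body_sway=0.06, left_right_asymmetry=0.9, speed_drift=0.25),
        scissors=dict(cadence_hz=0.6, arm_swing=0.08, leg_swing=0.15, step_height=0.03,
                      body_sway=0.04, speed_drift=0.02),
        festinating=dict(cadence_hz=1.8, arm_swing=0.04, leg_swing=0.08, step_height=0.02,
                         speed_drift=0.05, trunk_lean=0.25),
        hemiplegic=dict(cadence_hz=0.85, arm_swing=0.12, leg_swing=0.22, step_height=0.05,
                        left_right_asymmetry=0.45, speed_drift=0.03),
        chorea=dict(cadence_hz=0.95, arm_swing=0.10, leg_swing=0.22, step_height=0.05,
                    body_sway=0.05, speed_drift=0.15, tremor_hz=4.5, tremor_amplitude=0.06),
        antalgic=dict(cadence_hz=0.8, arm_swing=0.10, leg_swing=0.20, step_height=0.04,
                      left_right_asymmetry=0.7, speed_drift=0.02),
    )
    return {
        name: GaitClassSpec(class_id=k, name=name, **kw)
        for k, (name, kw) in enumerate(recipes.items())
    }


def fft_magnitude_features(seq: SkeletonSequence) -> np.ndarray:
    """Flattened magnitudes of the temporal real FFT of each joint coordinate
    (mean removed) — a simple spectral signature used in sanity checks."""
    x = seq.values - seq.values.mean(axis=1, keepdims=True)
    return np.abs(np.fft.rfft(x, axis=1, norm="ortho")).reshape(-1)
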