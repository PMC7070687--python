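"""Synthetic occlusion-experiment scenes.

Emulates the ground-truth protocol used to evaluate the correction method
without optical motion capture: a subject's wrist traverses a quarter-circle
arc of known radius in the sensor's (x, z) plane at fixed height (the arc is
enforced physically by a tape measure anchored at the circle center), while
an obstruction creates a window of frames in which the pose estimator
reports grossly wrong wrist positions.  Runs are 120 frames at 30 Hz.

A scene contains the noise-free truth (wrist + elbow, the elbow held at a
constant bone-length offset), the corrupted observation stream (Gaussian
sensor jitter everywhere, gross errors inside the occlusion window) and a
noisy sound-source bearing channel.  Everything is a deterministic function
of the seed.

The occlusion artifact itself is an emulation, not a reproduction of any
particular sensor's failure: two error modes are provided.  ``random_jump``
displaces each occluded frame by a random in-plane jump whose side
alternates frame to frame — the high-frequency vibration a pose estimator
exhibits when it loses a joint, and the direction-reversal signature the
vibration-degree classifier detects.  ``offset_toward_parent`` applies a
systematic offset toward the parent joint (the estimator collapsing the
wrist onto the forearm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .skeleton import SkeletonSequence, SkeletonTopology

__all__ = ["SceneConfig", "SyntheticScene", "generate_quarter_circle",
           "corrupt_with_occlusion"]

# Fixed unit direction from wrist to elbow (the forearm points down and away
# from the sensor); the truth elbow is wrist + bone_length * this.
_ELBOW_DIRECTION = np.array([0.0, -0.6, 0.8])


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic quarter-circle occlusion run.

    Defaults describe the reference condition: a 120-frame (4 s) run at
    30 Hz, arc radius 0.5 m centered 2.5 m from the sensor, wrist at 0.8 m
    height, a 0.25 m forearm, per-axis sensor jitter of 0.004 m (so the
    stationary displacement-vector scale is ~0.01 m), and a 30-frame (1 s)
    occlusion window in which observations deviate by 0.2 m.
    """

    seed: int = 0
    n_frames: int = 120
    frame_rate: float = 30.0
    radius: float = 0.5
    center: tuple[float, float] = (0.0, 2.5)   # (x, z) of the arc center
    y_level: float = 0.8
    bone_length: float = 0.25
    jitter_sigma: float = 0.004
    occlusion_window: tuple[int, int] = (45, 75)  # half-open [start, end)
    error_magnitude: float = 0.2
    error_mode: str = "random_jump"            # or "offset_toward_parent"
    angle_noise_sigma: float = 2.0             # degrees
    elbow_jitter: bool = False

    def __post_init__(self) -> None:
        start, end = self.occlusion_window
        if not (0 <= start <= end <= self.n_frames):
            raise ValidationError(
                f"occlusion window {self.occlusion_window} must satisfy "
                f"0 <= start <= end <= n_frames={self.n_frames}")
        if self.n_frames < 1 or self.radius <= 0 or self.bone_length <= 0:
            raise ValidationError("n_frames, radius and bone_length must be positive")
        if min(self.jitter_sigma, self.error_magnitude, self.angle_noise_sigma) < 0:
            raise ValidationError("noise magnitudes must be >= 0")
        if self.error_mode not in ("random_jump", "offset_toward_parent"):
            raise ValidationError(f"unknown error_mode {self.error_mode!r}")


@dataclass
class SyntheticScene:
    """Ground truth, corrupted observations and the generating configuration."""

    truth: SkeletonSequence
    observed: SkeletonSequence
    config: SceneConfig

    def topology(self) -> SkeletonTopology:
        """Two-joint elbow->wrist chain with the configured bone length."""
        return SkeletonTopology(
            joints=("elbow", "wrist"),
            parent={"elbow": "elbow", "wrist": "elbow"},
            bone_length={"wrist": self.config.bone_length})


def _truth_positions(config: SceneConfig) -> np.ndarray:
    """(n, 2, 3) noise-free elbow and wrist positions (joint order elbow, wrist)."""
    n = config.n_frames
    cx, cz = config.center
    # quarter arc at constant angular speed, symmetric about the sensor axis
    alpha = np.linspace(-np.pi / 4.0, np.pi / 4.0, n)
    wrist = np.empty((n, 3))
    wrist[:, 0] = cx + config.radius * np.sin(alpha)
    wrist[:, 1] = config.y_level
    wrist[:, 2] = cz - config.radius * np.cos(alpha)
    elbow = wrist + config.bone_length * _ELBOW_DIRECTION
    return np.stack([elbow, wrist], axis=1)


def corrupt_with_occlusion(truth: SkeletonSequence, config: SceneConfig,
                           rng: np.random.Generator | None = None) -> SkeletonSequence:
    """Add sensor jitter everywhere and gross wrist errors inside the window.

    Outside the occlusion window the observed wrist is truth plus i.i.d.
    Gaussian jitter; inside it an additional gross error of magnitude
    ``error_magnitude`` is applied per frame — an in-plane random jump
    oscillating from side to side (tracking-failure vibration), or a fixed
    offset toward the elbow.  The elbow receives jitter only if
    ``elbow_jitter`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    start, end = config.occlusion_window
    if end > truth.frame_count:
        raise ValidationError("occlusion window exceeds the sequence length")
    pos = truth.positions.copy()
    ei = truth.joints.index("elbow")
    wi = truth.joints.index("wrist")
    n = truth.frame_count
    pos[:, wi] += rng.normal(0.0, config.jitter_sigma, size=(n, 3))
    if config.elbow_jitter:
        pos[:, ei] += rng.normal(0.0, config.jitter_sigma, size=(n, 3))
    if end > start and config.error_magnitude > 0:
        m = end - start
        if config.error_mode == "random_jump":
            # random in-plane jump axis per window, perturbed per frame, with
            # alternating sign: a high-frequency oscillation about the truth
            phi = (rng.uniform(0.0, 2.0 * np.pi)
                   + rng.normal(0.0, np.radians(25.0), size=m))
            sign = (-1.0) ** np.arange(m)
            jump = np.zeros((m, 3))
            jump[:, 0] = sign * np.cos(phi)
            jump[:, 2] = sign * np.sin(phi)
            pos[start:end, wi] += config.error_magnitude * jump
        else:  # offset_toward_parent
            toward = truth.positions[start:end, ei] - truth.positions[start:end, wi]
            toward /= np.linalg.norm(toward, axis=1, keepdims=True)
            pos[start:end, wi] += config.error_magnitude * toward
    return SkeletonSequence(truth.joints, pos, truth.frame_rate,
                            None if truth.sound_angle is None
                            else truth.sound_angle.copy())


def generate_quarter_circle(config: SceneConfig | None = None) -> SyntheticScene:
    """Generate a complete quarter-circle occlusion scene from its config."""
    config = config or SceneConfig()
    rng = np.random.default_rng(config.seed)
    pos = _truth_positions(config)
    truth = SkeletonSequence(("elbow", "wrist"), pos, config.frame_rate)
    observed = corrupt_with_occlusion(truth, config, rng)
    # sound-source bearing of the true wrist, with microphone-array noise
    bearing = np.arctan2(pos[:, 1, 0], pos[:, 1, 2])
    noise = rng.normal(0.0, np.radians(config.angle_noise_sigma), size=config.n_frames)
    observed.sound_angle = bearing + noise
    truth.sound_angle = bearing.copy()
    return SyntheticScene(truth=truth, observed=observed, config=config)
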