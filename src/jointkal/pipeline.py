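"""End-to-end correction pipeline.

Per joint: (1) compute the vibration-degree reliability trace and classify
every frame as noise or erroneous; (2) run the extended Kalman filter over
the frames — noise frames receive the normal predict/update cycle (with the
sound-bearing channel when available), erroneous frames are advanced by
prediction only and projected onto the bone sphere around the (already
processed) parent joint.  Joints are processed root-to-leaf so a corrected
parent can anchor its children's constraint; an erroneous root frame keeps
the unconstrained prediction.

Processing is batch: the reliability of a frame needs the following frame's
displacement, so the whole sequence is classified before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _version
from .correction import DEFAULT_COV_CAP, correct_erroneous_frame
from .errors import ConfigurationError, DegenerateDirectionError
from .filters import (FilterModel, FilterState, Measurement, ekf_smooth,
                      linear_kalman_filter, moving_mean_filter, predict, update)
from .reliability import (DEFAULT_THRESHOLD, FrameClassification,
                          ReliabilityParams, ReliabilityTrace, classify_frames,
                          reliability_trace)
from .skeleton import SkeletonSequence, SkeletonTopology

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_baselines"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself."""

    reliability: ReliabilityParams = field(default_factory=ReliabilityParams)
    threshold: float = DEFAULT_THRESHOLD
    filter_model: FilterModel = field(default_factory=FilterModel)
    use_sound_angle: bool = True
    moving_mean_window: int = 5
    cov_cap: float = DEFAULT_COV_CAP
    baselines: tuple[str, ...] = ("moving_mean", "kalman")

    def __post_init__(self) -> None:
        if not (0 < self.threshold < 1):
            raise ConfigurationError("threshold must lie in (0, 1)")


@dataclass
class PipelineResult:
    """Corrected sequence plus per-joint diagnostics and provenance."""

    corrected: SkeletonSequence
    classification: dict[str, FrameClassification]
    trace: dict[str, ReliabilityTrace]
    provenance: dict


def _filter_joint(traj: np.ndarray, angles: np.ndarray | None,
                  erroneous: np.ndarray, parent_traj: np.ndarray | None,
                  bone_length: float | None, cfg: PipelineConfig) -> np.ndarray:
    """EKF over one joint with constraint correction on erroneous frames."""
    model = cfg.filter_model
    n = traj.shape[0]
    finite = np.isfinite(traj).all(axis=1)
    first = int(np.argmax(finite)) if finite.any() else 0
    if not finite.any():
        raise ConfigurationError("joint has no finite positions at all")
    state = model.initial_state(traj[first])
    out = np.empty_like(traj)
    last_direction: np.ndarray | None = None
    for f in range(n):
        if erroneous[f] and parent_traj is not None and bone_length is not None:
            parent = parent_traj[f]
            try:
                _, state = correct_erroneous_frame(state, model, parent,
                                                   bone_length, cfg.cov_cap)
            except DegenerateDirectionError:
                # prediction sits on the parent: reuse the last valid bone
                # direction, or hold the unconstrained prediction
                pred = predict(state, model)
                x = pred.x.copy()
                if last_direction is not None:
                    x[:3] = parent + bone_length * last_direction
                state = FilterState(x=x, P=pred.P)
            direction = state.position - parent
            nrm = float(np.linalg.norm(direction))
            if nrm > 1e-12:
                last_direction = direction / nrm
        elif erroneous[f]:
            # root joint (or unconstrained): keep the prediction
            state = predict(state, model)
        else:
            angle = None
            if angles is not None and np.isfinite(angles[f]):
                angle = float(angles[f])
            state = update(predict(state, model), Measurement(traj[f], angle), model)
        out[f] = state.position
    return out


def run_pipeline(seq: SkeletonSequence, topo: SkeletonTopology,
                 cfg: PipelineConfig | None = None) -> PipelineResult:
    """Classify, smooth and correct every joint of a sequence.

    Joints are processed in topological (root-to-leaf) order; the corrected
    trajectory of a parent serves as the sphere center for its erroneous
    children.  A non-root joint with erroneous frames but no configured
    bone length raises :class:`ConfigurationError`.
    """
    cfg = cfg or PipelineConfig()
    if seq.frame_count < 3:
        raise ConfigurationError("pipeline needs at least 3 frames")
    missing = set(seq.joints) - set(topo.joints)
    if missing:
        raise ConfigurationError(f"sequence joints {sorted(missing)} absent from topology")
    angles = seq.sound_angle if cfg.use_sound_angle else None
    traces: dict[str, ReliabilityTrace] = {}
    classes: dict[str, FrameClassification] = {}
    corrected: dict[str, np.ndarray] = {}
    for joint in topo.topological_order():
        if joint not in seq.joints:
            continue
        traj = seq.joint(joint)
        trace = reliability_trace(traj, cfg.reliability)
        cls = classify_frames(trace, cfg.threshold)
        traces[joint] = trace
        classes[joint] = cls
        parent = topo.parent[joint]
        is_root = parent == joint
        parent_traj = None
        bone_length = None
        if not is_root and cls.erroneous.any():
            bone_length = topo.bone_length.get(joint)
            if bone_length is None:
                raise ConfigurationError(
                    f"joint {joint!r} has erroneous frames but no bone length configured")
            if parent in corrected:
                parent_traj = corrected[parent]
            elif parent in seq.joints:
                parent_traj = seq.joint(parent)
            else:
                raise ConfigurationError(
                    f"parent {parent!r} of erroneous joint {joint!r} is not in the sequence")
        corrected[joint] = _filter_joint(traj, angles, cls.erroneous,
                                         parent_traj, bone_length, cfg)
    out = np.stack([corrected[j] for j in seq.joints], axis=1)
    result_seq = SkeletonSequence(seq.joints, out, seq.frame_rate,
                                  None if seq.sound_angle is None
                                  else seq.sound_angle.copy())
    provenance = {
        "jointkal_version": _version,
        "threshold": cfg.threshold,
        "reliability": {"d_min": cfg.reliability.d_min,
                        "theta_min": cfg.reliability.theta_min,
                        "theta_max": cfg.reliability.theta_max},
        "filter": {"dt": cfg.filter_model.dt, "sigma_a": cfg.filter_model.sigma_a,
                   "sigma_p": cfg.filter_model.sigma_p,
                   "sigma_theta_deg": cfg.filter_model.sigma_theta_deg},
        "use_sound_angle": cfg.use_sound_angle,
    }
    return PipelineResult(corrected=result_seq, classification=classes,
                          trace=traces, provenance=provenance)


def run_baselines(seq: SkeletonSequence,
                  cfg: PipelineConfig | None = None) -> dict[str, SkeletonSequence]:
    """Apply each enabled comparison baseline independently to the raw sequence.

    Supported baselines: ``moving_mean`` (centered moving average) and
    ``kalman`` (traditional linear position-only Kalman filter).
    """
    cfg = cfg or PipelineConfig()
    out: dict[str, SkeletonSequence] = {}
    for name in cfg.baselines:
        filtered = np.empty_like(seq.positions)
        for k in range(len(seq.joints)):
            traj = seq.positions[:, k, :]
            if name == "moving_mean":
                filtered[:, k, :] = moving_mean_filter(traj, cfg.moving_mean_window)
            elif name == "kalman":
                filtered[:, k, :] = linear_kalman_filter(traj, cfg.filter_model)
            else:
                raise ConfigurationError(f"unknown baseline {name!r}")
        out[name] = seq.with_positions(filtered)
    return out
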