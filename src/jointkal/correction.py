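"""Bone-length-constrained correction of erroneous frames.

A frame flagged erroneous carries no usable position observation: the
corrector discards it, advances the joint's Kalman state by prediction only
(the motion trend), and projects the predicted position onto the sphere of
radius l_AB (the constant bone length) centered at the trusted parent joint
A.  Of the two intersections of the sphere with the line through A and the
prediction P~, the one nearer P~ is taken, which reduces to the radial
rescaling B^ = A + l_AB * (P~ - A)/||P~ - A||.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDirectionError, ValidationError
from .filters import FilterModel, FilterState, predict

__all__ = ["CorrectionInput", "project_to_bone_sphere", "correct_erroneous_frame"]

#: Cap on the predicted position variance (m^2) during long runs of
#: consecutive erroneous frames, to keep the covariance from diverging.
DEFAULT_COV_CAP = 1.0


@dataclass(frozen=True)
class CorrectionInput:
    """Estimate P~, parent position A, and bone length l_AB for one frame."""

    estimate: np.ndarray
    parent: np.ndarray
    bone_length: float

    def __post_init__(self) -> None:
        if not self.bone_length > 0:
            raise ValidationError("bone_length must be > 0")


def project_to_bone_sphere(inp: CorrectionInput) -> np.ndarray:
    """Nearest point to the estimate on the bone sphere around the parent.

    The line through A and P~ meets the sphere ||B - A|| = l at
    A ± l * u where u = (P~ - A)/||P~ - A||; the '+' solution is always the
    nearer to P~, giving B^ = A + l * u.
    """
    estimate = np.asarray(inp.estimate, dtype=float)
    parent = np.asarray(inp.parent, dtype=float)
    v = estimate - parent
    norm = float(np.linalg.norm(v))
    if not np.isfinite(norm) or norm < 1e-12:
        raise DegenerateDirectionError(
            "estimate coincides with the parent joint; projection direction undefined")
    return parent + inp.bone_length * (v / norm)


def correct_erroneous_frame(state: FilterState, model: FilterModel,
                            parent_pos: np.ndarray, bone_length: float,
                            cov_cap: float = DEFAULT_COV_CAP
                            ) -> tuple[np.ndarray, FilterState]:
    """Prediction-only step followed by bone-sphere projection.

    The erroneous observation is never used: the state is advanced with the
    time update alone, the predicted position is projected onto the bone
    sphere around ``parent_pos``, and the filter's position is overwritten
    with the projected point while the predicted velocity is retained.  The
    covariance keeps its (inflated) predicted value, rescaled if its
    largest position variance exceeds ``cov_cap``.

    Returns the corrected 3-D point and the updated state.
    """
    pred = predict(state, model)
    corrected = project_to_bone_sphere(
        CorrectionInput(estimate=pred.position, parent=parent_pos,
                        bone_length=bone_length))
    x = pred.x.copy()
    x[:3] = corrected
    P = pred.P
    peak = float(np.max(np.diag(P)[:3]))
    if peak > cov_cap:
        P = P * (cov_cap / peak)
    return corrected, FilterState(x=x, P=P)
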