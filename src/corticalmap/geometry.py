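"""Shaft axis, two-step diaphysis cropping, and shaft bone volume.

The long axis is the first principal direction of the periosteal vertex
cloud, sign-oriented so LM1 projects proximal of LM2.  Cropping first
keeps material between the planes through the two landmarks orthogonal
to that axis, then removes a proximal and a distal margin (fractions of
the landmark-to-landmark axial span; defaults 10% and 5%).  Shaft volume
caps the cut boundary rings with planar fans and integrates the closed
surface, so the medullary cavity is included (the endosteum plays no
role in the volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from trimesh.intersections import slice_mesh_plane

from ._mesh import cap_boundary_loops
from .errors import AxisError, CropError, ParameterError, VolumeError
from .io import LandmarkSet, SurfacePair

__all__ = ["ShaftAxis", "DiaphysisSegment", "fit_long_axis", "crop_diaphysis",
           "shaft_volume"]

DEFAULT_MARGINS = (0.10, 0.05)

#: minimum anisotropy (first / second singular value) for a defined axis
_MIN_ELONGATION = 1.5


@dataclass
class ShaftAxis:
    """Oriented long axis of the diaphysis (proximal -> distal)."""

    origin: np.ndarray
    direction: np.ndarray
    s_min: float
    s_max: float

    def project(self, points: np.ndarray) -> np.ndarray:
        """Axial coordinate (mm along direction) of each point."""
        return np.atleast_2d(points - self.origin) @ self.direction

    @property
    def span(self) -> float:
        return self.s_max - self.s_min


@dataclass
class DiaphysisSegment:
    """Cropped surface pair plus the axis and crop provenance."""

    pair: SurfacePair
    axis: ShaftAxis
    margins: tuple
    landmarks: LandmarkSet

    def report(self) -> dict:
        return {
            "specimen_id": self.pair.specimen_id,
            "axis_direction": self.axis.direction.tolist(),
            "axial_span_mm": [float(self.axis.s_min), float(self.axis.s_max)],
            "margins": list(self.margins),
        }


def fit_long_axis(pair: SurfacePair, landmarks: LandmarkSet) -> ShaftAxis:
    """First principal direction of the periosteal vertices, LM-oriented.

    PCA is robust to landmark placement noise; the landmarks fix only the
    proximal->distal sign.  A near-isotropic vertex cloud (no dominant
    direction) raises AxisError.
    """
    verts = pair.periosteum.vertices
    centroid = verts.mean(axis=0)
    centered = verts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 0 or s[0] / s[1] < _MIN_ELONGATION:
        raise AxisError(
            f"vertex cloud too isotropic for an axis (elongation "
            f"{s[0] / max(s[1], 1e-30):.2f} < {_MIN_ELONGATION})")
    direction = vt[0]
    if (landmarks.lm1 - centroid) @ direction > (landmarks.lm2 - centroid) @ direction:
        direction = -direction
    s_axis = centered @ direction
    return ShaftAxis(origin=centroid, direction=direction,
                     s_min=float(s_axis.min()), s_max=float(s_axis.max()))


def _slice_between(mesh: trimesh.Trimesh, axis: ShaftAxis,
                   lo: float, hi: float) -> trimesh.Trimesh:
    out = slice_mesh_plane(mesh, plane_normal=axis.direction,
                           plane_origin=axis.origin + lo * axis.direction,
                           cap=False)
    out = slice_mesh_plane(out, plane_normal=-axis.direction,
                           plane_origin=axis.origin + hi * axis.direction,
                           cap=False)
    return out


def crop_diaphysis(pair: SurfacePair, landmarks: LandmarkSet,
                   margins: tuple = DEFAULT_MARGINS) -> DiaphysisSegment:
    """Two-step crop to the diaphysis proper.

    Step 1 keeps material between the planes through LM1 and LM2 orthogonal
    to the long axis (a cylinder that still carries metaphyseal flaring at
    its ends).  Step 2 trims ``margins[0]`` of the step-1 axial span on the
    proximal side and ``margins[1]`` on the distal side.  The cut leaves
    open boundary rings; they are capped only inside :func:`shaft_volume`.
    """
    mp, md = margins
    if mp < 0 or md < 0 or mp + md >= 1.0:
        raise ParameterError(
            f"margins must be nonnegative and sum below 1, got {margins}")
    axis = fit_long_axis(pair, landmarks)
    s1 = float(axis.project(landmarks.lm1[None])[0])
    s2 = float(axis.project(landmarks.lm2[None])[0])
    if not (axis.s_min - 1e-9 <= s1 <= axis.s_max + 1e-9
            and axis.s_min - 1e-9 <= s2 <= axis.s_max + 1e-9):
        raise CropError("landmarks project outside the bone's axial extent")
    span = s2 - s1
    lo = s1 + mp * span
    hi = s2 - md * span
    if hi <= lo:
        raise CropError("margins leave an empty axial window")
    peri = _slice_between(pair.periosteum, axis, lo, hi)
    endo = _slice_between(pair.endosteum, axis, lo, hi)
    if len(peri.vertices) == 0:
        raise CropError("cropping produced an empty periosteum")
    cropped = SurfacePair(peri, endo, specimen_id=pair.specimen_id)
    seg_axis = ShaftAxis(origin=axis.origin, direction=axis.direction,
                         s_min=lo, s_max=hi)
    return DiaphysisSegment(pair=cropped, axis=seg_axis, margins=(mp, md),
                            landmarks=landmarks)


def shaft_volume(segment: DiaphysisSegment) -> float:
    """Total volume (cm^3) enclosed by the cropped periosteum, medulla included.

    The two planar cut rings are closed with triangle fans about their
    centroids and the volume of the resulting closed surface is computed by
    the divergence theorem.
    """
    peri = segment.pair.periosteum
    if len(peri.vertices) == 0:
        raise VolumeError("empty cropped periosteum")
    capped = cap_boundary_loops(peri)
    if not capped.is_watertight:
        raise VolumeError(
            "cropped periosteum boundary is non-manifold; cannot cap")
    return float(capped.volume) / 1000.0
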