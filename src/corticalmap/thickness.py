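"""Cortical thickness on the cropped periosteum and cylindrical unrolling.

Thickness at each periosteal vertex is the exact minimal distance to the
endosteal surface (point-to-triangle, not nearest-vertex).  Unrolling
parameterizes each vertex by its normalized axial position x and its
azimuth y about the shaft axis, measured from the meridian through LM1
(the cut line); for left bones the azimuth is mirrored so maps are
comparable irrespective of laterality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mesh import min_distance_to_surface
from .errors import CutLineError, ParameterError
from .geometry import DiaphysisSegment
from .io import LandmarkSet

__all__ = ["ThicknessCloud", "cortical_thickness", "unroll"]


@dataclass
class ThicknessCloud:
    """Scattered unrolled points for one specimen.

    x: axial fraction in [0, 1] (proximal -> distal);
    y: circumferential fraction in [0, 1) from the LM1 cut line;
    z: cortical thickness, in mm or min-max standardized.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    specimen_id: str = ""
    laterality: str = "right"
    standardized: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if not (self.x.shape == self.y.shape == self.z.shape):
            raise ParameterError("x, y, z must have identical shapes")
        if self.x.min() < -1e-9 or self.x.max() > 1 + 1e-9:
            raise ParameterError("x must lie in [0, 1]")
        if self.y.min() < -1e-9 or self.y.max() >= 1 + 1e-9:
            raise ParameterError("y must lie in [0, 1)")

    def __len__(self):
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z": self.z})

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


def cortical_thickness(segment: DiaphysisSegment) -> np.ndarray:
    """Exact distance from each periosteal vertex to the endosteal surface."""
    endo = segment.pair.endosteum
    if len(endo.faces) == 0:
        raise ParameterError("segment has an empty endosteum")
    d = min_distance_to_surface(segment.pair.periosteum.vertices, endo)
    n_zero = int(np.sum(d <= 0))
    if n_zero:
        warnings.warn(f"{n_zero} periosteal vertices touch the endosteum "
                      "(thickness 0 retained)")
    return d


def unroll(segment: DiaphysisSegment, thickness: np.ndarray,
           landmarks: LandmarkSet | None = None) -> ThicknessCloud:
    """Project the cropped periosteum onto normalized cylinder coordinates.

    x is the axial coordinate rescaled to [0, 1] over the kept span; y is
    the azimuth about the shaft axis (fraction of a turn) anchored at the
    meridian through LM1's radial projection.  Right bones use the
    right-handed azimuth about the proximal->distal direction; left bones
    are mirrored (y -> 1 - y) so left and right yield comparable maps.
    """
    landmarks = landmarks or segment.landmarks
    axis = segment.axis
    verts = segment.pair.periosteum.vertices
    thickness = np.asarray(thickness, dtype=float)
    if len(thickness) != len(verts):
        raise ParameterError("thickness must be per periosteal vertex")

    s = axis.project(verts)
    x = np.clip((s - axis.s_min) / axis.span, 0.0, 1.0)

    d = axis.direction
    v1 = landmarks.lm1 - axis.origin
    v1_perp = v1 - (v1 @ d) * d
    r1 = np.linalg.norm(v1_perp)
    if r1 < 1e-9:
        raise CutLineError("LM1 projects onto the axis; cut line undefined")
    e1 = v1_perp / r1
    e2 = np.cross(d, e1)

    w = verts - axis.origin
    y = np.arctan2(w @ e2, w @ e1) / (2.0 * np.pi) % 1.0
    if landmarks.laterality == "left":
        y = (1.0 - y) % 1.0
    return ThicknessCloud(x=x, y=y, z=thickness,
                          specimen_id=segment.pair.specimen_id,
                          laterality=landmarks.laterality)
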