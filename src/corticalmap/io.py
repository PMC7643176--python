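"""Reading, writing and validating the pipeline's inputs.

Surface pairs (periosteum + endosteum) as PLY/STL/OFF via trimesh,
landmark and specimen/muscle tables as CSV, CT-like volumes as raw +
JSON sidecar, and midpoint-threshold segmentation of a volume into a
nested surface pair.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
from skimage import measure

from ._mesh import contains_points
from .errors import FormatError, ParameterError, SchemaError, SegmentationError

log = logging.getLogger(__name__)

MUSCLES = ("ANC", "BRA", "COR", "ECR", "PEC")
#: grouping factors used in the reference study design
KNOWN_GROUPS = ("WB_ctrl", "WB_stall", "WB_pen", "WB_wc",
                "PIG_Land", "PIG_Cor", "PIG_Improv")

METADATA_COLUMNS = ("specimen_id", "group", "sex", "age_months", "body_mass_kg")
MUSCLE_COLUMNS = ("specimen_id", "muscle", "mass_g", "fascicle_length_cm")
LANDMARK_COLUMNS = ("specimen_id", "lm1_x", "lm1_y", "lm1_z",
                    "lm2_x", "lm2_y", "lm2_z", "laterality",
                    "periosteum_path", "endosteum_path")


@dataclass
class LandmarkSet:
    """Two anatomical landmarks anchoring the crop and the cut line.

    lm1 sits on the periosteal surface at the proximal limit (extremity of
    the teres minor tuberosity in the humerus); lm2 is an internal landmark
    at the distal limit (distal fork of the medullary cavity).
    """

    lm1: np.ndarray
    lm2: np.ndarray
    laterality: str = "right"

    def __post_init__(self):
        self.lm1 = np.asarray(self.lm1, dtype=float)
        self.lm2 = np.asarray(self.lm2, dtype=float)
        if self.lm1.shape != (3,) or self.lm2.shape != (3,):
            raise ParameterError("landmarks must be 3D points")
        if not (np.all(np.isfinite(self.lm1)) and np.all(np.isfinite(self.lm2))):
            raise ParameterError("landmarks must be finite")
        if np.allclose(self.lm1, self.lm2):
            raise ParameterError("LM1 and LM2 must be distinct points")
        if self.laterality not in ("left", "right"):
            raise ParameterError(
                f"laterality must be 'left' or 'right', got {self.laterality!r}")


@dataclass
class SurfacePair:
    """Closed periosteal and endosteal triangle meshes of one bone (mm)."""

    periosteum: trimesh.Trimesh
    endosteum: trimesh.Trimesh
    specimen_id: str = ""

    def __post_init__(self):
        # the nesting invariant is only well-defined for closed surfaces
        if not (self.periosteum.is_watertight and self.endosteum.is_watertight):
            return
        if abs(self.endosteum.volume) >= abs(self.periosteum.volume):
            raise ParameterError(
                "endosteum volume must be smaller than periosteum volume "
                f"({abs(self.endosteum.volume):.1f} >= "
                f"{abs(self.periosteum.volume):.1f} mm^3)")

    def audit(self) -> dict:
        """Mesh-quality report; open meshes are flagged, not fatal."""
        report = {}
        for name, mesh in (("periosteum", self.periosteum),
                           ("endosteum", self.endosteum)):
            report[name] = {
                "watertight": bool(mesh.is_watertight),
                "winding_consistent": bool(mesh.is_winding_consistent),
                "euler_number": int(mesh.euler_number),
                "n_vertices": int(len(mesh.vertices)),
                "volume_mm3": float(mesh.volume),
            }
            if not mesh.is_watertight:
                warnings.warn(f"{name} mesh of {self.specimen_id!r} is not "
                              "watertight; downstream distances remain defined")
        return report


def _load_mesh(path) -> trimesh.Trimesh:
    try:
        # process=True welds duplicated vertices (STL stores de-indexed
        # triangles) so topology audits see the true surface
        mesh = trimesh.load(str(path), force="mesh", process=True)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise FormatError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path} does not contain a triangle mesh")
    return mesh


def read_surface_pair(path_periosteum, path_endosteum,
                      specimen_id: str = "") -> SurfacePair:
    """Load a periosteum/endosteum pair from PLY/STL/OFF files (units mm)."""
    pair = SurfacePair(_load_mesh(path_periosteum), _load_mesh(path_endosteum),
                       specimen_id=specimen_id or Path(path_periosteum).stem)
    pair.audit()
    return pair


def write_surface_pair(pair: SurfacePair, path_periosteum, path_endosteum):
    pair.periosteum.export(str(path_periosteum))
    pair.endosteum.export(str(path_endosteum))


# ---------------------------------------------------------------------------
# volumes


def save_volume(data: np.ndarray, voxel_size: float, prefix):
    """Write a volume as float32 raw + JSON sidecar (shape, dtype, voxel mm)."""
    prefix = Path(prefix)
    arr = np.ascontiguousarray(data, dtype=np.float32)
    arr.tofile(prefix.with_suffix(".raw"))
    sidecar = {"shape": list(arr.shape), "dtype": "float32",
               "voxel_size_mm": float(voxel_size), "order": "C"}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_volume(prefix):
    prefix = Path(prefix)
    try:
        sidecar = json.loads(prefix.with_suffix(".json").read_text())
        arr = np.fromfile(prefix.with_suffix(".raw"),
                          dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"could not read volume {prefix}: {exc}") from exc
    return arr, float(sidecar["voxel_size_mm"])


def segmentation_threshold(volume: np.ndarray) -> float:
    """Midpoint between the extreme intensities (bone max, air min)."""
    vol = np.asarray(volume)
    return float((vol.max() + vol.min()) / 2.0)


def segment_volume(volume: np.ndarray, voxel_size: float,
                   specimen_id: str = "") -> SurfacePair:
    """Threshold segmentation of a voxel volume into a nested surface pair.

    The iso-level is the midpoint of the extreme intensities; marching
    cubes extracts the iso-surface, whose connected components are sorted
    into the outer (periosteal) surface and the largest fully enclosed
    cavity (endosteal) surface.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.max() == vol.min():
        raise SegmentationError("volume has no intensity contrast")
    level = segmentation_threshold(vol)
    verts, faces, _, _ = measure.marching_cubes(
        vol, level=level, spacing=(voxel_size,) * 3)
    surface = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    components = surface.split(only_watertight=False)
    if len(components) < 2:
        raise SegmentationError(
            "no enclosed cavity found: iso-surface has a single component")
    components = sorted(components, key=lambda c: abs(c.volume), reverse=True)
    outer = components[0]
    if outer.volume < 0:
        outer.invert()
    cavities = [c for c in components[1:]
                if contains_points(outer, c.centroid[None])[0]]
    if not cavities:
        raise SegmentationError("no component is enclosed by the outer surface")
    if len(cavities) > 1:
        log.warning("%d enclosed cavities found; keeping the largest",
                    len(cavities))
    endo = cavities[0]
    if endo.volume < 0:
        endo.invert()
    return SurfacePair(outer, endo, specimen_id=specimen_id)


# ---------------------------------------------------------------------------
# tables


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): "
                          + ", ".join(missing))


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the specimen metadata table (CSV, UTF-8)."""
    df = pd.read_csv(path)
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, METADATA_COLUMNS, "metadata")
    dup = df["specimen_id"][df["specimen_id"].duplicated()].tolist()
    if dup:
        raise SchemaError("duplicated specimen_id: " + ", ".join(map(str, dup)))
    if df["group"].isna().any() or (df["group"].astype(str) == "").any():
        raise SchemaError("group must be nonempty for every specimen")
    if (df["age_months"] <= 0).any():
        raise SchemaError("age_months must be positive")
    mass = df["body_mass_kg"].dropna()
    if (mass <= 0).any():
        raise SchemaError("body_mass_kg must be positive when present")
    bad_sex = set(df["sex"].dropna()) - {"M", "F"}
    if bad_sex:
        raise SchemaError(f"sex must be M or F, got {sorted(bad_sex)}")
    unknown = sorted(set(df["group"]) - set(KNOWN_GROUPS))
    if unknown:
        log.info("user-defined group labels: %s", ", ".join(unknown))
    return df


def read_landmarks(path) -> pd.DataFrame:
    """Read the per-specimen landmark/mesh manifest table."""
    df = pd.read_csv(path)
    _require_columns(df, LANDMARK_COLUMNS, "landmark")
    bad = set(df["laterality"]) - {"left", "right"}
    if bad:
        raise SchemaError(f"laterality must be left/right, got {sorted(bad)}")
    return df


def landmark_row_to_set(row) -> LandmarkSet:
    return LandmarkSet(
        np.array([row["lm1_x"], row["lm1_y"], row["lm1_z"]], dtype=float),
        np.array([row["lm2_x"], row["lm2_y"], row["lm2_z"]], dtype=float),
        laterality=row["laterality"])


def read_muscles(path) -> pd.DataFrame:
    """Read and validate the muscle table (mass in g, fascicle length in cm)."""
    df = pd.read_csv(path)
    _require_columns(df, MUSCLE_COLUMNS, "muscle")
    bad = sorted(set(df["muscle"]) - set(MUSCLES))
    if bad:
        raise SchemaError(f"unknown muscle code(s): {bad}; expected {MUSCLES}")
    if (df["mass_g"] <= 0).any():
        raise SchemaError("mass_g must be positive")
    if (df["fascicle_length_cm"] <= 0).any():
        raise SchemaError("fascicle_length_cm must be positive")
    return df
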