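"""Parametric hollow-diaphysis phantoms and synthetic cohorts.

A specimen is a tube whose wall thickness is an analytic field
``base_wall + sum of periodic Gaussian bumps`` (the bumps emulate
localized entheseal thickenings).  The endosteum is the periosteum
offset inward along the local radial direction, so the radial wall
thickness is known exactly everywhere and serves as the oracle for the
whole measurement pipeline.  Cohorts plant group effects, sexual
dimorphism, and trait-map covariation at the bump-amplitude level, so
per-specimen analytic truth stays available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from .errors import ParameterError, ResolutionError
from .io import MUSCLES, LandmarkSet, SurfacePair

__all__ = [
    "Bump", "TubeSpec", "make_tube_specimen", "make_ct_volume",
    "BumpSite", "GroupSpec", "CohortDesign", "Cohort", "make_cohort",
    "analytic_maps", "wall_thickness_field", "segment_axial_window",
    "simulate_volume_mass_cohort", "mirror_specimen",
    "ANCHOR_SITE", "EFFECT_SITE", "null_design", "group_difference_design",
    "trait_loading_design", "site_field",
]


@dataclass(frozen=True)
class Bump:
    """One Gaussian thickening of the wall, periodic in the angular coordinate.

    Positions and widths are dimensionless fractions of tube length /
    circumference; amplitude is in mm (negative = local thinning).
    """

    axial_fraction: float
    angle_fraction: float
    amplitude: float
    sigma_axial: float = 0.08
    sigma_angular: float = 0.06


@dataclass(frozen=True)
class TubeSpec:
    """Geometry of one synthetic hollow diaphysis (all lengths in mm).

    ``waist`` smoothly narrows the outer radius toward mid-shaft
    (R(x) = outer_radius * (1 - 4*waist*x*(1-x))), exercising the
    non-cylindrical case; 0 gives a perfect cylinder.
    """

    length: float = 120.0
    outer_radius: float = 10.0
    base_wall: float = 3.0
    bumps: tuple = ()
    waist: float = 0.0
    axial_resolution: int = 120
    angular_resolution: int = 64
    laterality: str = "right"
    landmark_axial_fractions: tuple = (0.05, 0.95)

    def __post_init__(self):
        if self.base_wall <= 0:
            raise ParameterError("violated constraint: base_wall > 0")
        if self.length <= 0 or self.outer_radius <= 0:
            raise ParameterError("violated constraint: length, outer_radius > 0")
        neg = sum(min(0.0, b.amplitude) for b in self.bumps)
        if self.base_wall + neg <= 0:
            raise ParameterError(
                "violated constraint: base_wall + sum of negative bump "
                "amplitudes > 0 (endosteum would cross periosteum)")
        amax = max((b.amplitude for b in self.bumps), default=0.0)
        r_min = self.outer_radius * (1.0 - max(0.0, self.waist))
        if r_min <= self.base_wall + max(0.0, amax):
            raise ParameterError(
                "violated constraint: outer_radius > base_wall + max bump "
                "amplitude (endosteal radius would vanish)")
        if self.axial_resolution < 8 or self.angular_resolution < 8:
            raise ParameterError("violated constraint: resolutions >= 8")
        if self.laterality not in ("left", "right"):
            raise ParameterError("violated constraint: laterality in {left, right}")
        f1, f2 = self.landmark_axial_fractions
        if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0) or f1 == f2:
            raise ParameterError(
                "violated constraint: landmark fractions distinct, in [0, 1]")
        for b in self.bumps:
            if b.sigma_axial <= 0 or b.sigma_angular <= 0:
                raise ParameterError("violated constraint: bump sigmas > 0")

    # -- analytic truth -----------------------------------------------------

    def outer_radius_at(self, axial_fraction):
        xf = np.asarray(axial_fraction, dtype=float)
        return self.outer_radius * (1.0 - 4.0 * self.waist * xf * (1.0 - xf))

    def wall_at(self, axial_fraction, angle_fraction):
        """Exact wall thickness (mm) at fractional coordinates."""
        xf = np.asarray(axial_fraction, dtype=float)
        af = np.asarray(angle_fraction, dtype=float)
        t = np.full(np.broadcast(xf, af).shape, self.base_wall, dtype=float)
        for b in self.bumps:
            dx = (xf - b.axial_fraction) / b.sigma_axial
            dy = af - b.angle_fraction
            dy = (dy + 0.5) % 1.0 - 0.5          # wrap across the seam
            dy = dy / b.sigma_angular
            t = t + b.amplitude * np.exp(-0.5 * (dx ** 2 + dy ** 2))
        return t


def _closed_tube(radii: np.ndarray, zs: np.ndarray, thetas: np.ndarray):
    """Watertight tube of revolution-like surface with fan caps.

    radii has shape (n_z, n_a): the radius of vertex (i, j).
    """
    nz, na = radii.shape
    cos, sin = np.cos(thetas), np.sin(thetas)
    verts = np.empty((nz * na + 2, 3))
    verts[:nz * na, 0] = (radii * cos).ravel()
    verts[:nz * na, 1] = (radii * sin).ravel()
    verts[:nz * na, 2] = np.repeat(zs, na)
    bottom, top = nz * na, nz * na + 1
    verts[bottom] = (0.0, 0.0, zs[0])
    verts[top] = (0.0, 0.0, zs[-1])

    i = np.repeat(np.arange(nz - 1), na)
    j = np.tile(np.arange(na), nz - 1)
    jn = (j + 1) % na
    a = i * na + j
    b = i * na + jn
    c = (i + 1) * na + jn
    d = (i + 1) * na + j
    side = np.concatenate([np.column_stack([a, b, c]),
                           np.column_stack([a, c, d])])
    j0 = np.arange(na)
    j1 = (j0 + 1) % na
    cap_bot = np.column_stack([j1, j0, np.full(na, bottom)])
    ring = (nz - 1) * na
    cap_top = np.column_stack([ring + j0, ring + j1, np.full(na, top)])
    mesh = trimesh.Trimesh(vertices=verts,
                           faces=np.vstack([side, cap_bot, cap_top]),
                           process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def make_tube_specimen(spec: TubeSpec, specimen_id: str = "synthetic"):
    """Build the (periosteum, endosteum) pair and landmarks for a tube spec.

    LM1 lies on the periosteum at axial fraction f1 on the theta=0 meridian
    (this meridian is the unrolling cut line); LM2 lies on the medullary
    axis at fraction f2.
    """
    nz, na = spec.axial_resolution, spec.angular_resolution
    zs = np.linspace(0.0, spec.length, nz)
    thetas = 2.0 * np.pi * np.arange(na) / na
    xf = zs[:, None] / spec.length
    af = (thetas / (2.0 * np.pi))[None, :]
    r_out = np.broadcast_to(spec.outer_radius_at(xf), (nz, na)).copy()
    r_in = r_out - spec.wall_at(xf, af)

    periosteum = _closed_tube(r_out, zs, thetas)
    endosteum = _closed_tube(r_in, zs, thetas)
    pair = SurfacePair(periosteum, endosteum, specimen_id=specimen_id)

    f1, f2 = spec.landmark_axial_fractions
    lm1 = np.array([float(spec.outer_radius_at(f1)), 0.0, f1 * spec.length])
    lm2 = np.array([0.0, 0.0, f2 * spec.length])
    landmarks = LandmarkSet(lm1, lm2, laterality=spec.laterality)
    return pair, landmarks


def mirror_specimen(pair: SurfacePair, landmarks: LandmarkSet):
    """Mirror a specimen through the x=0 plane and flip its laterality."""
    flip = np.array([-1.0, 1.0, 1.0])

    def m(mesh):
        out = trimesh.Trimesh(vertices=mesh.vertices * flip,
                              faces=mesh.faces[:, ::-1], process=False)
        return out

    other = "left" if landmarks.laterality == "right" else "right"
    return (SurfacePair(m(pair.periosteum), m(pair.endosteum),
                        specimen_id=pair.specimen_id + "_mirror"),
            LandmarkSet(landmarks.lm1 * flip, landmarks.lm2 * flip,
                        laterality=other))


def make_ct_volume(spec: TubeSpec, bone_value: float = 1900.0,
                   air_value: float = -1000.0, voxel_size: float = 0.25):
    """Rasterize the analytic solid wall into a two-valued voxel volume.

    The tube ends are closed with bone material one base-wall thick, so the
    medullary cavity is fully enclosed (as the distal fork of a real
    medullary cavity encloses it) and threshold segmentation can recover a
    nested surface pair.  Returns ``(volume, voxel_size)``; the volume
    origin is at ``(-extent, -extent, -2*voxel)`` with the tube axis along
    the third array axis.  Refuses voxel sizes where the thinnest wall
    spans fewer than 3 voxels (the surface pair would not be resolvable).
    """
    if bone_value == air_value:
        raise ParameterError("degenerate contrast: bone_value == air_value")
    probe_x = np.linspace(0, 1, 201)[:, None]
    probe_y = np.linspace(0, 1, 201, endpoint=False)[None, :]
    min_wall = float(spec.wall_at(probe_x, probe_y).min())
    if min_wall < 3.0 * voxel_size:
        raise ResolutionError(
            f"minimum wall {min_wall:.3f} mm spans fewer than 3 voxels at "
            f"voxel_size={voxel_size} mm")
    r_max = spec.outer_radius
    pad = 2.0 * voxel_size
    nxy = int(np.ceil(2 * (r_max + pad) / voxel_size))
    nz = int(np.ceil((spec.length + 2 * pad) / voxel_size))
    xy = (np.arange(nxy) + 0.5) * voxel_size - (r_max + pad)
    zc = (np.arange(nz) + 0.5) * voxel_size - pad
    xx, yy = np.meshgrid(xy, xy, indexing="ij")
    rr = np.hypot(xx, yy)
    aa = (np.arctan2(yy, xx) / (2.0 * np.pi)) % 1.0
    vol = np.full((nxy, nxy, nz), air_value, dtype=np.float32)
    for iz, z in enumerate(zc):
        if z < 0.0 or z > spec.length:
            continue
        xf = z / spec.length
        r_out = spec.outer_radius_at(xf)
        wall = spec.wall_at(np.full_like(aa, xf), aa)
        in_end_cap = (z <= spec.base_wall) or (z >= spec.length - spec.base_wall)
        inside = (rr <= r_out) & ((rr >= r_out - wall) | in_end_cap)
        vol[:, :, iz][inside] = bone_value
    return vol, voxel_size


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class BumpSite:
    """A shared enthesis locus; per-specimen amplitude is set by the design."""

    axial_fraction: float
    angle_fraction: float
    sigma_axial: float = 0.08
    sigma_angular: float = 0.06


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    amplitudes: tuple            # mean bump amplitude (mm) per shared site
    body_mass_mean: float = 80.0
    body_mass_sd: float = 12.0
    age_range: tuple = (12.0, 36.0)
    bone_volume_mean: float = 30.0   # cm^3, used for metadata-level studies
    bone_volume_sd: float = 4.0

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("violated constraint: group n >= 1")


@dataclass(frozen=True)
class CohortDesign:
    """Planted statistical structure for a synthetic cohort.

    Per-specimen bump amplitudes are
    ``group mean + trait_map_loading * z(body mass) + N(0, noise_sd)``;
    metadata are drawn from the stated Gaussians, and males get
    ``sex_effect`` added to bone volume.  A fixed seed fully determines
    the output.
    """

    sites: tuple
    groups: tuple
    trait_map_loading: tuple = ()
    sex_effect: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    tube: TubeSpec = field(default_factory=TubeSpec)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("violated constraint: noise_sd >= 0")
        for g in self.groups:
            if len(g.amplitudes) != len(self.sites):
                raise ParameterError(
                    f"group {g.name!r} has {len(g.amplitudes)} amplitudes for "
                    f"{len(self.sites)} sites")
        if self.trait_map_loading and len(self.trait_map_loading) != len(self.sites):
            raise ParameterError("trait_map_loading must have one value per site")


@dataclass
class SyntheticSpecimen:
    specimen_id: str
    amplitudes: np.ndarray
    spec: TubeSpec
    pair: SurfacePair | None = None
    landmarks: LandmarkSet | None = None


@dataclass
class Cohort:
    specimens: list
    metadata: pd.DataFrame
    muscles: pd.DataFrame
    design: CohortDesign


# plausible porcine forelimb muscle scales (mass g, fascicle length cm)
_MUSCLE_SCALES = {
    "ANC": (25.0, 5.0, 6.0, 1.0),
    "BRA": (180.0, 30.0, 18.0, 2.5),
    "COR": (30.0, 6.0, 9.0, 1.5),
    "ECR": (110.0, 20.0, 12.0, 2.0),
    "PEC": (220.0, 40.0, 16.0, 2.5),
}


def _specimen_spec(design: CohortDesign, amplitudes: np.ndarray) -> TubeSpec:
    bumps = tuple(Bump(s.axial_fraction, s.angle_fraction, float(a),
                       s.sigma_axial, s.sigma_angular)
                  for s, a in zip(design.sites, amplitudes))
    return replace(design.tube, bumps=bumps)


def make_cohort(design: CohortDesign, meshes: bool = True) -> Cohort:
    """Draw a full synthetic cohort (geometry + metadata + muscle table)."""
    rng = np.random.default_rng(design.seed)
    loading = (np.asarray(design.trait_map_loading, dtype=float)
               if design.trait_map_loading else np.zeros(len(design.sites)))
    specimens, meta_rows, muscle_rows = [], [], []
    for g in design.groups:
        masses = rng.normal(g.body_mass_mean, g.body_mass_sd, g.n)
        masses = np.clip(masses, 1.0, None)
        ages = rng.uniform(*g.age_range, g.n)
        volumes = rng.normal(g.bone_volume_mean, g.bone_volume_sd, g.n)
        for k in range(g.n):
            sid = f"{g.name}_{k:03d}"
            sex = "M" if k % 2 == 0 else "F"
            z_mass = (masses[k] - g.body_mass_mean) / g.body_mass_sd
            amps = (np.asarray(g.amplitudes, dtype=float)
                    + loading * z_mass
                    + rng.normal(0.0, design.noise_sd, len(design.sites)))
            spec = _specimen_spec(design, amps)
            sp = SyntheticSpecimen(sid, amps, spec)
            if meshes:
                sp.pair, sp.landmarks = make_tube_specimen(spec, specimen_id=sid)
            specimens.append(sp)
            meta_rows.append({
                "specimen_id": sid, "group": g.name, "sex": sex,
                "age_months": round(float(ages[k]), 1),
                "body_mass_kg": round(float(masses[k]), 2),
                "bone_volume_cm3": round(float(
                    volumes[k] + (design.sex_effect if sex == "M" else 0.0)), 3),
            })
            for muscle in MUSCLES:
                mu_m, sd_m, mu_l, sd_l = _MUSCLE_SCALES[muscle]
                muscle_rows.append({
                    "specimen_id": sid, "muscle": muscle,
                    "mass_g": round(float(np.clip(
                        rng.normal(mu_m, sd_m), 1.0, None)), 2),
                    "fascicle_length_cm": round(float(np.clip(
                        rng.normal(mu_l, sd_l), 0.5, None)), 2),
                })
    return Cohort(specimens, pd.DataFrame(meta_rows), pd.DataFrame(muscle_rows),
                  design)


# ---------------------------------------------------------------------------
# analytic oracles


def segment_axial_window(landmark_fractions, margins=(0.10, 0.05)):
    """Axial window (as tube-length fractions) kept by the two-step crop."""
    f1, f2 = sorted(landmark_fractions)
    span = f2 - f1
    return f1 + margins[0] * span, f2 - margins[1] * span


def wall_thickness_field(spec: TubeSpec, grid_x: np.ndarray, grid_y: np.ndarray,
                         axial_window=None) -> np.ndarray:
    """Exact wall field evaluated on map coordinates (x axial, y angular).

    With ``axial_window=(lo, hi)`` the map x in [0, 1] is interpreted in
    the cropped segment's frame and converted back to tube fractions.
    """
    gx, gy = np.meshgrid(grid_x, grid_y)   # (K, M)
    if axial_window is not None:
        lo, hi = axial_window
        gx = lo + gx * (hi - lo)
    return spec.wall_at(gx, gy)


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = a.min(), a.max()
    if hi == lo:
        return np.full_like(a, 0.5)
    return (a - lo) / (hi - lo)


def analytic_maps(design: CohortDesign, gridspec=None, seed=None):
    """Cohort map matrix straight from the analytic fields (no meshes).

    Evaluates each specimen's exact wall field on the standard grid in the
    full-tube frame, min-max standardizes it per specimen, and returns the
    (n, K*M) matrix plus metadata.  This is the fast route used for
    statistical calibration studies where mesh measurement error is not
    the quantity under test.
    """
    from .gridmap import GridSpec
    gridspec = gridspec or GridSpec()
    if seed is not None:
        design = replace(design, seed=seed)
    cohort = make_cohort(design, meshes=False)
    rows = []
    for sp in cohort.specimens:
        grid = wall_thickness_field(sp.spec, gridspec.x, gridspec.y)
        rows.append(_minmax(grid).ravel())
    maps = pd.DataFrame(np.array(rows),
                        index=[sp.specimen_id for sp in cohort.specimens])
    return maps, cohort.metadata


# ---------------------------------------------------------------------------
# reference study designs
#
# Shared conditions for the calibration and recovery studies: an "anchor"
# thickening (amplitude 1 mm) pins the per-specimen min-max range so a
# planted amplitude difference of d mm at the second site appears as a
# difference of ~d on the standardized [0, 1] scale.

ANCHOR_SITE = BumpSite(0.35, 0.60, 0.10, 0.08)
EFFECT_SITE = BumpSite(0.70, 0.25, 0.10, 0.08)


def null_design(n_per_group: int = 8, noise_sd: float = 0.3,
                seed: int = 0) -> CohortDesign:
    """Two groups with identical mean fields; only amplitude noise differs."""
    amps = (1.0, 0.5)
    return CohortDesign(
        sites=(ANCHOR_SITE, EFFECT_SITE),
        groups=(GroupSpec("A", n_per_group, amps),
                GroupSpec("B", n_per_group, amps)),
        noise_sd=noise_sd, seed=seed)


def group_difference_design(delta: float = 0.2, n_per_group: int = 8,
                            noise_sd: float = 0.05, seed: int = 0) -> CohortDesign:
    """Two groups whose standardized fields differ by ~delta at EFFECT_SITE."""
    return CohortDesign(
        sites=(ANCHOR_SITE, EFFECT_SITE),
        groups=(GroupSpec("A", n_per_group, (1.0, 0.4)),
                GroupSpec("B", n_per_group, (1.0, 0.4 + delta))),
        noise_sd=noise_sd, seed=seed)


def trait_loading_design(loading: float = 0.3, n_per_group: int = 8,
                         noise_sd: float = 0.05, seed: int = 0) -> CohortDesign:
    """Body mass loads on the EFFECT_SITE amplitude (trait-map covariation)."""
    amps = (1.0, 0.5)
    return CohortDesign(
        sites=(ANCHOR_SITE, EFFECT_SITE),
        groups=(GroupSpec("A", n_per_group, amps),
                GroupSpec("B", n_per_group, amps)),
        trait_map_loading=(0.0, loading),
        noise_sd=noise_sd, seed=seed)


def site_field(site: BumpSite, gridspec) -> np.ndarray:
    """Unit-amplitude Gaussian field of one site on the grid (K x M)."""
    spec = TubeSpec(bumps=(Bump(site.axial_fraction, site.angle_fraction, 1.0,
                                site.sigma_axial, site.sigma_angular),))
    return wall_thickness_field(spec, gridspec.x, gridspec.y) - spec.base_wall


def simulate_volume_mass_cohort(n: int, slope: float = 0.20,
                                r_squared: float = 0.89,
                                mass_mean: float = 80.0, mass_sd: float = 15.0,
                                intercept: float = 10.0, seed: int = 0):
    """Bone-volume ~ body-mass cohort with a planted allometric slope.

    The residual scale is set from the target coefficient of determination:
    sigma = |slope| * mass_sd * sqrt(1/R^2 - 1).
    """
    if not 0 < r_squared < 1:
        raise ParameterError("violated constraint: 0 < r_squared < 1")
    rng = np.random.default_rng(seed)
    mass = rng.normal(mass_mean, mass_sd, n)
    sigma = abs(slope) * mass_sd * np.sqrt(1.0 / r_squared - 1.0)
    volume = intercept + slope * mass + rng.normal(0.0, sigma, n)
    return pd.DataFrame({"body_mass_kg": mass, "bone_volume_cm3": volume})
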