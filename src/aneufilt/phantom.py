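"""Synthetic 3D angiography phantoms with known ground truth.

A phantom emulates the structure the detector assumes: bright curved
tubular vessels on a dark background with bright near-spherical aneurysms
attached to a vessel wall, plus additive Gaussian noise.  Profiles are
soft-edged — intensity falls off as ``2**(-(d/r)**2)`` with distance ``d``
from the centerline (tube) or center (sphere) — because second derivatives
of binary masks are impulse-like, while real vessels have smooth profiles;
the half-maximum surface sits exactly at the nominal radius.

Clinical multiplicity can be emulated: most patients carry one aneurysm,
a minority two, rarely three (127 : 16 : 2 among 145 in the cohort the
detector targets).  Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import interpolate, ndimage, spatial

from .volume_io import Volume

__all__ = [
    "PhantomTruth",
    "PhantomSpec",
    "make_vessel",
    "add_aneurysm",
    "generate_phantom",
    "sample_aneurysm_count",
    "truths_to_json",
]

#: clinical aneurysms-per-patient frequencies (1, 2, 3 aneurysms)
MULTIPLICITY_WEIGHTS = (127.0, 16.0, 2.0)


@dataclass
class PhantomTruth:
    """Ground-truth record for one planted aneurysm."""

    center: tuple[float, float, float]
    radius: float
    vessel_id: int = 0


@dataclass
class PhantomSpec:
    """Declarative description of one synthetic volume.

    ``n_aneurysms=None`` draws the count from the clinical multiplicity
    distribution.  Radii are in voxels; ``noise_sigma`` is the standard
    deviation of the additive Gaussian noise on a [0, 1] intensity scale.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    n_vessels: int = 1
    vessel_radius_range: tuple[float, float] = (2.0, 4.0)
    n_aneurysms: int | None = 1
    aneurysm_radius_range: tuple[float, float] = (3.0, 8.0)
    #: non-aneurysmal wall bumps (mostly-embedded spheres): the clinical
    #: confounder whose peaky response generates false candidates
    n_protrusions: int = 2
    protrusion_radius_range: tuple[float, float] = (1.5, 3.0)
    vessel_contrast: float = 1.0
    aneurysm_contrast: float = 1.0
    noise_sigma: float = 0.03
    psf_sigma: float = 0.8
    min_separation: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 0 or (self.n_aneurysms is not None and self.n_aneurysms < 0):
            raise ValueError("counts must be >= 0")


def truths_to_json(truths: Sequence[PhantomTruth]) -> str:
    """Ground-truth sidecar (JSON) for a phantom written to disk."""
    import json

    return json.dumps([{"center": list(t.center), "radius": t.radius,
                        "vessel_id": t.vessel_id} for t in truths], indent=2)


def sample_aneurysm_count(rng: np.random.Generator) -> int:
    """Draw 1, 2 or 3 aneurysms with clinical frequencies."""
    w = np.asarray(MULTIPLICITY_WEIGHTS)
    return int(rng.choice([1, 2, 3], p=w / w.sum()))


def _soft_profile(dist: np.ndarray, radius: float, contrast: float) -> np.ndarray:
    return contrast * np.exp2(-((dist / radius) ** 2))


def make_vessel(shape: Sequence[int], radius: float,
                seed: int | np.random.Generator = 0,
                control_points: np.ndarray | None = None,
                contrast: float = 1.0,
                ) -> tuple[np.ndarray, np.ndarray]:
    """A curved soft-edged tube spanning the volume.

    A cubic spline through jittered control points (or the given ones) is
    densely sampled, rasterized, and expanded into a tube via a Euclidean
    distance transform; intensity is ~1 on the axis and 0.5 at distance
    ``radius``.  Returns the intensity field and the sampled centerline
    as an (N, 3) array of (z, y, x) coordinates.
    """
    shape = tuple(int(n) for n in shape)
    if radius < 1:
        raise ValueError(f"vessel radius must be >= 1 voxel, got {radius}")
    if radius > min(shape) / 4:
        raise ValueError(f"radius {radius} too large for shape {shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if control_points is None:
        # the curve overshoots the z faces so the tube crosses the whole
        # volume: a tube *cap* inside the field of view is itself a bright
        # sphere-like structure, which real vessels (extending beyond the
        # FOV) do not show
        # few control points with moderate jitter: main cerebral arteries in
        # a ~5 cm field of view bend at radii well above the lumen radius;
        # tighter bends turn apexes into sphere-like structures
        n_ctrl = 4
        over = 0.15 * shape[0]
        t_ctrl = np.linspace(-over, shape[0] - 1 + over, n_ctrl)
        mid_y, mid_x = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
        amp_y, amp_x = shape[1] / 8.0, shape[2] / 8.0
        control_points = np.column_stack([
            t_ctrl,
            mid_y + rng.uniform(-amp_y, amp_y, n_ctrl),
            mid_x + rng.uniform(-amp_x, amp_x, n_ctrl),
        ])
    control_points = np.asarray(control_points, dtype=float)

    t = np.linspace(0.0, 1.0, len(control_points))
    spline = interpolate.CubicSpline(t, control_points, axis=0)
    # sample densely (~0.1 voxel) so distance-to-point-cloud is distance to
    # the smooth curve: voxelized centerlines give a scalloped tube surface
    # whose fine-scale curvature pollutes the Hessian
    coarse = spline(np.linspace(0.0, 1.0, 64))
    length = float(np.sum(np.linalg.norm(np.diff(coarse, axis=0), axis=1)))
    n_samples = max(int(length / 0.1), 64)
    centerline = spline(np.linspace(0.0, 1.0, n_samples))

    tree = spatial.cKDTree(centerline)
    grid = np.indices(shape, dtype=float).reshape(3, -1).T
    dist = tree.query(grid, workers=-1)[0].reshape(shape)
    inside = np.all((centerline >= 0)
                    & (centerline <= np.asarray(shape, dtype=float) - 1), axis=1)
    # only in-bounds centerline samples are usable downstream (placement)
    return _soft_profile(dist, radius, contrast), centerline[inside]


def add_aneurysm(field: np.ndarray, centerline: np.ndarray, radius: float,
                 seed: int | np.random.Generator = 0,
                 vessel_radius: float = 3.0,
                 contrast: float = 1.0,
                 vessel_id: int = 0,
                 avoid: Sequence[PhantomTruth] = (),
                 min_separation: float = 0.0,
                 embed_fraction: float = 0.0,
                 ) -> tuple[np.ndarray, PhantomTruth]:
    """Attach a soft-edged bright sphere tangent to a vessel.

    The sphere center sits at distance ``vessel_radius + radius`` from a
    randomly chosen centerline point, along a direction orthogonal to the
    local tangent; placement retries until the sphere lies fully inside the
    volume and clear of ``avoid`` centers, raising after 100 attempts.
    The sphere is composited by voxelwise maximum.

    With ``embed_fraction > 0`` the center is pulled toward the vessel by
    that fraction of the sphere radius, producing a wall *protrusion*
    rather than a pedunculated sac — the non-aneurysmal confounder whose
    filter response is peaky instead of uniform.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = np.asarray(field.shape, dtype=float)
    offset = vessel_radius + (1.0 - embed_fraction) * radius

    for _ in range(100):
        i = int(rng.integers(len(centerline) // 8, 7 * len(centerline) // 8))
        pt = centerline[i]
        tangent = centerline[min(i + 1, len(centerline) - 1)] - centerline[max(i - 1, 0)]
        norm = np.linalg.norm(tangent)
        tangent = tangent / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        direction = rng.normal(size=3)
        direction -= direction @ tangent * tangent
        norm = np.linalg.norm(direction)
        if norm < 1e-8:
            continue
        direction /= norm
        center = pt + offset * direction
        if np.any(center < radius + 2) or np.any(center > shape - radius - 3):
            continue
        if any(np.linalg.norm(center - np.asarray(t.center)) < min_separation
               for t in avoid):
            continue
        break
    else:
        raise ValueError("no valid aneurysm placement found after 100 tries")

    # composite on a local sub-box for speed
    lo = np.maximum(np.floor(center - 4 * radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + 4 * radius).astype(int) + 1,
                    shape.astype(int))
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.ogrid[sl]
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    out = np.array(field, copy=True)
    out[sl] = np.maximum(out[sl], _soft_profile(d, radius, contrast))
    truth = PhantomTruth(center=tuple(float(c) for c in center),
                         radius=float(radius), vessel_id=vessel_id)
    return out, truth


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, list[PhantomTruth]]:
    """Build the full phantom: vessels, aneurysms, noise, clip to [0, 1].

    Bit-reproducible for a fixed spec (including seed).  The truth list has
    exactly the requested number of aneurysms (or the clinically drawn
    count when ``n_aneurysms is None``).
    """
    rng = np.random.default_rng(spec.seed)
    field = np.zeros(spec.shape, dtype=np.float64)
    centerlines: list[np.ndarray] = []
    for _ in range(spec.n_vessels):
        r = rng.uniform(*spec.vessel_radius_range)
        tube, line = make_vessel(spec.shape, r, rng, contrast=spec.vessel_contrast)
        field = np.maximum(field, tube)
        centerlines.append(line)

    n_an = spec.n_aneurysms if spec.n_aneurysms is not None else sample_aneurysm_count(rng)
    truths: list[PhantomTruth] = []
    vessel_radius_mid = float(np.mean(spec.vessel_radius_range))
    for _ in range(n_an):
        r = rng.uniform(*spec.aneurysm_radius_range)
        vid = int(rng.integers(len(centerlines))) if centerlines else 0
        field, truth = add_aneurysm(field, centerlines[vid], r, rng,
                                    vessel_radius=vessel_radius_mid,
                                    contrast=spec.aneurysm_contrast,
                                    vessel_id=vid, avoid=truths,
                                    min_separation=spec.min_separation)
        truths.append(truth)

    # wall protrusions: distractors, deliberately absent from the truth list
    placed = list(truths)
    for _ in range(spec.n_protrusions if centerlines else 0):
        r = rng.uniform(*spec.protrusion_radius_range)
        vid = int(rng.integers(len(centerlines)))
        try:
            field, bump = add_aneurysm(field, centerlines[vid], r, rng,
                                       vessel_radius=vessel_radius_mid,
                                       contrast=spec.vessel_contrast,
                                       vessel_id=vid, avoid=placed,
                                       min_separation=spec.min_separation,
                                       embed_fraction=0.6)
            placed.append(bump)
        except ValueError:
            continue  # crowded volume: skip this distractor

    if spec.psf_sigma > 0:
        # reconstruction point-spread function band-limits the object
        field = ndimage.gaussian_filter(field, spec.psf_sigma)
    if spec.noise_sigma > 0:
        # detector noise in a reconstructed volume is filtered by the same
        # kernel as the object, so it is correlated, not voxel-white;
        # noise_sigma is the post-reconstruction standard deviation
        noise = rng.standard_normal(field.shape)
        if spec.psf_sigma > 0:
            noise = ndimage.gaussian_filter(noise, spec.psf_sigma)
            noise /= noise.std()
        field = field + spec.noise_sigma * noise
    return Volume(np.clip(field, 0.0, 1.0)), truths
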