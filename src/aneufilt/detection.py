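"""Aneurysm extraction: adaptive thresholding, region growth, iterative removal.

A round of detection filters the (preprocessed) volume at the per-round
optimal (s, tau), seeds at the global response maximum, grows a 26-connected
target region, and classifies it by comparing the mean (V_mean) or maximum
(V_max) response over the target with a threshold.  A positive target is
removed from the image by zeroing a sphere centered at the target's center
of mass, and the loop repeats — each aneurysm gets its own optimal filter
parameters — until a round classifies negative or the round cap is reached.
The removal guarantees no target is detected twice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .bayes_opt import OptTrace, bayes_optimize, reciprocal_loss
from .blob_filter import (FilterParams, ResponseField, filter_response,
                          lam3_reference)
from .preprocess import preprocess
from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = [
    "TargetStats",
    "Detection",
    "DetectionConfig",
    "grow_region",
    "target_stats",
    "classify_target",
    "removal_sphere",
    "remove_target",
    "detect_aneurysms",
    "detections_to_json",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TargetStats:
    """Response statistics over one extracted target (V_mean <= V_max)."""

    v_max: float
    v_mean: float
    values: np.ndarray


@dataclass
class Detection:
    """One extracted target and the decision made about it."""

    mask: np.ndarray
    seed: tuple[int, int, int]
    stats: TargetStats
    centroid: tuple[float, float, float]
    removal_radius: float
    is_aneurysm: bool
    round_index: int
    params: FilterParams | None = None
    trace: OptTrace | None = None


def _values(response: ResponseField | np.ndarray) -> np.ndarray:
    return response.values if isinstance(response, ResponseField) else np.asarray(response)


def grow_region(response: ResponseField | np.ndarray,
                seed: Sequence[int],
                alpha: float = 0.5,
                floor: float = 0.0) -> np.ndarray:
    """26-connected region growth from a seed voxel.

    A voxel qualifies iff its response is at least
    ``max(alpha * response[seed], floor)``; the result is the 26-connected
    component of qualifying voxels containing the seed.
    """
    vals = _values(response)
    seed = tuple(int(i) for i in seed)
    if vals[seed] <= 0:
        raise ValueError(f"empty target: response at seed {seed} is not positive")
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    cutoff = max(alpha * float(vals[seed]), floor)
    labels, _ = ndimage.label(vals >= cutoff, structure=_CONN26)
    return labels == labels[seed]


def target_stats(response: ResponseField | np.ndarray, mask: np.ndarray) -> TargetStats:
    """V_max and V_mean of the response over exactly the masked voxels."""
    vals = _values(response)[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("empty mask")
    return TargetStats(v_max=float(vals.max()), v_mean=float(vals.mean()), values=vals)


def classify_target(stats: TargetStats, mode: str, threshold: float) -> bool:
    """True iff the chosen statistic strictly exceeds the threshold."""
    if mode == "mean":
        stat = stats.v_mean
    elif mode == "max":
        stat = stats.v_max
    else:
        raise ValueError(f"mode must be 'mean' or 'max', got {mode!r}")
    return stat > threshold


def removal_sphere(mask: np.ndarray) -> tuple[tuple[float, float, float], float]:
    """Removal sphere for a target: center of mass, radius = max bbox extent.

    The radius convention follows the extraction rule literally: the maximum
    of the target's axis-aligned bounding-box extents is used as the radius
    (see :class:`DetectionConfig.removal_radius_mode` for the half-extent
    alternative).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    center = ndimage.center_of_mass(mask)
    idx = np.nonzero(mask)
    extents = [int(ax.max() - ax.min() + 1) for ax in idx]
    return tuple(float(c) for c in center), float(max(extents))


def remove_target(volume: Volume, center: Sequence[float], radius: float,
                  feather: float = 0.0) -> Volume:
    """Zero all voxels within Euclidean distance ``radius`` of ``center``.

    With ``feather > 0`` the cut edge is tapered with a cosine ramp of that
    width (in voxels) instead of a hard step: a hard crater rim through a
    bright vessel is itself a sharp sphere-like structure that pollutes
    later detection rounds.  Voxels beyond ``radius + feather`` are
    bit-identical to the input.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    center = np.asarray(center, dtype=float)
    grids = np.ogrid[tuple(slice(0, n) for n in volume.shape)]
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    out = np.array(volume.data, copy=True)
    if feather > 0:
        ramp = np.clip((d - radius) / feather, 0.0, 1.0)
        factor = 0.5 * (1.0 - np.cos(np.pi * ramp))
        band = d <= radius + feather
        out[band] = out[band] * factor[band]
    else:
        out[d <= radius] = 0.0
    return volume.with_data(out)


@dataclass
class DetectionConfig:
    """All knobs of the detection pipeline.

    ``threshold`` applies to the statistic chosen by ``mode`` ('mean'
    recommended: aneurysm responses are uniform, so V_mean separates better
    than V_max).  ``record_all=True`` keeps rejected targets in the output
    and continues removing up to ``max_rounds`` — used for threshold sweeps.
    """

    s_bounds: tuple[float, float] = (0.5, 20.0)
    tau_bounds: tuple[float, float] = (0.7, 1.0)
    budget: int = 50
    seed: int = 0
    alpha: float = 0.5
    mode: str = "mean"
    threshold: float = 0.5
    max_rounds: int = 5
    removal_radius_mode: str = "extent"  # or "half": max extent / 2
    removal_feather: float = 2.0
    exclusion_margin: float = 3.0
    jerman_compat: bool = False
    min_peak: float = 1e-8
    record_all: bool = False
    already_preprocessed: bool = False

    def bounds(self) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.s_bounds, self.tau_bounds)


def detect_aneurysms(volume: Volume,
                     config: DetectionConfig | None = None) -> list[Detection]:
    """Full iterative detection loop.

    Preprocess once; per round, Bayesian-optimize (s, tau) on the current
    image, build the response at the optimum, grow the target at the
    response argmax, classify by the configured statistic, and — if
    positive — remove its sphere and continue.  Stops at the first negative
    classification (unless ``record_all``), when the response vanishes, or
    at ``max_rounds``.  Returns classified-positive detections in round
    order (all candidates when ``record_all``).
    """
    config = config or DetectionConfig()
    work = volume if config.already_preprocessed else preprocess(volume)
    if float(work.data.max()) == float(work.data.min()):
        logger.info("constant volume: nothing to detect")
        return []

    detections: list[Detection] = []
    # voxels inside removed spheres (plus a margin) are out of consideration
    # for later rounds: the cut edges would otherwise re-detect as targets
    removed = np.zeros(work.shape, dtype=bool)
    for round_index in range(1, config.max_rounds + 1):
        exclude = removed if removed.any() else None
        ref = lam3_reference(work, exclude=exclude)
        if ref <= 0:
            logger.info("round %d: no bright blob structure left; stopping",
                        round_index)
            break
        loss = reciprocal_loss(work, jerman_compat=config.jerman_compat,
                               lam3_ref=ref, exclude=exclude)
        round_seed = (config.seed * 100003 + round_index) % (2 ** 31 - 1)
        best, trace = bayes_optimize(loss, bounds=config.bounds(),
                                     budget=config.budget, seed=round_seed)
        resp = filter_response(work, best, lam3_ref=ref,
                               jerman_compat=config.jerman_compat,
                               exclude=exclude)
        peak = float(resp.values.max())
        if peak <= config.min_peak:
            logger.info("round %d: response vanished (peak %g); stopping",
                        round_index, peak)
            break
        seed_vox = tuple(int(i) for i in
                         np.unravel_index(int(np.argmax(resp.values)), resp.values.shape))
        mask = grow_region(resp, seed_vox, alpha=config.alpha)
        stats = target_stats(resp, mask)
        center, extent = removal_sphere(mask)
        radius = extent / 2.0 if config.removal_radius_mode == "half" else extent
        positive = classify_target(stats, config.mode, config.threshold)
        det = Detection(mask=mask, seed=seed_vox, stats=stats, centroid=center,
                        removal_radius=radius, is_aneurysm=positive,
                        round_index=round_index, params=best, trace=trace)
        logger.info("round %d: s=%.3f tau=%.3f Vmax=%.4g Vmean=%.4g -> %s",
                    round_index, best.s, best.tau, stats.v_max, stats.v_mean,
                    "aneurysm" if positive else "not an aneurysm")
        if positive or config.record_all:
            detections.append(det)
        if not positive and not config.record_all:
            break
        work = remove_target(work, center, radius,
                             feather=config.removal_feather)
        grids = np.ogrid[tuple(slice(0, n) for n in work.shape)]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        reach = radius + config.removal_feather + config.exclusion_margin
        removed |= d2 <= reach ** 2
    return detections


def detections_to_json(detections: list[Detection]) -> str:
    """Serialize detections (without masks) to a JSON string."""
    recs = []
    for d in detections:
        recs.append({
            "round": d.round_index,
            "s": d.params.s if d.params else None,
            "tau": d.params.tau if d.params else None,
            "seed": list(d.seed),
            "centroid": list(d.centroid),
            "removal_radius": d.removal_radius,
            "v_max": d.stats.v_max,
            "v_mean": d.stats.v_mean,
            "is_aneurysm": bool(d.is_aneurysm),
            "n_voxels": int(np.count_nonzero(d.mask)),
        })
    return json.dumps(recs, indent=2, sort_keys=True)
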