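"""Vessel landmarks, curve extraction and grid-search ROI correction.

A landmark marks a candidate vessel voxel (five arterial, AIF_0..AIF_4, and
three venous, VOF_0..VOF_2).  Because a landmark placed even one voxel off a
small vessel yields a flat, useless curve, each landmark is refined by an
exhaustive search over the surrounding voxel ball: the voxel whose curve has
the highest baseline-subtracted area under the curve wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

from .curves import IntensityCurve
from .prep import CTPSeries

AIF_NAMES = tuple(f"AIF_{i}" for i in range(5))
VOF_NAMES = tuple(f"VOF_{i}" for i in range(3))
LANDMARK_NAMES = AIF_NAMES + VOF_NAMES

__all__ = [
    "Landmark",
    "extract_curve",
    "curve_auc",
    "correct_roi",
    "heuristic_localize",
    "load_landmarks",
    "save_landmarks",
    "AIF_NAMES",
    "VOF_NAMES",
    "LANDMARK_NAMES",
]


@dataclass(frozen=True)
class Landmark:
    """A named vessel candidate at a 0-based 3D voxel index."""

    name: str
    index: tuple[int, int, int]

    def __post_init__(self):
        if self.name not in LANDMARK_NAMES:
            raise ValueError(f"unknown landmark name {self.name!r}")
        object.__setattr__(self, "index", tuple(int(i) for i in self.index))
        if len(self.index) != 3:
            raise ValueError("index must be a 3D voxel index")

    @property
    def kind(self) -> str:
        """'AIF' or 'VOF', derived from the name."""
        return self.name.split("_")[0]


def save_landmarks(landmarks: list[Landmark], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([{"name": lm.name, "index": list(lm.index)} for lm in landmarks], indent=2)
    )


def load_landmarks(path: str | Path) -> list[Landmark]:
    return [Landmark(d["name"], tuple(d["index"])) for d in json.loads(Path(path).read_text())]


def _check_inside(series: CTPSeries, index: tuple[int, int, int]) -> None:
    for i, n in zip(index, series.shape[:3]):
        if not 0 <= i < n:
            raise IndexError(f"landmark index {index} outside grid {series.shape[:3]}")


def extract_curve(
    series: CTPSeries,
    lm: Landmark,
    neighborhood_radius: int = 0,
    baseline_frames: int = 4,
) -> IntensityCurve:
    """Mean HU time series over the voxels within ``neighborhood_radius``
    (Euclidean, voxel units) of the landmark; radius 0 reads a single voxel.
    """
    _check_inside(series, lm.index)
    x, y, z = lm.index
    if neighborhood_radius == 0:
        values = series.data[x, y, z, :]
    else:
        r = int(np.ceil(neighborhood_radius))
        idx = [
            (x + dx, y + dy, z + dz)
            for dx, dy, dz in product(range(-r, r + 1), repeat=3)
            if dx * dx + dy * dy + dz * dz <= neighborhood_radius**2
            and 0 <= x + dx < series.shape[0]
            and 0 <= y + dy < series.shape[1]
            and 0 <= z + dz < series.shape[2]
        ]
        values = np.mean([series.data[i, j, k, :] for i, j, k in idx], axis=0)
    return IntensityCurve(np.array(values, dtype=float), dt=series.dt, baseline_frames=baseline_frames)


def curve_auc(curve: IntensityCurve) -> float:
    """Trapezoidal area under the baseline-subtracted curve, in HU*s.

    Baseline-subtraction keeps the tissue/bone offset from dominating the
    integral; what is ranked is the bolus enhancement itself.
    """
    return float(np.trapezoid(curve.baseline_subtracted(), dx=curve.dt))


def _ball_offsets(radius: float) -> list[tuple[int, int, int]]:
    r = int(np.floor(radius))
    offs = [
        (dx, dy, dz)
        for dx, dy, dz in product(range(-r, r + 1), repeat=3)
        if dx * dx + dy * dy + dz * dz <= radius**2
    ]
    return offs


def correct_roi(
    series: CTPSeries,
    lm: Landmark,
    radius: float = 8.0,
    metric: str = "euclidean",
    baseline_frames: int = 4,
) -> Landmark:
    """Grid-search ROI correction.

    Scans every in-grid voxel within a 3D ball (or Chebyshev box when
    ``metric='chebyshev'``) of ``radius`` voxels around the landmark and
    returns the landmark moved to the voxel whose single-voxel curve has the
    highest AUC.  Ties break to the voxel nearest the original position,
    then lexicographically, so the result is deterministic.
    """
    _check_inside(series, lm.index)
    if metric == "euclidean":
        offsets = _ball_offsets(radius)
    elif metric == "chebyshev":
        r = int(np.floor(radius))
        offsets = list(product(range(-r, r + 1), repeat=3))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    x, y, z = lm.index
    shape = series.shape[:3]
    best_key, best_index = None, lm.index
    for dx, dy, dz in offsets:
        i, j, k = x + dx, y + dy, z + dz
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            continue
        auc = curve_auc(
            IntensityCurve(series.data[i, j, k, :], dt=series.dt, baseline_frames=baseline_frames)
        )
        key = (-auc, dx * dx + dy * dy + dz * dz, (i, j, k))
        if best_key is None or key < best_key:
            best_key, best_index = key, (i, j, k)
    return Landmark(lm.name, best_index)


def heuristic_localize(
    series: CTPSeries,
    mask: np.ndarray,
    baseline_frames: int = 4,
    min_separation: float = 3.0,
) -> list[Landmark]:
    """Classical vessel localisation: rank masked voxels by curve AUC.

    Arterial candidates are the top-AUC voxels among the earlier-peaking
    half of the mask (time-to-peak below the masked median), venous
    candidates the top-AUC among the later-peaking half; candidates are kept
    pairwise at least ``min_separation`` voxels apart.  A stand-in for a
    learned localiser so the pipeline runs fully automatically.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    data = series.data[mask]  # (V, T)
    baseline = data[:, :baseline_frames].mean(axis=1, keepdims=True)
    enhanced = data - baseline
    auc = np.trapezoid(enhanced, dx=series.dt, axis=1)
    ttp = enhanced.argmax(axis=1) * series.dt
    coords = np.argwhere(mask)
    median_ttp = np.median(ttp)

    def pick(cand_order, coords_sub, n):
        chosen: list[np.ndarray] = []
        for i in cand_order:
            c = coords_sub[i]
            if all(np.linalg.norm(c - p) >= min_separation for p in chosen):
                chosen.append(c)
            if len(chosen) == n:
                return chosen
        raise ValueError("fewer than the required number of separated candidate voxels")

    early = ttp < median_ttp
    late = ~early
    if early.sum() < 5 or late.sum() < 3:
        raise ValueError("mask too small to localise 5 AIF + 3 VOF candidates")
    aif_order = np.argsort(-auc[early], kind="stable")
    vof_order = np.argsort(-auc[late], kind="stable")
    aif_coords = pick(aif_order, coords[early], 5)
    vof_coords = pick(vof_order, coords[late], 3)
    landmarks = [Landmark(AIF_NAMES[i], tuple(c)) for i, c in enumerate(aif_coords)]
    landmarks += [Landmark(VOF_NAMES[i], tuple(c)) for i, c in enumerate(vof_coords)]
    return landmarks
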