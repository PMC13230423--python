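"""CTP series container and preprocessing.

Preprocessing mirrors what clinical perfusion pipelines do before vessel
localisation: align frames to a reference (here an exhaustive integer-voxel
translation search, which is deterministic and adequate for translational
motion), standardise the grid by centred crop / symmetric zero-pad, collapse
the time axis into a temporal max-minus-min projection that highlights
vessels, and z-score normalise.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "CTPSeries",
    "MIPVolume",
    "motion_correct",
    "resize_to_grid",
    "compute_mip",
    "znormalize",
]


@dataclass(frozen=True)
class CTPSeries:
    """4D HU volume, spatial axes first, time axis last.

    ``spacing`` is the voxel size in mm (x, y, z); ``dt`` the frame interval
    in seconds.  Voxel indices are 0-based.
    """

    data: np.ndarray  # (X, Y, Z, T)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    dt: float = 1.5

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if d.ndim != 4:
            raise ValueError("CTPSeries data must be 4D (X, Y, Z, T)")
        if d.shape[3] < 2:
            raise ValueError("need at least 2 time frames")
        if any(s <= 0 for s in self.spacing) or self.dt <= 0:
            raise ValueError("spacing and dt must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def frame(self, t: int) -> np.ndarray:
        return self.data[..., t]

    # --- I/O ---------------------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write as 4D NIfTI with spacing in the header and dt in a JSON sidecar."""
        path = Path(path)
        affine = np.diag([*self.spacing, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.float32), affine)
        img.header.set_zooms((*self.spacing, self.dt))
        nib.save(img, path)
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
        sidecar = Path(str(sidecar) + ".json")
        sidecar.write_text(json.dumps({"frame_interval_s": self.dt}, indent=2))

    @classmethod
    def from_nifti(cls, path: str | Path, dt: float | None = None) -> "CTPSeries":
        path = Path(path)
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        zooms = img.header.get_zooms()
        spacing = tuple(float(z) for z in zooms[:3])
        if dt is None:
            sidecar = Path(str(path).removesuffix(".gz").removesuffix(".nii") + ".json")
            if sidecar.exists():
                dt = float(json.loads(sidecar.read_text())["frame_interval_s"])
            elif len(zooms) > 3 and zooms[3] > 0:
                dt = float(zooms[3])
            else:
                raise ValueError("frame interval not found; pass dt explicitly")
        return cls(data, spacing=spacing, dt=dt)


@dataclass(frozen=True)
class MIPVolume:
    """Temporal max-minus-min projection of a CTP series."""

    data: np.ndarray  # (X, Y, Z)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    normalized: bool = False

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", d)
        if d.ndim != 3:
            raise ValueError("MIPVolume data must be 3D")
        if not self.normalized and np.any(d < 0):
            raise ValueError("raw max-minus-min projection cannot be negative")

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float32), np.diag([*self.spacing, 1.0]))
        nib.save(img, Path(path))


def _shift_frame(frame: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Integer-translate a 3D frame, filling exposed voxels from the edge."""
    return ndimage.shift(frame, shift, order=0, mode="nearest")


def motion_correct(
    series: CTPSeries, reference_frame: int = 0, max_shift: int = 3
) -> CTPSeries:
    """Align each frame to the reference by exhaustive integer-translation search.

    For every frame the integer 3D translation within ``±max_shift`` voxels
    maximising Pearson correlation with the reference frame is applied.
    Exposed out-of-field voxels take the nearest edge value.  A constant
    reference frame makes correlation undefined; correction is then skipped
    with a warning.
    """
    if not 0 <= reference_frame < series.n_frames:
        raise ValueError("reference_frame out of range")
    ref = series.frame(reference_frame)
    if np.ptp(ref) == 0:
        log.warning("constant reference frame; motion correction skipped")
        warnings.warn("constant reference frame; motion correction skipped")
        return series
    refc = ref - ref.mean()
    refn = np.sqrt((refc**2).sum())
    offsets = range(-max_shift, max_shift + 1)
    out = np.empty_like(series.data)
    for t in range(series.n_frames):
        frame = series.frame(t)
        best_key, best_shift = None, (0, 0, 0)
        for dx in offsets:
            for dy in offsets:
                for dz in offsets:
                    cand = _shift_frame(frame, (dx, dy, dz))
                    candc = cand - cand.mean()
                    denom = refn * np.sqrt((candc**2).sum())
                    score = (refc * candc).sum() / denom if denom > 0 else -np.inf
                    # ties go to the smaller shift so aligned frames stay put
                    key = (score, -(dx * dx + dy * dy + dz * dz), (dx, dy, dz))
                    if best_key is None or key > best_key:
                        best_key, best_shift = key, (dx, dy, dz)
        out[..., t] = _shift_frame(frame, best_shift) if best_shift != (0, 0, 0) else frame
    return replace(series, data=out)


def _crop_pad_axis(arr: np.ndarray, axis: int, target: int) -> np.ndarray:
    n = arr.shape[axis]
    if n == target:
        return arr
    if n > target:  # centred crop
        start = (n - target) // 2
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(start, start + target)
        return arr[tuple(sl)]
    # symmetric zero-pad
    before = (target - n) // 2
    after = target - n - before
    pad = [(0, 0)] * arr.ndim
    pad[axis] = (before, after)
    return np.pad(arr, pad)


def resize_to_grid(obj, target_dims: tuple[int, int, int]):
    """Centred crop / symmetric zero-pad the spatial axes to ``target_dims``.

    Accepts a CTPSeries, MIPVolume or bare 3D/4D array and returns the same
    kind.
    """
    if any(d <= 0 for d in target_dims):
        raise ValueError("target dims must be positive")
    if isinstance(obj, CTPSeries):
        return replace(obj, data=resize_to_grid(obj.data, target_dims))
    if isinstance(obj, MIPVolume):
        return replace(obj, data=resize_to_grid(obj.data, target_dims))
    arr = np.asarray(obj)
    for axis, target in enumerate(target_dims):
        arr = _crop_pad_axis(arr, axis, int(target))
    return arr


def compute_mip(series: CTPSeries) -> MIPVolume:
    """Temporal projection: per-voxel max minus min over the time axis.

    Vessels, which carry the full bolus passage, light up far more than
    tissue; the projection is the localisation substrate.
    """
    data = series.data.max(axis=3) - series.data.min(axis=3)
    return MIPVolume(data, spacing=series.spacing, normalized=False)


def znormalize(vol: MIPVolume, mask: np.ndarray | None = None) -> MIPVolume:
    """Z-score normalise: mean 0, SD 1 over the mask (or whole volume).

    A zero-variance input yields an all-zero volume with a warning.
    """
    data = vol.data
    sel = data[mask.astype(bool)] if mask is not None else data
    mu, sd = float(sel.mean()), float(sel.std())
    if sd == 0:
        log.warning("zero-variance volume; z-normalization returns zeros")
        warnings.warn("zero-variance volume; z-normalization returns zeros")
        return replace(vol, data=np.zeros_like(data), normalized=True)
    return replace(vol, data=(data - mu) / sd, normalized=True)
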