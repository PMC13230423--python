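"""Lesion-volume quantification from perfusion maps.

Two clinically standard summaries of a stroke CTP study:

* **Volume F** — tissue with relative CBF strictly below 30% of a reference,
  a proxy for the irreversibly injured core;
* **Volume T** — tissue with Tmax strictly above 6 s, the hypoperfused
  (core + penumbra) territory.

Both are reported in millilitres and rounded to integers for the report,
with the exact values retained.  When the upstream pair selection could not
find a valid AIF/VOF pair, the report carries the warning and claims no
volumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .validity import PairWarning

__all__ = [
    "PerfusionMaps",
    "VolumeReport",
    "rcbf_map",
    "volume_f",
    "volume_t",
    "make_report",
]


@dataclass(frozen=True)
class PerfusionMaps:
    """Voxelwise CBF/CBV/MTT/Tmax maps over a brain mask."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    tmax: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self):
        shapes = {a.shape for a in (self.cbf, self.cbv, self.mtt, self.tmax, self.mask)}
        if len(shapes) != 1:
            raise ValueError("map shapes disagree")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def to_nifti_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*self.spacing, 1.0])
        for name in ("cbf", "cbv", "mtt", "tmax"):
            img = nib.Nifti1Image(getattr(self, name).astype(np.float32), affine)
            nib.save(img, outdir / f"{name}.nii.gz")


def rcbf_map(
    maps: PerfusionMaps,
    reference: str = "global_median",
    explicit_value: float | None = None,
    tmax_normal_cutoff: float = 6.0,
    mirror_axis: int = 0,
) -> np.ndarray:
    """Relative CBF: cbf divided by a reference flow.

    ``global_median`` divides by the median CBF over masked voxels with
    Tmax <= the normal cutoff (non-hypoperfused tissue); ``contralateral``
    mirrors across the mid-sagittal plane and uses the median of the
    mirrored voxel's hemisphere; ``explicit_value`` divides by a constant.
    """
    cbf, mask = maps.cbf, maps.mask
    out = np.zeros_like(cbf)
    if reference == "global_median":
        normal = mask & (maps.tmax <= tmax_normal_cutoff)
        sel = cbf[normal] if normal.any() else cbf[mask]
        ref = float(np.median(sel))
        if ref == 0:
            raise ValueError("reference CBF is zero; rCBF undefined")
        out[mask] = cbf[mask] / ref
    elif reference == "contralateral":
        nleft = cbf.shape[mirror_axis] // 2
        sl_left = [slice(None)] * 3
        sl_right = [slice(None)] * 3
        sl_left[mirror_axis] = slice(0, nleft)
        sl_right[mirror_axis] = slice(cbf.shape[mirror_axis] - nleft, cbf.shape[mirror_axis])
        refs = {}
        for side, sl in (("left", tuple(sl_left)), ("right", tuple(sl_right))):
            m = np.zeros_like(mask)
            m[sl] = mask[sl]
            vals = cbf[m]
            refs[side] = float(np.median(vals)) if vals.size else 0.0
        # a voxel is normalised by the opposite hemisphere's median
        half = np.arange(cbf.shape[mirror_axis]) < nleft
        shape = [1, 1, 1]
        shape[mirror_axis] = cbf.shape[mirror_axis]
        is_left = half.reshape(shape)
        ref_vol = np.where(is_left, refs["right"], refs["left"])
        if np.any((ref_vol == 0) & mask):
            raise ValueError("reference CBF is zero; rCBF undefined")
        out[mask] = (cbf / ref_vol)[mask]
    elif reference == "explicit_value":
        if explicit_value is None or explicit_value == 0:
            raise ValueError("explicit reference must be a nonzero value")
        out[mask] = cbf[mask] / explicit_value
    else:
        raise ValueError(f"unknown reference strategy {reference!r}")
    return out


def _round_ml(x: float) -> int:
    """Round half away from zero, as clinical reports do."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _region_volume_ml(condition: np.ndarray, mask: np.ndarray, spacing) -> float:
    voxels = int(np.count_nonzero(condition & np.asarray(mask, dtype=bool)))
    return voxels * float(np.prod(spacing)) / 1000.0


def volume_f(
    rcbf: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    threshold: float = 0.30,
    exact: bool = False,
):
    """Core-proxy volume: masked voxels with rCBF strictly < threshold, in mL."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    ml = _region_volume_ml(rcbf < threshold, mask, spacing)
    return ml if exact else _round_ml(ml)


def volume_t(
    tmax: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    threshold: float = 6.0,
    exact: bool = False,
):
    """Hypoperfusion volume: masked voxels with Tmax strictly > threshold, in mL."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    ml = _region_volume_ml(tmax > threshold, mask, spacing)
    return ml if exact else _round_ml(ml)


@dataclass(frozen=True)
class VolumeReport:
    """Final report: integer-mL volumes, warnings, and provenance."""

    volume_f_ml: int | None
    volume_t_ml: int | None
    warnings: tuple[str, ...] = ()
    volume_f_ml_exact: float | None = None
    volume_t_ml_exact: float | None = None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "volume_f_ml": self.volume_f_ml,
                "volume_t_ml": self.volume_t_ml,
                "volume_f_ml_exact": self.volume_f_ml_exact,
                "volume_t_ml_exact": self.volume_t_ml_exact,
                "warnings": list(self.warnings),
                "provenance": self.provenance,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "VolumeReport":
        d = json.loads(text)
        return cls(
            volume_f_ml=d["volume_f_ml"],
            volume_t_ml=d["volume_t_ml"],
            warnings=tuple(d["warnings"]),
            volume_f_ml_exact=d["volume_f_ml_exact"],
            volume_t_ml_exact=d["volume_t_ml_exact"],
            provenance=d["provenance"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def make_report(
    maps: PerfusionMaps | None,
    pair_outcome,
    rcbf_threshold: float = 0.30,
    tmax_threshold: float = 6.0,
    reference: str = "global_median",
    explicit_value: float | None = None,
    provenance: dict | None = None,
) -> VolumeReport:
    """Assemble the volume report, honouring a pair-selection warning.

    A PairWarning outcome yields a report that carries the warning and no
    volumes; otherwise both thresholded volumes are computed and recorded
    together with the thresholds and reference strategy.
    """
    prov = dict(provenance or {})
    prov.update(
        {
            "rcbf_threshold": rcbf_threshold,
            "tmax_threshold_s": tmax_threshold,
            "rcbf_reference": reference,
        }
    )
    if isinstance(pair_outcome, PairWarning):
        prov["warning_detail"] = pair_outcome.detail
        return VolumeReport(volume_f_ml=None, volume_t_ml=None,
                            warnings=(pair_outcome.message,), provenance=prov)
    if maps is None:
        raise ValueError("maps required when pair selection succeeded")
    rcbf = rcbf_map(maps, reference=reference, explicit_value=explicit_value)
    vf = volume_f(rcbf, maps.mask, maps.spacing, rcbf_threshold, exact=True)
    vt = volume_t(maps.tmax, maps.mask, maps.spacing, tmax_threshold, exact=True)
    prov["pair"] = list(pair_outcome) if pair_outcome is not None else None
    return VolumeReport(
        volume_f_ml=_round_ml(vf),
        volume_t_ml=_round_ml(vt),
        volume_f_ml_exact=vf,
        volume_t_ml_exact=vt,
        warnings=(),
        provenance=prov,
    )
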