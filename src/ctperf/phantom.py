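"""Digital perfusion phantom with known ground truth.

The phantom emulates a 30-frame, 1.5 s-interval stroke CTP acquisition: a
gamma-variate arterial bolus, a venous curve that is the arterial one
delayed, dispersed and amplified, and tissue whose curves follow the
forward model (delayed AIF convolved with a mono-exponential residue,
scaled by CBF).  Hypoperfused lesions are planted as regions with reduced
CBF (core) or prolonged arrival delay (penumbra), so the true CBF, CBV,
MTT, Tmax and lesion volumes are known exactly and every downstream stage
can be scored against them.

Vessel curves can be corrupted (multi-peak, jagged, truncated bolus, flat)
to exercise the validity-checking and warning paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .curves import (
    BolusParams,
    IntensityCurve,
    TissueClassSpec,
    corrupt_curve,
    make_bolus_curve,
    make_tissue_curve,
)
from .prep import CTPSeries
from .roi import AIF_NAMES, VOF_NAMES, Landmark
from .validity import RuleConfig, ValidityLabel, featurize, rule_check

__all__ = [
    "BoxRegion",
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom",
    "default_spec",
    "label_curve",
    "write_phantom",
]


@dataclass(frozen=True)
class BoxRegion:
    """Half-open voxel box [lo, hi) on each spatial axis."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self):
        if any(l >= h for l, h in zip(self.lo, self.hi)):
            raise ValueError("empty box region")

    def mask(self, dims: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(dims, dtype=bool)
        sl = tuple(slice(l, h) for l, h in zip(self.lo, self.hi))
        m[sl] = True
        return m

    @property
    def n_voxels(self) -> int:
        return int(np.prod([h - l for l, h in zip(self.lo, self.hi)]))


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to synthesise one phantom acquisition."""

    dims: tuple[int, int, int, int] = (64, 64, 8, 30)
    spacing: tuple[float, float, float] = (1.0, 1.0, 4.0)
    dt: float = 1.5
    aif_params: BolusParams = field(default_factory=BolusParams)
    vof_delay: float = 4.5  # s; keeps the arteriovenous peak delay in 3-12 s
    vof_dispersion: float = 1.3  # widening factor on beta
    vof_amplitude_factor: float = 1.5  # veins peak higher than arteries
    brain: BoxRegion = field(default_factory=lambda: BoxRegion((2, 2, 0), (62, 62, 8)))
    normal: TissueClassSpec = field(
        default_factory=lambda: TissueClassSpec("normal", cbf=0.04, mtt=4.0)
    )
    lesions: tuple = ()  # of (BoxRegion, TissueClassSpec)
    landmarks: dict = field(default_factory=dict)  # name -> (x, y, z)
    noise_sigma: float = 0.0  # HU
    baseline_hu: float = 0.0
    seed: int = 0
    residue_shape: str = "exponential"
    baseline_frames: int = 4
    vessel_corruption: str | None = None  # corruption mode for vessel curves
    corruption_severity: float = 1.0

    def __post_init__(self):
        if any(d <= 0 for d in self.dims) or len(self.dims) != 4:
            raise ValueError("dims must be 4 positive integers")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.dims[3] < 2:
            raise ValueError("need at least 2 frames")
        for name, idx in self.landmarks.items():
            if not all(0 <= i < n for i, n in zip(idx, self.dims[:3])):
                raise ValueError(f"landmark {name} outside grid")
        covered = np.zeros(self.dims[:3], dtype=int)
        for region, _cls in self.lesions:
            covered += region.mask(self.dims[:3]).astype(int)
        if (covered > 1).any():
            raise ValueError("lesion regions overlap")

    @property
    def n_frames(self) -> int:
        return self.dims[3]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def vof_params(self) -> BolusParams:
        p = self.aif_params
        return BolusParams(
            amplitude=p.amplitude * self.vof_amplitude_factor,
            t0=p.t0 + self.vof_delay,
            alpha=p.alpha,
            beta=p.beta * self.vof_dispersion,
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth maps, masks, landmarks and labels for one phantom."""

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    tmax: np.ndarray
    masks: dict  # class name -> 3D bool (brain mask under "brain")
    landmarks: list
    labels: dict  # landmark name -> bool validity
    volumes_ml: dict  # class name -> exact mL
    curves: dict  # "AIF"/"VOF" -> clean IntensityCurve; per-landmark planted curves

    @property
    def brain_mask(self) -> np.ndarray:
        return self.masks["brain"]


def default_lesions() -> tuple:
    """Core (flow 20% of normal) and penumbra (7.5 s arrival delay) boxes.

    At 1 x 1 x 4 mm voxels the core box is 3000 voxels = 12.0 mL and the
    penumbra box 10000 voxels = 40.0 mL.
    """
    core = (
        BoxRegion((4, 4, 2), (29, 34, 6)),  # 25*30*4 = 3000 voxels
        TissueClassSpec("core", cbf=0.008, mtt=8.0),
    )
    penumbra = (
        BoxRegion((4, 36, 0), (54, 61, 8)),  # 50*25*8 = 10000 voxels
        TissueClassSpec("penumbra", cbf=0.02, mtt=6.0, delay=7.5),
    )
    return (core, penumbra)


def default_landmarks() -> dict:
    """Vessel voxels in normal tissue, pairwise >= 3 voxels apart."""
    lms = {name: (58, 6 + 4 * i, 4) for i, name in enumerate(AIF_NAMES)}
    lms.update({name: (58, 40 + 4 * i, 4) for i, name in enumerate(VOF_NAMES)})
    return lms


def default_spec(seed: int = 0, noise_sigma: float = 0.0, **overrides) -> PhantomSpec:
    """The standard test phantom: 64 x 64 x 8 x 30 at 1.5 s, with core and
    penumbra lesions and 5 + 3 vessel landmarks planted."""
    kwargs = dict(
        lesions=default_lesions(),
        landmarks=default_landmarks(),
        seed=seed,
        noise_sigma=noise_sigma,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def build_phantom(spec: PhantomSpec) -> tuple[CTPSeries, PhantomTruth]:
    """Synthesise the CTP series and its exact ground truth.

    Deterministic: the same spec (including seed) yields byte-identical
    output.
    """
    dims3 = spec.dims[:3]
    n = spec.n_frames
    aif = make_bolus_curve(spec.aif_params, n, spec.dt, spec.baseline_frames)
    vof = make_bolus_curve(spec.vof_params(), n, spec.dt, spec.baseline_frames)

    vessel_curves = {"AIF": aif, "VOF": vof}
    if spec.vessel_corruption is not None:
        vessel_curves = {
            kind: corrupt_curve(c, spec.vessel_corruption, spec.corruption_severity, spec.seed)
            for kind, c in vessel_curves.items()
        }

    brain = spec.brain.mask(dims3)
    data = np.zeros((*dims3, n))

    # tissue: normal class everywhere in brain, lesion classes override
    class_curves = {}
    cbf = np.zeros(dims3)
    cbv = np.zeros(dims3)
    mtt = np.zeros(dims3)
    tmax = np.zeros(dims3)
    masks = {"brain": brain}
    volumes = {}

    def paint(region_mask, cls):
        curve = make_tissue_curve(aif, cls, spec.dt, spec.residue_shape)
        class_curves[cls.name] = curve
        data[region_mask] = curve.values
        cbf[region_mask] = cls.cbf
        cbv[region_mask] = cls.cbv
        mtt[region_mask] = cls.mtt
        tmax[region_mask] = cls.delay

    paint(brain, spec.normal)
    for region, cls in spec.lesions:
        rmask = region.mask(dims3) & brain
        paint(rmask, cls)
        masks[cls.name] = rmask
        volumes[cls.name] = rmask.sum() * spec.voxel_volume_mm3 / 1000.0
    volumes["brain"] = brain.sum() * spec.voxel_volume_mm3 / 1000.0

    # vessels: planted on single voxels
    landmarks = []
    planted = {}
    vessel_mask = np.zeros(dims3, dtype=bool)
    for name, idx in spec.landmarks.items():
        kind = name.split("_")[0]
        curve = vessel_curves[kind]
        data[tuple(idx)] = curve.values
        vessel_mask[tuple(idx)] = True
        landmarks.append(Landmark(name, tuple(idx)))
        planted[name] = curve
    masks["vessels"] = vessel_mask
    lesion_any = np.zeros(dims3, dtype=bool)
    for k, m in masks.items():
        if k not in ("brain", "vessels"):
            lesion_any |= m
    masks["normal"] = brain & ~lesion_any & ~vessel_mask

    if spec.baseline_hu:
        data += spec.baseline_hu
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, data.shape)

    labels = {}
    for name, curve in planted.items():
        kind = name.split("_")[0]
        partner = planted.get("VOF_0" if kind == "AIF" else "AIF_0")
        labels[name] = label_curve(curve, kind, partner).label

    series = CTPSeries(data, spacing=spec.spacing, dt=spec.dt)
    truth = PhantomTruth(
        cbf=cbf, cbv=cbv, mtt=mtt, tmax=tmax,
        masks=masks, landmarks=landmarks, labels=labels, volumes_ml=volumes,
        curves={**vessel_curves, **planted, "tissue": class_curves},
    )
    return series, truth


def label_curve(
    curve: IntensityCurve,
    kind: str,
    partner: IntensityCurve | None = None,
    config: RuleConfig | None = None,
) -> ValidityLabel:
    """Rule-based ground-truth validity label for a synthetic curve.

    Conjunction of the rule set; when the paired vessel curve is supplied,
    the arteriovenous peak delay must also fall in the configured window.
    """
    cfg = config or RuleConfig()
    ok = rule_check(curve, kind, cfg).valid
    if ok and partner is not None:
        ttp_self = featurize(curve, cfg).time_to_peak
        ttp_partner = featurize(partner, cfg).time_to_peak
        delay = ttp_self - ttp_partner if kind == "VOF" else ttp_partner - ttp_self
        lo, hi = cfg.delay_window
        ok = lo <= delay <= hi
    return ValidityLabel(curve_id="", kind=kind, label=bool(ok))


def write_phantom(series: CTPSeries, truth: PhantomTruth, outdir: str | Path) -> None:
    """Write the series (4D NIfTI + sidecar), truth maps (3D NIfTI), and
    landmark/label JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    series.to_nifti(outdir / "ctp.nii.gz")
    affine = np.diag([*series.spacing, 1.0])
    for name in ("cbf", "cbv", "mtt", "tmax"):
        img = nib.Nifti1Image(getattr(truth, name).astype(np.float32), affine)
        nib.save(img, outdir / f"true_{name}.nii.gz")
    for name, mask in truth.masks.items():
        img = nib.Nifti1Image(mask.astype(np.uint8), affine)
        nib.save(img, outdir / f"mask_{name}.nii.gz")
    (outdir / "landmarks.json").write_text(
        json.dumps([{"name": lm.name, "index": list(lm.index)} for lm in truth.landmarks], indent=2)
    )
    (outdir / "labels.json").write_text(json.dumps(truth.labels, indent=2, sort_keys=True))
    (outdir / "volumes_ml.json").write_text(json.dumps(truth.volumes_ml, indent=2, sort_keys=True))
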