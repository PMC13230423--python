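"""End-to-end orchestration: preprocessing, ROI correction, pair
validation, deconvolution and volume reporting — plus synthesis of the
labelled training set for the validity classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import BolusParams, IntensityCurve, corrupt_curve, make_bolus_curve
from .deconv import make_maps
from .phantom import label_curve
from .prep import CTPSeries, compute_mip, motion_correct
from .quant import PerfusionMaps, VolumeReport, make_report
from .roi import AIF_NAMES, VOF_NAMES, Landmark, correct_roi, extract_curve, heuristic_localize
from .validity import (
    IVClassifier,
    LVClassifier,
    PairWarning,
    RuleConfig,
    train_iv,
    train_lv,
)

__all__ = [
    "PipelineResult",
    "run_pipeline",
    "make_training_curves",
    "train_default_models",
]


@dataclass(frozen=True)
class PipelineResult:
    report: VolumeReport
    maps: PerfusionMaps | None
    landmarks: list
    pair: tuple | PairWarning
    curves: dict


def run_pipeline(
    series: CTPSeries,
    landmarks: list[Landmark] | None = None,
    mask: np.ndarray | None = None,
    *,
    do_motion_correct: bool = True,
    mask_threshold: float = 2.0,
    use_cor: bool = True,
    roi_radius: float = 8.0,
    use_iv: bool = True,
    use_lv: bool = True,
    iv_aif: IVClassifier | None = None,
    iv_vof: IVClassifier | None = None,
    lv: LVClassifier | None = None,
    rule_config: RuleConfig | None = None,
    mode: str = "bcSVD",
    truncation_fraction: float = 0.10,
    rcbf_threshold: float = 0.30,
    tmax_threshold: float = 6.0,
    reference: str = "global_median",
    baseline_frames: int = 4,
    provenance: dict | None = None,
) -> PipelineResult:
    """Run the full pipeline on a CTP series.

    Landmarks may come from any provider (file, heuristic localiser, or an
    external model); when None the heuristic localiser runs on the brain
    mask.  A missing mask is approximated by thresholding the temporal
    max-minus-min projection.  Classifier stages degrade gracefully: with
    ``use_iv``/``use_lv`` off (or no fitted models supplied) the rule set
    and the arteriovenous delay window still gate the pair.
    """
    if do_motion_correct:
        series = motion_correct(series)
    if mask is None:
        mask = compute_mip(series).data > mask_threshold
    if landmarks is None:
        landmarks = heuristic_localize(series, mask, baseline_frames=baseline_frames)

    if use_cor:
        landmarks = [
            correct_roi(series, lm, radius=roi_radius, baseline_frames=baseline_frames)
            for lm in landmarks
        ]

    curves = {
        lm.name: extract_curve(series, lm, baseline_frames=baseline_frames) for lm in landmarks
    }
    aif_cands = [curves[n] for n in AIF_NAMES if n in curves]
    vof_cands = [curves[n] for n in VOF_NAMES if n in curves]

    from .validity import select_pair

    pair = select_pair(
        aif_cands,
        vof_cands,
        iv_aif=iv_aif if use_iv else None,
        iv_vof=iv_vof if use_iv else None,
        lv=lv if use_lv else None,
        config=rule_config,
    )

    prov = dict(provenance or {})
    prov.update(
        {
            "modules": {
                "motion_correct": do_motion_correct,
                "roi_correction": use_cor,
                "iv_model": use_iv and iv_aif is not None,
                "lv_model": use_lv and lv is not None,
            },
            "deconvolution": {"mode": mode, "truncation_fraction": truncation_fraction},
            "landmarks": {lm.name: list(lm.index) for lm in landmarks},
        }
    )

    if isinstance(pair, PairWarning):
        report = make_report(None, pair, rcbf_threshold, tmax_threshold, reference,
                             provenance=prov)
        return PipelineResult(report, None, landmarks, pair, curves)

    ai, vi = pair
    aif_curve = aif_cands[ai]
    aif_name = [n for n in AIF_NAMES if n in curves][ai]
    vof_name = [n for n in VOF_NAMES if n in curves][vi]
    prov["pair_landmarks"] = [aif_name, vof_name]
    maps = make_maps(series, aif_curve, mask, mode=mode,
                     truncation_fraction=truncation_fraction, baseline_frames=baseline_frames)
    report = make_report(maps, pair, rcbf_threshold, tmax_threshold, reference, provenance=prov)
    return PipelineResult(report, maps, landmarks, pair, curves)


def make_training_curves(
    kind: str,
    n_valid: int = 200,
    n_invalid: int = 200,
    n_frames: int = 30,
    dt: float = 1.5,
    seed: int = 0,
    noise_sigma: float = 2.0,
):
    """Synthesise a labelled curve set for one vessel kind.

    Valid-intended curves are gamma-variate boluses with jittered
    parameters and mild noise; invalid-intended curves cycle through the
    corruption modes plus a weak-enhancement variant.  Labels are assigned
    by the rule set (the annotation procedure), not by intent.
    """
    if kind not in ("AIF", "VOF"):
        raise ValueError("kind must be 'AIF' or 'VOF'")
    rng = np.random.default_rng(seed)
    amp_scale = 1.0 if kind == "AIF" else 1.5
    beta_scale = 1.0 if kind == "AIF" else 1.3
    t0_shift = 0.0 if kind == "VOF" else 0.0

    def sample_params(weak: bool = False):
        amp = rng.uniform(25, 60) if weak else rng.uniform(110, 200) * amp_scale
        return BolusParams(
            amplitude=amp,
            t0=rng.uniform(4.5, 7.5) + (4.5 if kind == "VOF" else t0_shift),
            alpha=rng.uniform(1.6, 2.4),
            beta=rng.uniform(1.2, 1.8) * beta_scale,
        )

    curves, labels = [], []
    for i in range(n_valid):
        c = make_bolus_curve(sample_params(), n_frames, dt)
        c = corrupt_curve(c, "gaussian", noise_sigma, seed=int(rng.integers(2**31)))
        curves.append(c)
        labels.append(label_curve(c, kind).label)
    modes = ("multi_peak", "jagged", "truncated_bolus", "flat", "weak")
    for i in range(n_invalid):
        mode = modes[i % len(modes)]
        if mode == "weak":
            c = make_bolus_curve(sample_params(weak=True), n_frames, dt)
            c = corrupt_curve(c, "gaussian", noise_sigma, seed=int(rng.integers(2**31)))
        else:
            c = make_bolus_curve(sample_params(), n_frames, dt)
            c = corrupt_curve(c, mode, severity=1.0, seed=int(rng.integers(2**31)))
        curves.append(c)
        labels.append(label_curve(c, kind).label)
    return curves, labels


def train_default_models(
    seed: int = 0,
    n_valid: int = 200,
    n_invalid: int = 200,
    n_frames: int = 30,
    dt: float = 1.5,
):
    """Train IV (AIF and VOF) and LV classifiers on synthetic curve sets.

    Returns ``(iv_aif, iv_vof, lv)`` fitted models.
    """
    aif_curves, aif_labels = make_training_curves("AIF", n_valid, n_invalid, n_frames, dt, seed)
    vof_curves, vof_labels = make_training_curves(
        "VOF", n_valid, n_invalid, n_frames, dt, seed + 1
    )
    iv_aif = train_iv(aif_curves, aif_labels, "AIF", seed=seed)
    iv_vof = train_iv(vof_curves, vof_labels, "VOF", seed=seed)
    # LV: arterial vs venous, using only physiologically valid curves
    lv_curves = [c for c, l in zip(aif_curves, aif_labels) if l]
    lv_labels = [False] * len(lv_curves)
    vof_valid = [c for c, l in zip(vof_curves, vof_labels) if l]
    lv_curves += vof_valid
    lv_labels += [True] * len(vof_valid)
    lv = train_lv(lv_curves, lv_labels, seed=seed)
    return iv_aif, iv_vof, lv
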