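"""Physiological validity checking of AIF/VOF candidate curves.

Three layers of defence against computing perfusion maps from a bad input:

* a rule set encoding what a usable arterial or venous curve looks like —
  strong single peak (> 80 HU enhancement), narrow width, fast attenuation
  back toward baseline, and (for arteries) an early peak;
* a trainable intensity-validity (IV) classifier, one per vessel kind,
  gradient-boosted on curve features, which catches shapes the hand rules
  miss;
* a landmark-validity (LV) classifier that decides arterial vs venous, so
  the final pair cannot be two copies of the same vessel.

Pair selection then requires a 3–12 s peak delay from artery to vein.  When
no candidate pair survives, the result is a warning — a result in its own
right, signalling the acquisition (bad bolus timing, motion, off-vessel
landmarks) rather than the pipeline.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBClassifier

from .curves import IntensityCurve

__all__ = [
    "CurveFeatures",
    "RuleConfig",
    "ValidityResult",
    "ValidityLabel",
    "PairWarning",
    "featurize",
    "feature_vector",
    "FEATURE_NAMES",
    "rule_check",
    "IVClassifier",
    "LVClassifier",
    "train_iv",
    "iv_predict",
    "train_lv",
    "lv_predict",
    "select_pair",
    "CLINICAL_IV_PRESET",
]

# IV hyperparameters reported for the original clinical tuning; kept as a
# preset, not defaults — they were tuned to a different data distribution.
CLINICAL_IV_PRESET = dict(
    n_estimators=100,
    max_depth=78,
    learning_rate=0.07,
    gamma=5,
    max_delta_step=10,
    scale_pos_weight=0.1118,
)

FEATURE_NAMES = (
    "baseline",
    "peak_enhancement",
    "time_to_peak",
    "fwhm",
    "n_peaks",
    "decay_fraction",
    "auc",
)


@dataclass(frozen=True)
class CurveFeatures:
    """Shape descriptors of a time–attenuation curve."""

    baseline: float  # HU
    peak_enhancement: float  # HU above baseline
    time_to_peak: float  # s
    fwhm: float  # s
    n_peaks: int  # local maxima above the prominence floor
    decay_fraction: float  # enhancement shed within the decay window, in [0,1]
    auc: float  # HU*s, baseline-subtracted


@dataclass(frozen=True)
class ValidityResult:
    valid: bool
    failed_rules: tuple[str, ...]
    features: CurveFeatures


@dataclass(frozen=True)
class ValidityLabel:
    curve_id: str
    kind: str  # AIF | VOF
    label: bool


@dataclass(frozen=True)
class PairWarning:
    """Returned when no physiologically valid AIF/VOF pair exists."""

    message: str = "invalid curve"
    detail: str = ""


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the rule-based validity check.

    The enhancement floor (80 HU) and the arteriovenous peak-delay window
    (3–12 s) are the two numeric rules stated for clinical curves; the rest
    quantify the qualitative rules (sharp single peak, fast attenuation,
    early arterial peak) and are configurable.
    """

    min_peak_enhancement: float = 80.0  # HU above baseline
    peak_is_absolute: bool = False  # True: compare raw max HU instead
    fwhm_max: dict = field(default_factory=lambda: {"AIF": 12.0, "VOF": 20.0})  # s
    decay_min: float = 0.4
    decay_window: float = 15.0  # s after the peak
    prominence_fraction: float = 0.1  # of peak enhancement
    early_fraction: float = 2.0 / 3.0  # AIF peak before this fraction of scan
    delay_window: tuple[float, float] = (3.0, 12.0)  # s, VOF peak minus AIF peak
    enabled: tuple[str, ...] = ("peak", "single_peak", "sharpness", "decay", "early_peak")


def _fwhm(values: np.ndarray, dt: float, baseline: float) -> float:
    """Full width at half maximum by linear interpolation around the argmax."""
    enh = values - baseline
    imax = int(np.argmax(enh))
    peak = enh[imax]
    if peak <= 0:
        return 0.0
    half = peak / 2.0
    # walk left from the peak to the half-height crossing
    left = 0.0
    for i in range(imax, 0, -1):
        if enh[i - 1] <= half:
            frac = (enh[i] - half) / (enh[i] - enh[i - 1])
            left = imax - (i - 1) - (1 - frac)
            break
    else:
        left = float(imax)
    right = float(len(values) - 1 - imax)
    for i in range(imax, len(values) - 1):
        if enh[i + 1] <= half:
            frac = (enh[i] - half) / (enh[i] - enh[i + 1])
            right = (i + 1) - imax - (1 - frac)
            break
    return (left + right) * dt


def featurize(curve: IntensityCurve, config: RuleConfig | None = None) -> CurveFeatures:
    """Compute the feature set used by both the rules and the classifiers."""
    cfg = config or RuleConfig()
    v = curve.values
    baseline = curve.baseline
    enh = v - baseline
    peak_enh = float(enh.max())
    imax = int(np.argmax(enh))
    ttp = imax * curve.dt

    if peak_enh > 0:
        prominence = cfg.prominence_fraction * peak_enh
        peaks, _ = find_peaks(enh, prominence=prominence)
        # an argmax at either boundary is a peak find_peaks cannot see
        n_peaks = len(peaks)
        if imax not in peaks and (imax == 0 or imax == len(v) - 1):
            n_peaks += 1
        fwhm = _fwhm(v, curve.dt, baseline)
        decay_idx = min(len(v) - 1, imax + int(round(cfg.decay_window / curve.dt)))
        decay = float(np.clip((enh[imax] - enh[decay_idx]) / peak_enh, 0.0, 1.0))
    else:
        n_peaks, fwhm, decay = 0, 0.0, 0.0

    auc = float(np.trapezoid(enh, dx=curve.dt))
    return CurveFeatures(
        baseline=float(baseline),
        peak_enhancement=peak_enh,
        time_to_peak=float(ttp),
        fwhm=float(fwhm),
        n_peaks=int(n_peaks),
        decay_fraction=decay,
        auc=auc,
    )


def feature_vector(curve: IntensityCurve, config: RuleConfig | None = None) -> np.ndarray:
    f = featurize(curve, config)
    return np.array([getattr(f, name) for name in FEATURE_NAMES], dtype=float)


def rule_check(
    curve: IntensityCurve, kind: str, config: RuleConfig | None = None
) -> ValidityResult:
    """Apply the rule set; returns every failed rule, not just the first.

    Rules, in order: peak (enhancement > 80 HU), single_peak, sharpness
    (FWHM cap per vessel kind), decay (fast attenuation after the peak),
    and for AIF the early_peak rule.
    """
    cfg = config or RuleConfig()
    if kind not in ("AIF", "VOF"):
        raise ValueError("kind must be 'AIF' or 'VOF'")
    f = featurize(curve, cfg)
    failed = []
    peak_value = curve.values.max() if cfg.peak_is_absolute else f.peak_enhancement
    if "peak" in cfg.enabled and not peak_value > cfg.min_peak_enhancement:
        failed.append("peak")
    if "single_peak" in cfg.enabled and f.n_peaks != 1:
        failed.append("single_peak")
    if "sharpness" in cfg.enabled and not f.fwhm <= cfg.fwhm_max[kind]:
        failed.append("sharpness")
    if "decay" in cfg.enabled and not f.decay_fraction >= cfg.decay_min:
        failed.append("decay")
    if kind == "AIF" and "early_peak" in cfg.enabled:
        if not f.time_to_peak <= cfg.early_fraction * curve.duration:
            failed.append("early_peak")
    return ValidityResult(valid=not failed, failed_rules=tuple(failed), features=f)


class _CurveClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared fit/predict plumbing for curve classifiers.

    Estimators take a list of IntensityCurve (or a pre-built feature
    matrix) and fit an underlying sklearn-compatible model on the curve
    feature set, optionally concatenated with the peak-normalised raw
    curve.  Deterministic given ``random_state``.
    """

    role: str = ""

    def __init__(self, random_state=0, include_raw=False, augment_sigma=0.0, n_augment=0):
        self.random_state = random_state
        self.include_raw = include_raw
        self.augment_sigma = augment_sigma
        self.n_augment = n_augment

    def _make_model(self):  # pragma: no cover - abstract
        raise NotImplementedError

    def _features(self, curves) -> np.ndarray:
        rows = []
        for c in curves:
            row = feature_vector(c)
            if self.include_raw:
                peak = max(abs(c.values).max(), 1e-12)
                row = np.concatenate([row, c.values / peak])
            rows.append(row)
        return np.asarray(rows)

    def _augmented(self, curves, y):
        if self.n_augment <= 0 or self.augment_sigma <= 0:
            return list(curves), np.asarray(y, dtype=int)
        out, labels = list(curves), list(np.asarray(y, dtype=int))
        for c, lab in zip(curves, y):
            # per-curve seed from the curve content, so augmentation does
            # not depend on the position of the curve in the training list
            seed = (zlib.crc32(np.ascontiguousarray(c.values).tobytes()) ^ self.random_state) & 0x7FFFFFFF
            rng = np.random.default_rng(seed)
            for _ in range(self.n_augment):
                noisy = c.with_values(c.values + rng.normal(0, self.augment_sigma, len(c)))
                out.append(noisy)
                labels.append(int(lab))
        return out, np.asarray(labels)

    def fit(self, curves, y):
        y = np.asarray(y, dtype=int)
        if len(curves) != len(y):
            raise ValueError("curves and labels length mismatch")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        lengths = {len(c) for c in curves}
        if self.include_raw and len(lengths) > 1:
            raise ValueError("raw-curve features require equal-length curves")
        curves_aug, y_aug = self._augmented(curves, y)
        X = self._features(curves_aug)
        # canonical row order: training is invariant to curve order
        order = np.lexsort(np.vstack([X.T, y_aug[None, :]])[::-1])
        X, y_aug = X[order], y_aug[order]
        self.model_ = self._make_model()
        self.model_.fit(X, y_aug)
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.unique(y_aug)
        return self

    def predict_proba_curve(self, curve: IntensityCurve) -> float:
        check_is_fitted(self, "model_")
        X = self._features([curve])
        return float(self.model_.predict_proba(X)[0, 1])

    def predict_curve(self, curve: IntensityCurve, threshold: float = 0.5) -> bool:
        return self.predict_proba_curve(curve) >= threshold

    # array-style sklearn interface on feature matrices built via _features
    def predict(self, curves):
        check_is_fitted(self, "model_")
        return self.model_.predict(self._features(curves))

    def predict_proba(self, curves):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self._features(curves))

    # --- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist fitted state plus a feature-contract manifest."""
        import joblib

        path = Path(path)
        joblib.dump(self, path)
        manifest = {
            "role": self.role,
            "feature_names": list(FEATURE_NAMES),
            "include_raw": self.include_raw,
            "n_features": int(getattr(self, "n_features_in_", 0)),
            "random_state": self.random_state,
            "format_version": 1,
        }
        Path(str(path) + ".manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path):
        import joblib

        return joblib.load(Path(path))


class IVClassifier(_CurveClassifierBase):
    """Intensity-validity model: is this curve a usable AIF (or VOF)?

    One gradient-boosted model per vessel kind, trained only on curves of
    that kind, with Gaussian-noise augmentation emulating jagged /
    multi-peak artefacts.
    """

    def __init__(
        self,
        kind="AIF",
        random_state=0,
        include_raw=False,
        augment_sigma=5.0,
        n_augment=1,
        xgb_params=None,
    ):
        super().__init__(
            random_state=random_state,
            include_raw=include_raw,
            augment_sigma=augment_sigma,
            n_augment=n_augment,
        )
        self.kind = kind
        self.xgb_params = xgb_params

    @property
    def role(self):
        return f"IV_{self.kind}"

    def _make_model(self):
        params = dict(self.xgb_params or {})
        params.setdefault("n_estimators", 50)
        params.setdefault("max_depth", 4)
        return XGBClassifier(
            random_state=self.random_state,
            eval_metric="logloss",
            n_jobs=1,
            **params,
        )


class LVClassifier(_CurveClassifierBase):
    """Landmark-validity model: is this curve venous (VOF) rather than arterial?

    A feed-forward network on the curve features; time-to-peak and peak
    enhancement carry most of the signal, since veins peak later and higher
    than arteries.
    """

    role = "LV"

    def __init__(
        self,
        random_state=0,
        include_raw=False,
        augment_sigma=0.0,
        n_augment=0,
        hidden_layer_sizes=(32, 16),
        max_iter=2000,
    ):
        super().__init__(
            random_state=random_state,
            include_raw=include_raw,
            augment_sigma=augment_sigma,
            n_augment=n_augment,
        )
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter

    def _features(self, curves) -> np.ndarray:
        X = super()._features(curves)
        # HU- and second-scale features need comparable magnitudes for the MLP
        scale = np.array([100.0, 100.0, 10.0, 10.0, 1.0, 1.0, 1000.0])
        X = X.copy()
        X[:, : len(scale)] /= scale
        return X

    def _make_model(self):
        return MLPClassifier(
            hidden_layer_sizes=self.hidden_layer_sizes,
            max_iter=self.max_iter,
            random_state=self.random_state,
        )


def train_iv(
    curves,
    labels,
    kind: str,
    augment_sigma: float = 5.0,
    n_augment: int = 1,
    seed: int = 0,
) -> IVClassifier:
    """Fit the intensity-validity classifier for one vessel kind."""
    y = [lab.label if isinstance(lab, ValidityLabel) else bool(lab) for lab in labels]
    clf = IVClassifier(kind=kind, random_state=seed, augment_sigma=augment_sigma, n_augment=n_augment)
    return clf.fit(curves, y)


def iv_predict(model: IVClassifier, curve: IntensityCurve, kind: str | None = None):
    """Probability the curve is a valid vessel curve, and the 0.5-call."""
    if kind is not None and model.role != f"IV_{kind}":
        raise ValueError(f"model role {model.role} does not match curve kind {kind}")
    p = model.predict_proba_curve(curve)
    return p, p >= 0.5


def train_lv(curves, is_vof_labels, seed: int = 0) -> LVClassifier:
    """Fit the arterial-vs-venous classifier."""
    clf = LVClassifier(random_state=seed)
    return clf.fit(curves, [bool(b) for b in is_vof_labels])


def lv_predict(model: LVClassifier, curve: IntensityCurve):
    """Probability the curve is venous, and the 0.5-call."""
    p = model.predict_proba_curve(curve)
    return p, p >= 0.5


def select_pair(
    aif_cands: list[IntensityCurve],
    vof_cands: list[IntensityCurve],
    iv_aif: IVClassifier | None = None,
    iv_vof: IVClassifier | None = None,
    lv: LVClassifier | None = None,
    config: RuleConfig | None = None,
):
    """Choose the final AIF/VOF pair, or return a :class:`PairWarning`.

    AIF candidates must pass the rules, the AIF IV model, and be called
    arterial by the LV model; VOF candidates must pass the rules, the VOF IV
    model, and be called venous.  Surviving cross pairs must have a venous
    peak 3–12 s after the arterial peak.  AIF rank: earlier peak, then
    higher enhancement; VOF rank: higher enhancement.  Classifiers may be
    None (ablation), leaving the rules and delay window in force.

    Returns ``(aif_index, vof_index)`` into the candidate lists, or a
    PairWarning.
    """
    cfg = config or RuleConfig()
    if len(aif_cands) == 0 or len(vof_cands) == 0:
        return PairWarning(detail="empty candidate list")

    def survives(curve, kind, iv, want_vof):
        if not rule_check(curve, kind, cfg).valid:
            return False
        if iv is not None and not iv_predict(iv, curve)[1]:
            return False
        if lv is not None and lv_predict(lv, curve)[1] != want_vof:
            return False
        return True

    aif_ok = [i for i, c in enumerate(aif_cands) if survives(c, "AIF", iv_aif, want_vof=False)]
    vof_ok = [i for i, c in enumerate(vof_cands) if survives(c, "VOF", iv_vof, want_vof=True)]
    if not aif_ok or not vof_ok:
        return PairWarning(detail="no candidate passed validity checks")

    feats_a = {i: featurize(aif_cands[i], cfg) for i in aif_ok}
    feats_v = {i: featurize(vof_cands[i], cfg) for i in vof_ok}
    lo, hi = cfg.delay_window
    pairs = [
        (i, j)
        for i in aif_ok
        for j in vof_ok
        if lo <= feats_v[j].time_to_peak - feats_a[i].time_to_peak <= hi
    ]
    if not pairs:
        return PairWarning(detail="no pair within the arteriovenous delay window")
    pairs.sort(
        key=lambda ij: (
            feats_a[ij[0]].time_to_peak,
            -feats_a[ij[0]].peak_enhancement,
            -feats_v[ij[1]].peak_enhancement,
            ij,
        )
    )
    return pairs[0]
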