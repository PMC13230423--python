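"""Time–attenuation curves: the gamma-variate bolus, the tissue forward model,
and controlled corruption modes.

An :class:`IntensityCurve` is a sampled HU time series at a fixed frame
interval ``dt`` — the carrier of arterial input (AIF), venous output (VOF)
and tissue signals.  The forward model convolves a delayed AIF with a
mono-exponential vascular residue function, scaled by CBF, which is the
discrete relationship every deconvolution stage inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "IntensityCurve",
    "BolusParams",
    "TissueClassSpec",
    "gamma_variate",
    "make_bolus_curve",
    "make_tissue_curve",
    "corrupt_curve",
    "CORRUPTION_MODES",
]


@dataclass(frozen=True)
class IntensityCurve:
    """A HU time series at fixed frame interval.

    Parameters
    ----------
    values : ndarray, shape (T,)
        HU samples.
    dt : float
        Frame interval in seconds.
    baseline_frames : int
        Number of pre-contrast frames used for baseline estimation.
    """

    values: np.ndarray
    dt: float
    baseline_frames: int = 4

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("curve needs at least 2 samples")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 1 <= self.baseline_frames < v.size:
            raise ValueError("baseline_frames must be in [1, T)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame 0 at t=0)."""
        return np.arange(len(self)) * self.dt

    @property
    def duration(self) -> float:
        """Time of the last sample in seconds."""
        return (len(self) - 1) * self.dt

    @property
    def baseline(self) -> float:
        """Mean of the first ``baseline_frames`` samples."""
        return float(np.mean(self.values[: self.baseline_frames]))

    def baseline_subtracted(self) -> np.ndarray:
        return self.values - self.baseline

    def with_values(self, values: np.ndarray) -> "IntensityCurve":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as (frame, time_s, hu) for CSV export."""
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "time_s": self.times, "hu": self.values}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, dt: float | None = None, baseline_frames: int = 4):
        df = pd.read_csv(path)
        if dt is None:
            t = df["time_s"].to_numpy()
            dt = float(t[1] - t[0])
        return cls(df["hu"].to_numpy(float), dt=dt, baseline_frames=baseline_frames)


@dataclass(frozen=True)
class BolusParams:
    """Gamma-variate bolus parameters.

    The curve is ``amplitude * ((t-t0)/(alpha*beta))**alpha
    * exp(alpha - (t-t0)/beta)`` for t >= t0, zero before onset; normalised
    so the analytic peak value equals ``amplitude`` at ``t0 + alpha*beta``.
    """

    amplitude: float = 150.0  # HU at peak
    t0: float = 6.0  # onset, s
    alpha: float = 2.0  # shape
    beta: float = 1.5  # scale, s

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.t0 < 0:
            raise ValueError("onset t0 must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def time_to_peak(self) -> float:
        """Analytic mode of the bolus, t0 + alpha*beta (seconds)."""
        return self.t0 + self.alpha * self.beta


@dataclass(frozen=True)
class TissueClassSpec:
    """Perfusion parameters of one tissue class.

    cbf is in internal arbitrary flow units (1/s scale); cbv follows from
    the central volume theorem cbv = cbf * mtt.
    """

    name: str
    cbf: float
    mtt: float
    delay: float = 0.0

    def __post_init__(self):
        if self.cbf < 0:
            raise ValueError("cbf must be >= 0")
        if self.mtt <= 0:
            raise ValueError("mtt must be positive")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")

    @property
    def cbv(self) -> float:
        return self.cbf * self.mtt


def gamma_variate(t: np.ndarray, params: BolusParams) -> np.ndarray:
    """Evaluate the peak-normalised gamma-variate bolus at times ``t``."""
    t = np.asarray(t, dtype=float)
    tau = t - params.t0
    out = np.zeros_like(tau)
    pos = tau > 0
    x = tau[pos] / (params.alpha * params.beta)
    out[pos] = params.amplitude * x**params.alpha * np.exp(
        params.alpha - tau[pos] / params.beta
    )
    return out


def make_bolus_curve(
    params: BolusParams, n_frames: int, dt: float, baseline_frames: int = 4
) -> IntensityCurve:
    """Sample a gamma-variate bolus on the acquisition grid.

    The curve is zero before onset, unimodal, and non-negative; its discrete
    argmax falls on the sample nearest the analytic peak t0 + alpha*beta.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(n_frames) * dt
    return IntensityCurve(gamma_variate(t, params), dt=dt, baseline_frames=baseline_frames)


def residue_function(
    t: np.ndarray, mtt: float, delay: float = 0.0, shape: str = "exponential"
) -> np.ndarray:
    """Vascular residue function Fr(t): tracer fraction still intravascular.

    Mono-exponential ``exp(-(t-delay)/mtt)`` by default; a box-car of width
    mtt is available for sensitivity checks.  Zero before the arrival delay.
    """
    t = np.asarray(t, dtype=float)
    tau = t - delay
    if shape == "exponential":
        out = np.where(tau >= 0, np.exp(-np.maximum(tau, 0.0) / mtt), 0.0)
    elif shape == "boxcar":
        out = np.where((tau >= 0) & (tau < mtt), 1.0, 0.0)
    else:
        raise ValueError(f"unknown residue shape {shape!r}")
    return out


def make_tissue_curve(
    aif: IntensityCurve,
    cls: TissueClassSpec,
    dt: float | None = None,
    residue_shape: str = "exponential",
) -> IntensityCurve:
    """Forward model: tissue curve = dt * CBF * (AIF convolved with Fr).

    Direct discrete summation Fv[j] = dt * CBF * sum_{i<=j} AIF[i] *
    Fr(t_j - t_i), with Fr delayed by the class's arrival delay.
    """
    if dt is None:
        dt = aif.dt
    if cls.mtt <= 0:
        raise ValueError("mtt must be positive")
    n = len(aif)
    t = np.arange(n) * dt
    fr = residue_function(t, cls.mtt, cls.delay, residue_shape)
    # full convolution truncated to n samples == the causal double sum
    conv = np.convolve(aif.values, fr)[:n]
    return aif.with_values(dt * cls.cbf * conv)


CORRUPTION_MODES = ("gaussian", "multi_peak", "jagged", "truncated_bolus", "flat")


def corrupt_curve(
    curve: IntensityCurve, mode: str, severity: float = 1.0, seed: int = 0
) -> IntensityCurve:
    """Degrade a curve the way bad acquisitions do.

    Modes
    -----
    gaussian
        Additive N(0, severity) HU noise.
    multi_peak
        Adds a second gamma-shaped bump (amplitude ``severity`` x peak
        enhancement, floor 0.5x) well after the original peak, emulating
        recirculation or motion artefact.
    jagged
        Heavy high-frequency noise (sign-alternating component) so local
        maxima proliferate.
    truncated_bolus
        Shifts the enhancement late so the curve has not returned toward
        baseline by the final frame (bad bolus timing).
    flat
        Near-constant baseline: the off-vessel / no-enhancement case.
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}")
    rng = np.random.default_rng(seed)
    v = curve.values.copy()
    n = len(v)
    t = curve.times
    base = float(np.mean(v[: curve.baseline_frames]))
    enh = float(v.max() - base)

    if mode == "gaussian":
        v = v + rng.normal(0.0, severity, n) if severity > 0 else v
    elif mode == "multi_peak":
        amp = max(0.5, severity) * max(enh, 1.0)
        peak_t = t[int(np.argmax(v))]
        bump_t0 = min(peak_t + 6.0, curve.duration - 4 * curve.dt)
        bump = gamma_variate(t, BolusParams(amplitude=amp, t0=bump_t0, alpha=2.0, beta=1.0))
        v = v + bump
    elif mode == "jagged":
        sigma = max(severity, 15.0)
        v = v + rng.normal(0.0, sigma, n) + sigma * 0.8 * np.where(np.arange(n) % 2, 1, -1)
    elif mode == "truncated_bolus":
        # push onset so the peak sits in the last frames: no downslope captured
        shift = max(int(severity), n - int(np.argmax(v)) - 2)
        v = np.concatenate([np.full(shift, base), v[: n - shift]]) if shift > 0 else v
    elif mode == "flat":
        v = np.full(n, base) + rng.normal(0.0, min(severity, 1.0), n)
    return curve.with_values(v)
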