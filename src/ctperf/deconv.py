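"""Truncated-SVD deconvolution of tissue curves against the AIF.

The tissue curve is the convolution of the arterial input with the voxel's
CBF-scaled residue function, Fv = dt * (A r) where A is built from AIF
samples.  Two constructions are provided:

* **sSVD** — the lower-triangular Toeplitz system.  Exact for zero
  bolus-arrival delay, but a causal system: tracer arriving later than the
  AIF forces the recovered residue into non-physical shapes and
  underestimates CBF.
* **bcSVD** — the block-circulant extension.  The AIF column is zero-padded
  to length 2N and wrapped, making the inversion time-shift invariant:
  arrival delay moves the residue peak (read out as Tmax) instead of
  corrupting its height.

Singular values below ``truncation_fraction`` of the largest are discarded
when inverting, the standard regularisation against noise amplification.

Perfusion parameters follow the field conventions: CBF is the residue
maximum, Tmax its time, CBV the ratio of tissue to arterial curve areas,
and MTT = CBV/CBF by the central volume theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import IntensityCurve
from .prep import CTPSeries

__all__ = [
    "DeconvSystem",
    "ResidueSolution",
    "PerfusionParams",
    "build_conv_matrix",
    "build_circulant_matrix",
    "deconvolve",
    "estimate_params",
    "make_maps",
]

_DEFAULT_TRUNCATION = 0.10


def _curve_values(aif) -> tuple[np.ndarray, float | None]:
    if isinstance(aif, IntensityCurve):
        return aif.values, aif.dt
    return np.asarray(aif, dtype=float), None


@dataclass(frozen=True)
class DeconvSystem:
    """A deconvolution system: the matrix, its SVD, and the mode."""

    matrix: np.ndarray
    mode: str  # "sSVD" | "bcSVD"
    dt: float
    n: int  # number of time samples of the underlying curves
    U: np.ndarray
    S: np.ndarray
    Vt: np.ndarray

    def pseudo_inverse(self, truncation_fraction: float = _DEFAULT_TRUNCATION) -> np.ndarray:
        """V S^+ U^T with reciprocals of small singular values zeroed."""
        smax = self.S.max()
        if smax <= 0:
            raise np.linalg.LinAlgError("all-zero system matrix")
        floor = max(truncation_fraction, 1e-15) * smax
        s_inv = np.where(self.S >= floor, 1.0 / np.where(self.S > 0, self.S, 1.0), 0.0)
        return (self.Vt.T * s_inv) @ self.U.T


def _make_system(matrix: np.ndarray, mode: str, dt: float, n: int) -> DeconvSystem:
    U, S, Vt = np.linalg.svd(matrix)
    return DeconvSystem(matrix=matrix, mode=mode, dt=dt, n=n, U=U, S=S, Vt=Vt)


def build_conv_matrix(aif, dt: float | None = None) -> DeconvSystem:
    """Lower-triangular Toeplitz convolution matrix, A[i, j] = dt * aif[i - j].

    The AIF is used as given; pass a baseline-subtracted curve.
    """
    values, curve_dt = _curve_values(aif)
    dt = dt if dt is not None else curve_dt
    if dt is None or dt <= 0:
        raise ValueError("dt must be positive")
    n = values.size
    if n < 2:
        raise ValueError("AIF needs at least 2 samples")
    idx = np.arange(n)
    lag = idx[:, None] - idx[None, :]
    A = np.where(lag >= 0, dt * values[np.clip(lag, 0, n - 1)], 0.0)
    return _make_system(A, "sSVD", dt, n)


def build_circulant_matrix(aif, dt: float | None = None) -> DeconvSystem:
    """Block-circulant matrix: first column = dt * (aif padded to 2N with
    zeros), entry (i, j) = column[(i - j) mod 2N].

    Its top-left N x N block equals the Toeplitz matrix; the wrap-around
    makes deconvolution delay-invariant.
    """
    values, curve_dt = _curve_values(aif)
    dt = dt if dt is not None else curve_dt
    if dt is None or dt <= 0:
        raise ValueError("dt must be positive")
    n = values.size
    if n < 2:
        raise ValueError("AIF needs at least 2 samples")
    col = np.concatenate([dt * values, np.zeros(n)])
    L = 2 * n
    idx = np.arange(L)
    A = col[(idx[:, None] - idx[None, :]) % L]
    return _make_system(A, "bcSVD", dt, n)


@dataclass(frozen=True)
class ResidueSolution:
    """CBF-scaled residue samples recovered by deconvolution.

    ``r`` has length N in sSVD mode and 2N in bcSVD mode; in the circulant
    case indices at or beyond N wrap to negative lags.
    """

    r: np.ndarray
    mode: str
    dt: float
    n: int

    @property
    def residue(self) -> np.ndarray:
        """First N samples (the physical non-negative-lag part)."""
        return self.r[: self.n]

    @property
    def argmax_lag(self) -> int:
        """Argmax position as a (possibly negative) lag in frames."""
        i = int(np.argmax(self.r))
        return i - len(self.r) if self.mode == "bcSVD" and i >= self.n else i

    @property
    def argmax_time(self) -> float:
        """Tmax convention: time of the residue maximum, negative lags
        clamped to zero (negative delays are non-physiological)."""
        return max(self.argmax_lag, 0) * self.dt


def deconvolve(
    tissue,
    system: DeconvSystem,
    truncation_fraction: float = _DEFAULT_TRUNCATION,
) -> ResidueSolution:
    """Solve A r = v by truncated SVD.

    The tissue curve is used as given (pass baseline-subtracted values); in
    bcSVD mode it is zero-padded to 2N.
    """
    v, _ = _curve_values(tissue)
    if v.size != system.n:
        raise ValueError(f"tissue length {v.size} != system length {system.n}")
    if system.S.max() <= 0:
        raise np.linalg.LinAlgError("singular system: all-zero AIF")
    if system.mode == "bcSVD":
        v = np.concatenate([v, np.zeros(system.n)])
    r = system.pseudo_inverse(truncation_fraction) @ v
    return ResidueSolution(r=r, mode=system.mode, dt=system.dt, n=system.n)


def _residue_transit_time(r: np.ndarray, mode: str, n: int, dt: float) -> float:
    """Transit time from the recovered residue: trapezoidal area of the
    decay segment starting at the residue maximum, divided by the maximum.

    Reading the area from the peak onward (circularly in bcSVD mode, so a
    wrapped negative-lag peak still heads its own decay) halves the
    rectangle-rule bias that the raw area ratio carries at coarse frame
    intervals.
    """
    i = int(np.argmax(r))
    peak = r[i]
    if peak <= 0:
        return 0.0
    seg = np.roll(r, -i)[:n] if mode == "bcSVD" else r[i:]
    if seg.size < 2:
        return 0.0
    return float(np.trapezoid(seg, dx=dt) / peak)


@dataclass(frozen=True)
class PerfusionParams:
    """Voxelwise perfusion parameters in internal units.

    cbf in the AIF's flow units (1/s scale), cbv unitless (area ratio), mtt
    and tmax in seconds.  Physiological display constants (hematocrit,
    density) are not applied — they cancel in rCBF and do not move Tmax.
    """

    cbf: float
    cbv: float
    mtt: float
    tmax: float


def estimate_params(
    r: ResidueSolution, tissue, aif, cbf_eps: float = 1e-12, mtt_from: str = "residue"
) -> PerfusionParams:
    """CBF = max r; Tmax = its (clamped) time; CBV = area(tissue)/area(AIF).

    MTT defaults to the residue transit time (area of the recovered decay
    over its peak), which is far less biased by the frame interval than
    the central-volume ratio CBV/CBF; pass ``mtt_from='cvt'`` for the
    latter.
    """
    tv, _ = _curve_values(tissue)
    av, _ = _curve_values(aif)
    aif_int = float(np.trapezoid(av, dx=r.dt))
    if abs(aif_int) < 1e-12:
        raise ValueError("AIF integral is (near) zero; CBV undefined")
    cbf = float(r.r.max())
    cbv = float(np.trapezoid(tv, dx=r.dt)) / aif_int
    if mtt_from == "residue":
        mtt = _residue_transit_time(r.r, r.mode, r.n, r.dt) if cbf > cbf_eps else 0.0
    elif mtt_from == "cvt":
        mtt = cbv / cbf if cbf > cbf_eps else 0.0
    else:
        raise ValueError("mtt_from must be 'residue' or 'cvt'")
    return PerfusionParams(cbf=cbf, cbv=cbv, mtt=mtt, tmax=r.argmax_time)


def make_maps(
    series: CTPSeries,
    aif: IntensityCurve,
    mask: np.ndarray,
    mode: str = "bcSVD",
    truncation_fraction: float = _DEFAULT_TRUNCATION,
    baseline_frames: int = 4,
):
    """Voxelwise perfusion maps over a brain mask.

    Baseline-subtracts the AIF and every tissue curve (mean of the first
    ``baseline_frames``), builds the system once, and applies the truncated
    pseudo-inverse to all masked voxels in one pass.  Unmasked voxels are 0.
    """
    from .quant import PerfusionMaps

    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.shape[:3]:
        raise ValueError("mask shape does not match series grid")
    if mode not in ("sSVD", "bcSVD"):
        raise ValueError(f"unknown mode {mode!r}")

    aif_bs = aif.baseline_subtracted()
    if np.abs(aif_bs).max() <= 0:
        raise np.linalg.LinAlgError("singular system: all-zero AIF")
    build = build_circulant_matrix if mode == "bcSVD" else build_conv_matrix
    system = build(aif_bs, dt=series.dt)
    M = system.pseudo_inverse(truncation_fraction)

    n = system.n
    data = series.data[mask]  # (V, T)
    data = data - data[:, :baseline_frames].mean(axis=1, keepdims=True)
    V = data.T  # (T, V)
    if mode == "bcSVD":
        V = np.concatenate([V, np.zeros_like(V)], axis=0)
    R = M @ V  # (N or 2N, V)

    cbf = R.max(axis=0)
    idx = R.argmax(axis=0)
    if mode == "bcSVD":
        lag = np.where(idx >= n, idx - 2 * n, idx)
    else:
        lag = idx
    tmax = np.maximum(lag, 0) * series.dt

    aif_int = float(np.trapezoid(aif_bs, dx=series.dt))
    if abs(aif_int) < 1e-12:
        raise ValueError("AIF integral is (near) zero; CBV undefined")
    cbv = np.trapezoid(data, dx=series.dt, axis=1) / aif_int

    # vectorised residue transit time: decay segment from each voxel's peak
    L = R.shape[0]
    k = np.arange(n)[:, None]
    if mode == "bcSVD":
        seg = np.take_along_axis(R, (idx[None, :] + k) % L, axis=0)
    else:
        rows = np.minimum(idx[None, :] + k, L - 1)
        seg = np.take_along_axis(R, rows, axis=0)
        seg[idx[None, :] + k > L - 1] = 0.0
    area = series.dt * (seg.sum(axis=0) - 0.5 * (seg[0] + seg[-1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > 1e-12, area / np.where(cbf > 0, cbf, 1.0), 0.0)

    shape = series.shape[:3]
    maps = {}
    for name, vals in (("cbf", cbf), ("cbv", cbv), ("mtt", mtt), ("tmax", tmax)):
        vol = np.zeros(shape)
        vol[mask] = vals
        maps[name] = vol
    return PerfusionMaps(
        cbf=maps["cbf"],
        cbv=maps["cbv"],
        mtt=maps["mtt"],
        tmax=maps["tmax"],
        spacing=series.spacing,
        mask=mask,
    )
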