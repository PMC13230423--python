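"""Evaluation metrics and the statistical contrasts used to compare
automated perfusion pipelines.

Agreement between two sets of volume estimates is measured with Lin's
concordance correlation coefficient,

    CCC = 2 * PCC * sx * sy / (sx^2 + sy^2 + (mx - my)^2),

which penalises both decorrelation and systematic bias (moments use 1/n
denominators, Lin's convention).  Warning behaviour is scored as
correct / (correct + incorrect), and two methods' warning accuracies are
contrasted with a pooled two-proportion z-test and a 2x2 log-odds
difference (the single-predictor logistic / GEE contrast reduces to the
table's log odds-ratio).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AgreementStats",
    "WarningTally",
    "euclidean_distance",
    "ccc",
    "bootstrap_ccc",
    "warning_accuracy",
    "mae",
    "two_proportion_ztest",
    "logodds_contrast",
]


@dataclass(frozen=True)
class AgreementStats:
    ccc: float
    pcc: float
    mean_x: float
    mean_y: float
    sd_x: float
    sd_y: float
    n: int
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class WarningTally:
    correct: int
    incorrect: int

    def __post_init__(self):
        if self.correct < 0 or self.incorrect < 0:
            raise ValueError("tallies must be non-negative")

    @property
    def total(self) -> int:
        return self.correct + self.incorrect


def euclidean_distance(p, q, spacing=(1.0, 1.0, 1.0), mode: str = "3d") -> float:
    """Distance in mm between two landmarks on the same grid.

    ``2d`` uses only the in-plane axes; ``3d`` includes the slice axis
    (the sensible default for anisotropic voxels).
    """
    def _coords(obj):
        idx = getattr(obj, "index", None)
        return idx if isinstance(idx, (tuple, list, np.ndarray)) else obj

    pi = np.asarray(_coords(p), dtype=float)
    qi = np.asarray(_coords(q), dtype=float)
    d = (pi - qi) * np.asarray(spacing, dtype=float)
    if mode == "2d":
        d = d[:2]
    elif mode != "3d":
        raise ValueError("mode must be '2d' or '3d'")
    return float(np.sqrt((d**2).sum()))


def _moments(x: np.ndarray, ddof: int):
    return x.mean(), x.std(ddof=ddof)


def ccc(x, y, ddof: int = 0) -> AgreementStats:
    """Lin's concordance correlation coefficient.

    ``ddof=0`` (1/n moments) is Lin's original convention; ``ddof=1`` is
    available and differs only when the means differ.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.array_equal(x, y):  # exact agreement: CCC is 1 by definition
        m, s = _moments(x, ddof)
        return AgreementStats(1.0, 1.0, float(m), float(m), float(s), float(s), n)
    mx, sx = _moments(x, ddof)
    my, sy = _moments(y, ddof)
    if sx == 0 and sy == 0:
        if mx == my:
            return AgreementStats(1.0, 1.0, mx, my, sx, sy, n)
        raise ValueError("both sequences constant and unequal; CCC undefined")
    cov = ((x - mx) * (y - my)).sum() / (n - ddof)
    pcc = cov / (sx * sy) if sx > 0 and sy > 0 else 0.0
    val = 2 * cov / (sx**2 + sy**2 + (mx - my) ** 2)
    return AgreementStats(float(val), float(pcc), float(mx), float(my),
                          float(sx), float(sy), n)


def bootstrap_ccc(x, y, n_boot: int = 1000, seed: int = 0, alpha: float = 0.05):
    """Percentile bootstrap CI for the CCC over paired resamples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired sequences of length >= 2")
    rng = np.random.default_rng(seed)
    n = x.size
    vals = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        try:
            vals[b] = ccc(xb, yb).ccc
        except ValueError:  # degenerate resample (all-identical pairs)
            vals[b] = 1.0 if np.array_equal(xb, yb) else np.nan
    vals = vals[~np.isnan(vals)]
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def warning_accuracy(t: WarningTally) -> float:
    """Correct warnings over all issued warnings."""
    if t.total == 0:
        raise ValueError("no warnings issued; accuracy undefined")
    return t.correct / t.total


def mae(y, yhat) -> float:
    """Mean absolute error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch")
    return float(np.abs(y - yhat).mean())


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> float:
    """Pooled two-proportion z statistic for k1/n1 vs k2/n2."""
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError("need 0 <= k <= n with n > 0")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("degenerate pooled proportion; z undefined")
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float((p1 - p2) / se)


def logodds_contrast(k1: int, n1: int, k2: int, n2: int) -> float:
    """Log-odds difference ln(k1/(n1-k1)) - ln(k2/(n2-k2)) of a 2x2 table."""
    cells = (k1, n1 - k1, k2, n2 - k2)
    if any(c <= 0 for c in cells):
        raise ValueError("all four cells must be positive (no continuity correction)")
    return float(np.log(k1 / (n1 - k1)) - np.log(k2 / (n2 - k2)))
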