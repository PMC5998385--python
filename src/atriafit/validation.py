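"""Agreement indices between measured and simulated activation times.

Four indicators, pooled over electrodes and coupling intervals:

* regression line ``y = m x + q`` of computed (y) on measured (x) LATs —
  a faithful model has m near 1 and q near 0;
* Pearson correlation ``r``;
* covariance "slender ratio" ``sl`` — minor/major principal component of
  the 2x2 covariance of (measured, computed); 0 means perfectly collinear;
* functional-block error — percentage of simulated non-activations among
  the available LAT measurements,
  ``100 * sum_s2 N_blocked(s2) / sum_s2 N_measured(s2)``.

Electrodes blocked in the simulation carry no computed LAT and are
excluded from the paired indices; they are counted by the block index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ValidationReport",
    "regression_line",
    "pearson_r",
    "slender_ratio",
    "fblock_error",
    "build_report",
]


@dataclass
class ValidationReport:
    q: float           # ms
    m: float
    r: float
    sl: float
    fblock_error: float  # %
    n_pairs: int
    per_s2: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "q_ms": self.q,
            "m": self.m,
            "r": self.r,
            "sl": self.sl,
            "fblock_error_pct": self.fblock_error,
            "n_pairs": self.n_pairs,
        }


def _paired(measured, computed, min_pairs):
    x = np.asarray(measured, dtype=float)
    y = np.asarray(computed, dtype=float)
    if x.shape != y.shape:
        raise ValueError("measured and computed must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        raise ValueError(f"need at least {min_pairs} valid pairs, got {len(x)}")
    return x, y


def regression_line(measured, computed) -> tuple[float, float]:
    """Ordinary least squares of computed on measured: returns (q, m)."""
    x, y = _paired(measured, computed, 2)
    if np.ptp(x) == 0:
        raise ValueError("measured LATs have zero variance")
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope)


def pearson_r(measured, computed) -> float:
    x, y = _paired(measured, computed, 2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in measured or computed LATs")
    return float(stats.pearsonr(x, y).statistic)


def slender_ratio(measured, computed) -> float:
    """Minor/major eigenvalue ratio of the 2x2 (measured, computed)
    covariance; 0 for collinear data, ~1 for isotropic scatter."""
    x, y = _paired(measured, computed, 3)
    cov = np.cov(np.vstack([x, y]))
    lams = np.linalg.eigvalsh(cov)
    if lams[1] <= 0:
        return 0.0
    return float(max(lams[0], 0.0) / lams[1])


def fblock_error(n_blocked_per_s2, n_measured_per_s2) -> float:
    """Percentage of simulated blocks among available measurements."""
    b = np.asarray(n_blocked_per_s2, dtype=float)
    m = np.asarray(n_measured_per_s2, dtype=float)
    if b.shape != m.shape:
        raise ValueError("per-s2 counts must be aligned")
    tot = m.sum()
    if tot <= 0:
        raise ValueError("no measured LATs: block error undefined")
    return float(100.0 * b.sum() / tot)


def build_report(
    measured,
    computed,
    n_blocked_per_s2=None,
    n_measured_per_s2=None,
    apply_offset: bool = True,
    per_s2: dict | None = None,
) -> ValidationReport:
    """Pooled report over all (electrode, s2) LAT pairs for one pacing site.

    A single global offset (mean measured - computed over valid pairs) is
    applied to the computed LATs before the indices, mirroring the
    systematic-delay correction of the onset search.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(computed, dtype=float)
    if apply_offset:
        from .eikonal import offset_correct

        y = offset_correct(y, x)
    q, m = regression_line(x, y)
    r = pearson_r(x, y)
    sl = slender_ratio(x, y)
    if n_blocked_per_s2 is None:
        ok = np.isfinite(x)
        blocked = np.isfinite(x) & ~np.isfinite(y)
        fb = fblock_error([blocked.sum()], [ok.sum()])
    else:
        fb = fblock_error(n_blocked_per_s2, n_measured_per_s2)
    n_pairs = int(np.sum(np.isfinite(x) & np.isfinite(y)))
    return ValidationReport(q=q, m=m, r=r, sl=sl, fblock_error=fb,
                            n_pairs=n_pairs, per_s2=per_s2 or {})
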