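"""Small exact arithmetic used in efficacy and expression readouts.

Tumor volume from caliper diameters, tumor growth inhibition (TGI) and
per-animal regression percentages, and comparative-Ct (ddCt) relative
quantification for qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._errors import UsageError

__all__ = [
    "tumor_volume",
    "tgi_percent",
    "regression_percent",
    "median_regression_percent",
    "CtRecord",
    "relative_quantification",
]


def tumor_volume(d: float, D: float) -> float:
    """Ellipsoid-approximation tumor volume V = d^2 * D / 2 (mm^3).

    ``d`` is the smallest and ``D`` the largest perpendicular diameter
    in mm; passing them swapped is an error, not silently corrected.
    """
    if d <= 0 or D <= 0:
        raise UsageError(f"diameters must be positive, got d={d}, D={D}")
    if d > D:
        raise UsageError(
            f"d={d} > D={D}: d must be the smallest perpendicular diameter"
        )
    return d * d * D / 2.0


def tgi_percent(treated_deltas, control_deltas, endpoint: bool = False) -> float:
    """Tumor growth inhibition, percent.

    Default: 100 * (1 - mean treated volume change / mean control volume
    change), on changes from baseline.  With ``endpoint=True`` the same
    ratio on endpoint volumes instead of changes.  TGI is undefined when
    the control group itself regressed (mean change <= 0).
    """
    t = np.asarray(list(treated_deltas), dtype=float)
    c = np.asarray(list(control_deltas), dtype=float)
    if t.size == 0 or c.size == 0:
        raise UsageError("both groups must be non-empty")
    c_mean = c.mean()
    if not endpoint and c_mean <= 0:
        raise UsageError(
            f"TGI undefined: control mean volume change is {c_mean:g} <= 0"
        )
    if endpoint and c_mean <= 0:
        raise UsageError("endpoint TGI needs positive control volumes")
    return 100.0 * (1.0 - t.mean() / c_mean)


def regression_percent(baseline: float, current: float) -> float:
    """Per-animal tumor regression: 100 * (baseline - current) / baseline.

    Positive for shrinkage (capped at 100 for full disappearance by
    construction), negative for growth.
    """
    if baseline <= 0:
        raise UsageError(f"baseline volume must be positive, got {baseline}")
    return 100.0 * (baseline - current) / baseline


def median_regression_percent(pairs) -> float:
    """Group median of per-animal regressions over (baseline, current) pairs."""
    vals = [regression_percent(b, c) for b, c in pairs]
    if not vals:
        raise UsageError("no animals supplied")
    return float(np.median(vals))


@dataclass(frozen=True)
class CtRecord:
    """One sample's qPCR cycle thresholds for target and reference gene."""

    target_ct: float
    reference_ct: float
    condition: str = ""

    def __post_init__(self):
        for name, v in (("target_ct", self.target_ct),
                        ("reference_ct", self.reference_ct)):
            if not np.isfinite(v) or v <= 0:
                raise UsageError(f"{name} must be finite and positive, got {v}")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - self.reference_ct


def relative_quantification(sample: CtRecord, calibrator: CtRecord) -> float:
    """Comparative-Ct relative quantity RQ = 2^-(dCt_sample - dCt_calibrator)."""
    ddct = sample.delta_ct - calibrator.delta_ct
    return float(2.0 ** (-ddct))
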