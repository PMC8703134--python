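"""Depth-dependent axial-shift regressions, effect size and power.

The axial shift of a non-reference channel relative to the reference is
modelled as a linear function of depth,

    Δz = a·d + b,

fitted per channel pair by ordinary least squares (depth d = the
reference-channel centroid z of each calibration object).  Fit quality is
summarised by r²; the regression effect size is Cohen's f² = r²/(1−r²); and
the achieved power is that of the F-test that the single-predictor
regression's R² is zero: a noncentral F with df1 = 1, df2 = n−2 and
noncentrality λ = f²·n (the fixed-model "R² deviation from zero" convention,
matching standard a-priori/post-hoc power software).  A calibration is
considered sufficient when the achieved power exceeds 0.7; insufficient
regressions are flagged, and the correction step refuses them unless forced.

Lateral (x–y) shifts are summarised — mean and max |Δx|, |Δy| per channel —
but never regressed or corrected: at the depths and lenses this method
targets they stay well below a voxel, and only the axial component is
corrected downstream.

Noiseless synthetic data can reach r² = 1; this is reported as an infinite
f² and power 1 with a ``degenerate_fit`` flag rather than an error.
"""

from __future__ import annotations

import datetime
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import DataError
from .measurement import AberrationSample

__all__ = [
    "AxialRegression",
    "CalibrationModel",
    "fit_axial",
    "cohens_f2",
    "regression_power",
    "required_n",
    "build_model",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_POWER_THRESHOLD = 0.7
_R2_DEGENERATE = 1.0 - 1e-12


@dataclass
class AxialRegression:
    """OLS fit of axial shift vs depth for one channel pair.

    ``slope`` is μm of shift per μm of depth (dimensionless), ``intercept``
    in μm.  ``depth_mean``/``depth_ssx``/``resid_std`` are retained so that
    the standard error of the fitted line at an arbitrary depth can be
    propagated into correction-accuracy bounds.
    """

    ref_channel: str
    target_channel: str
    slope: float
    intercept: float
    n: int
    r2: float
    f2: float
    power: float
    alpha: float = DEFAULT_ALPHA
    stderr_slope: float = float("nan")
    stderr_intercept: float = float("nan")
    resid_std: float = float("nan")
    depth_mean: float = float("nan")
    depth_ssx: float = float("nan")
    flags: tuple[str, ...] = ()

    def predict(self, depth) -> np.ndarray:
        """Expected axial shift Δz at the given depth(s), μm."""
        return self.slope * np.asarray(depth, dtype=float) + self.intercept

    def prediction_se(self, depth) -> np.ndarray:
        """Standard error of the fitted mean line at the given depth(s), μm."""
        d = np.asarray(depth, dtype=float)
        if not np.isfinite(self.resid_std):
            return np.full_like(d, np.nan, dtype=float)
        return self.resid_std * np.sqrt(1.0 / self.n + (d - self.depth_mean) ** 2 / self.depth_ssx)

    def to_dict(self) -> dict:
        return {
            "ref_channel": self.ref_channel,
            "target_channel": self.target_channel,
            "slope": self.slope,
            "intercept": self.intercept,
            "n": self.n,
            "r2": self.r2,
            "f2": self.f2,
            "power": self.power,
            "alpha": self.alpha,
            "stderr_slope": self.stderr_slope,
            "stderr_intercept": self.stderr_intercept,
            "resid_std": self.resid_std,
            "depth_mean": self.depth_mean,
            "depth_ssx": self.depth_ssx,
            "flags": list(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AxialRegression":
        d = dict(d)
        d["flags"] = tuple(d.get("flags", ()))
        # JSON has no Infinity in strict mode; f2 may round-trip as string
        if isinstance(d.get("f2"), str):
            d["f2"] = float(d["f2"])
        return cls(**d)


def cohens_f2(r2: float) -> float:
    """Cohen's effect size f² = r²/(1−r²); r² = 1 yields ``inf``."""
    if not 0.0 <= r2 <= 1.0:
        raise DataError(f"r2 must lie in [0, 1], got {r2}")
    if r2 >= _R2_DEGENERATE:
        return math.inf
    return r2 / (1.0 - r2)


def regression_power(f2: float, n: int, alpha: float = DEFAULT_ALPHA) -> float:
    """Achieved power of the single-predictor regression F-test.

    The test that R² deviates from zero in a fixed-predictor linear
    regression with one predictor: F(1, n−2) under the null, noncentral
    F(1, n−2, λ = f²·n) under the alternative.  In the f² -> 0 limit the
    power equals ``alpha``.
    """
    if n < 3:
        raise DataError(f"n must be >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha must lie in (0, 1), got {alpha}")
    if f2 < 0:
        raise DataError(f"f2 must be >= 0, got {f2}")
    if math.isinf(f2):
        return 1.0
    df2 = n - 2
    fcrit = stats.f.isf(alpha, 1, df2)
    if f2 == 0.0:
        return float(alpha)
    return float(stats.ncf.sf(fcrit, 1, df2, f2 * n))


def required_n(
    f2: float,
    target_power: float,
    alpha: float = DEFAULT_ALPHA,
    n_max: int = 1_000_000,
) -> int:
    """Smallest n >= 3 with ``regression_power(f2, n, alpha) >= target_power``."""
    if not f2 > 0:
        raise DataError(f"f2 must be > 0, got {f2}")
    if not 0.0 < target_power < 1.0:
        raise DataError(f"target_power must lie in (0, 1), got {target_power}")
    if regression_power(f2, 3, alpha) >= target_power:
        return 3
    lo, hi = 3, 6
    while regression_power(f2, hi, alpha) < target_power:
        lo = hi
        hi *= 2
        if hi > n_max:
            raise DataError(
                f"required_n exceeds cap {n_max} for f2={f2}, target={target_power}"
            )
    # power is strictly increasing in n: bisect for the smallest sufficient n
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if regression_power(f2, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def fit_axial(
    samples: list[AberrationSample],
    ref: str,
    target: str,
    alpha: float = DEFAULT_ALPHA,
    flag_outliers_mad: float | None = None,
) -> AxialRegression:
    """OLS fit of Δz(target vs ref) on depth over the given samples.

    ``flag_outliers_mad``, if set (e.g. 3.0), excludes samples whose initial
    residual exceeds that many MADs and refits once; excluded counts are
    logged and recorded in the flags.  Off by default.
    """
    pts = [(s.depth, s.shifts[target][2]) for s in samples if target in s.shifts]
    if len(pts) < 3:
        raise DataError(
            f"need >= 3 samples with channel {target!r}, got {len(pts)}"
        )
    depth = np.array([p[0] for p in pts], dtype=float)
    dz = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(depth) == 0:
        raise DataError("all sample depths identical: depth regression is rank-deficient")

    flags: list[str] = []
    if flag_outliers_mad is not None:
        res = _ols(depth, dz)
        resid = dz - (res["slope"] * depth + res["intercept"])
        mad = float(np.median(np.abs(resid - np.median(resid))))
        if mad > 0:
            keep = np.abs(resid) <= flag_outliers_mad * mad
            n_out = int((~keep).sum())
            if n_out and keep.sum() >= 3 and np.ptp(depth[keep]) > 0:
                logger.info(
                    "fit_axial %s->%s: excluding %d outlier(s) beyond %g MAD",
                    ref, target, n_out, flag_outliers_mad,
                )
                flags.append(f"outliers_excluded:{n_out}")
                depth, dz = depth[keep], dz[keep]

    res = _ols(depth, dz)
    r2 = res["r2"]
    if r2 >= _R2_DEGENERATE:
        flags.append("degenerate_fit")
        f2, power = math.inf, 1.0
    else:
        f2 = cohens_f2(r2)
        power = regression_power(f2, len(depth), alpha) if f2 > 0 else alpha

    return AxialRegression(
        ref_channel=ref,
        target_channel=target,
        slope=res["slope"],
        intercept=res["intercept"],
        n=len(depth),
        r2=r2,
        f2=f2,
        power=power,
        alpha=alpha,
        stderr_slope=res["stderr_slope"],
        stderr_intercept=res["stderr_intercept"],
        resid_std=res["resid_std"],
        depth_mean=float(depth.mean()),
        depth_ssx=float(((depth - depth.mean()) ** 2).sum()),
        flags=tuple(flags),
    )


def _ols(x: np.ndarray, y: np.ndarray) -> dict:
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    # centered total SS of a constant response is zero; define r2 = 0 there
    # (the depth covariate explains nothing) instead of statsmodels' nan
    if np.ptp(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.clip(fit.rsquared, 0.0, 1.0))
    dof = len(x) - 2
    resid_std = float(np.sqrt(fit.ssr / dof)) if dof > 0 else float("nan")
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r2": r2,
        "stderr_slope": float(fit.bse[1]),
        "stderr_intercept": float(fit.bse[0]),
        "resid_std": resid_std,
    }


@dataclass
class CalibrationModel:
    """Per-channel-pair axial regressions plus lateral summary and provenance.

    The lateral summary (mean and max |Δx|, |Δy| per target channel) is
    reported only; it is never used for correction.
    """

    reference_channel: str
    regressions: dict[str, AxialRegression]
    lateral_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    power_threshold: float = DEFAULT_POWER_THRESHOLD

    def insufficient_channels(self) -> list[str]:
        return [
            ch for ch, reg in self.regressions.items() if reg.power < self.power_threshold
        ]

    def to_dict(self) -> dict:
        return {
            "reference_channel": self.reference_channel,
            "regressions": {
                ch: _jsonable(reg.to_dict()) for ch, reg in self.regressions.items()
            },
            "lateral_summary": self.lateral_summary,
            "provenance": self.provenance,
            "power_threshold": self.power_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            reference_channel=d["reference_channel"],
            regressions={
                ch: AxialRegression.from_dict(r) for ch, r in d["regressions"].items()
            },
            lateral_summary=d.get("lateral_summary", {}),
            provenance=d.get("provenance", {}),
            power_threshold=d.get("power_threshold", DEFAULT_POWER_THRESHOLD),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        path = Path(path)
        if not path.exists():
            raise DataError(f"model file not found: {path}")
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(d: dict) -> dict:
    return {k: (repr(v) if isinstance(v, float) and math.isinf(v) else v) for k, v in d.items()}


def build_model(
    samples: list[AberrationSample],
    ref: str,
    alpha: float = DEFAULT_ALPHA,
    power_threshold: float = DEFAULT_POWER_THRESHOLD,
    pitch_xy: float | None = None,
    flag_outliers_mad: float | None = None,
) -> CalibrationModel:
    """Fit every target channel against the reference and assemble a model.

    Regressions whose achieved power falls below ``power_threshold`` are
    flagged ``insufficient_power`` (the model is still emitted; the
    correction step refuses it unless forced).  If ``pitch_xy`` is given, a
    warning is logged when a channel's mean |Δx| or |Δy| exceeds one pitch.
    """
    if not samples:
        raise DataError("no samples to build a model from")
    targets = sorted({ch for s in samples for ch in s.shifts if ch != ref})
    if not targets:
        raise DataError("samples contain no non-reference channel")
    regressions: dict[str, AxialRegression] = {}
    lateral: dict[str, dict[str, float]] = {}
    for target in targets:
        reg = fit_axial(samples, ref, target, alpha=alpha, flag_outliers_mad=flag_outliers_mad)
        if reg.power < power_threshold:
            reg.flags = reg.flags + ("insufficient_power",)
            logger.warning(
                "regression %s->%s: power %.3f below threshold %.2f",
                ref, target, reg.power, power_threshold,
            )
        regressions[target] = reg
        dxs = np.array([abs(s.shifts[target][0]) for s in samples if target in s.shifts])
        dys = np.array([abs(s.shifts[target][1]) for s in samples if target in s.shifts])
        lateral[target] = {
            "mean_abs_dx_um": float(dxs.mean()),
            "max_abs_dx_um": float(dxs.max()),
            "mean_abs_dy_um": float(dys.mean()),
            "max_abs_dy_um": float(dys.max()),
        }
        if pitch_xy is not None and (
            lateral[target]["mean_abs_dx_um"] > pitch_xy
            or lateral[target]["mean_abs_dy_um"] > pitch_xy
        ):
            logger.warning(
                "channel %s: mean lateral shift exceeds one voxel pitch (%g um); "
                "lateral aberration is reported but NOT corrected",
                target, pitch_xy,
            )
    sources = sorted({s.source for s in samples})
    provenance = {
        "source": sources[0] if len(sources) == 1 else sources,
        "n_samples": len(samples),
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return CalibrationModel(
        reference_channel=ref,
        regressions=regressions,
        lateral_summary=lateral,
        provenance=provenance,
        power_threshold=power_threshold,
    )
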