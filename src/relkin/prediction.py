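"""Area-to-volume calibration and forward release prediction.

Across hollow-cylinder designs the Korsmeyer-Peppas exponent n is nearly
constant (it encodes the transport mechanism) while the rate constant k
tracks the area-to-volume ratio A/V of the drug-loaded part.  The
empirical link is a power law on the double-logarithmic scale:

    log10 k = 10**a * (A/V)**m

so that log10(log10 k) is linear in log10(A/V) with slope m and
intercept a.  Once (a, m) are calibrated on tested designs and the
pooled exponent n is fixed, the fractional release of *any* shape with
known A/V follows from the original power law

    %Q_t = k * t**n,    k = 10**(10**a * (A/V)**m)

truncated at 80% of dose, beyond which the empirical law no longer holds
(drug depletion).  Absolute amounts follow by scaling with the theoretical
dose of the shape: drug load x printing-line density x CAD volume.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .profiles import ReleaseProfile

__all__ = [
    "PowerCalibration",
    "AVPowerModel",
    "calibrate_av_power",
    "predict_log_k",
    "predict_fraction_profile",
    "predict_absolute_profile",
]


@dataclasses.dataclass(frozen=True)
class PowerCalibration:
    """Fitted constants of the A/V power law, plus the pooled exponent.

    The calibration inputs are retained so the regression is auditable:
    reproducing the constants from rounded published per-design values
    gives a slightly different slope than fitting on unrounded ones.
    """

    a: float
    m: float
    n_mean: float
    r_squared: float
    av_ratios: tuple[float, ...] = ()
    log_k: tuple[float, ...] = ()

    @property
    def n_points(self) -> int:
        return len(self.av_ratios)

    def predict_log_k(self, av_ratio: float) -> float:
        return predict_log_k(self, av_ratio)

    def fraction_profile(self, av_ratio: float, times: Sequence[float],
                         cap: float = 80.0, **meta) -> ReleaseProfile:
        return predict_fraction_profile(self, av_ratio, times, cap=cap, **meta)

    def summary(self) -> str:
        lines = [
            "Area-to-volume power calibration: log10 k = 10^a * (A/V)^m",
            f"  a (intercept)    : {self.a:.4f}",
            f"  m (exponent)     : {self.m:.4f}",
            f"  pooled n         : {self.n_mean:.4f}",
            f"  R^2 (double-log) : {self.r_squared:.4f}",
            f"  designs used     : {self.n_points}",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "m": self.m,
            "n_mean": self.n_mean,
            "r_squared": self.r_squared,
            "av_ratios": list(self.av_ratios),
            "log_k": list(self.log_k),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PowerCalibration":
        return cls(
            a=float(payload["a"]),
            m=float(payload["m"]),
            n_mean=float(payload["n_mean"]),
            r_squared=float(payload.get("r_squared", float("nan"))),
            av_ratios=tuple(payload.get("av_ratios", ())),
            log_k=tuple(payload.get("log_k", ())),
        )


class AVPowerModel:
    """Double-logarithmic regression of log10(k) on A/V.

    Parameters
    ----------
    av_ratios : sequence of float
        Area-to-volume ratios of the calibrated designs (1/mm), > 0.
    log_k : sequence of float
        Per-design log10 of the Korsmeyer-Peppas constant.  Each must be
        > 0 (i.e. k > 1 %/day^n), otherwise its second logarithm is
        undefined.
    n_mean : float
        Pooled diffusional exponent carried along for prediction.
    """

    def __init__(self, av_ratios: Sequence[float], log_k: Sequence[float],
                 n_mean: float):
        av = np.asarray(av_ratios, dtype=float)
        lk = np.asarray(log_k, dtype=float)
        if av.shape != lk.shape or av.ndim != 1:
            raise ValueError("av_ratios and log_k must be 1-D and equally long")
        if av.size < 2:
            raise ValueError("need at least 2 calibration points")
        if np.any(av <= 0):
            bad = int(np.flatnonzero(av <= 0)[0])
            raise ValueError(f"av_ratio must be > 0 (point {bad}: {av[bad]!r})")
        if np.any(lk <= 0):
            bad = int(np.flatnonzero(lk <= 0)[0])
            raise ValueError(
                f"log_k must be > 0 for the double-log regression "
                f"(point {bad}: {lk[bad]!r})"
            )
        if np.unique(av).size < 2:
            raise ValueError("need at least 2 distinct A/V values")
        if not np.isfinite(n_mean) or n_mean <= 0:
            raise ValueError(f"n_mean must be a positive number, got {n_mean!r}")
        self.av_ratios = av
        self.log_k = lk
        self.n_mean = float(n_mean)

    def fit(self) -> PowerCalibration:
        x = np.log10(self.av_ratios)
        y = np.log10(self.log_k)
        res = stats.linregress(x, y)
        return PowerCalibration(
            a=float(res.intercept),
            m=float(res.slope),
            n_mean=self.n_mean,
            r_squared=float(res.rvalue**2),
            av_ratios=tuple(self.av_ratios.tolist()),
            log_k=tuple(self.log_k.tolist()),
        )


def calibrate_av_power(points: Iterable[tuple[float, float]],
                       n_mean: float) -> PowerCalibration:
    """Calibrate (a, m) from (A/V, log10 k) pairs; functional front-end."""
    pts = list(points)
    if not pts:
        raise ValueError("need at least 2 calibration points")
    av, lk = zip(*pts)
    return AVPowerModel(av, lk, n_mean=n_mean).fit()


def predict_log_k(cal: PowerCalibration, av_ratio: float) -> float:
    """log10 of the Korsmeyer-Peppas constant at a given A/V."""
    if not av_ratio > 0:
        raise ValueError(f"av_ratio must be > 0, got {av_ratio!r}")
    return 10.0**cal.a * av_ratio**cal.m


def predict_fraction_profile(
    cal: PowerCalibration,
    av_ratio: float,
    times: Sequence[float],
    cap: float = 80.0,
    **meta,
) -> ReleaseProfile:
    """Predicted fractional release %Q_t = k * t^n_mean on a time grid.

    Grid points whose prediction exceeds ``cap`` percent are dropped (the
    curve terminates rather than clamping); the empirical power law is
    not credible beyond the cap.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty time grid")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing and > 0")
    k = 10.0 ** predict_log_k(cal, av_ratio)
    fractions = k * np.power(t, cal.n_mean)
    keep = fractions <= cap
    if not keep.any():
        raise ValueError(
            f"all predicted fractions exceed the {cap:g}% cap; "
            "extend the grid toward earlier times"
        )
    return ReleaseProfile.from_fractions(t[keep], fractions[keep], **meta)


def predict_absolute_profile(
    fraction_profile: ReleaseProfile,
    cad_volume_mm3: float,
    density_mg_mm3: float,
    drug_load: float,
) -> np.ndarray:
    """Absolute released amounts (mg) from a fractional profile.

    The theoretical dose of the shape is drug_load x density x CAD volume
    of the drug-loaded part; amounts scale linearly with each factor.
    """
    for name, value in (("cad_volume_mm3", cad_volume_mm3),
                        ("density_mg_mm3", density_mg_mm3),
                        ("drug_load", drug_load)):
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    dose = drug_load * density_mg_mm3 * cad_volume_mm3
    return fraction_profile.fractions / 100.0 * dose
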