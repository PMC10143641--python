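"""Release-kinetics model fitting by linearization.

Five empirical/semi-empirical dissolution models are fitted by ordinary
least squares on their linearization plots (y vs x), and ranked by the
coefficient of determination R^2 of the linearized regression:

=================  ============================  ===============================
model              kinetic equation              linearization (y vs x)
=================  ============================  ===============================
zero order         %Q_t = k0 * t                 %Q_t            vs  t
first order        Q_t = 1 - exp(-k1 * t)        ln(100 - %Q_t)  vs  t
Higuchi            %Q_t = kH * sqrt(t)           %Q_t            vs  sqrt(t)
Weibull            Q_t = 1 - exp(-(t-T)^b / a)   log10(-ln(1-Q)) vs  log10(t)
Korsmeyer-Peppas   %Q_t = kK * t^n               log10(%Q_t)     vs  log10(t)
=================  ============================  ===============================

%Q_t is the cumulative percentage of the dose released at time t (days);
Q_t = %Q_t / 100.  Fits use the mean data points of the replicate studies
truncated at 80% of fractional release; points where a log transform is
undefined (t = 0, %Q_t = 0 or >= 100) are excluded.  All regressions carry
a free intercept, with log10 in the Weibull and Korsmeyer-Peppas plots and
the natural log in the first-order transform.  The Weibull lag time T is
fixed at 0 unless shifted times are supplied.

The Korsmeyer-Peppas power law is the workhorse: its exponent n reflects
the transport mechanism (n = 0.45: Fickian diffusion from a cylinder;
0.45 < n < 0.89: anomalous transport) and its constant kK absorbs the
structural/geometrical characteristics of the device, which is what the
area-to-volume calibration in :mod:`relkin.prediction` exploits.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ReleaseProfile, mean_profile

__all__ = [
    "MODELS",
    "KineticFit",
    "KineticModel",
    "fit_linearized",
    "fit_all_models",
    "select_best_model",
    "summarize_designs",
    "pooled_exponent",
]

#: fixed model order, also the tie-break order in model selection
MODELS = ("korsmeyer_peppas", "weibull", "first", "higuchi", "zero")

_CUTOFF_DEFAULT = 80.0


@dataclasses.dataclass(frozen=True)
class KineticFit:
    """Result of one linearized kinetic-model fit.

    ``params`` holds the back-transformed model constants (e.g. ``k0`` in
    %/day, ``k1`` in 1/day, ``kH`` in %/day^0.5, ``alpha``/``beta`` for
    Weibull, ``kK`` in %/day^n and ``n`` for Korsmeyer-Peppas) next to the
    raw regression ``slope`` and ``intercept``; ``r_squared`` is computed
    on the linearized scale.
    """

    model: str
    params: Mapping[str, float]
    r_squared: float
    n_points: int
    slope: float
    intercept: float
    tied_with: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"R^2 out of [0, 1]: {self.r_squared!r}")
        if self.model == "korsmeyer_peppas" and not self.params["kK"] > 0:
            raise ValueError("Korsmeyer-Peppas constant kK must be positive")

    def predict(self, times: Sequence[float]) -> np.ndarray:
        """Forward-evaluate the fitted kinetic equation, in %Q_t."""
        t = np.asarray(times, dtype=float)
        p = self.params
        if self.model == "zero":
            return p["k0"] * t + p["q0"]
        if self.model == "first":
            return 100.0 - np.exp(self.intercept) * np.exp(-p["k1"] * t)
        if self.model == "higuchi":
            return p["kH"] * np.sqrt(t) + p["q0"]
        if self.model == "weibull":
            frac = 1.0 - np.exp(-np.power(t, p["beta"]) / p["alpha"])
            return 100.0 * frac
        if self.model == "korsmeyer_peppas":
            return p["kK"] * np.power(t, p["n"])
        raise ValueError(f"unknown model {self.model!r}")  # pragma: no cover

    def summary(self) -> str:
        lines = [
            f"Kinetic fit: {self.model}",
            f"  points used      : {self.n_points}",
            f"  R^2 (linearized) : {self.r_squared:.4f}",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:<16} : {value:.4g}")
        if self.tied_with:
            lines.append(f"  tied with        : {', '.join(self.tied_with)}")
        return "\n".join(lines)


# ---------------------------------------------------------------------- #
# linearizations: each returns (x, y, back_transform)

def _lin_zero(t, q):
    return t, q, lambda s, b: {"k0": s, "q0": b}


def _lin_first(t, q):
    mask = q < 100.0
    return t[mask], np.log(100.0 - q[mask]), lambda s, b: {"k1": -s}


def _lin_higuchi(t, q):
    return np.sqrt(t), q, lambda s, b: {"kH": s, "q0": b}


def _lin_weibull(t, q):
    frac = q / 100.0
    mask = (t > 0) & (frac > 0) & (frac < 1)
    y = np.log10(-np.log(1.0 - frac[mask]))
    return np.log10(t[mask]), y, lambda s, b: {"beta": s, "alpha": 10.0 ** (-b)}


def _lin_kp(t, q):
    mask = (t > 0) & (q > 0)
    return (np.log10(t[mask]), np.log10(q[mask]),
            lambda s, b: {"n": s, "kK": 10.0 ** b})


_LINEARIZATIONS: dict[str, Callable] = {
    "zero": _lin_zero,
    "first": _lin_first,
    "higuchi": _lin_higuchi,
    "weibull": _lin_weibull,
    "korsmeyer_peppas": _lin_kp,
}


class KineticModel:
    """Kinetic release model to be fitted on one (mean) release profile.

    Parameters
    ----------
    profile : ReleaseProfile
        Release data of a single implant or, preferably, the mean of
        replicate implants of one design.
    model : str
        One of ``zero``, ``first``, ``higuchi``, ``weibull``,
        ``korsmeyer_peppas``.
    cutoff : float
        Truncation level in percent of dose; data beyond it are in the
        depletion plateau and excluded from the fit.

    Examples
    --------
    >>> profile = ReleaseProfile.from_fractions([0.5, 1, 2, 3],
    ...                                         [26.1, 39.4, 59.6, 75.9])
    >>> fit = KineticModel(profile, "korsmeyer_peppas").fit()
    >>> round(fit.params["n"], 2)
    0.6
    """

    def __init__(self, profile: ReleaseProfile, model: str = "korsmeyer_peppas",
                 cutoff: float = _CUTOFF_DEFAULT):
        if model not in _LINEARIZATIONS:
            raise ValueError(
                f"unknown model {model!r}; choose from {sorted(_LINEARIZATIONS)}"
            )
        self.profile = profile
        self.model = model
        self.cutoff = cutoff

    @classmethod
    def from_replicates(cls, profiles: Sequence[ReleaseProfile],
                        model: str = "korsmeyer_peppas",
                        cutoff: float = _CUTOFF_DEFAULT) -> "KineticModel":
        """Build the model on the point-wise mean of replicate profiles."""
        return cls(mean_profile(profiles), model=model, cutoff=cutoff)

    def fit(self) -> KineticFit:
        usable = self.profile.truncate(self.cutoff).without_origin()
        t = usable.times
        q = usable.fractions
        x, y, back = _LINEARIZATIONS[self.model](t, q)
        if x.size < 3:
            raise ValueError(
                f"model {self.model!r}: only {x.size} usable point(s) after "
                f"transform/truncation; need >= 3"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            bad = int(np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))[0])
            raise ValueError(
                f"model {self.model!r}: non-finite transformed value at point {bad}"
            )
        if np.ptp(x) == 0:
            raise ValueError(f"model {self.model!r}: zero variance in x")
        res = stats.linregress(x, y)
        r2 = float(res.rvalue**2)
        params = back(float(res.slope), float(res.intercept))
        return KineticFit(
            model=self.model,
            params=params,
            r_squared=min(r2, 1.0),
            n_points=int(x.size),
            slope=float(res.slope),
            intercept=float(res.intercept),
        )


def fit_linearized(profile: ReleaseProfile, model: str,
                   cutoff: float = _CUTOFF_DEFAULT) -> KineticFit:
    """Fit one model on one profile (functional form of :class:`KineticModel`)."""
    return KineticModel(profile, model=model, cutoff=cutoff).fit()


def fit_all_models(profile: ReleaseProfile,
                   cutoff: float = _CUTOFF_DEFAULT) -> dict[str, KineticFit]:
    """Fit all five models; models whose transform fails are skipped."""
    fits: dict[str, KineticFit] = {}
    errors: list[str] = []
    for model in MODELS:
        try:
            fits[model] = fit_linearized(profile, model, cutoff)
        except ValueError as exc:
            errors.append(str(exc))
    if not fits:
        raise ValueError("no model could be fitted: " + "; ".join(errors))
    return fits


def select_best_model(fits: Sequence[KineticFit] | Mapping[str, KineticFit]) -> KineticFit:
    """Fit with the highest linearization R^2.

    Exact ties are broken by the fixed model order (Korsmeyer-Peppas,
    Weibull, first, Higuchi, zero) and flagged on the winner.
    """
    pool = list(fits.values()) if isinstance(fits, Mapping) else list(fits)
    if not pool:
        raise ValueError("no fits to select from")
    pool.sort(key=lambda f: MODELS.index(f.model))
    best = max(pool, key=lambda f: f.r_squared)
    ties = tuple(
        f.model for f in pool
        if f is not best and f.r_squared == best.r_squared
    )
    if ties:
        best = dataclasses.replace(best, tied_with=ties)
    return best


def summarize_designs(
    fits_by_design: Mapping[str, Mapping[str, KineticFit]]
) -> pd.DataFrame:
    """Per-design fit-quality table (one row per design).

    Columns are the R^2 of each model plus the Korsmeyer-Peppas ``n`` and
    ``log_k``; fitting is expected to have been done on per-design mean
    profiles.
    """
    if not fits_by_design:
        raise ValueError("no designs to summarize")
    rows = []
    for design, fits in fits_by_design.items():
        row: dict[str, float | str] = {"design": design}
        for model in MODELS:
            if model in fits:
                row[f"r2_{model}"] = fits[model].r_squared
        kp = fits.get("korsmeyer_peppas")
        if kp is not None:
            row["n"] = kp.params["n"]
            row["log_k"] = np.log10(kp.params["kK"])
        rows.append(row)
    table = pd.DataFrame(rows).set_index("design")
    return table


def pooled_exponent(summary: pd.DataFrame | Mapping[str, float]) -> float:
    """Unweighted arithmetic mean of the per-design diffusional exponents.

    The exponent reflects the transport mechanism and is similar across
    designs, so a single pooled value is used for prediction.
    """
    if isinstance(summary, pd.DataFrame):
        values = summary["n"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(summary.values()), dtype=float)
    if values.size == 0:
        raise ValueError("no exponents to pool")
    return float(values.mean())
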