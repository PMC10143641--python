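"""Release profiles and release-accounting arithmetic.

A release study transfers an implant through a sequence of fresh medium
vessels; each vessel captures the drug amount eluted during one sampling
interval.  The cumulative released amount is therefore the running sum of
the per-interval amounts, and the percentage fraction of release relates
the cumulative amount to the theoretical total drug dose of the implant
(drug load times the mass of the drug-loaded part).

Times are in days, amounts in mg and fractions in percent of dose (0-100)
throughout the package.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseProfile",
    "cumulative_from_intervals",
    "dose_from_drug_part_mass",
    "truncate_at_fraction",
    "mean_profile",
    "read_release_csv",
    "write_release_csv",
]

#: default theoretical drug load of the drug-containing part (mass fraction)
DEFAULT_DRUG_LOAD = 0.10

RELEASE_CSV_COLUMNS = (
    "implant_id",
    "design_id",
    "time_days",
    "interval_amount_mg",
    "mass_mg",
    "drug_part_mass_mg",
)


def cumulative_from_intervals(interval_amounts: Sequence[float]) -> np.ndarray:
    """Running sum of per-interval released amounts (mg).

    The output has the same length as the input and is non-decreasing for
    non-negative inputs.  Negative amounts are rejected: an apparent
    negative release indicates a sampling or bookkeeping error upstream.
    """
    amounts = np.asarray(interval_amounts, dtype=float)
    if amounts.size and np.any(amounts < 0):
        idx = int(np.flatnonzero(amounts < 0)[0])
        raise ValueError(
            f"negative interval amount {amounts[idx]:g} mg at position {idx}"
        )
    return np.cumsum(amounts)


def dose_from_drug_part_mass(
    mass_drug_part_mg: float, drug_load: float = DEFAULT_DRUG_LOAD
) -> float:
    """Theoretical total drug dose as ``drug_load`` of the drug-part mass."""
    if not mass_drug_part_mg > 0:
        raise ValueError(f"drug-part mass must be > 0, got {mass_drug_part_mg!r}")
    if not 0 < drug_load < 1:
        raise ValueError(f"drug load must lie in (0, 1), got {drug_load!r}")
    return drug_load * mass_drug_part_mg


@dataclasses.dataclass(frozen=True)
class ReleaseProfile:
    """Time series of cumulative drug release from one implant.

    Parameters
    ----------
    times : array of float
        Sampling times in days, strictly increasing.  An optional leading
        origin point at t = 0 with zero release is allowed; log-transformed
        fits downstream exclude it automatically.
    fractions : array of float
        Cumulative percentage of the dose released at each time (%Q_t).
    dose : float, optional
        Theoretical total drug dose in mg.  Absent for purely fractional
        (e.g. predicted) profiles.
    interval_amounts : array of float, optional
        Per-sampling-interval released amounts in mg (measured studies).
    """

    times: np.ndarray
    fractions: np.ndarray
    dose: float | None = None
    interval_amounts: np.ndarray | None = None
    implant_id: str | None = None
    design_id: str | None = None
    metadata: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fractions", fractions)
        if times.shape != fractions.shape or times.ndim != 1:
            raise ValueError("times and fractions must be 1-D and equally long")
        if times.size and np.any(np.diff(times) <= 0):
            idx = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValueError(
                f"times must be strictly increasing; violation at point {idx}"
                f" (t = {times[idx]:g} d)"
            )
        if times.size and times[0] < 0:
            raise ValueError("negative times are not meaningful")
        if np.any(np.diff(fractions) < -1e-9):
            raise ValueError("cumulative fractions must be non-decreasing")
        if self.interval_amounts is not None:
            amounts = np.asarray(self.interval_amounts, dtype=float)
            object.__setattr__(self, "interval_amounts", amounts)
            if amounts.shape != times.shape:
                raise ValueError("interval_amounts length must match times")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_intervals(
        cls,
        times: Sequence[float],
        interval_amounts: Sequence[float],
        dose: float,
        **meta,
    ) -> "ReleaseProfile":
        """Build a profile from per-interval amounts and the dose."""
        if not dose > 0:
            raise ValueError(f"dose must be > 0, got {dose!r}")
        cumulative = cumulative_from_intervals(interval_amounts)
        fractions = 100.0 * cumulative / dose
        return cls(
            times=np.asarray(times, dtype=float),
            fractions=fractions,
            dose=float(dose),
            interval_amounts=np.asarray(interval_amounts, dtype=float),
            **meta,
        )

    @classmethod
    def from_fractions(
        cls, times: Sequence[float], fractions: Sequence[float],
        dose: float | None = None, **meta,
    ) -> "ReleaseProfile":
        return cls(times=np.asarray(times, float),
                   fractions=np.asarray(fractions, float),
                   dose=dose, **meta)

    # ------------------------------------------------------------------ #
    # derived series

    @property
    def cumulative_amounts(self) -> np.ndarray:
        """Cumulative released amount in mg (requires a dose)."""
        if self.interval_amounts is not None:
            return cumulative_from_intervals(self.interval_amounts)
        if self.dose is None:
            raise ValueError("profile has neither interval amounts nor a dose")
        return self.fractions / 100.0 * self.dose

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points

    def without_origin(self) -> "ReleaseProfile":
        """Drop a leading t = 0 (or zero-release) point, if present.

        Log transforms of either axis are undefined there; fitting code
        calls this before any logarithmic linearization.
        """
        keep = (self.times > 0) & (self.fractions > 0)
        return self._subset(keep)

    def truncate(self, cutoff: float = 80.0) -> "ReleaseProfile":
        return truncate_at_fraction(self, cutoff)

    def _subset(self, mask: np.ndarray) -> "ReleaseProfile":
        amounts = None
        if self.interval_amounts is not None:
            amounts = self.interval_amounts[mask]
        return ReleaseProfile(
            times=self.times[mask],
            fractions=self.fractions[mask],
            dose=self.dose,
            interval_amounts=amounts,
            implant_id=self.implant_id,
            design_id=self.design_id,
            metadata=self.metadata,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_days": self.times, "fraction_pct": self.fractions}
        if self.interval_amounts is not None:
            data["interval_amount_mg"] = self.interval_amounts
        if self.dose is not None:
            data["cumulative_mg"] = self.cumulative_amounts
        return pd.DataFrame(data)

    def plot(self, ax=None, **kwargs):
        """Plot %released vs time on ``ax`` (created if missing)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        label = kwargs.pop("label", self.implant_id or self.design_id)
        ax.plot(self.times, self.fractions, marker="o", label=label, **kwargs)
        ax.set_xlabel("time (d)")
        ax.set_ylabel("released fraction (% of dose)")
        return ax


def truncate_at_fraction(profile: ReleaseProfile, cutoff: float = 80.0) -> ReleaseProfile:
    """Keep the leading points with fraction <= ``cutoff`` percent.

    Kinetic fits use release data only up to 80% of fractional release;
    the late plateau reflects drug depletion, not the transport law.
    """
    if not 0 < cutoff <= 100:
        raise ValueError(f"cutoff must lie in (0, 100], got {cutoff!r}")
    keep = profile.fractions <= cutoff
    # only the *leading* run is retained to preserve contiguity in time
    below = np.flatnonzero(~keep)
    if below.size:
        keep[below[0]:] = False
    if not keep.any():
        raise ValueError(f"profile starts above cutoff ({cutoff:g}%)")
    return profile._subset(keep)


def mean_profile(profiles: Sequence[ReleaseProfile]) -> ReleaseProfile:
    """Average replicate profiles point-wise on a shared time grid.

    Kinetic characterization operates on the mean data points across the
    replicate implants of one design.  All replicates must share the same
    sampling schedule (shorter replicates, terminated earlier at the
    plateau, are averaged over their common leading window).
    """
    if not profiles:
        raise ValueError("no profiles to average")
    n = min(p.n_points for p in profiles)
    base = profiles[0].times[:n]
    for p in profiles[1:]:
        if not np.allclose(p.times[:n], base):
            raise ValueError("replicates are not sampled on a common time grid")
    fractions = np.mean([p.fractions[:n] for p in profiles], axis=0)
    doses = [p.dose for p in profiles if p.dose is not None]
    amounts = None
    if all(p.interval_amounts is not None for p in profiles):
        amounts = np.mean([p.interval_amounts[:n] for p in profiles], axis=0)
    return ReleaseProfile(
        times=base.copy(),
        fractions=fractions,
        dose=float(np.mean(doses)) if doses else None,
        interval_amounts=amounts,
        design_id=profiles[0].design_id,
    )


# ---------------------------------------------------------------------- #
# CSV input / output


def profiles_from_frame(
    frame: pd.DataFrame, drug_load: float = DEFAULT_DRUG_LOAD
) -> list[ReleaseProfile]:
    """Group a release-study table into one :class:`ReleaseProfile` per implant."""
    missing = [c for c in RELEASE_CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"release table is missing columns: {', '.join(missing)}")
    if frame.empty:
        raise ValueError("no records in release table")
    profiles: list[ReleaseProfile] = []
    for implant_id, group in frame.groupby("implant_id", sort=False):
        times = group["time_days"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = group.index[int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1]
            raise ValueError(
                f"implant {implant_id!r}: time_days not strictly increasing at row {bad}"
            )
        amounts = group["interval_amount_mg"].to_numpy(dtype=float)
        if np.any(amounts < 0):
            bad = group.index[int(np.flatnonzero(amounts < 0)[0])]
            raise ValueError(
                f"implant {implant_id!r}: negative interval_amount_mg at row {bad}"
            )
        part_mass = float(group["drug_part_mass_mg"].iloc[0])
        dose = dose_from_drug_part_mass(part_mass, drug_load)
        profiles.append(
            ReleaseProfile.from_intervals(
                times,
                amounts,
                dose,
                implant_id=str(implant_id),
                design_id=str(group["design_id"].iloc[0]),
                metadata={
                    "mass_mg": float(group["mass_mg"].iloc[0]),
                    "drug_part_mass_mg": part_mass,
                    "drug_load": drug_load,
                },
            )
        )
    return profiles


def read_release_csv(
    path: str | Path, drug_load: float = DEFAULT_DRUG_LOAD
) -> list[ReleaseProfile]:
    """Read a release-study CSV (one row per implant x sampling interval)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"no records in {path}") from exc
    return profiles_from_frame(frame, drug_load=drug_load)


def profiles_to_frame(profiles: Iterable[ReleaseProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        if p.interval_amounts is None:
            raise ValueError(
                f"profile {p.implant_id or p.design_id!r} has no interval amounts"
            )
        meta = dict(p.metadata)
        for t, amt in zip(p.times, p.interval_amounts):
            rows.append(
                {
                    "implant_id": p.implant_id,
                    "design_id": p.design_id,
                    "time_days": t,
                    "interval_amount_mg": amt,
                    "mass_mg": meta.get("mass_mg", np.nan),
                    "drug_part_mass_mg": meta.get("drug_part_mass_mg", np.nan),
                }
            )
    return pd.DataFrame(rows, columns=list(RELEASE_CSV_COLUMNS))


def write_release_csv(profiles: Iterable[ReleaseProfile], path: str | Path) -> None:
    """Inverse of :func:`read_release_csv` (comma-separated, dot decimal, UTF-8).

    Floats are written with 17 significant digits so the round trip is
    bit-exact.
    """
    profiles_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")
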