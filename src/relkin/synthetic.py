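"""Synthetic release studies, design series, formulations and mesh fixtures.

The generator emulates the multi-day in-vitro release protocol: replicate
implants are transferred through fresh medium at scheduled time points,
each vessel yielding one per-interval released amount; the study stops in
the plateau phase once the release rate falls below a detectability
threshold.  The underlying truth is the Korsmeyer-Peppas power law with a
rate constant tied to the area-to-volume ratio through the double-log
power calibration, which makes a zero-noise simulation exactly invertible
by the fitting/calibration pipeline (the master self-consistency check).

Variability model:

* per-implant drug-part mass and drug content vary lognormally with the
  given relative standard deviations (multiplicative errors compound, so
  a lognormal is the natural choice);
* each measured interval amount carries multiplicative Gaussian error of
  the given coefficient of variation, floored at zero (a UV reading
  cannot be negative).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import trimesh

from . import reference
from .geometry import ImplantDesign, cylinder_av_ratio, cylinder_drug_volume
from .prediction import PowerCalibration, predict_fraction_profile

__all__ = [
    "NoiseModel",
    "make_design_series",
    "simulate_release_study",
    "formulation_fractions",
    "make_mesh_fixture",
]

#: plateau detectability threshold: fraction of dose per 24 h below which
#: the study is terminated (only minimal assay signal remains)
DETECT_THRESHOLD_PER_DAY = 0.002

#: total implant mass per unit drug-part mass (inert layers included);
#: cosmetic metadata only, it does not enter any computation
_TOTAL_MASS_FACTOR = 1.57

# the ten unique hollow-cylinder designs: (drug-part height, drug wall) in
# mm at a common outer diameter of 10 mm.  Series A varies height at
# constant wall (constant A/V), B varies wall at constant height
# (constant area), C trades wall against height (constant volume).  The
# standard design S doubles as A1, B2 and C1.
_DESIGN_DIMENSIONS = {
    "S": (19.2, 0.8),
    "A2": (14.4, 0.8),
    "A3": (9.6, 0.8),
    "A4": (4.8, 0.8),
    "B1": (19.2, 0.4),
    "B3": (19.2, 1.2),
    "B4": (19.2, 1.6),
    "C2": (13.4, 1.2),
    "C3": (10.5, 1.6),
    "C4": (8.8, 2.0),
}


def make_design_series(outer_diameter: float = 10.0) -> list[ImplantDesign]:
    """The ten unique hollow-cylinder designs of the A/B/C series."""
    return [
        ImplantDesign(
            design_id=name,
            outer_diameter_D=outer_diameter,
            drug_wall_t=wall,
            drug_height_h=height,
        )
        for name, (height, wall) in _DESIGN_DIMENSIONS.items()
    ]


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Variability levels of a simulated study (all as fractions, not %)."""

    measurement_cv: float = 0.0
    mass_rsd: float = 0.0
    content_rsd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("measurement_cv", "mass_rsd", "content_rsd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def is_noiseless(self) -> bool:
        return self.measurement_cv == self.mass_rsd == self.content_rsd == 0


def _lognormal_factor(rng: np.random.Generator, rsd: float, size: int) -> np.ndarray:
    """Unit-mean lognormal multipliers with the requested RSD."""
    if rsd == 0:
        return np.ones(size)
    sigma2 = np.log1p(rsd**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_release_study(
    design: ImplantDesign | None = None,
    av_ratio: float | None = None,
    truth: tuple[float, float, float] = (
        reference.A_INTERCEPT,
        reference.M_EXPONENT,
        reference.N_MEAN,
    ),
    dose_mg: float | None = None,
    schedule: Sequence[float] = reference.DEFAULT_SCHEDULE,
    noise: NoiseModel = NoiseModel(),
    replicates: int = 3,
    seed: int | np.random.Generator | None = None,
    design_id: str | None = None,
    drug_load: float = reference.DRUG_LOAD,
    density_mg_mm3: float = reference.PRINT_LINE_DENSITY,
    detect_threshold_per_day: float = DETECT_THRESHOLD_PER_DAY,
) -> pd.DataFrame:
    """Simulate one release study, returning release-CSV-shaped records.

    Parameters
    ----------
    design, av_ratio
        Either a parametric design (A/V and nominal dose derive from its
        geometry) or an explicit area-to-volume ratio in 1/mm.
    truth
        Calibration truth (a, m, n): log10 k = 10**a * (A/V)**m and
        %Q_t = k * t**n capped at 100.
    dose_mg
        Nominal theoretical dose; defaults to drug_load x density x CAD
        volume when a design is given.
    schedule
        Medium-transfer time points in days, strictly increasing, > 0.
    noise, replicates, seed
        Variability levels, number of replicate implants and RNG seed
        (all randomness flows from this single seed).
    """
    if (design is None) == (av_ratio is None):
        raise ValueError("provide exactly one of `design` or `av_ratio`")
    if design is not None:
        av_ratio = cylinder_av_ratio(design)
        if dose_mg is None:
            dose_mg = drug_load * density_mg_mm3 * cylinder_drug_volume(design)
        design_id = design_id or design.design_id
    if dose_mg is None or not dose_mg > 0:
        raise ValueError("a positive nominal dose_mg is required with av_ratio")
    t = np.asarray(schedule, dtype=float)
    if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("schedule must be strictly increasing and start > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not detect_threshold_per_day >= 0:
        raise ValueError("detect_threshold_per_day must be >= 0")

    a, m, n = truth
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cal = PowerCalibration(a=a, m=m, n_mean=n, r_squared=1.0)
    # true cumulative fraction, capped at complete release
    true_profile = predict_fraction_profile(cal, av_ratio, t, cap=np.inf)
    true_fraction = np.minimum(true_profile.fractions, 100.0)

    design_id = design_id or f"AV{av_ratio:.2f}"
    mass_factors = _lognormal_factor(rng, noise.mass_rsd, replicates)
    content_factors = _lognormal_factor(rng, noise.content_rsd, replicates)
    interval_lengths = np.diff(np.concatenate(([0.0], t)))

    rows = []
    for rep in range(replicates):
        part_mass = dose_mg / drug_load * mass_factors[rep]
        actual_dose = dose_mg * mass_factors[rep] * content_factors[rep]
        cumulative = true_fraction / 100.0 * actual_dose
        intervals = np.diff(np.concatenate(([0.0], cumulative)))
        if noise.measurement_cv > 0:
            factors = 1.0 + noise.measurement_cv * rng.standard_normal(t.size)
            intervals = np.maximum(intervals * factors, 0.0)
        # plateau termination: stop once the release rate over a sampling
        # interval drops below the detectability threshold per 24 h
        rates = intervals / interval_lengths
        below = np.flatnonzero(rates < detect_threshold_per_day * dose_mg)
        last = t.size if below.size == 0 else int(below[0]) + 1
        implant_id = f"{design_id}-r{rep + 1}"
        for i in range(last):
            rows.append(
                {
                    "implant_id": implant_id,
                    "design_id": design_id,
                    "time_days": t[i],
                    "interval_amount_mg": intervals[i],
                    "mass_mg": part_mass * _TOTAL_MASS_FACTOR,
                    "drug_part_mass_mg": part_mass,
                }
            )
    return pd.DataFrame(rows)


def formulation_fractions(
    drug_load: float = reference.DRUG_LOAD,
    rs_rl_ratio: tuple[float, float] = (80, 20),
    tec_polymer_ratio: tuple[float, float] | None = (5, 95),
) -> dict[str, float]:
    """Mass fractions (% w/w) of a powder blend for hot-melt extrusion.

    The drug takes ``drug_load`` of the total; the plasticizer (TEC) and
    polymer split the remainder by ``tec_polymer_ratio``; the copolymers
    RS and RL split the polymer share by ``rs_rl_ratio``.  All four
    fractions sum to 100.
    """
    if not 0 < drug_load < 1:
        raise ValueError(f"drug_load must lie in (0, 1), got {drug_load!r}")
    rs_part, rl_part = rs_rl_ratio
    if rs_part < 0 or rl_part < 0 or rs_part + rl_part == 0:
        raise ValueError(f"invalid RS:RL ratio {rs_rl_ratio!r}")
    remainder = 100.0 * (1.0 - drug_load)
    if tec_polymer_ratio is None:
        tec = 0.0
    else:
        tec_part, poly_part = tec_polymer_ratio
        if tec_part < 0 or poly_part <= 0:
            raise ValueError(f"invalid TEC:polymer ratio {tec_polymer_ratio!r}")
        tec = remainder * tec_part / (tec_part + poly_part)
    polymer = remainder - tec
    rs = polymer * rs_part / (rs_part + rl_part)
    rl = polymer * rl_part / (rs_part + rl_part)
    return {
        "paracetamol": 100.0 * drug_load,
        "eudragit_rs": rs,
        "eudragit_rl": rl,
        "tec": tec,
    }


def make_mesh_fixture(
    kind: str,
    dims: dict[str, float],
    segments: int = 64,
    path: str | Path | None = None,
    ascii_stl: bool = False,
) -> trimesh.Trimesh:
    """Closed, outward-oriented test meshes with known analytic geometry.

    ``kind`` is one of ``cylinder`` (dims: diameter, height; tessellated
    with ``segments`` sides), ``sphere`` (dims: radius; icosphere with
    ``segments`` as the subdivision count) or ``cube`` (dims: edge).
    Optionally exports an STL (binary, or ASCII with ``ascii_stl``).
    """
    if kind == "cylinder":
        if segments < 3:
            raise ValueError("a tessellated cylinder needs >= 3 segments")
        mesh = trimesh.creation.cylinder(
            radius=dims["diameter"] / 2.0, height=dims["height"], sections=segments
        )
    elif kind == "sphere":
        mesh = trimesh.creation.icosphere(
            subdivisions=int(segments), radius=dims["radius"]
        )
    elif kind == "cube":
        mesh = trimesh.creation.box(extents=[dims["edge"]] * 3)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    for value in dims.values():
        if not value > 0:
            raise ValueError("all dimensions must be > 0")
    if path is not None:
        path = Path(path)
        if ascii_stl:
            path.write_text(
                trimesh.exchange.stl.export_stl_ascii(mesh), encoding="utf-8"
            )
        else:
            mesh.export(path, file_type="stl")
    return mesh
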