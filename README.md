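# relkin

Release kinetics, geometry and prediction for unidirectional drug-eluting
implants.

3D printing makes it practical to manufacture drug-eluting implants whose
shape is adapted to an individual patient's anatomy — but every new shape
changes the releasing surface area and the drug-loaded volume, and with
them the release profile. Testing each customized geometry in vitro is
exactly what individualization is supposed to avoid. `relkin` implements
the empirical modelling chain that makes release from such implants
predictable from geometry alone, for matrix-type devices that elute
through a single outer (abluminal) surface:

1. **Geometry.** For the drug-loaded part of a bilayered hollow cylinder
   (outer diameter *D*, drug-wall thickness *t*, height *h*), the
   releasing area is the outer lateral surface *A* = π·*D*·*h* and the
   drug volume is the annulus *V* = π·*t*(*D* − *t*)·*h*, so
   *A*/*V* = *D*/(*t*(*D* − *t*)) is independent of height. For
   patient-specific shapes, *A* and *V* come from closed STL meshes.
2. **Kinetics.** Release data (truncated at 80% of dose) are fitted by
   linearization for five dissolution models — zero order, first order,
   Higuchi, Weibull and the Korsmeyer–Peppas power law
   %*Q*<sub>t</sub> = *k*·*t*<sup>*n*</sup> — and ranked by the *R*² of
   the linearized regression. For these diffusion-controlled devices the
   power law wins, with a nearly design-independent exponent *n* ≈ 0.6.
3. **Calibration.** The rate constant tracks the area-to-volume ratio
   through a double-logarithmic power law,
   log *k* = 10<sup>*a*</sup> · (*A*/*V*)<sup>*m*</sup>,
   fitted by OLS of log₁₀(log₁₀ *k*) on log₁₀(*A*/*V*).
4. **Prediction & congruence.** Any shape with known *A*/*V* gets a
   predicted fractional profile %*Q*<sub>t</sub> = *k*·*t*<sup>*n̄*</sup>
   (truncated at 80%), scaled to absolute amounts by the theoretical dose
   (drug load × printing-line density × CAD volume). Predicted and
   observed profiles are compared with the difference factor
   *f*₁ = 100·Σ|*R*<sub>t</sub> − *T*<sub>t</sub>|/Σ*R*<sub>t</sub> and
   the similarity factor
   *f*₂ = 50·log₁₀(100·[1 + (1/n)Σ(*R*<sub>t</sub> − *T*<sub>t</sub>)²]<sup>−½</sup>).

Since no raw release data are deposited anywhere, the package ships a
synthetic release-study generator (`relkin.synthetic`) that emulates the
wet-lab protocol — replicate implants, medium transfers on a dense-early
schedule, lognormal mass/content variability, multiplicative measurement
noise, plateau termination — so the whole chain is testable end to end.

## Worked example

```python
import numpy as np, pandas as pd
from relkin import *
from relkin.profiles import profiles_from_frame

# thin-walled design B1: wall 0.4 mm -> the highest A/V of the series
design = {d.design_id: d for d in make_design_series()}["B1"]
print(cylinder_geometry(design).rounded(2))   # (603.19, 231.62, 2.6)

# simulate a noisy release study over all ten designs
rng = np.random.default_rng(42)
noise = NoiseModel(measurement_cv=0.02, mass_rsd=0.033, content_rsd=0.02)
frames = [simulate_release_study(design=d, seed=rng, noise=noise)
          for d in make_design_series()]
profiles = profiles_from_frame(pd.concat(frames, ignore_index=True))

# fit all five kinetic models on per-design mean profiles
by = {}
for p in profiles:
    by.setdefault(p.design_id, []).append(p)
fits = {d: fit_all_models(mean_profile(v)) for d, v in by.items()}
print(select_best_model(fits["S"]).summary())

# calibrate the A/V power law and score a prediction
table = summarize_designs(fits)
av = {d.design_id: cylinder_av_ratio(d) for d in make_design_series()}
cal = AVPowerModel([av[d] for d in table.index],
                   [table.loc[d, "log_k"] for d in table.index],
                   n_mean=pooled_exponent(table)).fit()
print(cal.summary())

observed = mean_profile(by["S"])
predicted = predict_fraction_profile(cal, av["S"], observed.times, cap=80)
r = compare_profiles(predicted, observed)
print(f"f1 = {r.f1:.2f}%, f2 = {r.f2:.2f}%, equivalent = {r.equivalent}")
```

Output:

```
(603.19, 231.62, 2.6)
Kinetic fit: korsmeyer_peppas
  points used      : 6
  R^2 (linearized) : 1.0000
  n                : 0.5964
  kK               : 36.48
Area-to-volume power calibration: log10 k = 10^a * (A/V)^m
  a (intercept)    : 0.1649
  m (exponent)     : 0.2263
  pooled n         : 0.5973
  R^2 (double-log) : 0.9989
  designs used     : 10
f1 = 1.08%, f2 = 97.92%, n = 6, equivalent = True
```

Reading: the power law fits the simulated standard design essentially
perfectly (*R*² = 1.000, *n* ≈ 0.60); calibrating across all ten designs
recovers the generating constants (*a* = 0.1649, *m* = 0.2263) despite 2%
measurement noise and ~3% dose variability; and the profile predicted
from geometry alone is congruent with the "measured" one (*f*₁ ≈ 1%,
*f*₂ ≈ 98%, both far inside the conventional *f*₁ ≤ 15 / *f*₂ ≥ 50
similarity bounds).

The same workflow is available from a shell (`relkin simulate / geometry /
fit / calibrate / predict / compare / run`); `relkin run scenario.yaml
outdir` executes the whole chain and writes a manifest with the seed and
config hash.

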