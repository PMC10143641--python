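# Methods

## System and scope

The modelled system is a matrix-type, non-degrading drug-eluting implant
printed in two materials: a drug-loaded Eudragit RS/RL band and an inert
PLA layer covering the lumen, top and bottom. Release is therefore
unidirectional through the outer (abluminal) surface, driven by diffusion
of a water-soluble drug out of a water-insoluble polymer matrix under
sink conditions. The package covers geometry characterization, empirical
kinetic fitting, geometry-based calibration and prediction, and profile
congruence scoring. It does not model the transport mechanistically (no
Fickian PDE, swelling or pore formation), does not process CBCT/DICOM
segmentations, and does not repair or offset meshes.

## Geometry

For parametric hollow cylinders the closed forms of the drug-loaded part
are exact: A = πDh (outer lateral surface only), V = πt(D − t)h,
A/V = D/(t(D − t)). The top/bottom annuli and the luminal wall are
excluded from A because the inert layer covers them; only the abluminal
band elutes. A and V are computed from modeled (CAD) dimensions, not from
printed-part calipers: printed inner diameters shrink during
solidification, but the calibration covariate is deliberately CAD-based
so that predictions require no measurements of the physical part.

Patient-specific shells are closed triangle meshes in millimetres (STL
carries no units; a scale factor is exposed). Surface area is the sum of
cross-product halves, enclosed volume the absolute signed-tetrahedron sum
(divergence theorem), both via trimesh; open meshes are rejected with the
boundary-edge count. Drainage openings cannot be detected reliably on
arbitrary meshes, so the caller declares the non-eluting area to subtract.
Shell volume is the difference of outer and inner enclosed volumes when
an inner mesh exists, else the thin-shell approximation A·t. The
thin-shell route gives A/V = 1/t exactly, which for the standard cylinder
(t = 0.8 mm, D = 10 mm) understates the exact annulus value 1.359 /mm by
about 8%; the bias grows with t/D and is asserted in the tests as a known
property, not hidden.

Report output is rounded to 2 decimals, half away from zero (0.625 →
0.63), matching how the design table is conventionally printed.

## Kinetic fitting

Five dissolution models are fitted by OLS on their linearization plots,
with a free intercept, and ranked by the R² of the linearized regression
(not a back-transformed R², and deliberately no AIC/BIC — the selection
criterion of the original analysis is linearization R² only):

| model            | %Q form                   | y                | x        |
|------------------|---------------------------|------------------|----------|
| zero order       | k0·t                      | %Q               | t        |
| first order      | 100(1 − e^(−k1·t))        | ln(100 − %Q)     | t        |
| Higuchi          | kH·√t                     | %Q               | √t       |
| Weibull          | 100(1 − e^(−(t−T)^β/α))   | log10(−ln(1−Q))  | log10 t  |
| Korsmeyer–Peppas | kK·t^n                    | log10 %Q         | log10 t  |

Conventions: log10 in the Weibull and power-law transforms, natural log
in the first-order transform; the Weibull lag T is 0 by default (shift
times beforehand to model a lag); Q = %Q/100. Data enter the fit as the
point-wise mean of replicate implants of one design, truncated at 80% of
dose (inclusive) — beyond that the depletion plateau, not the transport
law, shapes the curve. Points with t = 0 or %Q = 0 (and %Q ≥ 100 for the
first-order/Weibull transforms) are dropped before log transforms; fewer
than 3 usable points, zero x-variance or non-finite transforms raise
errors naming the model. The power law needs ≥ 3 points spanning a time
range; exact ties in model selection are broken by a fixed order
(Korsmeyer–Peppas, Weibull, first, Higuchi, zero) and flagged.

The pooled diffusional exponent n̄ is the unweighted arithmetic mean of
the per-design power-law exponents: n encodes the transport mechanism,
which is shared across designs, while k absorbs geometry.

## Area-to-volume calibration

The empirical link between the power-law constant and geometry is

    log10 k = 10^a · (A/V)^m,

estimated by OLS of log10(log10 k) on log10(A/V). This requires
log10 k > 0 for every design (k > 1 %/day^n); violating points are named.
k carries units of % per day^n — a choice the data cannot determine but
which is consistent with multi-day release horizons and log k values of
1.3–1.9. The calibration object retains its regression inputs so any
reproduction is auditable: refitting on the *rounded* published
per-design constants reproduces the published intercept (a = 0.1655 vs
0.1650) but gives a slope of 0.2536 rather than the published 0.2251,
which was evidently derived from unrounded per-fit constants that were
never published. The package reports what its inputs imply and does not
force-match the slope.

Prediction composes the two laws: %Q_t = k·t^n̄ with
k = 10^(10^a·(A/V)^m), truncated (not clamped) at an 80% cap — grid
points above the cap are dropped, because the power law is not credible
into the plateau. Absolute amounts scale the fractions by the theoretical
dose = drug load (0.10) × printing-line density (default 1.18 mg/mm³,
the grand mean over all cylinder designs) × CAD volume. Two shapes with
equal A/V therefore predict identical *fractional* curves regardless of
absolute size; their absolute curves differ by dose alone.

## Profile congruence

f1 (difference factor) and f2 (similarity factor) compare cumulative
percent-release series at shared time points:

    f1 = 100 · Σ|R_t − T_t| / ΣR_t
    f2 = 50 · log10(100 · [1 + (1/n)Σ(R_t − T_t)²]^(−1/2))

computed on fractional (percent-of-dose) series, the scale on which the
factors are conventionally defined. Time points are taken where the
reference (predicted) profile is at or below the 80% cutoff, keeping the
dense early samples that resolve burst behaviour; profiles must share
sampling times unless linear interpolation onto the reference grid is
explicitly enabled. f2 is symmetric, f1 is not (its denominator is the
reference sum) — both facts are tested. No minimum sample size is
enforced, but fewer than 3 compared points triggers a warning. The
conventional bounds f1 ≤ 15 and f2 ≥ 50 are reported as an `equivalent`
flag, never enforced.

## Synthetic release studies

The generator emulates the in-vitro protocol: per replicate implant, a
drug-part mass and a drug-content multiplier are drawn from unit-mean
lognormals with the given RSDs (multiplicative errors compound, so
lognormal is the natural family; the original uniformity tables report
RSDs of roughly 1–7% for mass and dose, ~12% for the worst single-line
design). The true cumulative fraction follows the calibrated power law
capped at 100%; interval amounts are successive differences of the
cumulative mass, each perturbed by multiplicative Gaussian error of the
given CV and floored at zero. The default schedule
{0.125, 0.25, 0.5, 1, 2, …, 7} days places short intervals early. The
study terminates at the first sample whose release rate falls below a
detectability threshold (default 0.2% of dose per 24 h — the assay
detects "minimal" signal, and this value ends a completed study within
one or two intervals without ever clipping the sub-80% fitting window).
The recorded drug-part mass reflects the mass perturbation but not the
content perturbation, so analysis doses (10% of recorded part mass) are
biased relative to actual drug content exactly as they are in a real
study.

What the generator does *not* emulate: burst release (the truth is a pure
power law; none was modelled for this system), carry-over between media,
truncated selection of replicates by similar mass (plain lognormal
sampling is used), assay chemistry, or any deviation of printed geometry
from CAD geometry. Passing tests therefore demonstrate the *internal*
consistency of the chain — a zero-noise simulation is exactly inverted by
fitting + calibration (truth recovered to 1e-6), and recovery degrades
gracefully under realistic noise — not that real implants follow a power
law; that evidence lives in the original experiments.

## Numerical choices and problem sizes

All regressions are `scipy.stats.linregress`; calibration R² is squared
Pearson r on the double-log scale. Randomness flows from a single
`numpy.random.Generator` seed; identical seeds give byte-identical CSVs.
CSV floats are written at 17 significant digits and parsed with pandas'
round-trip parser so file round trips are bit-exact. Mesh fixtures use
trimesh primitives: a 512-segment tessellated cylinder is within 0.1% of
the analytic lateral area, a 4-subdivision icosphere within 0.5% of the
sphere volume; refinement tests use {16, 64, 256} segments. Test suites
simulate 3 replicates × 10 designs on the 10-point default schedule
(hundreds of rows, sub-second); the noise-recovery checks use 20
replicate fits and a 200-replicate dose-sampling check.

## Known limitations

- The exact A/V values of the three patient-specific shells used in the
  original study were never published; predictions for such shapes rest
  on the 1/t-class (thin-shell) approximation or on a supplied inner mesh.
- The calibration is specific to one drug–polymer–geometry system; a and
  m have no mechanistic interpretation and must be recalibrated for any
  other formulation.
- Fitting on mean profiles (the default) discards between-replicate
  variance; per-replicate fitting is possible by passing single profiles
  but no pooled uncertainty for (a, m) is propagated into predictions.
- The f2 statistic is used outside the sample-size conditions of the
  regulatory guidance it comes from; with the few shared time points of a
  multi-day implant study it is a descriptive congruence score, not an
  inferential test.
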