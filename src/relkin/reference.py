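"""Reference constants of the hollow-cylinder release study.

These are the published characterization results for the ten unique
hollow-cylinder designs (the standard design S is also labelled A1, B2
and C1): per-design Korsmeyer-Peppas constants fitted on mean release
data truncated at 80% of fractional release, the grand-mean density of
deposited printing lines, and the theoretical drug load.  They serve as
inputs when re-deriving the area-to-volume calibration and as the default
truth for the synthetic release-study generator.
"""

from __future__ import annotations

#: theoretical drug load of the drug-containing part (mass fraction)
DRUG_LOAD = 0.10

#: grand-mean density of printing lines of the drug-loaded part, mg/mm^3
PRINT_LINE_DENSITY = 1.18

#: per-design Korsmeyer-Peppas diffusional exponent n (slope of the
#: log %Q vs log t regression on mean release data)
KP_EXPONENT_N = {
    "S": 0.592,
    "A2": 0.600,
    "A3": 0.590,
    "A4": 0.600,
    "B1": 0.550,
    "B3": 0.600,
    "B4": 0.602,
    "C2": 0.611,
    "C3": 0.609,
    "C4": 0.607,
}

#: per-design log10 of the Korsmeyer-Peppas rate constant k (% / day^n)
KP_LOG_K = {
    "S": 1.59,
    "A2": 1.57,
    "A3": 1.56,
    "A4": 1.59,
    "B1": 1.87,
    "B3": 1.45,
    "B4": 1.38,
    "C2": 1.45,
    "C3": 1.36,
    "C4": 1.28,
}

#: area-to-volume power-law calibration constants: log10 k = 10**A_INTERCEPT * (A/V)**M_EXPONENT
A_INTERCEPT = 0.1650
M_EXPONENT = 0.2251

#: mean diffusional exponent pooled over all designs
N_MEAN = 0.5961

#: default sampling schedule in days -- dense early samples resolve any
#: burst phase, then daily transfers until the plateau
DEFAULT_SCHEDULE = (0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
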