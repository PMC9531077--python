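"""Published reference values for adult distal-humerus morphometry.

Reference measurements from a CT-based statistical shape analysis of 106
nonpathologic adult elbows (Chinese cohort): per-mode variance percentages of
the fitted SSM and the Table-style measurement values of the mean model and
the PC1 +- 3 SD models.  These serve as realistic design targets for the
phantom defaults and as inputs for arithmetic consistency checks of the
reporting conventions (e.g. that the published ratio rows equal the quotient
of their published component rows after rounding).
"""

from __future__ import annotations

# Per-PC percentage of total shape variance (the seven modes each > 3 %)
VARIANCE_PERCENTAGES = (44.4, 12.2, 7.9, 5.9, 4.1, 3.4, 3.0)
# The seven modes jointly account for this percentage of the variability
VARIANCE_TOP7_SUM = 80.9

# Measurement columns: mean model and PC1 +- 3 SD models (mm / degrees)
MEAN_MODEL = {
    "Wtel": 57.4,
    "Wcline": 42.1,
    "Wcap": 15.2,
    "Wtro": 19.2,
    "RT": 1.49,
    "RTC": 1.26,
    "ATC": 4.8,
    "Agro": 48.6,
    "R1": 11.4,
    "R2": 8.5,
    "R3": 9.2,
    "R4": 8.6,
    "R5": 9.9,
    "R6": 12.2,
}
PC1_PLUS_3SD = {"Wtel": 44.4, "Wcline": 32.9, "Wcap": 11.6, "Wtro": 12.9, "RTC": 1.11}
PC1_MINUS_3SD = {"Wtel": 71.1, "Wcline": 52.0, "Wcap": 17.9, "Wtro": 20.7, "RTC": 1.16}

# Articular point-to-mesh RMS of the size mode (PC1) vs the mean model (mm)
ARTICULAR_RMS_PC1 = {"+3SD": 2.38, "-3SD": 1.43}

# Cohort composition
COHORT = {"n": 106, "male": 72, "female": 34, "left": 54, "right": 52, "mean_age": 33.5}
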