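"""Published reference values for the WDR5–Kif2A study system.

These numbers are experimental results reported for the system this package
analyses. They are inputs for consistency checks (e.g. recomputing −TΔS from
K_D and ΔH) and for annotating reports — never fitted or adjusted here.
"""

from __future__ import annotations

# ITC results at 20 degC in 200 mM NaCl, single-site fits.
# K_D in mol/L; dH and minus_TdS in kcal/mol. 'nd' rows (no detectable
# binding) are omitted.
PUBLISHED_ITC = [
    {"label": "WDR5 + Kif2A(114-122)", "dh": -15.7, "minus_tds": 7.48,
     "n": 0.91, "k_d": 0.78e-6},
    {"label": "WDR5 + Kif2A(114-120)", "dh": -9.2, "minus_tds": 2.26,
     "n": 1.19, "k_d": 6.71e-6},
    {"label": "WDR5 + Kif2A(114-122) S121G", "dh": -10.6, "minus_tds": 3.29,
     "n": 0.94, "k_d": 3.72e-6},
    {"label": "WDR5 + Kif2A(114-122) S121A", "dh": -13.0, "minus_tds": 5.36,
     "n": 0.97, "k_d": 2.16e-6},
    {"label": "WDR5(Y191F) + Kif2A(114-122)", "dh": -9.0, "minus_tds": 0.92,
     "n": 1.27, "k_d": 0.96e-6},
]

ITC_TEMPERATURE_K = 293.15

# Reported Tyr191 ring rotations between structure pairs (degrees), used to
# annotate rotation reports when users supply local copies of the entries.
PUBLISHED_ROTATIONS = {
    ("9J20", "6OI0"): 12.6,   # Kif2A-bound vs arginine-bound
    ("8WXQ", "6OI0"): 88.2,   # MBD3C-bound vs arginine-bound
    ("6E23", "6OI0"): 87.5,   # compound C6-bound vs arginine-bound
    ("9JWV", "9J20"): 17.0,   # Y191F variant vs wild-type Kif2A complex
    ("9KD4", "9J20"): 9.0,    # Kif2A 114-120 truncation vs full peptide
}

# Reported S7 pocket states per entry context.
PUBLISHED_S7_STATES = {
    "9J20": "open", "9KD5": "open", "8WXQ": "open", "6DAS": "open",
    "6E23": "open", "6OI0": "closed", "9JWV": "closed", "9KD4": "closed",
}

# Reported Calpha superposition of the two receptor copies in the Kif2A
# complex asymmetric unit.
PUBLISHED_COPY_RMSD = {"rmsd": 0.132, "n_atoms": 291}

# Number of ordered waters reported in the WIN-S7 region of the Kif2A complex.
PUBLISHED_WATER_COUNT = 9
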