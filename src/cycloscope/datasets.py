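"""Published experimental inputs for the piperine/β-cyclodextrin study.

These are measured quantities taken from the published study of piperine
(PN) inclusion complexes in native and derivatized β-cyclodextrins — the
phase-solubility regression parameters, the measured aqueous solubility of
piperine, the UV-Vis calibration line, the MM/GBSA component means and SDs,
and the deposited unit cells. They are *inputs* to the analyses in this
package (the analysis scripts and the acceptance checks recompute every
derived quantity from them); nothing here is a computed output.
"""

from __future__ import annotations

from .structure_io import UnitCell

#: measured aqueous solubility of piperine (mM) used as S0 in the Kc formula
PIPERINE_S0_MM = 0.0378

#: UV-Vis calibration at 345 nm: absorbance = slope·conc(mM) + intercept
CALIBRATION = {"slope": 39.19, "intercept": 0.0009, "r_squared": 0.99,
               "range_mM": (0.00125, 0.02)}

#: phase-solubility isotherms at 25 °C (n = 3): regression slope/intercept
#: (dissolved PN, mM, vs cyclodextrin, mM), profile type and fit R².
PHASE_SOLUBILITY = {
    "PN/beta-CD": {
        "profile": "B_s",
        "slope": 0.0652,
        "intercept": 0.0378,
        "r_squared": 0.9939,
        "cd_range_mM": (1.0, 15.0),
        "note": "slope fitted over the linear portion (1-3 mM)",
    },
    "PN/RM-beta-CD": {
        "profile": "A_L",
        "slope": 0.1562,
        "intercept": -0.3348,
        "r_squared": 0.9988,
        "cd_range_mM": (1.0, 60.0),
    },
    "PN/HP-beta-CD": {
        "profile": "A_L",
        "slope": 0.1148,
        "intercept": -0.3337,
        "r_squared": 0.9968,
        "cd_range_mM": (1.0, 60.0),
    },
}

#: published stability constants (M^-1) and complexation efficiencies (%)
PHASE_SOLUBILITY_PUBLISHED = {
    "PN/beta-CD": {"Kc": 1800.0, "Kc_sd": 300.0, "CE": 7.0, "CE_sd": 0.4},
    "PN/RM-beta-CD": {"Kc": 4900.0, "Kc_sd": 500.0, "CE": 18.5, "CE_sd": 0.3},
    "PN/HP-beta-CD": {"Kc": 3400.0, "Kc_sd": 300.0, "CE": 13.0, "CE_sd": 0.3},
}

#: MM/GBSA component means ± SD (kcal/mol) per simulated complex:
#: base components and entropy as published; derived rows as printed,
#: for consistency checking against the additive identities.
MMGBSA_COMPONENTS = {
    "PN1/beta-CD": {
        "dE_vdW": (-51.70, 4.08), "dE_ele": (-10.41, 4.64),
        "dG_GB": (26.68, 3.91), "dG_nonpolar": (-5.44, 0.30),
        "TdS": (-20.43, 3.76),
    },
    "PN2/beta-CD": {
        "dE_vdW": (-50.79, 4.27), "dE_ele": (-9.66, 4.18),
        "dG_GB": (25.31, 4.01), "dG_nonpolar": (-5.33, 0.25),
        "TdS": (-19.93, 3.14),
    },
    "PN/DM-beta-CD": {
        "dE_vdW": (-51.16, 3.01), "dE_ele": (-11.09, 4.08),
        "dG_GB": (26.43, 3.84), "dG_nonpolar": (-5.49, 0.20),
        "TdS": (-16.51, 4.16),
    },
    "PN/TM-beta-CD": {
        "dE_vdW": (-53.41, 3.60), "dE_ele": (-6.43, 2.58),
        "dG_GB": (27.16, 3.00), "dG_nonpolar": (-5.37, 0.23),
        "TdS": (-17.61, 3.78),
    },
    "PN_im1/HP-beta-CD": {
        "dE_vdW": (-27.15, 2.24), "dE_ele": (-5.79, 3.15),
        "dG_GB": (23.64, 3.68), "dG_nonpolar": (-3.28, 0.25),
        "TdS": (-15.63, 1.48),
    },
    "PN_im2/HP-beta-CD": {
        "dE_vdW": (-26.23, 2.60), "dE_ele": (-7.00, 3.16),
        "dG_GB": (25.43, 3.28), "dG_nonpolar": (-3.29, 0.34),
        "TdS": (-16.31, 1.71),
    },
}

#: published derived rows (means only, kcal/mol), as printed
MMGBSA_PUBLISHED = {
    "PN1/beta-CD": {"dE_MM": -62.11, "dG_solvation": 21.24, "dH": -40.87, "dG_binding": -20.43},
    "PN2/beta-CD": {"dE_MM": -60.45, "dG_solvation": 19.99, "dH": -40.47, "dG_binding": -20.53},
    "PN/DM-beta-CD": {"dE_MM": -62.25, "dG_solvation": 20.93, "dH": -41.31, "dG_binding": -24.80},
    "PN/TM-beta-CD": {"dE_MM": -59.84, "dG_solvation": 21.78, "dH": -38.06, "dG_binding": -20.45},
    "PN_im1/HP-beta-CD": {"dE_MM": -32.94, "dG_solvation": 20.35, "dH": -12.58, "dG_binding": 3.04},
    "PN_im2/HP-beta-CD": {"dE_MM": -33.27, "dG_solvation": 22.16, "dH": -11.11, "dG_binding": 5.20},
}

#: deposited unit cells (lengths Å, angles deg) for disambiguating which
#: CCDC deposit holds which complex — matching is by cell, not identifier
DEPOSIT_CELLS = {
    "PN/beta-CD": UnitCell(15.435, 15.452, 15.502, 104.761, 100.770, 104.207),
    "PN/DM-beta-CD": UnitCell(15.364, 10.3253, 25.006, 90.0, 106.552, 90.0),
    "PN/TM-beta-CD": UnitCell(20.8000, 14.7391, 27.0968, 90.0, 96.214, 90.0),
}
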