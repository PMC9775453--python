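"""Higuchi–Connors phase-solubility analysis.

A phase-solubility experiment dissolves an excess of a poorly soluble guest
in solutions of increasing cyclodextrin concentration and measures the
total dissolved guest. For a 1:1 complex with a linear (A_L) profile of
slope *m* and guest aqueous solubility S0,

    Kc = m / (S0 · (1 − m))          (apparent stability constant, M⁻¹)
    CE = m / (1 − m)                 (complexation efficiency)

CE depends only on the slope, which makes it more robust than Kc when S0 is
small and poorly determined. B_s profiles (rise, plateau at the complex's
own solubility limit, then decline) are analysed over the initial linear
portion only.

S0 is always an explicit argument: A_L profiles of poorly soluble drugs
commonly have negative intercepts, which must not be fed into the Kc
formula — the measured aqueous solubility is used instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SolubilityDataset",
    "ComplexationResult",
    "fit_calibration",
    "absorbance_to_conc",
    "classify_profile",
    "linear_portion",
    "compute_kc",
    "compute_ce",
    "analyze",
    "plot_phase_diagram",
]

PROFILES = ("A_L", "A_P", "A_N", "B_s", "B_i")

#: fractional drop below the running maximum that marks a B-type decline
B_DROP = 0.05
#: minimum R² for a run of points to count as the linear portion
LINEAR_R2 = 0.99


@dataclass
class CalibrationCurve:
    slope: float          # absorbance per mM
    intercept: float      # absorbance
    r_squared: float
    valid_range: tuple[float, float]  # mM

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


@dataclass
class SolubilityDataset:
    """Mean dissolved-guest concentration at each cyclodextrin level (mM)."""

    cd_conc: np.ndarray
    guest_solubility: np.ndarray
    replicate_sd: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.cd_conc = np.asarray(self.cd_conc, dtype=float)
        self.guest_solubility = np.asarray(self.guest_solubility, dtype=float)
        if self.cd_conc.ndim != 1 or len(self.cd_conc) != len(self.guest_solubility):
            raise ValueError("cd_conc and guest_solubility must be 1-D and equal length")
        if np.any(np.diff(self.cd_conc) <= 0):
            raise ValueError("cyclodextrin concentrations must be strictly ascending")
        if np.any(self.guest_solubility < 0):
            raise ValueError("solubilities must be non-negative")
        if self.replicate_sd is not None:
            self.replicate_sd = np.asarray(self.replicate_sd, dtype=float)

    def __len__(self) -> int:
        return len(self.cd_conc)


@dataclass
class ComplexationResult:
    profile: str
    linear_range: tuple[int, int]    # [start, stop) indices of the fitted run
    slope: float
    intercept: float                 # mM
    r_squared: float
    S0_used: float                   # mM
    Kc: float                        # M^-1
    Kc_sd: float
    CE: float                        # percent
    CE_sd: float


def fit_calibration(conc, absorbance) -> CalibrationCurve:
    """Ordinary least-squares Beer–Lambert calibration line."""
    conc = np.asarray(conc, dtype=float)
    absorbance = np.asarray(absorbance, dtype=float)
    if len(conc) < 3 or len(np.unique(conc)) < 3:
        raise ValueError("calibration needs at least 3 distinct concentrations")
    res = stats.linregress(conc, absorbance)
    return CalibrationCurve(
        res.slope, res.intercept, res.rvalue**2, (float(conc.min()), float(conc.max()))
    )


def absorbance_to_conc(curve: CalibrationCurve, absorbance: float, dilution_factor: float = 1.0) -> float:
    """Invert the calibration line: conc = factor · (A − intercept) / slope."""
    conc = dilution_factor * (absorbance - curve.intercept) / curve.slope
    if conc < -1e-9:
        raise ValueError(
            f"absorbance {absorbance} below the calibration intercept gives a negative concentration"
        )
    return max(conc, 0.0)


def linear_portion(dataset: SolubilityDataset) -> tuple[int, int]:
    """Longest initial run of ≥3 points with OLS R² ≥ 0.99, as [start, stop)."""
    x, y = dataset.cd_conc, dataset.guest_solubility
    best = (0, min(3, len(x)))
    for stop in range(3, len(x) + 1):
        res = stats.linregress(x[:stop], y[:stop])
        r2 = res.rvalue**2 if not math.isnan(res.rvalue) else 1.0
        if r2 >= LINEAR_R2:
            best = (0, stop)
        else:
            break
    return best


def classify_profile(dataset: SolubilityDataset) -> tuple[str, tuple[int, int]]:
    """Phase-solubility profile type and the linear range to fit.

    Rules: a later level dropping more than 5% below the running maximum
    marks a B-type isotherm — B_s when at least two near-maximum plateau
    points precede the drop, else B_i. Otherwise the curvature of a
    quadratic fit decides: significantly positive (t-test, α = 0.05) → A_P,
    significantly negative → A_N, else A_L.
    """
    if len(dataset) < 4:
        raise ValueError("profile classification needs at least 4 concentration levels")
    y = dataset.guest_solubility
    imax = int(np.argmax(y))
    ymax = y[imax]
    declined = np.nonzero(y[imax:] < (1.0 - B_DROP) * ymax)[0]
    if len(declined) > 0:
        plateau = np.nonzero(y >= (1.0 - B_DROP) * ymax)[0]
        subtype = "B_s" if len(plateau) >= 2 else "B_i"
        return subtype, linear_portion(dataset)
    x = dataset.cd_conc
    import statsmodels.api as sm

    design = sm.add_constant(np.column_stack([x, x**2]))
    fit = sm.OLS(y, design).fit()
    if len(x) > 3 and fit.pvalues[2] < 0.05:
        return ("A_P" if fit.params[2] > 0 else "A_N"), linear_portion(dataset)
    return "A_L", (0, len(dataset))


def compute_kc(slope: float, S0_mM: float) -> float:
    """Apparent 1:1 stability constant Kc = slope / (S0·(1 − slope)), in M⁻¹."""
    if not 0.0 < slope < 1.0:
        raise ValueError(f"slope {slope} outside (0, 1); the 1:1 isotherm model is invalid")
    if S0_mM <= 0:
        raise ValueError("S0 must be positive")
    return slope / ((S0_mM * 1e-3) * (1.0 - slope))


def compute_ce(slope: float) -> float:
    """Complexation efficiency CE = slope / (1 − slope), as percent."""
    if not 0.0 < slope < 1.0:
        raise ValueError(f"slope {slope} outside (0, 1)")
    return 100.0 * slope / (1.0 - slope)


def analyze(dataset: SolubilityDataset, S0_mM: float) -> ComplexationResult:
    """Classify the profile, fit the appropriate range, and report Kc and CE.

    B-type profiles are fitted over the initial linear portion, A_L over the
    full range. Uncertainties are first-order (delta-method) propagation of
    the regression slope standard error:
    sd(Kc) = SE(m)/(S0·(1−m)²), sd(CE) = 100·SE(m)/(1−m)².
    """
    profile, rng = classify_profile(dataset)
    start, stop = rng
    x = dataset.cd_conc[start:stop]
    y = dataset.guest_solubility[start:stop]
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2) if not math.isnan(res.rvalue) else 1.0
    se = float(res.stderr) if res.stderr is not None and not math.isnan(res.stderr) else 0.0
    kc = compute_kc(slope, S0_mM)
    ce = compute_ce(slope)
    kc_sd = se / ((S0_mM * 1e-3) * (1.0 - slope) ** 2)
    ce_sd = 100.0 * se / (1.0 - slope) ** 2
    return ComplexationResult(profile, rng, slope, intercept, r2, S0_mM, kc, kc_sd, ce, ce_sd)


def plot_phase_diagram(dataset: SolubilityDataset, result: ComplexationResult, ax=None):
    """Phase-solubility diagram with the fitted linear portion and class label."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    x, y = dataset.cd_conc, dataset.guest_solubility
    if dataset.replicate_sd is not None:
        ax.errorbar(x, y, yerr=dataset.replicate_sd, fmt="o", capsize=3, label="data")
    else:
        ax.plot(x, y, "o", label="data")
    start, stop = result.linear_range
    xs = np.linspace(x[start], x[stop - 1], 50)
    ax.plot(xs, result.intercept + result.slope * xs, "-", label="linear portion")
    ax.set_xlabel("cyclodextrin (mM)")
    ax.set_ylabel("dissolved guest (mM)")
    ax.set_title(
        f"{result.profile}-type; Kc = {result.Kc:.0f} M$^{{-1}}$, CE = {result.CE:.1f}%"
    )
    ax.legend()
    return ax
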