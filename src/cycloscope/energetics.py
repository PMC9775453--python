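"""MM/GBSA binding-energy bookkeeping.

End-state MM/GBSA decomposes a host–guest binding free energy as

    ΔG_binding = ΔH − TΔS = ΔE_MM + ΔG_solvation − TΔS
    ΔE_MM        = ΔE_vdW + ΔE_ele
    ΔG_solvation = ΔG_GB + ΔG_nonpolar,   ΔG_nonpolar = γ·SASA + b

This module never computes the physics: force-field terms, GB energies,
SASA and normal-mode entropies are upstream-program outputs consumed as
data. What it owns is the bookkeeping — combining per-frame component
tables into means and standard deviations, recomputing summary tables from
component means, and consistency-checking published tables against the
additive identities.

Convention notes: standard deviations of derived quantities are SDs of the
per-frame sums (sample SD, ddof=1), not quadrature combinations of the
component SDs — per-frame components are correlated, so the two differ.
TΔS is stored exactly as published tables print it (often negative) and
ΔG_binding = ΔH − TΔS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BASE_COMPONENTS",
    "DERIVED_COMPONENTS",
    "NonpolarParams",
    "BindingSummary",
    "nonpolar_from_sasa",
    "combine_frames",
    "summarize_means",
    "consistency_check",
]

BASE_COMPONENTS = ("dE_vdW", "dE_ele", "dG_GB", "dG_nonpolar")
DERIVED_COMPONENTS = ("dE_MM", "dG_solvation", "dH", "dG_binding")


@dataclass
class NonpolarParams:
    """ΔG_nonpolar = γ·SASA + b (kcal/mol; γ in kcal·mol⁻¹·Å⁻²)."""

    gamma: float = 0.0072
    b: float = 0.0


@dataclass
class BindingSummary:
    """Component means (and optional SDs), kcal/mol."""

    means: dict[str, float]
    sds: dict[str, float] = field(default_factory=dict)
    n_frames: int | None = None

    def __getitem__(self, key: str) -> float:
        return self.means[key]


def nonpolar_from_sasa(sasa, params: NonpolarParams | None = None) -> np.ndarray:
    """Per-frame nonpolar solvation term γ·SASA + b."""
    params = params or NonpolarParams()
    sasa = np.asarray(sasa, dtype=float)
    if np.any(sasa < 0):
        raise ValueError("SASA values must be non-negative")
    return params.gamma * sasa + params.b


def _require(table: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"energy table is missing required column(s): {missing}")


def combine_frames(
    table: pd.DataFrame,
    tds: float | None = None,
    nonpolar_params: NonpolarParams | None = None,
) -> BindingSummary:
    """Combine a per-frame component table into a binding summary.

    ``table`` needs columns dE_vdW, dE_ele, dG_GB and either dG_nonpolar or
    SASA (converted via γ·SASA + b). Derived columns are computed per frame
    and *then* averaged; SDs are sample SDs of the per-frame sums. The
    entropy term may come as a ``TdS`` column or the scalar ``tds``; without
    it, ΔH doubles as the entropy-free binding estimate and dG_binding is
    omitted.
    """
    df = table.copy()
    _require(df, ("dE_vdW", "dE_ele", "dG_GB"))
    if "dG_nonpolar" not in df.columns:
        if "SASA" not in df.columns:
            raise ValueError("energy table is missing required column(s): ['dG_nonpolar' or 'SASA']")
        df["dG_nonpolar"] = nonpolar_from_sasa(df["SASA"].to_numpy(), nonpolar_params)
    if len(df) < 1 or not np.all(np.isfinite(df[list(BASE_COMPONENTS)].to_numpy())):
        raise ValueError("energy table must have ≥1 frame of finite values")
    df["dE_MM"] = df["dE_vdW"] + df["dE_ele"]
    df["dG_solvation"] = df["dG_GB"] + df["dG_nonpolar"]
    df["dH"] = df["dE_MM"] + df["dG_solvation"]
    tds_col = None
    if "TdS" in df.columns:
        tds_col = df["TdS"]
    elif tds is not None:
        tds_col = pd.Series(float(tds), index=df.index)
    if tds_col is not None:
        df["dG_binding"] = df["dH"] - tds_col
    cols = list(BASE_COMPONENTS) + ["dE_MM", "dG_solvation", "dH"]
    if tds_col is not None:
        cols += ["dG_binding"]
    n = len(df)
    means = {c: float(df[c].mean()) for c in cols}
    sds = {c: (float(df[c].std(ddof=1)) if n > 1 else 0.0) for c in cols}
    means["dG_binding_no_entropy"] = means["dH"]
    if tds_col is not None:
        means["TdS"] = float(tds_col.mean())
        sds["TdS"] = float(tds_col.std(ddof=1)) if (n > 1 and "TdS" in df.columns) else 0.0
    return BindingSummary(means, sds, n_frames=n)


def summarize_means(
    means: dict[str, float],
    tds: float | None = None,
) -> BindingSummary:
    """Recompute the derived rows of a summary table from component means.

    Pure arithmetic on the four base components (plus optional TΔS); used to
    verify published MM/GBSA tables.
    """
    out = dict(means)
    _requireable = [c for c in BASE_COMPONENTS if c not in out]
    if _requireable:
        raise ValueError(f"missing component mean(s): {_requireable}")
    out["dE_MM"] = out["dE_vdW"] + out["dE_ele"]
    out["dG_solvation"] = out["dG_GB"] + out["dG_nonpolar"]
    out["dH"] = out["dE_MM"] + out["dG_solvation"]
    out["dG_binding_no_entropy"] = out["dH"]
    if tds is None and "TdS" in means:
        tds = means["TdS"]
    if tds is not None:
        out["TdS"] = float(tds)
        out["dG_binding"] = out["dH"] - float(tds)
    return BindingSummary(out)


def consistency_check(published: BindingSummary, tolerance: float = 0.015) -> pd.DataFrame:
    """Residuals of the additive identities in a published summary.

    Checks ΔE_MM = ΔE_vdW + ΔE_ele, ΔG_solvation = ΔG_GB + ΔG_nonpolar,
    ΔH = ΔE_MM + ΔG_solvation and ΔG_binding = ΔH − TΔS, flagging residuals
    exceeding *tolerance* (default 0.015 kcal/mol — the worst rounding
    residual expected of a table printed to two decimals).
    """
    m = published.means
    rows = []

    def check(name: str, lhs: str, value: float) -> None:
        if lhs in m:
            resid = m[lhs] - value
            rows.append(
                {
                    "identity": name,
                    "published": m[lhs],
                    "recomputed": value,
                    "residual": resid,
                    "ok": abs(resid) <= tolerance,
                }
            )

    if all(k in m for k in ("dE_vdW", "dE_ele")):
        check("dE_MM = dE_vdW + dE_ele", "dE_MM", m["dE_vdW"] + m["dE_ele"])
    if all(k in m for k in ("dG_GB", "dG_nonpolar")):
        check("dG_solvation = dG_GB + dG_nonpolar", "dG_solvation", m["dG_GB"] + m["dG_nonpolar"])
    if all(k in m for k in ("dE_MM", "dG_solvation")):
        check("dH = dE_MM + dG_solvation", "dH", m["dE_MM"] + m["dG_solvation"])
    if all(k in m for k in ("dH", "TdS")):
        check("dG_binding = dH - TdS", "dG_binding", m["dH"] - m["TdS"])
    return pd.DataFrame(rows)
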