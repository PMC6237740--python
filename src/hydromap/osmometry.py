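"""Osmotic-stress linkage analysis: from K_D(osmolality) to water counts.

Excluded compatible osmolytes (betaine here) raise the free-energy cost of
sequestering water in a binding interface.  For colligatively acting
osmolytes the logarithm of the binding constant K_B = 1/K_D varies linearly
with solution osmolality, and the slope counts water:

    Gamma = d log10(K_B) / d osm = -delta_n_w / 128

where 128 is the printed rounding of 55.5 * ln(10) (molarity of water times
the natural-to-decadic log conversion) and a positive delta_n_w means net
water uptake on binding.  A strongly hydrated complex (Gamma < 0, binding
destabilized by osmotic pressure) therefore takes up water; a
hydration-neutral one has Gamma ~ 0.

The module fits the linear osmotic dependence, converts slopes to water
counts, extrapolates the normo-osmotic (0.3 osm) dissociation constant, and
budgets the counted water against the structural interface area.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OSMOTIC_CONVERSION",
    "NORMO_OSMOLALITY",
    "WATER_CROSS_SECTION",
    "OsmoticSeries",
    "OsmoticFit",
    "HydrationBudget",
    "fit_osmotic_series",
    "waters_from_slope",
    "extrapolate_affinity",
    "hydration_fraction",
    "read_osmotic_tsv",
    "write_osmotic_tsv",
]

# 55.5 M water x ln(10), rounded as conventionally printed; using the exact
# 127.79 would not reproduce the field's published water counts.
OSMOTIC_CONVERSION = 128.0

# physiologic baseline osmolality, osmolal
NORMO_OSMOLALITY = 0.3

# nominal cross-sectional area of one water molecule, A^2
WATER_CROSS_SECTION = 9.0


@dataclass(frozen=True)
class OsmoticSeries:
    """Fitted K_D values at graded osmolalities for one protein construct.

    ``points`` rows are (osmolality [osmolal], K_D [M], se_logK, n_replicates);
    se_logK may be NaN when unavailable, in which case the regression falls
    back to uniform weights.
    """

    points: tuple[tuple[float, float, float, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple(
            (float(o), float(k), float(se), int(n)) for o, k, se, n in self.points
        )
        object.__setattr__(self, "points", pts)
        if any(k <= 0 for _, k, _, _ in pts):
            raise ValueError("all K_D must be > 0")
        if any(o < 0 for o, _, _, _ in pts):
            raise ValueError("osmolalities must be >= 0")
        if len({o for o, _, _, _ in pts}) < 2:
            raise ValueError("need at least 2 distinct osmolalities")

    @property
    def osmolalities(self) -> np.ndarray:
        return np.array([o for o, _, _, _ in self.points])

    @property
    def log10_KB(self) -> np.ndarray:
        return np.array([-math.log10(k) for _, k, _, _ in self.points])

    @property
    def se_logK(self) -> np.ndarray:
        return np.array([se for _, _, se, _ in self.points])


@dataclass(frozen=True)
class OsmoticFit:
    """Linear fit of log10 K_B against osmolality.

    gamma
        Osmotic sensitivity (slope), osm^-1.
    intercept
        log10 K_B extrapolated to 0 osm.
    gamma_se
        Standard error of the slope (NaN when undefined, e.g. 2 points).
    delta_n_w
        Net water uptake implied by the slope (unrounded).
    normo_K_D
        Dissociation constant at the normo-osmotic baseline, M.
    """

    gamma: float
    intercept: float
    gamma_se: float
    delta_n_w: float
    normo_K_D: float
    normo_osmolality: float = NORMO_OSMOLALITY
    n_points: int = 0
    label: str = ""


@dataclass(frozen=True)
class HydrationBudget:
    """Counted osmotic water set against the structural interface area."""

    delta_n_w: float
    interface_area: float
    water_cross_section: float
    hydrated_fraction: float
    exceeds_interface: bool


def fit_osmotic_series(
    series: OsmoticSeries, normo_osmolality: float = NORMO_OSMOLALITY
) -> OsmoticFit:
    """Weighted least-squares line through (osmolality, log10 K_B).

    Weights are 1/se_logK^2 when every point carries a finite positive
    standard error, otherwise uniform.  With exactly two osmolalities the
    line is determined and ``gamma_se`` is NaN (undefined).
    """
    x = series.osmolalities
    y = series.log10_KB
    se = series.se_logK
    n = len(x)

    if np.all(np.isfinite(se)) and np.all(se > 0):
        w = 1.0 / se**2
    else:
        w = np.ones(n)

    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    gamma = float((w * (x - xbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - gamma * xbar)

    resid = y - (intercept + gamma * x)
    dof = n - 2
    if dof > 0:
        s2 = float((w * resid**2).sum() / dof)
        gamma_se = math.sqrt(s2 / sxx)
    else:
        gamma_se = float("nan")

    normo_logKB = intercept + gamma * normo_osmolality
    return OsmoticFit(
        gamma=gamma,
        intercept=intercept,
        gamma_se=gamma_se,
        delta_n_w=-OSMOTIC_CONVERSION * gamma,
        normo_K_D=10.0 ** (-normo_logKB),
        normo_osmolality=normo_osmolality,
        n_points=n,
        label=series.label,
    )


def waters_from_slope(gamma: float, rounded: bool = True) -> float:
    """Net water uptake from the osmotic slope: delta_n_w = -128 * Gamma.

    Negative Gamma (binding destabilized by osmotic pressure) yields a
    positive water count.  ``rounded=True`` (the reporting convention)
    rounds half-up to the nearest integer; the unrounded value is returned
    otherwise.
    """
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    waters = -OSMOTIC_CONVERSION * gamma
    if not rounded:
        return waters
    return float(math.floor(waters + 0.5))  # round half-up


def delta_n_w_se(gamma_se: float) -> float:
    """Propagated standard error on the water count: 128 * se(Gamma)."""
    return OSMOTIC_CONVERSION * gamma_se


def extrapolate_affinity(fit: OsmoticFit, osmolality: float = NORMO_OSMOLALITY) -> float:
    """K_D (M) on the fitted line at the given osmolality."""
    return 10.0 ** (-(fit.intercept + osmolality * fit.gamma))


def hydration_fraction(
    delta_n_w: float,
    interface_area: float,
    water_cross_section: float = WATER_CROSS_SECTION,
) -> HydrationBudget:
    """Fraction of the protein/DNA interface covered by the counted water.

    Each of the ``delta_n_w`` net-taken-up waters is assigned a nominal
    cross-section (9 A^2 default); the covered area is compared with the
    buried interface area.  A fraction above 1 is physically suspect
    (more water than the interface can tile) and is returned flagged, not
    clipped.
    """
    if interface_area <= 0:
        raise ValueError("interface_area must be > 0")
    if water_cross_section <= 0:
        raise ValueError("water_cross_section must be > 0")
    frac = delta_n_w * water_cross_section / interface_area
    return HydrationBudget(
        delta_n_w=delta_n_w,
        interface_area=interface_area,
        water_cross_section=water_cross_section,
        hydrated_fraction=frac,
        exceeds_interface=frac > 1.0,
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_osmotic_tsv(path: str | Path | io.StringIO) -> OsmoticSeries:
    """Columns: osmolality, K_D (molar), optional se_logK, n_replicates."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"osmolality", "K_D"}.issubset(df.columns):
        raise ValueError("osmotic TSV needs columns osmolality, K_D")
    se = df["se_logK"] if "se_logK" in df.columns else [float("nan")] * len(df)
    nrep = df["n_replicates"] if "n_replicates" in df.columns else [1] * len(df)
    points = tuple(
        (float(o), float(k), float(s), int(n))
        for o, k, s, n in zip(df["osmolality"], df["K_D"], se, nrep)
    )
    return OsmoticSeries(points=points)


def write_osmotic_tsv(series: OsmoticSeries, path: str | Path) -> None:
    lines = ["osmolality\tK_D\tse_logK\tn_replicates"]
    for o, k, se, n in series.points:
        lines.append(f"{o:.6g}\t{k:.10e}\t{se:.6g}\t{n}")
    Path(path).write_text("\n".join(lines) + "\n")
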