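"""Mutually exclusive competition equilibria and anisotropy titration fitting.

A single protein P binds either a fluorescently labeled DNA probe D or an
unlabeled competitor duplex C, never both::

    P + D <-> PD   (K_probe = [P][D]/[PD])
    P + C <-> PC   (K_comp  = [P][C]/[PC])

The observable is the steady-state fluorescence anisotropy of the probe,
a population-weighted average of the free (``r0``) and bound (``r1``)
limiting anisotropies:

    <r> = F_b * (r1 - r0) + r0,    F_b = [PD] / D_total.

Because experiments are run at protein concentrations comparable to the
dissociation constants, ligand depletion is significant and the coupled
mass-action system is solved exactly (no trace-probe or excess-titrant
approximations).  Fitting a competition curve therefore estimates the
competitor's dissociation constant directly, not an IC50.

Concentrations are molar throughout.
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

__all__ = [
    "BindingParameters",
    "TitrationPoint",
    "TitrationCurve",
    "EquilibriumState",
    "FitResult",
    "solve_equilibrium",
    "predicted_anisotropy",
    "fit_titration",
    "fit_titrations_global",
    "read_titration_tsv",
    "write_titration_tsv",
]

# Physical ceiling for single-photon steady-state anisotropy.
_ANISOTROPY_MAX = 0.4

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic and signal parameters of one competition experiment.

    Parameters
    ----------
    K_probe : float
        Dissociation constant of the protein·probe complex (M).
    K_comp : float
        Dissociation constant of the protein·competitor complex (M) — the
        quantity of interest, reported as K_D.
    r0, r1 : float
        Limiting anisotropies of the free and bound probe.
    """

    K_probe: float
    K_comp: float
    r0: float
    r1: float

    def __post_init__(self) -> None:
        for name in ("K_probe", "K_comp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name in ("r0", "r1"):
            v = getattr(self, name)
            if not (0 < v < _ANISOTROPY_MAX):
                raise ValueError(
                    f"{name} must lie in (0, {_ANISOTROPY_MAX}), got {v}"
                )
        if self.r1 == self.r0:
            raise ValueError("r1 must differ from r0 (no binding signal)")


@dataclass(frozen=True)
class TitrationPoint:
    """One point of a competition titration."""

    competitor_total: float
    anisotropy: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.competitor_total) and self.competitor_total >= 0):
            raise ValueError("competitor_total must be finite and >= 0")
        if not np.isfinite(self.anisotropy):
            raise ValueError("anisotropy must be finite")


@dataclass(frozen=True)
class TitrationCurve:
    """A competition titration: design concentrations plus measured anisotropies."""

    points: tuple[TitrationPoint, ...]
    probe_total: float
    protein_total: float
    osmolality: float
    label: str = ""
    sigma: tuple[float, ...] | None = None  # optional per-point anisotropy SD

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        if len(self.points) < 6:
            raise ValueError("a titration needs at least 6 points")
        if not (self.protein_total > 0 and self.probe_total > 0):
            raise ValueError("protein_total and probe_total must be > 0")
        conc = [p.competitor_total for p in self.points]
        if any(b < a for a, b in zip(conc, conc[1:])):
            raise ValueError("competitor_total values must be non-decreasing")
        if self.sigma is not None:
            sig = tuple(float(s) for s in self.sigma)
            if len(sig) != len(self.points) or any(s <= 0 for s in sig):
                raise ValueError("sigma must be positive, one value per point")
            object.__setattr__(self, "sigma", sig)

    @property
    def competitor_totals(self) -> np.ndarray:
        return np.array([p.competitor_total for p in self.points])

    @property
    def anisotropies(self) -> np.ndarray:
        return np.array([p.anisotropy for p in self.points])


@dataclass(frozen=True)
class EquilibriumState:
    """Free and complexed species concentrations (M) at one titration point."""

    free_protein: float
    free_probe: float
    free_competitor: float
    protein_probe: float
    protein_competitor: float

    def __post_init__(self) -> None:
        for name in (
            "free_protein",
            "free_probe",
            "free_competitor",
            "protein_probe",
            "protein_competitor",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is negative")

    def fraction_bound(self, probe_total: float) -> float:
        """F_b, the fraction of probe in complex."""
        return self.protein_probe / probe_total


@dataclass(frozen=True)
class FitResult:
    """Outcome of a titration fit."""

    estimates: BindingParameters
    standard_errors: dict[str, float]
    residual_sum_squares: float
    n_points: int
    converged: bool
    identifiable: bool = True
    free_parameters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.residual_sum_squares < 0:
            raise ValueError("residual_sum_squares must be >= 0")
        if any(v < 0 for v in self.standard_errors.values() if np.isfinite(v)):
            raise ValueError("standard errors must be >= 0")


# ---------------------------------------------------------------------------
# exact equilibrium solver
# ---------------------------------------------------------------------------


def _check_conc(name: str, value: float) -> None:
    if not np.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value}")


def solve_equilibrium(
    protein_total: float,
    probe_total: float,
    competitor_total: float,
    K_probe: float,
    K_comp: float,
) -> EquilibriumState:
    """Solve the coupled mass-action system for mutually exclusive competition.

    Eliminating the complexes through the two binding laws reduces the
    three mass balances to a single equation in the free protein ``p``::

        g(p) = p * (1 + D_t/(K_probe + p) + C_t/(K_comp + p)) - P_t = 0

    ``g`` is strictly increasing on [0, P_t] with g(0) = -P_t <= 0 and
    g(P_t) >= 0, so the physical root is unique and safely bracketed;
    it is located by Brent's method to ~1e-15 M absolute tolerance.

    Returns
    -------
    EquilibriumState
        All five species concentrations, satisfying the mass balances to
        better than 1e-9 relative and both binding laws to 1e-6 relative.
    """
    _check_conc("protein_total", protein_total)
    _check_conc("probe_total", probe_total)
    _check_conc("competitor_total", competitor_total)
    for name, k in (("K_probe", K_probe), ("K_comp", K_comp)):
        if not (np.isfinite(k) and k > 0):
            raise ValueError(f"{name} must be finite and > 0, got {k}")

    if protein_total == 0:
        return EquilibriumState(0.0, probe_total, competitor_total, 0.0, 0.0)

    def g(p: float) -> float:
        return (
            p
            * (1.0 + probe_total / (K_probe + p) + competitor_total / (K_comp + p))
            - protein_total
        )

    def dg(p: float) -> float:
        return (
            1.0
            + probe_total * K_probe / (K_probe + p) ** 2
            + competitor_total * K_comp / (K_comp + p) ** 2
        )

    if g(protein_total) <= 0:  # only at zero ligand, root is the endpoint
        p = protein_total
    else:
        p = brentq(
            g, 0.0, protein_total, xtol=1e-15, rtol=8.9e-16, maxiter=200
        )
        # where g is steep, a 1e-15 bracket still leaves g(p) above the
        # mass-balance tolerance; Newton polishing closes it (g' >= 1, so
        # steps are stable and quadratic)
        for _ in range(8):
            resid = g(p)
            if abs(resid) <= 1e-12 * protein_total:
                break
            p = min(max(p - resid / dg(p), 0.0), protein_total)

    protein_probe = p * probe_total / (K_probe + p)
    protein_comp = p * competitor_total / (K_comp + p)
    return EquilibriumState(
        free_protein=p,
        free_probe=probe_total - protein_probe,
        free_competitor=competitor_total - protein_comp,
        protein_probe=protein_probe,
        protein_competitor=protein_comp,
    )


def predicted_anisotropy(
    state: EquilibriumState, probe_total: float, r0: float, r1: float
) -> float:
    """Two-state anisotropy signal: <r> = r0 + (r1 - r0) * F_b."""
    if probe_total <= 0:
        raise ValueError("probe_total must be > 0")
    fb = state.fraction_bound(probe_total)
    return r0 + (r1 - r0) * fb


def _model_curve(
    competitor_totals: np.ndarray,
    protein_total: float,
    probe_total: float,
    K_probe: float,
    K_comp: float,
    r0: float,
    r1: float,
) -> np.ndarray:
    out = np.empty_like(competitor_totals, dtype=float)
    for i, ct in enumerate(competitor_totals):
        st = solve_equilibrium(protein_total, probe_total, float(ct), K_probe, K_comp)
        out[i] = r0 + (r1 - r0) * st.fraction_bound(probe_total)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_FITTABLE = ("K_probe", "K_comp", "r0", "r1")


def _initial_guess(curve: TitrationCurve, initial: BindingParameters | None) -> dict:
    """Default start: r0/r1 from the curve ends, K_comp near the midpoint dose."""
    r = curve.anisotropies
    ct = curve.competitor_totals
    positive = ct[ct > 0]
    k_mid = float(np.sqrt(positive[0] * positive[-1])) if positive.size else 1e-9
    guess = {
        "K_probe": initial.K_probe if initial else 1e-9,
        "K_comp": initial.K_comp if initial else k_mid,
        "r0": float(r[-1]),  # high competitor -> probe displaced
        "r1": float(r[0]),
    }
    if initial is not None:
        guess["r0"], guess["r1"] = initial.r0, initial.r1
    # keep limiting anisotropies physical
    eps = 1e-3
    for key in ("r0", "r1"):
        guess[key] = min(max(guess[key], eps), _ANISOTROPY_MAX - eps)
    if abs(guess["r1"] - guess["r0"]) < 1e-4:
        guess["r1"] = min(guess["r0"] + 0.01, _ANISOTROPY_MAX - eps)
    return guess


def _is_degenerate(curve: TitrationCurve) -> bool:
    """No anisotropy change beyond noise -> the fit cannot identify K_comp.

    The noise scale is estimated from first differences of the (dose-ordered)
    signal, which a smooth binding transition barely inflates.
    """
    r = curve.anisotropies
    span = float(r.max() - r.min())
    sigma_hat = float(np.std(np.diff(r)) / math.sqrt(2.0)) if len(r) > 1 else 0.0
    return span <= max(4.0 * sigma_hat, 1e-12)


def fit_titration(
    curve: TitrationCurve,
    fixed: dict[str, float] | None = None,
    initial: BindingParameters | None = None,
    bootstrap: int = 0,
    bootstrap_seed: int = 0,
) -> FitResult:
    """Fit the exact competition model to one titration by least squares.

    Parameters
    ----------
    curve : TitrationCurve
        The data; ``protein_total`` and ``probe_total`` come from its metadata.
    fixed : dict, optional
        Parameters to clamp, e.g. ``{"K_probe": 1e-9}``.  By default
        ``K_probe`` is fixed at the initial value and {K_comp, r0, r1} float,
        so the fit directly estimates the competitor's affinity.
    initial : BindingParameters, optional
        Starting values; defaults are derived from the data (limiting
        anisotropies from the curve ends, K_comp from the geometric midpoint
        dose).

    Notes
    -----
    Dissociation constants are optimized as log10(K) so the search is
    well-scaled across the nanomolar-to-micromolar range.  Standard errors
    come from the Jacobian at the optimum; ``bootstrap > 0`` replaces them
    with residual-resampling bootstrap errors over that many seeded draws.
    Non-convergence and degenerate (flat) curves are flagged on the result,
    never raised.
    """
    guess = _initial_guess(curve, initial)
    if fixed is None:
        fixed = {"K_probe": guess["K_probe"]}
    unknown = set(fixed) - set(_FITTABLE)
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
    guess.update(fixed)
    free = [name for name in _FITTABLE if name not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    n = len(curve.points)
    if n <= len(free):
        raise ValueError("need more points than free parameters")

    if _is_degenerate(curve):
        est = BindingParameters(
            K_probe=guess["K_probe"],
            K_comp=guess["K_comp"],
            r0=guess["r0"],
            r1=guess["r1"],
        )
        r = curve.anisotropies
        rss = float(np.sum((r - r.mean()) ** 2))
        return FitResult(
            estimates=est,
            standard_errors={p: float("nan") for p in free},
            residual_sum_squares=rss,
            n_points=n,
            converged=False,
            identifiable=False,
            free_parameters=tuple(free),
        )

    ct = curve.competitor_totals
    robs = curve.anisotropies
    weights = 1.0 / np.asarray(curve.sigma) if curve.sigma is not None else None

    def pack(values: dict) -> np.ndarray:
        out = []
        for name in free:
            v = values[name]
            out.append(math.log10(v) if name.startswith("K_") else v)
        return np.array(out)

    def unpack(x: np.ndarray) -> dict:
        vals = dict(guess)
        for name, xi in zip(free, x):
            vals[name] = 10.0**xi if name.startswith("K_") else float(xi)
        return vals

    def residuals(x: np.ndarray) -> np.ndarray:
        v = unpack(x)
        pred = _model_curve(
            ct, curve.protein_total, curve.probe_total,
            v["K_probe"], v["K_comp"], v["r0"], v["r1"],
        )
        res = pred - robs
        return res * weights if weights is not None else res

    lo = [(-15.0 if name.startswith("K_") else 1e-4) for name in free]
    hi = [(0.0 if name.startswith("K_") else _ANISOTROPY_MAX - 1e-4) for name in free]
    sol = least_squares(
        residuals, pack(guess), bounds=(lo, hi), method="trf",
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )

    v = unpack(sol.x)
    rss = float(np.sum(sol.fun**2))
    dof = n - len(free)
    # covariance from J^T J; singular Jacobian -> NaN errors, flagged converged
    # only if the optimizer itself reported success
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj) * (rss / dof if dof > 0 else float("nan"))
        se_x = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se_x = np.full(len(free), float("nan"))
    ses = {}
    for name, se in zip(free, se_x):
        # log10 K errors are converted to relative errors on K: se_K = K ln10 se_logK
        ses[name] = float(v[name] * math.log(10.0) * se) if name.startswith("K_") else float(se)

    if bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        pred = _model_curve(
            ct, curve.protein_total, curve.probe_total,
            v["K_probe"], v["K_comp"], v["r0"], v["r1"],
        )
        resid = robs - pred
        draws: list[np.ndarray] = []
        for _ in range(bootstrap):
            r_star = pred + rng.choice(resid, size=n, replace=True)

            def boot_residuals(x: np.ndarray) -> np.ndarray:
                vb = unpack(x)
                pb = _model_curve(
                    ct, curve.protein_total, curve.probe_total,
                    vb["K_probe"], vb["K_comp"], vb["r0"], vb["r1"],
                )
                return pb - r_star

            bsol = least_squares(
                boot_residuals, sol.x, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
            draws.append(bsol.x)
        spread = np.std(np.array(draws), axis=0, ddof=1)
        for name, se in zip(free, spread):
            ses[name] = (
                float(v[name] * math.log(10.0) * se)
                if name.startswith("K_")
                else float(se)
            )

    # the optimizer may land with r0/r1 swapped relative to the physical
    # labeling; that is the same curve, so keep the estimates as fitted
    est = BindingParameters(
        K_probe=v["K_probe"], K_comp=v["K_comp"], r0=v["r0"], r1=v["r1"]
    )
    return FitResult(
        estimates=est,
        standard_errors=ses,
        residual_sum_squares=rss,
        n_points=n,
        converged=bool(sol.success),
        identifiable=True,
        free_parameters=tuple(free),
    )


def fit_titrations_global(
    curves: Sequence[TitrationCurve],
    K_probe_initial: float = 1e-9,
) -> list[FitResult]:
    """Global fit sharing K_probe across curves; per-curve {K_comp, r0, r1}.

    Returns one FitResult per curve, each carrying the shared K_probe
    estimate.  Curves flagged degenerate are excluded from the global
    objective and fitted (flagged) individually afterwards.
    """
    active = [c for c in curves if not _is_degenerate(c)]
    if not active:
        raise ValueError("no identifiable curve in the set")

    guesses = [_initial_guess(c, None) for c in active]
    x0 = [math.log10(K_probe_initial)]
    for g in guesses:
        x0 += [math.log10(g["K_comp"]), g["r0"], g["r1"]]
    x0 = np.array(x0)

    def residuals(x: np.ndarray) -> np.ndarray:
        kp = 10.0 ** x[0]
        res = []
        for i, c in enumerate(active):
            kc = 10.0 ** x[1 + 3 * i]
            r0, r1 = x[2 + 3 * i], x[3 + 3 * i]
            pred = _model_curve(
                c.competitor_totals, c.protein_total, c.probe_total, kp, kc, r0, r1
            )
            res.append(pred - c.anisotropies)
        return np.concatenate(res)

    lo = [-15.0] + [-15.0, 1e-4, 1e-4] * len(active)
    hi = [0.0] + [0.0, _ANISOTROPY_MAX - 1e-4, _ANISOTROPY_MAX - 1e-4] * len(active)
    sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)

    kp = 10.0 ** sol.x[0]
    results: list[FitResult] = []
    j = 0
    for c in curves:
        if _is_degenerate(c):
            results.append(fit_titration(c))
            continue
        kc = 10.0 ** sol.x[1 + 3 * j]
        r0, r1 = float(sol.x[2 + 3 * j]), float(sol.x[3 + 3 * j])
        pred = _model_curve(
            c.competitor_totals, c.protein_total, c.probe_total, kp, kc, r0, r1
        )
        rss = float(np.sum((pred - c.anisotropies) ** 2))
        results.append(
            FitResult(
                estimates=BindingParameters(K_probe=kp, K_comp=kc, r0=r0, r1=r1),
                standard_errors={},
                residual_sum_squares=rss,
                n_points=len(c.points),
                converged=bool(sol.success),
                identifiable=True,
                free_parameters=("K_probe", "K_comp", "r0", "r1"),
            )
        )
        j += 1
    return results


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------


def read_titration_tsv(path: str | Path | io.StringIO) -> TitrationCurve:
    """Read a titration TSV with ``# key=value`` metadata header lines.

    Recognized metadata: probe_total, protein_total, osmolality, units, label.
    Columns: competitor_total, anisotropy, optional sigma.  Concentrations are
    scaled to molar by the ``units`` entry (default M).
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
    else:
        text = Path(path).read_text()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        m = re.match(r"#\s*([A-Za-z_]+)\s*=\s*(.+?)\s*$", line)
        if m:
            meta[m.group(1)] = m.group(2)
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(io.StringIO("\n".join(body_lines)), sep="\t")
    required = {"competitor_total", "anisotropy"}
    if not required.issubset(df.columns):
        raise ValueError(f"titration TSV needs columns {sorted(required)}")
    scale = _UNIT_SCALE.get(meta.get("units", "M"))
    if scale is None:
        raise ValueError(f"unknown concentration units {meta.get('units')!r}")
    for key in ("probe_total", "protein_total", "osmolality"):
        if key not in meta:
            raise ValueError(f"missing metadata line '# {key}='")
    points = tuple(
        TitrationPoint(competitor_total=float(c) * scale, anisotropy=float(a))
        for c, a in zip(df["competitor_total"], df["anisotropy"])
    )
    sigma = tuple(float(s) for s in df["sigma"]) if "sigma" in df.columns else None
    return TitrationCurve(
        points=points,
        probe_total=float(meta["probe_total"]) * scale,
        protein_total=float(meta["protein_total"]) * scale,
        osmolality=float(meta["osmolality"]),
        label=meta.get("label", ""),
        sigma=sigma,
    )


def write_titration_tsv(curve: TitrationCurve, path: str | Path) -> None:
    """Write a titration in the TSV format read_titration_tsv accepts (units M)."""
    lines = [
        f"# probe_total={curve.probe_total:.10e}",
        f"# protein_total={curve.protein_total:.10e}",
        f"# osmolality={curve.osmolality:.6g}",
        "# units=M",
    ]
    if curve.label:
        lines.append(f"# label={curve.label}")
    header = "competitor_total\tanisotropy"
    if curve.sigma is not None:
        header += "\tsigma"
    lines.append(header)
    for i, p in enumerate(curve.points):
        row = f"{p.competitor_total:.10e}\t{p.anisotropy:.8f}"
        if curve.sigma is not None:
            row += f"\t{curve.sigma[i]:.8f}"
        lines.append(row)
    Path(path).write_text("\n".join(lines) + "\n")
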