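"""Synthetic-data generators emulating the osmotic-stress binding experiments.

Every pipeline stage gets a deterministic, download-free input:

* competition titrations of a labeled probe against an unlabeled duplex,
  forward-modeled through the exact equilibrium solver plus the two-state
  anisotropy signal, with additive Gaussian noise on the anisotropy;
* osmotic series that are log-linear in osmolality, with Gaussian noise on
  log10 K_B per replicate — the simplest noise models consistent with
  replicate +/- SD reporting;
* binding-site sequences sampled column-independently from a PFM;
* toy sphere "complexes" for surface-area work.

All generators are pure functions of (design, seed): the same seed gives
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .equilibria import (
    BindingParameters,
    TitrationCurve,
    TitrationPoint,
    predicted_anisotropy,
    solve_equilibrium,
)
from .motif_ic import ALPHABET, PositionFrequencyMatrix
from .osmometry import NORMO_OSMOLALITY, OsmoticSeries
from .structure import FALLBACK_RADIUS, Atom, StructureModel

__all__ = [
    "TitrationDesign",
    "OsmoticDesign",
    "serial_dilution",
    "default_titration_design",
    "simulate_titration",
    "simulate_osmotic_experiment",
    "sample_sites",
    "write_fasta",
    "toy_complex",
    "DEFAULT_R0",
    "DEFAULT_R1",
]

# Plausible Cy3-probe limiting anisotropies; arbitrary simulation constants,
# not measured values.
DEFAULT_R0 = 0.18
DEFAULT_R1 = 0.28

# Default experimental window: protein in the 1e-9..1e-8 M range, probe
# sub-stoichiometric, osmolalities spanning the 0.29-2.0 osmolal series.
DEFAULT_PROTEIN_TOTAL = 5e-9
DEFAULT_PROBE_TOTAL = 1e-9
DEFAULT_OSMOLALITIES = (0.29, 0.7, 1.1, 1.5, 2.0)
DEFAULT_NOISE_SD_ANISOTROPY = 0.002
DEFAULT_NOISE_SD_LOGK = 0.05


@dataclass(frozen=True)
class TitrationDesign:
    """Design of one simulated competition titration."""

    probe_total: float = DEFAULT_PROBE_TOTAL
    protein_total: float = DEFAULT_PROTEIN_TOTAL
    competitor_concentrations: tuple[float, ...] = ()
    noise_sd: float = DEFAULT_NOISE_SD_ANISOTROPY
    seed: int = 0
    osmolality: float = NORMO_OSMOLALITY
    label: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        conc = tuple(float(c) for c in self.competitor_concentrations)
        if any(b < a for a, b in zip(conc, conc[1:])):
            raise ValueError("competitor concentrations must be non-decreasing")
        object.__setattr__(self, "competitor_concentrations", conc)


@dataclass(frozen=True)
class OsmoticDesign:
    """Design of one simulated osmotic-stress series."""

    gamma_true: float
    normo_logKB: float
    osmolalities: tuple[float, ...] = DEFAULT_OSMOLALITIES
    replicates: int = 3
    noise_sd_logK: float = DEFAULT_NOISE_SD_LOGK
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd_logK < 0:
            raise ValueError("noise_sd_logK must be >= 0")
        object.__setattr__(
            self, "osmolalities", tuple(float(o) for o in self.osmolalities)
        )


def serial_dilution(top: float, factor: float = 3.0, n: int = 12) -> tuple[float, ...]:
    """n-point serial dilution from ``top`` downward, returned ascending."""
    if top <= 0 or factor <= 1 or n < 2:
        raise ValueError("need top > 0, factor > 1, n >= 2")
    return tuple(top / factor ** (n - 1 - i) for i in range(n))


def default_titration_design(
    k_comp: float,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD_ANISOTROPY,
    osmolality: float = NORMO_OSMOLALITY,
    label: str = "",
    n_points: int = 12,
) -> TitrationDesign:
    """12-point 3-fold dilution geometrically centered on the expected K_comp."""
    top = k_comp * 3.0 ** ((n_points - 1) / 2.0)
    return TitrationDesign(
        competitor_concentrations=serial_dilution(top, 3.0, n_points),
        noise_sd=noise_sd,
        seed=seed,
        osmolality=osmolality,
        label=label,
    )


def simulate_titration(
    design: TitrationDesign, truth: BindingParameters
) -> TitrationCurve:
    """Forward-model a competition titration and add anisotropy noise."""
    if not design.competitor_concentrations:
        raise ValueError("design has no competitor concentrations")
    rng = np.random.default_rng(design.seed)
    noise = rng.normal(0.0, design.noise_sd, len(design.competitor_concentrations))
    points = []
    for ct, eps in zip(design.competitor_concentrations, noise):
        state = solve_equilibrium(
            design.protein_total, design.probe_total, ct, truth.K_probe, truth.K_comp
        )
        r = predicted_anisotropy(state, design.probe_total, truth.r0, truth.r1)
        points.append(TitrationPoint(competitor_total=ct, anisotropy=r + eps))
    return TitrationCurve(
        points=tuple(points),
        probe_total=design.probe_total,
        protein_total=design.protein_total,
        osmolality=design.osmolality,
        label=design.label,
    )


def simulate_osmotic_experiment(design: OsmoticDesign) -> OsmoticSeries:
    """Simulate replicate K_D measurements on a log-linear osmotic dependence.

    At each osmolality, ``replicates`` draws of
    log10 K_B = normo_logKB + gamma_true*(osm - 0.3) + N(0, noise_sd_logK)
    are averaged; the point carries K_D = 10^-mean and the replicate-scatter
    standard error of the mean (NaN for a single replicate).
    """
    rng = np.random.default_rng(design.seed)
    points = []
    for osm in design.osmolalities:
        mean_logKB = design.normo_logKB + design.gamma_true * (osm - NORMO_OSMOLALITY)
        draws = mean_logKB + rng.normal(0.0, design.noise_sd_logK, design.replicates)
        m = float(np.mean(draws))
        se = (
            float(np.std(draws, ddof=1) / math.sqrt(design.replicates))
            if design.replicates > 1
            else float("nan")
        )
        points.append((osm, 10.0 ** (-m), se, design.replicates))
    return OsmoticSeries(points=tuple(points), label=design.label)


# ---------------------------------------------------------------------------
# motif sampling
# ---------------------------------------------------------------------------


def sample_sites(
    pfm: PositionFrequencyMatrix, n: int, seed: int = 0
) -> list[str]:
    """Draw n binding-site sequences column-independently from the PFM."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = [
        rng.choice(4, size=n, p=pfm.probabilities[:, j]) for j in range(pfm.width)
    ]
    idx = np.column_stack(cols)
    return ["".join(ALPHABET[b] for b in row) for row in idx]


def write_fasta(sequences: Sequence[str], path: str | Path, prefix: str = "site") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(s), id=f"{prefix}_{i+1}", description="")
        for i, s in enumerate(sequences)
    ]
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------


def toy_complex(
    spheres: Sequence[tuple[str, tuple[float, float, float], float]],
    copies: tuple[tuple[str, ...], ...] = (),
) -> StructureModel:
    """Build a sphere-atom complex for surface-area tests.

    Each entry is (chain_kind_spec, center, radius) where chain_kind_spec is
    a chain id prefixed by 'P' (protein) or 'D' (DNA), e.g. "P:A" places a
    protein sphere on chain A.  Spheres on the same chain get consecutive
    residue numbers.  Coincident identical spheres trigger a warning.
    """
    import warnings as _warnings

    atoms: list[Atom] = []
    chain_kind: dict[str, str] = {}
    counters: dict[str, int] = {}
    seen: set[tuple] = set()
    for kind_spec, center, radius in spheres:
        kind_code, _, chain = kind_spec.partition(":")
        chain = chain or kind_code  # allow bare chain ids defaulting by code
        kind = {"P": "protein", "D": "dna"}[kind_code.upper()]
        prev = chain_kind.get(chain)
        if prev is not None and prev != kind:
            raise ValueError(f"chain {chain} given conflicting kinds")
        chain_kind[chain] = kind
        counters[chain] = counters.get(chain, 0) + 1
        key = (tuple(round(c, 6) for c in center), round(radius, 6))
        if key in seen:
            _warnings.warn("overlapping identical atoms in toy complex")
        seen.add(key)
        atoms.append(
            Atom(
                name="C" if kind == "protein" else "P",
                element="C" if kind == "protein" else "P",
                chain_id=chain,
                residue_number=counters[chain],
                residue_name="GLY" if kind == "protein" else "DA",
                coordinates=tuple(float(c) for c in center),
                vdw_radius=float(radius),
            )
        )
    return StructureModel(atoms=tuple(atoms), chain_kind=chain_kind, copies=copies)
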