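"""Information content of binding-site motifs.

A position frequency matrix (PFM) gives base probabilities p_b at each
position of a binding site.  Against a uniform background, the per-position
information content in bits is

    IC_j = 2 + sum_b p_b log2 p_b        (0*log2(0) := 0)

which runs from 0 bits (all four bases equally probable) to 2 bits (one
base fully specified); a W-position motif carries at most 2W bits.  Total
IC measures how stringently a transcription factor discriminates sequence,
and differences between paralogs' motifs localize where one factor reads
more sequence than the other.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ALPHABET",
    "PositionFrequencyMatrix",
    "MotifICReport",
    "pfm_from_counts",
    "position_ic",
    "total_ic",
    "ic_difference",
    "read_jaspar",
    "read_pfm_tsv",
    "write_ic_tsv",
]

ALPHABET = ("A", "C", "G", "T")
_NORM_TOL = 1e-6


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """4 x W base probabilities (rows A, C, G, T) for a binding-site motif."""

    probabilities: np.ndarray
    source: str = ""
    n_sites: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != 4:
            raise ValueError("probabilities must be a 4 x W array")
        if (p < 0).any():
            raise ValueError("probabilities must be >= 0")
        sums = p.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > _NORM_TOL):
            raise ValueError("each column must sum to 1 within 1e-6")
        object.__setattr__(self, "probabilities", p)

    @property
    def width(self) -> int:
        return self.probabilities.shape[1]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probabilities.argmax(axis=0))


@dataclass(frozen=True)
class MotifICReport:
    """Per-position and total information content in bits."""

    per_position_bits: tuple[float, ...]
    total_bits: float
    width: int

    def __post_init__(self) -> None:
        if any(not (-1e-9 <= b <= 2.0 + 1e-9) for b in self.per_position_bits):
            raise ValueError("per-position IC must lie in [0, 2] bits")


def pfm_from_counts(
    counts: np.ndarray,
    pseudocount: float = 0.0,
    source: str = "",
) -> PositionFrequencyMatrix:
    """Normalize a 4 x W count matrix to probabilities.

    Each column becomes (count + pseudocount) / (column total + 4*pseudocount).
    A pseudocount of 0 on an all-zero column is an error.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[0] != 4:
        raise ValueError("counts must be 4 x W")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    totals = c.sum(axis=0) + 4.0 * pseudocount
    if np.any(totals <= 0):
        raise ValueError("column with zero total and zero pseudocount")
    probs = (c + pseudocount) / totals
    n_sites = int(round(c.sum(axis=0).max())) if c.sum() > 0 else None
    return PositionFrequencyMatrix(probabilities=probs, source=source, n_sites=n_sites)


def position_ic(
    column: np.ndarray, background: np.ndarray | None = None
) -> float:
    """Information content of one motif column in bits.

    Uniform background (the default) gives IC = 2 + sum p log2 p, bounded by
    [0, 2].  An explicit 4-vector ``background`` switches to the relative
    entropy sum p log2(p/b), the convention for non-uniform genomes.
    """
    p = np.asarray(column, dtype=float)
    if p.shape != (4,):
        raise ValueError("column must have 4 entries")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError("column must sum to 1 within 1e-6")
    nz = p > 0
    if background is None:
        return float(2.0 + np.sum(p[nz] * np.log2(p[nz])))
    b = np.asarray(background, dtype=float)
    if b.shape != (4,) or (b <= 0).any():
        raise ValueError("background must be 4 positive entries")
    return float(np.sum(p[nz] * np.log2(p[nz] / b[nz])))


def _small_sample_correction(n_sites: int) -> float:
    """Schneider-style expected IC overestimate for n sampled sites: 3/(2 ln2 n)."""
    return 3.0 / (2.0 * math.log(2.0) * n_sites)


def total_ic(
    pfm: PositionFrequencyMatrix,
    background: np.ndarray | None = None,
    small_sample_correction: bool = False,
) -> MotifICReport:
    """Sum per-position IC across the motif.

    The optional small-sample correction subtracts the expected per-column
    overestimate for ``pfm.n_sites`` sampled sequences; it is off by default
    because curated motif models, not raw counts, are the usual input.
    """
    correction = 0.0
    if small_sample_correction:
        if pfm.n_sites is None:
            raise ValueError("small-sample correction requires n_sites")
        correction = _small_sample_correction(pfm.n_sites)
    bits = tuple(
        max(position_ic(pfm.probabilities[:, j], background) - correction, 0.0)
        for j in range(pfm.width)
    )
    return MotifICReport(
        per_position_bits=bits, total_bits=float(sum(bits)), width=pfm.width
    )


def ic_difference(
    a: PositionFrequencyMatrix,
    b: PositionFrequencyMatrix,
    offset: int | None = None,
    background: np.ndarray | None = None,
) -> tuple[float, tuple[float, ...], float]:
    """Selectivity comparison of two motifs: (delta_total, per-position, ratio).

    Equal widths compare position-by-position.  Unequal widths require an
    explicit ``offset``: position j of ``a`` aligns with j - offset of ``b``,
    and the comparison covers the overlap (totals still use full motifs).
    """
    rep_a = total_ic(a, background)
    rep_b = total_ic(b, background)
    if a.width != b.width and offset is None:
        raise ValueError("width mismatch: supply an explicit offset alignment")
    off = offset or 0
    deltas = []
    for j in range(a.width):
        k = j - off
        if 0 <= k < b.width:
            deltas.append(rep_a.per_position_bits[j] - rep_b.per_position_bits[k])
    return (
        rep_a.total_bits - rep_b.total_bits,
        tuple(deltas),
        rep_a.total_bits / rep_b.total_bits,
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_jaspar(path: str | Path, pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    """Read a JASPAR-format count matrix (via Bio.motifs) into a PFM."""
    from Bio import motifs

    with open(path) as fh:
        motif = motifs.read(fh, "jaspar")
    counts = np.array([list(motif.counts[b]) for b in ALPHABET], dtype=float)
    return pfm_from_counts(counts, pseudocount=pseudocount, source=str(motif.name or path))


def read_pfm_tsv(path: str | Path | io.StringIO, pseudocount: float = 0.0) -> PositionFrequencyMatrix:
    """Plain 4 x W TSV (rows A, C, G, T; header optional; counts or probabilities)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    # tolerate a leading base-label column
    if df.iloc[:, 0].astype(str).str.upper().tolist() == list(ALPHABET):
        df = df.iloc[:, 1:]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != 4:
        raise ValueError("PFM TSV must have 4 rows (A, C, G, T)")
    sums = mat.sum(axis=0)
    if np.allclose(sums, 1.0, atol=_NORM_TOL):
        return PositionFrequencyMatrix(probabilities=mat, source=str(path))
    return pfm_from_counts(mat, pseudocount=pseudocount, source=str(path))


def write_ic_tsv(report: MotifICReport, path: str | Path) -> None:
    lines = ["position\tbits"]
    for j, bits in enumerate(report.per_position_bits):
        lines.append(f"{j}\t{bits:.6f}")
    lines.append(f"total\t{report.total_bits:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
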