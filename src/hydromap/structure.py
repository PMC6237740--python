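"""Solvent-accessible surface area and protein/DNA contact-area accounting.

The buried ("contact") area of a protein residue is the solvent-accessible
surface area (SASA) it loses when the bound DNA is included in the
calculation:

    buried(residue) = SASA(protein alone) - SASA(protein in complex)

summed over the residue's atoms.  Per-element reports divide each element's
total burial by its residue count, and structures deposited with multiple
asymmetric copies of the complex are averaged copy-wise.

SASA uses the Shrake-Rupley rolling-probe construction: each atom is
inflated by the probe radius (1.4 A, a water molecule), a quasi-uniform
point set is placed on the inflated sphere, and the accessible area is the
surviving-point fraction times the sphere area.  The point set here is a
deterministic Fibonacci (golden-spiral) lattice, so results are exactly
reproducible at a given point count.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "VDW_RADII",
    "Atom",
    "StructureModel",
    "ElementDefinition",
    "ContactAreaReport",
    "read_structure",
    "write_structure",
    "sasa",
    "contact_area",
]

# Van-der-Waals radii (A) for the heavy elements of protein/DNA crystal
# structures; hydrogens are absent from the structures this targets and are
# excluded on reading.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
FALLBACK_RADIUS = 1.70
PROBE_RADIUS = 1.4

_WATER_RES = {"HOH", "WAT", "DOD", "H2O"}
_PROTEIN_RES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
_DNA_RES = {"DA", "DC", "DG", "DT", "DI", "DU", "A", "C", "G", "T", "I", "U"}


@dataclass(frozen=True)
class Atom:
    """One heavy atom with its van-der-Waals radius."""

    name: str
    element: str
    chain_id: str
    residue_number: int
    residue_name: str
    coordinates: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be > 0")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")

    @property
    def residue_id(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_number)


@dataclass(frozen=True)
class StructureModel:
    """Atoms grouped into protein and DNA chains, optionally in several copies.

    ``chain_kind`` classifies every chain as "protein" or "dna"; ``copies``
    lists disjoint chain-id groups that form independent asymmetric copies of
    the same complex (empty: the whole model is one copy).
    """

    atoms: tuple[Atom, ...]
    chain_kind: dict[str, str]
    copies: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(
            self, "copies", tuple(tuple(group) for group in self.copies)
        )
        chains = {a.chain_id for a in self.atoms}
        missing = chains - set(self.chain_kind)
        if missing:
            raise ValueError(f"unclassified chains: {sorted(missing)}")
        bad = {k for k in self.chain_kind.values()} - {"protein", "dna"}
        if bad:
            raise ValueError(f"chain_kind values must be protein/dna, got {bad}")
        seen: set[str] = set()
        for group in self.copies:
            overlap = seen & set(group)
            if overlap:
                raise ValueError(f"copies must be disjoint, chain(s) {overlap} repeat")
            seen |= set(group)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms])

    def subset(self, keep: np.ndarray) -> "StructureModel":
        atoms = tuple(a for a, k in zip(self.atoms, keep) if k)
        chains = {a.chain_id for a in atoms}
        return StructureModel(
            atoms=atoms,
            chain_kind={c: k for c, k in self.chain_kind.items() if c in chains},
            copies=tuple(
                g for g in self.copies if any(c in chains for c in g)
            ),
        )

    def copy_groups(self) -> tuple[tuple[str, ...], ...]:
        if self.copies:
            return self.copies
        return (tuple(sorted({a.chain_id for a in self.atoms})),)


@dataclass(frozen=True)
class ElementDefinition:
    """A named secondary-structure element as an inclusive residue range."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("element start must be <= end")


@dataclass(frozen=True)
class ContactAreaReport:
    """Buried-area accounting, averaged over asymmetric copies.

    ``per_element`` maps element name -> (total buried A^2, residue count,
    per-residue A^2); ``interface_area_total`` sums burial over all protein
    residues, i.e. the water-accessible area of the whole interface.
    """

    per_element: dict[str, tuple[float, int, float]]
    interface_area_total: float

    def __post_init__(self) -> None:
        if self.interface_area_total < 0:
            raise ValueError("interface area must be >= 0")
        for name, (total, count, per_res) in self.per_element.items():
            if total < 0:
                raise ValueError(f"negative buried area for {name}")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------


def _classify_chain(residue_names: set[str], chain_id: str) -> str:
    if residue_names & _DNA_RES:
        return "dna"
    if residue_names & _PROTEIN_RES:
        return "protein"
    warnings.warn(
        f"chain {chain_id}: residue names {sorted(residue_names)[:3]} not "
        "recognized; classifying as protein"
    )
    return "protein"


def read_structure(
    source: str | Path | io.StringIO,
    copies: tuple[tuple[str, ...], ...] = (),
) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Hydrogens and waters are dropped; chains are classified protein/DNA from
    residue names; van-der-Waals radii are assigned from :data:`VDW_RADII`
    with a warned fallback for unknown elements.  ``copies`` optionally
    declares asymmetric-copy chain groups (e.g. ``(("A","B"), ("C","D"))``).
    """
    pdb = PDBFile.read(source)
    arr = pdb.get_structure(model=1)

    keep = (~np.isin(arr.res_name, list(_WATER_RES))) & (arr.element != "H")
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ValueError("no heavy non-water atoms in structure")

    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).upper()
        radius = VDW_RADII.get(element)
        if radius is None:
            warnings.warn(
                f"unknown element {element!r}; using fallback radius "
                f"{FALLBACK_RADIUS} A"
            )
            radius = FALLBACK_RADIUS
        atoms.append(
            Atom(
                name=str(arr.atom_name[i]),
                element=element,
                chain_id=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                residue_name=str(arr.res_name[i]),
                coordinates=tuple(float(x) for x in arr.coord[i]),
                vdw_radius=radius,
            )
        )

    chain_res: dict[str, set[str]] = {}
    for a in atoms:
        chain_res.setdefault(a.chain_id, set()).add(a.residue_name)
    chain_kind = {c: _classify_chain(names, c) for c, names in chain_res.items()}
    return StructureModel(atoms=tuple(atoms), chain_kind=chain_kind, copies=copies)


def write_structure(model: StructureModel, path: str | Path | io.StringIO) -> None:
    """Write the model as a standard PDB file (biotite-backed)."""
    n = len(model.atoms)
    arr = struc.AtomArray(n)
    for i, a in enumerate(model.atoms):
        arr.coord[i] = a.coordinates
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_number
        arr.res_name[i] = a.residue_name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.hetero[i] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points on a golden-spiral lattice."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    model: StructureModel,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley.

    For each atom, ``n_points`` lattice points are placed on the sphere of
    radius vdw + probe; the accessible area is the fraction of points not
    engulfed by any neighboring atom's inflated sphere, times the sphere
    area.  Neighbor candidates come from a k-d tree, so cost is near-linear
    in atom count for globular structures.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if not model.atoms:
        raise ValueError("model has no atoms")

    coords = model.coordinates
    radii = model.radii + probe_radius
    n_atoms = len(coords)
    unit = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = radii[i]
        neighbors = tree.query_ball_point(coords[i], ri + max_r)
        neighbors = [j for j in neighbors if j != i]
        pts = coords[i] + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
            if not accessible.any():
                break
        areas[i] = 4.0 * np.pi * ri**2 * accessible.sum() / n_points
    return areas


# ---------------------------------------------------------------------------
# contact area
# ---------------------------------------------------------------------------


def _protein_burial_by_residue(
    model: StructureModel,
    probe_radius: float,
    n_points: int,
) -> dict[tuple[str, int], float]:
    """Buried area per protein residue: SASA(protein alone) - SASA(complex)."""
    is_protein = np.array(
        [model.chain_kind[a.chain_id] == "protein" for a in model.atoms]
    )
    if not is_protein.any():
        raise ValueError("model contains no protein chain")
    sasa_complex = sasa(model, probe_radius, n_points)
    protein_only = model.subset(is_protein)
    sasa_alone = sasa(protein_only, probe_radius, n_points)

    burial: dict[tuple[str, int], float] = {}
    complex_protein_areas = sasa_complex[is_protein]
    for atom, a_alone, a_cplx in zip(
        protein_only.atoms, sasa_alone, complex_protein_areas
    ):
        # numerical floor: identical lattices make alone >= complex exactly,
        # clip guards against any future point-set change
        burial[atom.residue_id] = burial.get(atom.residue_id, 0.0) + max(
            a_alone - a_cplx, 0.0
        )
    return burial


def contact_area(
    model: StructureModel,
    elements: list[ElementDefinition] | tuple[ElementDefinition, ...] = (),
    probe_radius: float = PROBE_RADIUS,
    n_points: int = 960,
) -> ContactAreaReport:
    """Per-element DNA-contact area, averaged across asymmetric copies.

    Each copy (a chain-id group) is treated as an independent complex: the
    burial of every protein residue is the SASA it loses when the copy's DNA
    is included.  Element totals sum their residues' burial; the per-residue
    figure divides by the residue count found in the range.  The total
    interface area sums burial over all protein residues of the copy.
    Multi-copy models report copy-wise averages.
    """
    per_copy_elements: list[dict[str, tuple[float, int]]] = []
    per_copy_total: list[float] = []

    for group in model.copy_groups():
        in_copy = np.array([a.chain_id in group for a in model.atoms])
        submodel = model.subset(in_copy)
        burial = _protein_burial_by_residue(submodel, probe_radius, n_points)
        per_copy_total.append(sum(burial.values()))

        elem_acc: dict[str, tuple[float, int]] = {}
        for elem in elements:
            if elem.chain_id not in group:
                continue
            residues = sorted(
                {
                    rid
                    for rid in burial
                    if rid[0] == elem.chain_id and elem.start <= rid[1] <= elem.end
                }
            )
            if not residues:
                raise ValueError(
                    f"element {elem.name}: no residues in "
                    f"{elem.chain_id}:{elem.start}-{elem.end}"
                )
            total = sum(burial[rid] for rid in residues)
            elem_acc[elem.name] = (total, len(residues))
        per_copy_elements.append(elem_acc)

    names = sorted({n for acc in per_copy_elements for n in acc})
    per_element: dict[str, tuple[float, int, float]] = {}
    for name in names:
        hits = [acc[name] for acc in per_copy_elements if name in acc]
        mean_total = float(np.mean([t for t, _ in hits]))
        count = hits[0][1]
        per_element[name] = (mean_total, count, mean_total / count)

    return ContactAreaReport(
        per_element=per_element,
        interface_area_total=float(np.mean(per_copy_total)),
    )


def read_elements_yaml(path: str | Path) -> list[ElementDefinition]:
    """Element config: YAML mapping name -> {chain, start, end}."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    out = []
    for name, spec in data.items():
        out.append(
            ElementDefinition(
                name=str(name),
                chain_id=str(spec["chain"]),
                start=int(spec["start"]),
                end=int(spec["end"]),
            )
        )
    return out
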