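"""Structure mapping and interface burial.

Projects per-residue scalars (rate-class ordinals, difference categories)
onto PDB structures via the temperature-factor column, and computes
solvent-accessible surface areas (Shrake-Rupley sphere sampling on heavy
atoms with a packaged element-radius table), buried surface areas between
chain groups, and the apolar fraction of an interface.

Buried-area convention: per-residue burial is SASA(own group alone) minus
SASA(in complex); the reported interface total is the sum over both sides
(document-consistent with per-interface BSA reports).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "StructureModel",
    "InterfaceReport",
    "read_structure",
    "write_annotated",
    "sasa",
    "buried_area",
    "apolar_fraction",
    "color_script",
]

B_SENTINEL = -1.0  # B-factor written for residues absent from a scalar map


def _load_radii() -> dict[str, float]:
    src = resources.files("hdxpipe.data").joinpath("element_radii.csv")
    with src.open() as fh:
        return {row["element"]: float(row["radius_A"]) for row in csv.DictReader(fh)}


_RADII = _load_radii()


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray
    radius: float
    chain: str
    res_seq: int  # author numbering
    res_name: str


@dataclass
class StructureModel:
    """Flat atom list grouped by (chain, residue) for surface work."""

    atoms: list[Atom]
    source: str = ""

    def __post_init__(self) -> None:
        if self.atoms and not all(np.isfinite(a.xyz).all() for a in self.atoms):
            raise ValueError("non-finite coordinates")
        if any(a.radius <= 0 for a in self.atoms):
            raise ValueError("all atoms need positive radii")

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain, None)
        return list(seen)

    def subset(self, chains: list[str]) -> "StructureModel":
        keep = set(chains)
        return StructureModel([a for a in self.atoms if a.chain in keep], self.source)

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms])

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.upper()
    return el if el else atom.name[0].upper()


def read_structure(
    pdb_file: str,
    keep_waters: bool = False,
    keep_hetero: bool = False,
    keep_hydrogens: bool = False,
) -> StructureModel:
    """Read a PDB file (first model) into a :class:`StructureModel`.

    Waters and other heteroatoms are stripped by default, as are hydrogens
    (crystal structures generally lack them and the radii convention is
    heavy-atom)."""
    st = gemmi.read_structure(str(pdb_file))
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.is_water() and not keep_waters:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_standard = info is not None and info.is_amino_acid()
            if not is_standard and not keep_hetero and not res.is_water():
                continue
            for atom in res:
                el = _element_of(atom)
                if el == "H" and not keep_hydrogens:
                    continue
                atoms.append(
                    Atom(
                        name=atom.name,
                        element=el,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        radius=_RADII.get(el, _RADII["DEFAULT"]),
                        chain=chain.name,
                        res_seq=res.seqid.num,
                        res_name=res.name,
                    )
                )
    if not atoms:
        raise ValueError(f"no atoms read from {pdb_file}")
    return StructureModel(atoms, source=str(pdb_file))


def write_annotated(
    pdb_file: str,
    scalar: dict[tuple[str, int], float],
    out_pdb: str,
    clip: tuple[float, float] = (0.0, 99.99),
) -> None:
    """Write ``scalar`` (keyed by (chain, author residue number)) into the
    B-factor column; unmapped residues get the sentinel -1.00.

    Raises if any scalar key has no matching residue, listing the unmatched
    keys."""
    st = gemmi.read_structure(str(pdb_file))
    present: set[tuple[str, int]] = set()
    for model in st:
        for chain in model:
            for res in chain:
                present.add((chain.name, res.seqid.num))
    missing = sorted(set(scalar) - present)
    if missing:
        raise ValueError(f"scalar keys not found in structure: {missing}")
    lo, hi = clip
    for model in st:
        for chain in model:
            for res in chain:
                val = scalar.get((chain.name, res.seqid.num))
                b = B_SENTINEL if val is None else float(min(max(val, lo), hi))
                for atom in res:
                    atom.b_iso = b
    st.write_pdb(str(out_pdb))


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    model: StructureModel,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
) -> tuple[np.ndarray, dict[tuple[str, int], float]]:
    """Shrake-Rupley solvent-accessible surface area.

    Returns (per-atom areas, per-residue totals), both in Å².  Each atom's
    accessible sphere (radius + probe) is sampled with ``sphere_points``
    quasi-uniform points; a point is buried if inside any neighbor's
    expanded sphere.
    """
    if not model.atoms:
        raise ValueError("structure has no atoms")
    xyz = model.coords()
    rad = model.radii() + probe_radius
    sphere = _fibonacci_sphere(sphere_points)
    tree = cKDTree(xyz)
    max_r = rad.max()
    per_atom = np.zeros(len(model.atoms))
    for i, (c, r) in enumerate(zip(xyz, rad)):
        pts = c + r * sphere
        neighbors = [j for j in tree.query_ball_point(c, r + max_r) if j != i]
        exposed = np.ones(sphere_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - xyz[j]) ** 2).sum(axis=1)
            exposed &= d2 > rad[j] ** 2
        per_atom[i] = 4.0 * np.pi * r * r * exposed.sum() / sphere_points
    per_res: dict[tuple[str, int], float] = {}
    for a, area in zip(model.atoms, per_atom):
        key = (a.chain, a.res_seq)
        per_res[key] = per_res.get(key, 0.0) + float(area)
    return per_atom, per_res


@dataclass
class InterfaceReport:
    group1: tuple[str, ...]
    group2: tuple[str, ...]
    per_residue: dict[tuple[str, int], float]  # buried area, both sides
    per_atom_buried: list[tuple[str, float]]  # (element, buried area)
    total: float

    def __post_init__(self) -> None:
        if any(v < -1e-6 for v in self.per_residue.values()):
            raise ValueError("negative per-residue buried area")


def buried_area(
    model: StructureModel,
    group1: list[str],
    group2: list[str],
    subset: list[tuple[str, int]] | None = None,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
) -> InterfaceReport:
    """Buried surface area between two chain groups.

    Per residue: SASA computed on its own group alone minus SASA in the
    two-group complex (negative numerical noise floored at 0).  ``subset``
    restricts the total to the listed (chain, residue) keys (e.g. the
    recognition residues); the default total sums both sides of the
    interface.
    """
    g1, g2 = set(group1), set(group2)
    if not g1 or not g2 or (g1 & g2):
        raise ValueError("chain groups must be nonempty and disjoint")
    both = model.subset(sorted(g1 | g2))
    alone1 = model.subset(sorted(g1))
    alone2 = model.subset(sorted(g2))
    if subset is not None:
        outside = [k for k in subset if k[0] not in (g1 | g2)]
        if outside:
            raise ValueError(f"subset residues outside the groups: {outside}")

    atoms_c, res_c = sasa(both, probe_radius, sphere_points)
    atoms_1, _ = sasa(alone1, probe_radius, sphere_points)
    atoms_2, _ = sasa(alone2, probe_radius, sphere_points)

    # align per-atom arrays: subset preserves atom order
    idx1 = [i for i, a in enumerate(both.atoms) if a.chain in g1]
    idx2 = [i for i, a in enumerate(both.atoms) if a.chain in g2]
    buried_atoms = np.zeros(len(both.atoms))
    buried_atoms[idx1] = atoms_1 - atoms_c[idx1]
    buried_atoms[idx2] = atoms_2 - atoms_c[idx2]
    buried_atoms = np.maximum(buried_atoms, 0.0)

    per_res: dict[tuple[str, int], float] = {}
    per_atom_el: list[tuple[str, float]] = []
    for a, area in zip(both.atoms, buried_atoms):
        key = (a.chain, a.res_seq)
        per_res[key] = per_res.get(key, 0.0) + float(area)
        per_atom_el.append((a.element, float(area)))
    keys = subset if subset is not None else list(per_res)
    total = float(sum(per_res.get(k, 0.0) for k in keys))
    return InterfaceReport(
        group1=tuple(sorted(g1)),
        group2=tuple(sorted(g2)),
        per_residue=per_res,
        per_atom_buried=per_atom_el,
        total=total,
    )


def apolar_fraction(report: InterfaceReport) -> float:
    """Fraction of the buried interface area contributed by apolar atoms
    (carbon and sulfur under the heavy-atom element convention)."""
    total = sum(a for _, a in report.per_atom_buried)
    if total <= 0:
        return 0.0
    apolar = sum(a for el, a in report.per_atom_buried if el in ("C", "S"))
    return apolar / total


def color_script(
    scalar: dict[tuple[str, int], float], palette: dict[float, str] | None = None
) -> str:
    """Generic text color script (chain, residue, value[, color]) for
    external viewers."""
    lines = ["# chain\tresidue\tvalue\tcolor"]
    for (chain, res), val in sorted(scalar.items()):
        color = ""
        if palette:
            color = palette.get(val, "")
        lines.append(f"{chain}\t{res}\t{val:g}\t{color}")
    return "\n".join(lines) + "\n"
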