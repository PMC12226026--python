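"""Structure parsing: protein/ligand files to element- and affiliation-labeled point clouds.

Proteins are read with gemmi (PDB or mmCIF); ligands with RDKit (SDF, MOL2) or,
for ligands embedded in a PDB file, by residue-name/chain selection from the
HETATM records. Only heavy atoms survive parsing: the featurization is defined
on C/N/O/S protein atoms and a drug-like ligand element set, and hydrogens are
never part of it. Alternate locations are collapsed to the highest-occupancy
conformer (ties resolved toward altloc 'A'); waters are always excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .config import LIGAND_ELEMENTS, PROTEIN_ELEMENTS, DEFAULT_CLASH_FLOOR

__all__ = [
    "Atom",
    "ComplexStructure",
    "ElementPairSubset",
    "LabeledPointCloud",
    "ValidationReport",
    "StructureParseError",
    "EmptySideError",
    "default_subsets",
    "load_complex",
    "extract_point_cloud",
    "validate_complex",
]

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


class StructureParseError(ValueError):
    """A structure file could not be read or contains no usable records."""


class EmptySideError(StructureParseError):
    """Parsing succeeded but the protein or ligand side has zero heavy atoms."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: stable id, element symbol, Cartesian coordinates in Å."""

    id: str
    element: str
    coords: tuple[float, float, float]
    affiliation: str  # "protein" | "ligand"

    def __post_init__(self) -> None:
        if self.affiliation not in ("protein", "ligand"):
            raise ValueError(f"bad affiliation {self.affiliation!r}")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.id}")
        if self.element == "H":
            raise ValueError("hydrogens are excluded at parse time")


@dataclass
class ComplexStructure:
    """A protein-ligand complex as two lists of labeled heavy atoms."""

    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.protein_atoms] + [a.id for a in self.ligand_atoms]
        if len(ids) != len(set(ids)):
            raise ValueError("atom ids must be unique across the complex")
        for a in self.protein_atoms:
            if a.affiliation != "protein":
                raise ValueError(f"atom {a.id} in protein list has {a.affiliation}")
        for a in self.ligand_atoms:
            if a.affiliation != "ligand":
                raise ValueError(f"atom {a.id} in ligand list has {a.affiliation}")

    @property
    def n_protein(self) -> int:
        return len(self.protein_atoms)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_atoms)

    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms], dtype=float).reshape(-1, 3)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms], dtype=float).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ComplexStructure":
        """Apply a rigid motion x -> R x + t to every atom (testing aid)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)

        def move(a: Atom) -> Atom:
            new = R @ np.asarray(a.coords) + t
            return Atom(a.id, a.element, tuple(float(v) for v in new), a.affiliation)

        return ComplexStructure(
            [move(a) for a in self.protein_atoms],
            [move(a) for a in self.ligand_atoms],
            dict(self.source),
        )


@dataclass(frozen=True)
class ElementPairSubset:
    """One (protein element, ligand element) channel of the featurization."""

    protein_element: str
    ligand_element: str

    def __str__(self) -> str:
        return f"{self.protein_element}-{self.ligand_element}"


def default_subsets(
    protein_elements: Sequence[str] = PROTEIN_ELEMENTS,
    ligand_elements: Sequence[str] = LIGAND_ELEMENTS,
) -> list[ElementPairSubset]:
    """The 36 default element-pair channels: {C,N,O,S} x {C,N,O,S,P,F,Cl,Br,I}."""
    return [ElementPairSubset(p, l) for p, l in product(protein_elements, ligand_elements)]


@dataclass
class LabeledPointCloud:
    """Points of one element-pair channel, keyed by originating atom id."""

    protein_points: list[tuple[str, tuple[float, float, float]]]
    ligand_points: list[tuple[str, tuple[float, float, float]]]
    subset: ElementPairSubset

    @property
    def n_protein(self) -> int:
        return len(self.protein_points)

    @property
    def n_ligand(self) -> int:
        return len(self.ligand_points)


@dataclass
class ValidationReport:
    counts: dict  # (affiliation, element) -> int
    min_distance: float  # Å; inf if < 2 atoms
    bounding_box: tuple[float, float, float]  # extent per axis, Å
    clash_floor: float
    has_clash: bool


# ---------------------------------------------------------------------------
# parsing


def _resolve_altlocs(records: list[dict]) -> list[dict]:
    """Collapse altloc copies of the same atom: keep highest occupancy, ties -> 'A'."""
    by_key: dict[tuple, list[dict]] = {}
    order: list[tuple] = []
    for rec in records:
        key = (rec["chain"], rec["resseq"], rec["resname"], rec["name"])
        if key not in by_key:
            by_key[key] = []
            order.append(key)
        by_key[key].append(rec)
    out = []
    for key in order:
        group = by_key[key]
        # max occupancy wins; among equals the lexicographically smallest altloc
        best = min(group, key=lambda r: (-r["occ"], r["altloc"] or "A"))
        out.append(best)
    return out


def _gemmi_records(path: Path) -> list[dict]:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    records = []
    for chain in model:
        for residue in chain:
            for atom in residue:
                el = atom.element.name
                if el in ("H", "D"):
                    continue
                records.append(
                    {
                        "chain": chain.name,
                        "resseq": residue.seqid.num,
                        "resname": residue.name,
                        "name": atom.name,
                        "altloc": atom.altloc,
                        "occ": atom.occ,
                        "element": el,
                        "coords": (atom.pos.x, atom.pos.y, atom.pos.z),
                        "het": residue.het_flag == "H",
                    }
                )
    return records


def _records_to_atoms(records: Iterable[dict], affiliation: str) -> list[Atom]:
    atoms = []
    for rec in records:
        aid = f"{rec['chain']}/{rec['resname']}{rec['resseq']}/{rec['name']}"
        atoms.append(Atom(aid, rec["element"], tuple(rec["coords"]), affiliation))
    return atoms


def _protein_from_file(path: Path, chains: Sequence[str] | None = None) -> list[Atom]:
    records = _gemmi_records(path)
    keep = [
        r
        for r in records
        if r["resname"] not in WATER_NAMES
        and not r["het"]  # polymer (ATOM) records only
        and (chains is None or r["chain"] in chains)
    ]
    return _records_to_atoms(_resolve_altlocs(keep), "protein")


def _ligand_from_pdb(path: Path, resname: str, chain: str | None) -> list[Atom]:
    records = _gemmi_records(path)
    keep = [
        r
        for r in records
        if r["resname"] == resname and (chain is None or r["chain"] == chain)
    ]
    atoms = _records_to_atoms(_resolve_altlocs(keep), "ligand")
    # disambiguate from protein ids drawn from the same file
    return [Atom("LIG:" + a.id, a.element, a.coords, a.affiliation) for a in atoms]


def _ligand_from_rdkit(path: Path) -> list[Atom]:
    from rdkit import Chem

    suffix = path.suffix.lower()
    if suffix == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        mol = next(iter(supplier), None)
    elif suffix == ".mol2":
        mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    else:
        raise StructureParseError(f"unsupported ligand format: {path}")
    if mol is None:
        raise StructureParseError(f"cannot parse ligand file {path}")
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        el = at.GetSymbol()
        if el == "H":
            continue
        pos = conf.GetAtomPosition(i)
        atoms.append(Atom(f"LIG:{i}:{el}", el, (pos.x, pos.y, pos.z), "ligand"))
    return atoms


def load_complex(
    protein_path: str | Path,
    ligand_path: str | Path | None = None,
    *,
    ligand_resname: str | None = None,
    ligand_chain: str | None = None,
    protein_chains: Sequence[str] | None = None,
) -> ComplexStructure:
    """Load a protein-ligand complex from structure files.

    The protein comes from a PDB or mmCIF file (polymer ATOM records, heavy
    atoms only). The ligand comes either from a separate SDF/MOL2/PDB file via
    ``ligand_path`` or from the protein file's HETATM records via
    ``ligand_resname`` (never inferred silently).

    Raises
    ------
    StructureParseError
        Unreadable file, or (``EmptySideError``) zero heavy atoms on a side.
    """
    protein_path = Path(protein_path)
    if not protein_path.exists():
        raise StructureParseError(f"no such file: {protein_path}")
    protein_atoms = _protein_from_file(protein_path, protein_chains)

    if ligand_path is not None:
        ligand_path = Path(ligand_path)
        if not ligand_path.exists():
            raise StructureParseError(f"no such file: {ligand_path}")
        if ligand_path.suffix.lower() in (".sdf", ".mol2"):
            ligand_atoms = _ligand_from_rdkit(ligand_path)
        else:
            if ligand_resname is None:
                raise StructureParseError(
                    "a PDB ligand requires an explicit ligand_resname"
                )
            ligand_atoms = _ligand_from_pdb(ligand_path, ligand_resname, ligand_chain)
        lig_src = str(ligand_path)
    elif ligand_resname is not None:
        ligand_atoms = _ligand_from_pdb(protein_path, ligand_resname, ligand_chain)
        lig_src = f"{protein_path}::{ligand_resname}"
    else:
        raise StructureParseError("no ligand source given")

    if not protein_atoms:
        raise EmptySideError(f"{protein_path}: zero protein heavy atoms")
    if not ligand_atoms:
        raise EmptySideError(f"{lig_src}: zero ligand heavy atoms")

    return ComplexStructure(
        protein_atoms,
        ligand_atoms,
        source={"protein": str(protein_path), "ligand": lig_src},
    )


def extract_point_cloud(cs: ComplexStructure, subset: ElementPairSubset) -> LabeledPointCloud:
    """Select the atoms of one element-pair channel, in file order."""
    return LabeledPointCloud(
        [(a.id, a.coords) for a in cs.protein_atoms if a.element == subset.protein_element],
        [(a.id, a.coords) for a in cs.ligand_atoms if a.element == subset.ligand_element],
        subset,
    )


def validate_complex(
    cs: ComplexStructure, clash_floor: float = DEFAULT_CLASH_FLOOR
) -> ValidationReport:
    """Report-only sanity checks: counts, minimum distance, extent, clashes."""
    counts: dict = {}
    for a in cs.protein_atoms + cs.ligand_atoms:
        key = (a.affiliation, a.element)
        counts[key] = counts.get(key, 0) + 1

    all_coords = np.vstack(
        [c for c in (cs.protein_coords(), cs.ligand_coords()) if c.size]
    )
    if all_coords.shape[0] >= 2:
        min_dist = float(pdist(all_coords).min())
    else:
        min_dist = float("inf")
    extent = tuple(
        float(v) for v in (all_coords.max(axis=0) - all_coords.min(axis=0))
    ) if all_coords.size else (0.0, 0.0, 0.0)

    has_clash = min_dist < clash_floor
    if has_clash:
        warnings.warn(
            f"minimum interatomic distance {min_dist:.3f} Å below clash floor "
            f"{clash_floor} Å",
            stacklevel=2,
        )
    return ValidationReport(counts, min_dist, extent, clash_floor, has_clash)
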