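"""Synthetic inputs for every pipeline stage.

Analytic fixtures (pair, square, generic K(2,2)) have persistence known in
closed form and carry their expected critical values in ``source`` for direct
assertion. Random complexes emulate the geometry the featurization cares
about — heavy-atom point sets with a minimum interatomic separation and a
ligand-sized cluster inside a protein-sized box — not chemistry: there are no
bonds, residues, or physically realistic conformations. Shell complexes give
a separable binder/decoy benchmark: binders place a protein shell in contact
range (4–10 Å) of the ligand, decoys push it beyond 12 Å, so contact-scale
IPC bins separate the classes. Training tables plant a tree-structured
response on uniform features so boosting-recovery tests have known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .models import TrainingTable
from .structures import Atom, ComplexStructure

__all__ = [
    "GenerationError",
    "PlantedResponse",
    "make_pair",
    "make_square",
    "make_k22_generic",
    "make_random_complex",
    "make_shell_complex",
    "make_screening_set",
    "make_training_table",
    "write_fixture_files",
]

PROTEIN_ELEMENT_FREQS = {"C": 0.60, "N": 0.16, "O": 0.20, "S": 0.04}
LIGAND_ELEMENT_FREQS = {
    "C": 0.60, "N": 0.15, "O": 0.15, "S": 0.04, "P": 0.02,
    "F": 0.01, "Cl": 0.01, "Br": 0.01, "I": 0.01,
}


class GenerationError(RuntimeError):
    """Rejection sampling could not satisfy the packing constraints."""


def _atoms(coords, elements, affiliation, prefix) -> list[Atom]:
    return [
        Atom(f"{prefix}{i}", el, tuple(float(v) for v in xyz), affiliation)
        for i, (xyz, el) in enumerate(zip(coords, elements))
    ]


def make_pair(d: float, elements: tuple[str, str] = ("C", "C")) -> ComplexStructure:
    """One protein atom at the origin, one ligand atom at (d, 0, 0).

    Expected persistence: deaths0 = {d}, births1 = {} (a single merge, no cycle).
    """
    if d <= 0:
        raise ValueError("d must be positive")
    return ComplexStructure(
        _atoms([(0.0, 0.0, 0.0)], [elements[0]], "protein", "P"),
        _atoms([(d, 0.0, 0.0)], [elements[1]], "ligand", "L"),
        source={"kind": "pair", "expected_deaths0": [d], "expected_births1": []},
    )


def make_square(scale: float, elements: tuple[str, str] = ("C", "C")) -> ComplexStructure:
    """Alternating square of side ``scale``: all four cross distances equal.

    Protein at (0,0,0) and (s,s,0); ligand at (s,0,0) and (0,s,0). Expected
    persistence: deaths0 = {s, s, s}, births1 = {s} — the degenerate 4-cycle.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    s = float(scale)
    return ComplexStructure(
        _atoms([(0.0, 0.0, 0.0), (s, s, 0.0)], [elements[0]] * 2, "protein", "P"),
        _atoms([(s, 0.0, 0.0), (0.0, s, 0.0)], [elements[1]] * 2, "ligand", "L"),
        source={"kind": "square", "expected_deaths0": [s, s, s], "expected_births1": [s]},
    )


def make_k22_generic(elements: tuple[str, str] = ("C", "C")) -> ComplexStructure:
    """K(2,2) with generic cross distances {1, 2, 3, 4}.

    Laid out so the weight-4 edge closes the cycle: expected deaths0 =
    {1, 2, 3}, births1 = {4} (Kruskal by hand).
    """
    p1 = (0.0, 0.0, 0.0)
    p2 = (3.0, 0.0, 0.0)
    l1 = (1.0, 0.0, 0.0)  # d(p1,l1)=1, d(p2,l1)=2
    x = 1.0 / 3.0
    y = float(np.sqrt(9.0 - x * x))  # d(p1,l2)=3, d(p2,l2)=4
    l2 = (x, y, 0.0)
    return ComplexStructure(
        _atoms([p1, p2], [elements[0]] * 2, "protein", "P"),
        _atoms([l1, l2], [elements[1]] * 2, "ligand", "L"),
        source={
            "kind": "k22_generic",
            "expected_deaths0": [1.0, 2.0, 3.0],
            "expected_births1": [4.0],
        },
    )


def _sample_elements(rng: np.random.Generator, freqs: dict, n: int) -> list[str]:
    symbols = list(freqs)
    p = np.array([freqs[s] for s in symbols], dtype=float)
    p /= p.sum()
    return [symbols[i] for i in rng.choice(len(symbols), size=n, p=p)]


def _pack_points(
    rng: np.random.Generator,
    n: int,
    low: np.ndarray,
    high: np.ndarray,
    existing: np.ndarray,
    min_separation: float,
    retry_cap: int = 20000,
) -> np.ndarray:
    placed = list(existing)
    out = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > retry_cap:
            raise GenerationError(
                f"could not place {n} points with separation {min_separation}"
            )
        cand = rng.uniform(low, high)
        if placed:
            dmin = np.linalg.norm(np.asarray(placed) - cand, axis=1).min()
            if dmin < min_separation:
                continue
        placed.append(cand)
        out.append(cand)
    return np.asarray(out)


def make_random_complex(
    n_protein: int,
    m_ligand: int,
    element_frequencies: tuple[dict, dict] | None = None,
    box: float = 40.0,
    min_separation: float = 1.0,
    seed: int = 0,
) -> ComplexStructure:
    """Uniform random heavy-atom complex with a minimum-separation floor.

    Ligand atoms fall in a 10 Å cube at the box center (a binding-site-sized
    cluster); protein atoms fill the whole box, so ligand-protein distances
    span from contact range to far beyond the truncation cutoff. Deterministic
    per seed.
    """
    if n_protein < 1 or m_ligand < 1:
        raise ValueError("need at least one atom per side")
    pf, lf = element_frequencies or (PROTEIN_ELEMENT_FREQS, LIGAND_ELEMENT_FREQS)
    rng = np.random.default_rng(seed)
    center = box / 2.0
    lig_half = min(5.0, box / 4.0)
    lig_low = np.full(3, center - lig_half)
    lig_high = np.full(3, center + lig_half)
    lig_xyz = _pack_points(rng, m_ligand, lig_low, lig_high, np.empty((0, 3)), min_separation)
    pro_xyz = _pack_points(
        rng, n_protein, np.zeros(3), np.full(3, box), lig_xyz, min_separation
    )
    return ComplexStructure(
        _atoms(pro_xyz, _sample_elements(rng, pf, n_protein), "protein", "P"),
        _atoms(lig_xyz, _sample_elements(rng, lf, m_ligand), "ligand", "L"),
        source={"kind": "random_cloud", "seed": seed, "box": box},
    )


def make_shell_complex(
    binder: bool,
    seed: int = 0,
    n_protein: int = 60,
    m_ligand: int = 8,
    min_separation: float = 1.0,
) -> ComplexStructure:
    """Binder/decoy geometry: a protein shell around a central ligand cluster.

    Binders put the shell at contact range (radii 4–10 Å from the center), so
    the carbon-carbon channels accumulate many critical values in the 4–10 Å
    bins; decoys push the shell to 12–20 Å, emptying those bins. Element mix
    follows the default frequency tables.
    """
    rng = np.random.default_rng(seed)
    lig_xyz = _pack_points(
        rng, m_ligand, np.full(3, -1.5), np.full(3, 1.5), np.empty((0, 3)), min_separation
    )
    r_lo, r_hi = (4.0, 10.0) if binder else (12.0, 20.0)
    placed = list(lig_xyz)
    pro = []
    tries = 0
    while len(pro) < n_protein:
        tries += 1
        if tries > 20000:
            raise GenerationError("shell packing failed")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cand = direction * rng.uniform(r_lo, r_hi)
        if np.linalg.norm(np.asarray(placed) - cand, axis=1).min() < min_separation:
            continue
        placed.append(cand)
        pro.append(cand)
    return ComplexStructure(
        _atoms(np.asarray(pro), _sample_elements(rng, PROTEIN_ELEMENT_FREQS, n_protein), "protein", "P"),
        _atoms(lig_xyz, _sample_elements(rng, LIGAND_ELEMENT_FREQS, m_ligand), "ligand", "L"),
        source={"kind": "shell_complex", "binder": binder, "seed": seed},
    )


def make_screening_set(
    n: int, binder_fraction: float = 0.5, seed: int = 0
) -> tuple[list[ComplexStructure], np.ndarray]:
    """n shell complexes with binary labels (1 = binder)."""
    rng = np.random.default_rng(seed)
    labels = (rng.uniform(size=n) < binder_fraction).astype(int)
    complexes = [
        make_shell_complex(bool(lbl), seed=int(rng.integers(2**31)))
        for lbl in labels
    ]
    return complexes, labels


@dataclass
class PlantedResponse:
    """Piecewise-constant ground truth: y = sum_j amp_j * 1[x_fj > thr_j] + noise."""

    features: list[str]
    thresholds: list[float]
    amplitudes: list[float]
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not len(self.features) == len(self.thresholds) == len(self.amplitudes):
            raise ValueError("features/thresholds/amplitudes must align")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def evaluate(self, X: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
        idx = [list(feature_names).index(f) for f in self.features]
        y = np.zeros(X.shape[0])
        for j, thr, amp in zip(idx, self.thresholds, self.amplitudes):
            y += amp * (X[:, j] > thr)
        return y


def make_training_table(
    n_rows: int,
    response: PlantedResponse,
    feature_names: Sequence[str],
    seed: int = 0,
) -> TrainingTable:
    """Uniform-[0,1] features with a planted tree-structured label."""
    missing = set(response.features) - set(feature_names)
    if missing:
        raise ValueError(f"planted features not in universe: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n_rows, len(feature_names)))
    y = response.evaluate(X, feature_names)
    if response.noise_sd > 0:
        y = y + rng.normal(scale=response.noise_sd, size=n_rows)
    ids = [f"row{i}" for i in range(n_rows)]
    return TrainingTable(ids, X, y, list(feature_names))


# ---------------------------------------------------------------------------
# file emission


def _pdb_lines(atoms: list[Atom]) -> list[str]:
    lines = []
    for i, a in enumerate(atoms, start=1):
        name = a.element.rjust(2).ljust(4)
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:>5} {name}ALA A{i:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{a.element.rjust(2)}"
        )
    lines.append("END")
    return lines


def _sdf_text(atoms: list[Atom]) -> str:
    lines = ["fixture", "  persfp".ljust(20) + "3D", ""]
    lines.append(f"{len(atoms):>3}  0  0  0  0  0  0  0  0  0999 V2000")
    for a in atoms:
        x, y, z = a.coords
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {a.element:<3}0  0  0  0  0  0  0  0  0  0  0  0"
        )
    lines.append("M  END")
    lines.append("$$$$")
    return "\n".join(lines) + "\n"


def write_fixture_files(
    cs: ComplexStructure, directory: str | Path, stem: str = "fixture"
) -> tuple[Path, Path]:
    """Emit a minimal PDB (protein) and SDF (ligand) that reload to ``cs``.

    Coordinates round-trip to PDB precision (1e-3 Å).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pdb_path = directory / f"{stem}_protein.pdb"
    sdf_path = directory / f"{stem}_ligand.sdf"
    pdb_path.write_text("\n".join(_pdb_lines(cs.protein_atoms)) + "\n")
    sdf_path.write_text(_sdf_text(cs.ligand_atoms))
    return pdb_path, sdf_path
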