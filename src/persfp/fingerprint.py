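"""The 10-component persistence fingerprint, its truncated approximation, and
per-atom attribution.

Each fingerprint component is one IPC density: the Gaussian-smoothed count of
critical values of one (protein element, ligand element, dimension) channel
falling in one 0.5 Å bin. Six components are 1D (cycle births — bipartite
matching distances), four are 0D (component-merge distances). Because the
Gaussian weight decays super-exponentially, protein atoms far from every
ligand atom contribute almost nothing to any component with a bounded bin:
dropping protein atoms beyond a cutoff radius (default 15 Å, versus a maximum
bin edge of 10.5 Å) perturbs each component by less than the Gaussian tail
mass beyond (cutoff − bin_hi), i.e. by a provably tiny epsilon. The test suite
verifies this bound empirically rather than assuming it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .config import DEFAULT_CUTOFF_RADIUS, DEFAULT_SIGMA
from .ipc import build_ipc, gaussian_mass, ipc_density
from .persistence import persistence
from .structures import (
    Atom,
    ComplexStructure,
    ElementPairSubset,
    extract_point_cloud,
)

__all__ = [
    "FeatureSpec",
    "PersistenceFingerprint",
    "ApproxConfig",
    "AtomAttribution",
    "default_feature_specs",
    "compute_fingerprint",
    "truncate_complex",
    "compute_fingerprint_approx",
    "attribute",
    "write_attribution_pdb",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One fingerprint component: channel plus the bin it integrates over."""

    protein_element: str
    ligand_element: str
    dimension: int
    bin_lo: float
    bin_hi: float

    def __post_init__(self) -> None:
        if self.dimension not in (0, 1):
            raise ValueError("dimension must be 0 or 1")
        if not self.bin_lo < self.bin_hi:
            raise ValueError("need bin_lo < bin_hi")

    @property
    def name(self) -> str:
        return (
            f"{self.protein_element}_{self.ligand_element}_{self.dimension}"
            f"_{self.bin_lo:g}_{self.bin_hi:g}"
        )

    @property
    def subset(self) -> ElementPairSubset:
        return ElementPairSubset(self.protein_element, self.ligand_element)


def default_feature_specs() -> list[FeatureSpec]:
    """The 10 selected components, in canonical order.

    Six 1D carbon/nitrogen channels (bipartite-matching scales 4–10.5 Å) and
    four 0D channels pairing protein carbon with ligand N/O/S.
    """
    rows = [
        ("C", "C", 1, 9.5, 10.0),
        ("C", "C", 1, 9.0, 9.5),
        ("C", "C", 1, 7.0, 7.5),
        ("C", "C", 1, 4.0, 4.5),
        ("N", "C", 1, 10.0, 10.5),
        ("N", "C", 1, 8.0, 8.5),
        ("C", "N", 0, 7.5, 8.0),
        ("C", "N", 0, 8.5, 9.0),
        ("C", "O", 0, 6.5, 7.0),
        ("C", "S", 0, 5.0, 5.5),
    ]
    return [FeatureSpec(*r) for r in rows]


@dataclass
class PersistenceFingerprint:
    values: np.ndarray
    specs: list[FeatureSpec]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specs),):
            raise ValueError("values length must match specs length")

    def __len__(self) -> int:
        return len(self.specs)

    def names(self) -> list[str]:
        return [s.name for s in self.specs]


@dataclass
class ApproxConfig:
    """Truncation settings: per-component error bound and cutoff radius."""

    epsilon: float = 1e-6
    cutoff_radius: float = DEFAULT_CUTOFF_RADIUS

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must be in (0, 1)")
        if self.cutoff_radius <= 0:
            raise ValueError("cutoff_radius must be positive")

    def validate_against(self, specs: list[FeatureSpec]) -> None:
        max_hi = max(s.bin_hi for s in specs)
        if self.cutoff_radius < max_hi:
            raise ValueError(
                f"cutoff_radius {self.cutoff_radius} Å below the largest bin "
                f"edge {max_hi} Å; truncation would bite into the features"
            )


def _channel_cvs(cs: ComplexStructure, specs: list[FeatureSpec], sigma: float):
    """Persistence once per distinct element-pair channel used by the specs."""
    cache = {}
    for spec in specs:
        key = (spec.protein_element, spec.ligand_element)
        if key not in cache:
            cloud = extract_point_cloud(cs, spec.subset)
            cache[key] = persistence(cloud)
    return cache


def compute_fingerprint(
    cs: ComplexStructure,
    specs: list[FeatureSpec] | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> PersistenceFingerprint:
    """Exact fingerprint: one IPC density per feature spec.

    Empty protein or ligand side yields the zero vector with a warning —
    screening pipelines must keep moving, not crash.
    """
    specs = specs if specs is not None else default_feature_specs()
    if cs.n_protein == 0 or cs.n_ligand == 0:
        warnings.warn("empty protein or ligand side: zero fingerprint", stacklevel=2)
        return PersistenceFingerprint(np.zeros(len(specs)), list(specs))
    cvs = _channel_cvs(cs, specs, sigma)
    values = np.empty(len(specs))
    for i, spec in enumerate(specs):
        cv = cvs[(spec.protein_element, spec.ligand_element)]
        ipc = build_ipc(cv, spec.dimension, spec.subset, sigma)
        values[i] = ipc_density(ipc, spec.bin_lo, spec.bin_hi)
    return PersistenceFingerprint(values, list(specs))


def truncate_complex(cs: ComplexStructure, cutoff_radius: float) -> ComplexStructure:
    """Drop protein atoms farther than ``cutoff_radius`` from every ligand atom."""
    if cutoff_radius <= 0:
        raise ValueError("cutoff_radius must be positive")
    if cs.n_protein == 0 or cs.n_ligand == 0:
        return ComplexStructure(
            list(cs.protein_atoms), list(cs.ligand_atoms), dict(cs.source)
        )
    dmin = cdist(cs.protein_coords(), cs.ligand_coords()).min(axis=1)
    kept = [a for a, d in zip(cs.protein_atoms, dmin) if d <= cutoff_radius]
    return ComplexStructure(kept, list(cs.ligand_atoms), dict(cs.source))


def compute_fingerprint_approx(
    cs: ComplexStructure,
    specs: list[FeatureSpec] | None = None,
    cfg: ApproxConfig | None = None,
    sigma: float = DEFAULT_SIGMA,
) -> PersistenceFingerprint:
    """Fingerprint of the radius-truncated complex.

    With the default 15 Å cutoff and 10.5 Å maximum bin edge, every critical
    value perturbed by dropping a far atom lies beyond the cutoff, i.e. more
    than 45 standard deviations past the bin at sigma = 0.1 Å; each component
    moves by far less than any practical epsilon.
    """
    specs = specs if specs is not None else default_feature_specs()
    cfg = cfg or ApproxConfig()
    cfg.validate_against(specs)
    return compute_fingerprint(truncate_complex(cs, cfg.cutoff_radius), specs, sigma)


# ---------------------------------------------------------------------------
# attribution


@dataclass
class AtomAttribution:
    """Per-atom shares of one fingerprint component.

    Every critical value contributing bin mass w has a realizing cross edge;
    w/2 is assigned to each endpoint, so per-feature shares sum exactly to the
    component value. Under exact ties the identity of the realizing edge is an
    arbitrary processing-order artifact, so the mass is symmetrized: it is
    split evenly over all cross edges of the channel whose weight equals the
    critical value. For generic (untied) weights this reduces to the plain
    critical-edge rule; on the degenerate square it gives the four atoms equal
    shares, as symmetry demands.
    """

    feature_index: int
    spec: FeatureSpec
    feature_value: float
    contributions: dict[str, float] = field(default_factory=dict)

    def total(self) -> float:
        return float(sum(self.contributions.values()))

    def to_rows(self) -> list[tuple[str, int, float]]:
        return [
            (aid, self.feature_index, val)
            for aid, val in sorted(self.contributions.items())
        ]


def attribute(
    cs: ComplexStructure,
    specs: list[FeatureSpec] | None = None,
    feature_index: int = 0,
    sigma: float = DEFAULT_SIGMA,
) -> AtomAttribution:
    """Split one component's value over the atoms whose holes carry it."""
    specs = specs if specs is not None else default_feature_specs()
    if not 0 <= feature_index < len(specs):
        raise IndexError(f"feature_index {feature_index} out of range")
    spec = specs[feature_index]
    cloud = extract_point_cloud(cs, spec.subset)
    cv = persistence(cloud)
    if spec.dimension == 0:
        values, edges = cv.deaths0, cv.death_edges
    else:
        values, edges = cv.births1, cv.birth_edges

    # all channel edges grouped by weight, for tie symmetrization
    from .persistence import cross_edges as _cross_edges

    all_edges = _cross_edges(cloud)
    weights = np.array([e.weight for e in all_edges])

    contributions: dict[str, float] = {}
    total = 0.0
    tie_tol = 1e-9
    for value, (pid, lid) in zip(values, edges):
        w = gaussian_mass(float(value), spec.bin_lo, spec.bin_hi, sigma)
        total += w
        tied = [
            all_edges[i]
            for i in np.nonzero(np.abs(weights - float(value)) <= tie_tol)[0]
        ]
        if len(tied) <= 1:
            tied = [None]  # fall back to the recorded critical edge
        share = w / (2.0 * len(tied))
        for e in tied:
            a, b = (pid, lid) if e is None else (e.protein_id, e.ligand_id)
            contributions[a] = contributions.get(a, 0.0) + share
            contributions[b] = contributions.get(b, 0.0) + share
    return AtomAttribution(feature_index, spec, total, contributions)


def write_attribution_pdb(
    cs: ComplexStructure, attribution: AtomAttribution, path: str | Path
) -> Path:
    """Write the complex as PDB with per-atom contributions in the B-factor
    column (scaled to the 0–99.99 print range), for molecular-viewer coloring."""
    path = Path(path)
    contrib = attribution.contributions
    vmax = max(contrib.values(), default=0.0)
    scale = 99.99 / vmax if vmax > 0 else 0.0
    lines = []
    serial = 1
    for atoms, record in ((cs.protein_atoms, "ATOM  "), (cs.ligand_atoms, "HETATM")):
        resname = "ALA" if record == "ATOM  " else "LIG"
        chain = "A" if record == "ATOM  " else "L"
        for a in atoms:
            b = contrib.get(a.id, 0.0) * scale
            name = a.element.rjust(2) + "  "
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:>5} {name[:4]} {resname} {chain}{serial % 9999:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
                f"{a.element.rjust(2)}"
            )
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
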