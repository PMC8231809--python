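"""Structure parsing, solvent accessibility and residue classification.

The tertiary-structure predictors used downstream are all derived from one
crystal structure of the TP53 DNA-binding + oligomerization domain tetramer
bound to its response element.  This module turns such a structure (PDB or
mmCIF) into per-residue quantities:

* solvent-accessible surface area (SASA) by Shrake-Rupley point sampling,
* Buried/Surface calls against a SASA cutoff, aggregated over the four
  monomers ("buried in any chain" rule),
* interface residues between two chain subsets (monomer-monomer or
  protein-DNA) from the isolated-minus-complex SASA difference,
* helix/sheet/loop classes from the structure file's annotation records.

Author residue numbering is taken at face value: for TP53 constructs the
crystallized regions 94-292 and 324-355 map identically onto the canonical
393-residue sequence, so ``canonical_map`` is the identity there and ``None``
elsewhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

import gemmi

__all__ = [
    "AtomRecord",
    "StructureModel",
    "ResidueSASA",
    "BurialCall",
    "InterfaceCall",
    "SSRange",
    "VDW_RADII",
    "CANONICAL_RANGES",
    "load_structure",
    "structure_from_atoms",
    "compute_sasa",
    "atom_sasa",
    "per_chain_residue_sasa",
    "classify_burial",
    "burial_from_structure",
    "find_interface_residues",
    "assign_secondary_structure",
    "sphere_points",
]

# Element van-der-Waals radii (Angstrom).  Values follow the common Bondi-style
# table used by molecular-viewer surface scripts; overridable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

#: Regions of the crystallized TP53 construct that coincide with canonical
#: full-length numbering (DNA-binding domain and oligomerization domain).
CANONICAL_RANGES: tuple[tuple[int, int], ...] = ((94, 292), (324, 355))

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
NUCLEIC_RESIDUES = {"DA", "DC", "DG", "DT", "DU", "DI", "A", "C", "G", "U", "I"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom after alternate-conformer resolution."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"non-positive vdW radius for atom {self}")


@dataclass(frozen=True)
class SSRange:
    """Secondary-structure annotation range (author numbering, inclusive)."""

    kind: str  # "helix" or "sheet"
    chain_id: str
    start: int
    end: int


@dataclass
class StructureModel:
    """Atoms plus chain classes and the canonical-position map."""

    atoms: list[AtomRecord]
    chain_class: dict[str, str]  # chain_id -> "protein" | "nucleic"
    canonical_map: dict[tuple[str, int], int | None]
    ss_ranges: list[SSRange] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        for a in self.atoms:
            if a.chain_id not in self.chain_class:
                raise ValueError(f"chain {a.chain_id!r} missing from chain_class")
        for pos in self.canonical_map.values():
            if pos is not None and not 1 <= pos <= 393:
                raise ValueError(f"canonical position {pos} outside 1..393")

    # -- array views -------------------------------------------------------
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)

    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def protein_chains(self) -> list[str]:
        return [c for c in self.chain_ids() if self.chain_class[c] == "protein"]

    def nucleic_chains(self) -> list[str]:
        return [c for c in self.chain_ids() if self.chain_class[c] == "nucleic"]

    def subset(self, chains: Iterable[str]) -> "StructureModel":
        chains = set(chains)
        unknown = chains - set(self.chain_class)
        if unknown:
            raise ValueError(f"unknown chains: {sorted(unknown)}")
        atoms = [a for a in self.atoms if a.chain_id in chains]
        return StructureModel(
            atoms=atoms,
            chain_class={c: k for c, k in self.chain_class.items() if c in chains},
            canonical_map={k: v for k, v in self.canonical_map.items() if k[0] in chains},
            ss_ranges=[r for r in self.ss_ranges if r.chain_id in chains],
            source=self.source,
        )

    def residues(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, residue_number) pairs."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_number), None)
        return list(seen)

    def canonical_positions(self) -> set[int]:
        """Canonical positions represented in at least one protein chain.

        This set is the background universe for the enrichment statistics.
        """
        out = set()
        for (chain, resnum) in self.residues():
            if self.chain_class[chain] != "protein":
                continue
            pos = self.canonical_map.get((chain, resnum))
            if pos is not None:
                out.add(pos)
        return out


@dataclass(frozen=True)
class ResidueSASA:
    chain_id: str
    residue_number: int
    sasa: float  # Angstrom^2

    def __post_init__(self) -> None:
        if self.sasa < -1e-9:
            raise ValueError("negative SASA")


@dataclass(frozen=True)
class BurialCall:
    canonical_position: int
    status: str  # "Buried" | "Surface" | "unknown"
    per_chain_sasa: Mapping[str, float]


@dataclass(frozen=True)
class InterfaceCall:
    chain_id: str
    residue_number: int
    partner_class: str  # "protein_monomer" | "DNA"
    buried_area: float


def _canonical_position(resnum: int) -> int | None:
    for lo, hi in CANONICAL_RANGES:
        if lo <= resnum <= hi:
            return resnum
    return None


def load_structure(
    path: str,
    radii: Mapping[str, float] | None = None,
    canonical_ranges: Sequence[tuple[int, int]] | None = None,
) -> StructureModel:
    """Parse a PDB/mmCIF file into a :class:`StructureModel`.

    Waters and non-polymer heteroatoms are dropped, the highest-occupancy
    alternate conformer is kept, chains are labelled protein/nucleic from
    their residue vocabulary, and helix/sheet annotation records are carried
    along for secondary-structure assignment.

    Parameters
    ----------
    path:
        PDB or mmCIF file.
    radii:
        Element -> vdW radius table; defaults to :data:`VDW_RADII`.  An atom
        whose element is missing from the table raises ``KeyError`` naming it.
    canonical_ranges:
        Author-numbering ranges that coincide with canonical TP53 numbering;
        default :data:`CANONICAL_RANGES`.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    ranges = tuple(canonical_ranges) if canonical_ranges is not None else CANONICAL_RANGES

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    model = st[0]

    atoms: list[AtomRecord] = []
    chain_class: dict[str, str] = {}
    canonical_map: dict[tuple[str, int], int | None] = {}

    for chain in model:
        n_prot = sum(1 for res in chain if res.name in PROTEIN_RESIDUES)
        n_nuc = sum(1 for res in chain if res.name in NUCLEIC_RESIDUES)
        if n_prot == 0 and n_nuc == 0:
            continue  # ligand-only or water chain
        kind = "protein" if n_prot >= n_nuc else "nucleic"
        chain_class[chain.name] = kind
        vocab = PROTEIN_RESIDUES if kind == "protein" else NUCLEIC_RESIDUES
        for res in chain:
            if res.name not in vocab:
                continue  # water / ligand / modified hetero outside vocabulary
            # highest-occupancy alternate conformer per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                el = atom.element.name.upper()
                if el not in radii:
                    raise KeyError(
                        f"no vdW radius for element {el!r} "
                        f"(atom {chain.name}/{res.seqid.num}/{name})"
                    )
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name,
                        atom_name=name,
                        element=el,
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        vdw_radius=radii[el],
                    )
                )
            if kind == "protein":
                pos = None
                for lo, hi in ranges:
                    if lo <= res.seqid.num <= hi:
                        pos = res.seqid.num
                        break
                canonical_map[(chain.name, res.seqid.num)] = pos

    if not atoms:
        raise ValueError(f"no polymer atoms found in {path}")

    ss_ranges: list[SSRange] = []
    for helix in st.helices:
        ss_ranges.append(
            SSRange("helix", helix.start.chain_name, helix.start.res_id.seqid.num,
                    helix.end.res_id.seqid.num)
        )
    for sheet in st.sheets:
        for strand in sheet.strands:
            ss_ranges.append(
                SSRange("sheet", strand.start.chain_name, strand.start.res_id.seqid.num,
                        strand.end.res_id.seqid.num)
            )

    return StructureModel(atoms, chain_class, canonical_map, ss_ranges, source=str(path))


def structure_from_atoms(
    atoms: Sequence[AtomRecord],
    chain_class: Mapping[str, str] | None = None,
    canonical_ranges: Sequence[tuple[int, int]] | None = None,
) -> StructureModel:
    """Build a StructureModel from in-memory atoms (synthetic fixtures)."""
    if chain_class is None:
        chain_class = {}
        for a in atoms:
            chain_class.setdefault(
                a.chain_id,
                "nucleic" if a.residue_name in NUCLEIC_RESIDUES else "protein",
            )
    ranges = tuple(canonical_ranges) if canonical_ranges is not None else CANONICAL_RANGES
    canonical_map: dict[tuple[str, int], int | None] = {}
    for a in atoms:
        if chain_class[a.chain_id] != "protein":
            continue
        pos = None
        for lo, hi in ranges:
            if lo <= a.residue_number <= hi:
                pos = a.residue_number
                break
        canonical_map[(a.chain_id, a.residue_number)] = pos
    return StructureModel(list(atoms), dict(chain_class), canonical_map)


def sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (deterministic golden-section spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def atom_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible area by Shrake-Rupley point sampling.

    Each atom's expanded sphere (vdW + probe) is covered with a fixed
    quasi-uniform point set; the accessible fraction is the share of points
    outside every neighbour's expanded sphere.  Deterministic given the
    point count.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 100:
        raise ValueError("n_sphere_points must be >= 100")
    if not structure.atoms:
        raise ValueError("empty structure")

    coords = structure.coordinates()
    radii = structure.radii() + probe_radius
    pts = sphere_points(n_sphere_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(coords))
    for i in range(len(coords)):
        ri = radii[i]
        surface = coords[i] + ri * pts
        neighbours = tree.query_ball_point(coords[i], ri + max_r)
        accessible = np.ones(len(surface), dtype=bool)
        for j in neighbours:
            if j == i:
                continue
            rj = radii[j]
            d = surface - coords[j]
            accessible &= np.einsum("ij,ij->i", d, d) >= rj * rj
            if not accessible.any():
                break
        areas[i] = 4.0 * math.pi * ri * ri * accessible.mean()
    return areas


def compute_sasa(
    structure: StructureModel,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> list[ResidueSASA]:
    """Residue SASA = sum of its atoms' accessible areas."""
    areas = atom_sasa(structure, probe_radius, n_sphere_points)
    per_res: dict[tuple[str, int], float] = {}
    for a, area in zip(structure.atoms, areas):
        key = (a.chain_id, a.residue_number)
        per_res[key] = per_res.get(key, 0.0) + float(area)
    return [ResidueSASA(c, n, s) for (c, n), s in per_res.items()]


def per_chain_residue_sasa(
    structure: StructureModel,
    chains: Iterable[str] | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> dict[str, dict[int, float]]:
    """SASA of each protein chain computed in isolation.

    Burial is judged monomer by monomer (a residue may be buried in one
    subunit and exposed in another), so each chain is extracted and its SASA
    computed alone.
    """
    if chains is None:
        chains = structure.protein_chains()
    out: dict[str, dict[int, float]] = {}
    for chain in chains:
        sub = structure.subset([chain])
        out[chain] = {
            rs.residue_number: rs.sasa for rs in compute_sasa(sub, probe_radius, n_sphere_points)
        }
    return out


def classify_burial(
    structure: StructureModel,
    residue_sasa: Mapping[str, Mapping[int, float]],
    cutoff: float = 11.0,
    query_positions: Iterable[int] | None = None,
) -> list[BurialCall]:
    """Buried/Surface calls per canonical position.

    A position is Buried when its SASA is strictly below ``cutoff`` in at
    least one chain; positions absent from the structure are ``unknown``.

    Parameters
    ----------
    residue_sasa:
        chain -> residue_number -> SASA, as from :func:`per_chain_residue_sasa`.
    cutoff:
        SASA threshold in Angstrom^2 (default 11, the value that marks roughly
        the most buried 30% of residues in the TP53 tetramer structure).
    query_positions:
        Optional extra canonical positions to report; those without any
        structure coverage come back ``unknown``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    by_pos: dict[int, dict[str, float]] = {}
    for chain, res_map in residue_sasa.items():
        for resnum, sasa in res_map.items():
            pos = structure.canonical_map.get((chain, resnum))
            if pos is None:
                continue
            by_pos.setdefault(pos, {})[chain] = float(sasa)

    positions = set(by_pos)
    if query_positions is not None:
        positions |= set(query_positions)

    calls = []
    for pos in sorted(positions):
        per_chain = by_pos.get(pos, {})
        if not per_chain:
            calls.append(BurialCall(pos, "unknown", {}))
            continue
        status = "Buried" if min(per_chain.values()) < cutoff else "Surface"
        calls.append(BurialCall(pos, status, per_chain))
    return calls


def burial_from_structure(
    structure: StructureModel,
    cutoff: float = 11.0,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    query_positions: Iterable[int] | None = None,
) -> list[BurialCall]:
    """Convenience: per-chain SASA then burial classification."""
    sasa = per_chain_residue_sasa(structure, None, probe_radius, n_sphere_points)
    return classify_burial(structure, sasa, cutoff, query_positions)


def find_interface_residues(
    structure: StructureModel,
    subset_x: Iterable[str],
    subset_y: Iterable[str],
    cutoff: float = 1.0,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> list[InterfaceCall]:
    """Residues whose surface is occluded by the partner subset.

    ``buried_area`` of a residue in subset X is its SASA with X alone minus
    its SASA in the X+Y complex; residues with buried_area strictly above
    ``cutoff`` (default 1.0 A^2) are reported, for both subsets.
    """
    xs, ys = set(subset_x), set(subset_y)
    if xs & ys:
        raise ValueError(f"overlapping chain subsets: {sorted(xs & ys)}")

    complex_model = structure.subset(xs | ys)
    complex_sasa = {
        (rs.chain_id, rs.residue_number): rs.sasa
        for rs in compute_sasa(complex_model, probe_radius, n_sphere_points)
    }

    def partner_class(partner_chains: set[str]) -> str:
        kinds = {structure.chain_class[c] for c in partner_chains}
        return "DNA" if kinds == {"nucleic"} else "protein_monomer"

    calls: list[InterfaceCall] = []
    for own, partner in ((xs, ys), (ys, xs)):
        own_model = structure.subset(own)
        pclass = partner_class(partner)
        for rs in compute_sasa(own_model, probe_radius, n_sphere_points):
            buried = rs.sasa - complex_sasa[(rs.chain_id, rs.residue_number)]
            if buried > cutoff:
                calls.append(InterfaceCall(rs.chain_id, rs.residue_number, pclass, buried))
    return calls


def assign_secondary_structure(
    structure: StructureModel,
    annotations: Sequence[SSRange] | None = None,
) -> dict[tuple[str, int], str]:
    """helix/sheet/loop class for every protein residue.

    Ranges come from the structure file's helix/sheet records (or are passed
    explicitly).  Unannotated residues are loop; where helix and sheet ranges
    overlap, helix wins (documented tie-break).  Ranges that reach outside the
    structure are clipped with a warning.
    """
    if annotations is None:
        annotations = structure.ss_ranges
    protein_res = {
        (c, n) for (c, n) in structure.residues() if structure.chain_class[c] == "protein"
    }
    assign = {key: "loop" for key in protein_res}
    # apply sheets first so that helix overwrites on overlap
    for kind in ("sheet", "helix"):
        for rng in annotations:
            if rng.kind != kind:
                continue
            hits = [
                (rng.chain_id, n) for n in range(rng.start, rng.end + 1)
                if (rng.chain_id, n) in protein_res
            ]
            if len(hits) < rng.end - rng.start + 1:
                warnings.warn(
                    f"{kind} range {rng.chain_id}:{rng.start}-{rng.end} "
                    "references residues missing from the structure; clipped",
                    stacklevel=2,
                )
            for key in hits:
                assign[key] = kind if kind != "sheet" else "sheet"
    return {k: ("helix" if v == "helix" else "sheet" if v == "sheet" else "loop")
            for k, v in assign.items()}
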