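"""Per-chlorophyll geometry: ring mapping, plane fitting, stacking, ligands.

A chlorophyll's chlorin macrocycle is a near-planar ring of 20 carbons and 4
nitrogens around a central Mg. The operations here answer the geometric
questions a pigment-site comparison needs:

* which file atom is which IUPAC macrocycle position (``map_ring_atoms``),
* the least-squares ring plane and its out-of-plane rms (``fit_plane``),
* how parallel two rings are (``interplane_angle``),
* where the C2 substituent sits — the methyl of Chl a vs the formyl of
  Chl f (``locate_c2_substituent``),
* which chlorophylls form stacked multimers, the candidate low-energy
  "red" antenna sites (``find_stacking_multimers``),
* what coordinates the central Mg axially (``detect_axial_ligands``), and
* whether a formyl oxygen modelled at C2 would clash sterically
  (``c2_crowding``).

Atom names follow the chemical-component-dictionary chlorophyll convention
(C1A..C4D, CHA..CHD, NA..ND, MG); the name table mapping them to IUPAC
positions C1..C20/N21..N24 is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .structure_io import (
    Atom,
    DEFAULT_LIGAND_TABLE,
    LigandCodeTable,
    Residue,
    ResidueKey,
    StructureModel,
    site_label,
)

__all__ = [
    "ChlorinRing",
    "RingPlane",
    "StackingPair",
    "AxialLigand",
    "CrowdingReport",
    "ChlorinError",
    "DEFAULT_ATOM_NAME_TABLE",
    "MACROCYCLE_CYCLE",
    "map_ring_atoms",
    "fit_plane",
    "interplane_angle",
    "locate_c2_substituent",
    "find_stacking_multimers",
    "detect_axial_ligands",
    "c2_crowding",
]


class ChlorinError(ValueError):
    """Raised when a residue cannot be interpreted as a chlorin ring."""


# IUPAC position -> CCD-convention atom name. The CCD ring letters are offset
# by one from the IUPAC rings (CCD ring A carries the C17 propionate and C18
# methyl of IUPAC ring D), hence C1 = C1B etc.
DEFAULT_ATOM_NAME_TABLE: dict[str, str] = {
    "C1": "C1B", "C2": "C2B", "C3": "C3B", "C4": "C4B", "C5": "CHC",
    "C6": "C1C", "C7": "C2C", "C8": "C3C", "C9": "C4C", "C10": "CHD",
    "C11": "C1D", "C12": "C2D", "C13": "C3D", "C14": "C4D", "C15": "CHA",
    "C16": "C1A", "C17": "C2A", "C18": "C3A", "C19": "C4A", "C20": "CHB",
    "N21": "NB", "N22": "NC", "N23": "ND", "N24": "NA",
    "MG": "MG",
}

#: IUPAC carbon positions in macrocycle bond order (C20 closes back to C1).
MACROCYCLE_CYCLE: tuple[str, ...] = tuple(f"C{i}" for i in range(1, 21))

#: All 24 macrocycle heavy-atom positions (no Mg).
MACROCYCLE_POSITIONS: tuple[str, ...] = MACROCYCLE_CYCLE + ("N21", "N22", "N23", "N24")

AXIAL_CLASSES = (
    "HIS_SIDECHAIN",
    "WATER",
    "BACKBONE_CARBONYL",
    "SIDECHAIN_O",
    "LIPID_HEADGROUP",
    "OTHER",
)

_LIPID_RESIDUES = frozenset({"LHG", "LMG", "LMT"})
_SIDECHAIN_O = frozenset(
    {
        ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
        ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
        ("ASN", "OD1"), ("GLN", "OE1"),
    }
)


@dataclass
class ChlorinRing:
    """A chlorophyll macrocycle mapped to IUPAC positions."""

    residue_key: ResidueKey
    residue_name: str
    atoms: dict[str, Atom]  # IUPAC position -> atom (MG included)
    residue: Residue = field(repr=False)
    unmapped: tuple[str, ...] = ()

    @property
    def mg(self) -> Atom:
        return self.atoms["MG"]

    def macrocycle_atoms(self) -> list[Atom]:
        return [self.atoms[p] for p in MACROCYCLE_POSITIONS if p in self.atoms]

    def macrocycle_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.macrocycle_atoms()])

    @property
    def label(self) -> str:
        return site_label(self.residue_key[0], self.residue_key[1])


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane of a chlorin ring."""

    normal: tuple[float, float, float]
    centroid: tuple[float, float, float]
    rms: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ChlorinError("plane normal must be a unit vector")
        if self.rms < 0:
            raise ChlorinError("rms deviation must be non-negative")


@dataclass(frozen=True)
class StackingPair:
    """Two chlorophylls close enough (Mg-Mg) to count as stacked."""

    site_a: ResidueKey
    site_b: ResidueKey
    mg_distance: float
    interplane_angle_deg: float
    min_ring_distance: float

    def __contains__(self, key: ResidueKey) -> bool:
        return key in (self.site_a, self.site_b)


@dataclass(frozen=True)
class AxialLigand:
    """An atom within coordination range of a chlorophyll's central Mg."""

    pigment: ResidueKey
    atom: Atom
    distance: float
    ligand_class: str


@dataclass(frozen=True)
class CrowdingReport:
    """Heavy atoms near a hypothetical C2 formyl-oxygen position."""

    pigment: ResidueKey
    probe_point: tuple[float, float, float]
    contacts: tuple[Atom, ...]
    distances: tuple[float, ...]

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def min_distance(self) -> Optional[float]:
        return min(self.distances) if self.distances else None


# -- ring mapping -----------------------------------------------------------


def map_ring_atoms(
    residue: Residue,
    atom_name_table: Mapping[str, str] = DEFAULT_ATOM_NAME_TABLE,
) -> ChlorinRing:
    """Map a chlorophyll residue's atoms to IUPAC macrocycle positions.

    Requires the central Mg and at least 20 of the 24 macrocycle heavy
    atoms; consecutive mapped ring carbons must be 1.2-1.7 Angstrom apart
    (a plausibility check that the name table fits the residue).
    """
    atoms: dict[str, Atom] = {}
    unmapped: list[str] = []
    for pos in ("MG",) + MACROCYCLE_POSITIONS:
        name = atom_name_table.get(pos)
        atom = residue.atom(name) if name else None
        if atom is None:
            unmapped.append(pos)
        else:
            atoms[pos] = atom
    if "MG" in unmapped:
        raise ChlorinError(f"central MG missing in residue {residue.key}")
    missing_ring = [p for p in unmapped if p != "MG"]
    if len(missing_ring) > 4:
        raise ChlorinError(
            f"{len(missing_ring)} macrocycle atoms unmapped in {residue.key}: "
            f"{missing_ring}"
        )
    if missing_ring:
        warnings.warn(
            f"residue {residue.key}: macrocycle positions {missing_ring} "
            "unmapped; ring accepted",
            UserWarning,
            stacklevel=2,
        )
    cycle = MACROCYCLE_CYCLE
    for i, pos in enumerate(cycle):
        nxt = cycle[(i + 1) % len(cycle)]
        if pos in atoms and nxt in atoms:
            d = float(np.linalg.norm(atoms[pos].xyz - atoms[nxt].xyz))
            if not 1.2 <= d <= 1.7:
                raise ChlorinError(
                    f"ring bond {pos}-{nxt} = {d:.2f} A outside [1.2, 1.7] in "
                    f"{residue.key}; wrong atom-name table?"
                )
    return ChlorinRing(
        residue_key=residue.key,
        residue_name=residue.name,
        atoms=atoms,
        residue=residue,
        unmapped=tuple(missing_ring),
    )


# -- plane geometry ---------------------------------------------------------


def fit_plane(ring: ChlorinRing | np.ndarray) -> RingPlane:
    """Least-squares plane through the mapped macrocycle heavy atoms.

    The normal is the smallest-variance direction of the centred
    coordinates (last right singular vector); its sign is arbitrary and all
    angle consumers fold to [0, 90] degrees.
    """
    coords = ring if isinstance(ring, np.ndarray) else ring.macrocycle_coords()
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ChlorinError("plane fit needs at least 3 atoms")
    centroid = coords.mean(axis=0)
    centred = coords - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return RingPlane(tuple(normal), tuple(centroid), rms)


def interplane_angle(a: RingPlane, b: RingPlane) -> float:
    """Angle between two ring planes, folded into [0, 90] degrees."""
    cosang = abs(float(np.dot(a.normal, b.normal)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# -- substituents -----------------------------------------------------------


def locate_c2_substituent(ring: ChlorinRing, bond_cutoff: float = 1.8) -> Atom:
    """The unique non-ring heavy atom covalently attached to ring carbon C2.

    For Chl a this is the methyl carbon; for Chl f it is the formyl carbon —
    the single-atom difference the whole chlorophyll-f site scan revolves
    around. Raises if nothing (or more than one atom) lies within the
    covalent cutoff.
    """
    if "C2" not in ring.atoms:
        raise ChlorinError(f"C2 not mapped for {ring.residue_key}")
    c2 = ring.atoms["C2"].xyz
    ring_names = {a.atom_name for a in ring.macrocycle_atoms()} | {ring.mg.atom_name}
    candidates = [
        a
        for a in ring.residue.heavy_atoms()
        if a.atom_name not in ring_names
        and float(np.linalg.norm(a.xyz - c2)) <= bond_cutoff
    ]
    if not candidates:
        raise ChlorinError(f"no substituent within {bond_cutoff} A of C2 in {ring.residue_key}")
    if len(candidates) > 1:
        names = [a.atom_name for a in candidates]
        raise ChlorinError(f"ambiguous C2 substituent in {ring.residue_key}: {names}")
    return candidates[0]


# -- stacking ---------------------------------------------------------------


def _rings_of(model: StructureModel, table: LigandCodeTable,
              atom_name_table: Mapping[str, str]) -> list[ChlorinRing]:
    rings = []
    for res in model.chlorophylls(table):
        try:
            rings.append(map_ring_atoms(res, atom_name_table))
        except ChlorinError:
            continue  # incomplete chlorophyll (e.g. down-sampled): skip
    return rings


def find_stacking_multimers(
    model: StructureModel,
    mg_cutoff: float = 9.0,
    ligand_table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
    atom_name_table: Mapping[str, str] = DEFAULT_ATOM_NAME_TABLE,
) -> tuple[list[StackingPair], list[frozenset[ResidueKey]]]:
    """Stacked chlorophyll pairs and their connected components.

    A pair is emitted iff the Mg-Mg distance is <= ``mg_cutoff`` (default 9
    Angstrom — a package choice; no field-standard number exists). Components
    are the transitive closure of pairs, so an isolated chlorophyll is a
    "monomer", a linked pair a "dimer", a chain of three a "trimer", etc.
    Output is independent of pigment enumeration order.
    """
    rings = sorted(_rings_of(model, ligand_table, atom_name_table),
                   key=lambda r: r.residue_key)
    if not rings:
        raise ChlorinError("no chlorophylls with mappable rings in model")
    planes = {r.residue_key: fit_plane(r) for r in rings}
    pairs: list[StackingPair] = []
    parent: dict[ResidueKey, ResidueKey] = {r.residue_key: r.residue_key for r in rings}

    def find(k: ResidueKey) -> ResidueKey:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for i, ra in enumerate(rings):
        for rb in rings[i + 1:]:
            d = float(np.linalg.norm(ra.mg.xyz - rb.mg.xyz))
            if d > mg_cutoff:
                continue
            ca, cb = ra.macrocycle_coords(), rb.macrocycle_coords()
            diff = ca[:, None, :] - cb[None, :, :]
            min_rr = float(np.sqrt((diff ** 2).sum(axis=2).min()))
            ang = interplane_angle(planes[ra.residue_key], planes[rb.residue_key])
            pairs.append(
                StackingPair(ra.residue_key, rb.residue_key, d, ang, min_rr)
            )
            parent[find(ra.residue_key)] = find(rb.residue_key)

    groups: dict[ResidueKey, set[ResidueKey]] = {}
    for r in rings:
        groups.setdefault(find(r.residue_key), set()).add(r.residue_key)
    components = sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda g: sorted(g)[0],
    )
    return pairs, components


# -- axial ligands ----------------------------------------------------------


def _classify_axial(atom: Atom) -> str:
    res, name = atom.residue_name, atom.atom_name
    if res == "HIS" and name in ("ND1", "NE2"):
        return "HIS_SIDECHAIN"
    if res == "HOH":
        return "WATER"
    if name == "O" and res not in _LIPID_RESIDUES:
        return "BACKBONE_CARBONYL"
    if (res, name) in _SIDECHAIN_O:
        return "SIDECHAIN_O"
    if res in _LIPID_RESIDUES:
        return "LIPID_HEADGROUP"
    return "OTHER"


def detect_axial_ligands(
    pigment: Residue,
    model: StructureModel,
    window: tuple[float, float] = (1.9, 3.0),
    ligand_table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
) -> list[AxialLigand]:
    """Non-pigment heavy atoms within Mg-coordination range, by distance.

    The window (default 1.9-3.0 Angstrom) brackets typical Mg-N/Mg-O
    coordination distances. The pigment's own atoms and other chlorophylls'
    atoms are excluded; an empty list is a valid result (five- vs
    six-coordinate Mg).
    """
    mg = pigment.atom("MG")
    if mg is None:
        raise ChlorinError(f"residue {pigment.key} has no MG")
    lo, hi = window
    chl_keys = {r.key for r in model.chlorophylls(ligand_table)}
    out = []
    for res in model:
        if res.key == pigment.key or res.key in chl_keys:
            continue
        for a in res.heavy_atoms():
            d = float(np.linalg.norm(a.xyz - mg.xyz))
            if lo <= d <= hi:
                out.append(AxialLigand(pigment.key, a, d, _classify_axial(a)))
    out.sort(key=lambda lig: lig.distance)
    return out


# -- C2 crowding ------------------------------------------------------------


def formyl_oxygen_probe(ring: ChlorinRing, extension: float = 1.2) -> np.ndarray:
    """Model a formyl-oxygen position beyond the C2 substituent carbon.

    The probe is placed ``extension`` Angstrom past the substituent along the
    C2 -> substituent direction — a linear simplification of the true sp2
    formyl geometry, adequate for a clash screen.
    """
    sub = locate_c2_substituent(ring)
    c2 = ring.atoms["C2"].xyz
    direction = sub.xyz - c2
    direction = direction / np.linalg.norm(direction)
    return sub.xyz + extension * direction


def c2_crowding(
    ring: ChlorinRing,
    model: StructureModel,
    probe_radius: float = 3.0,
    extension: float = 1.2,
) -> CrowdingReport:
    """Heavy atoms (excluding the pigment itself) crowding a modelled formyl.

    Used to argue *against* a chlorophyll-f assignment: if the hypothetical
    formyl oxygen would sit on top of a neighbouring ring or an axial-ligation
    partner, a formyl substituent is sterically implausible there.
    """
    probe = formyl_oxygen_probe(ring, extension)
    contacts: list[tuple[float, Atom]] = []
    for res in model:
        if res.key == ring.residue_key:
            continue
        for a in res.heavy_atoms():
            d = float(np.linalg.norm(a.xyz - probe))
            if d <= probe_radius:
                contacts.append((d, a))
    contacts.sort(key=lambda t: (t[0], t[1].residue_key, t[1].atom_name))
    return CrowdingReport(
        pigment=ring.residue_key,
        probe_point=tuple(probe),
        contacts=tuple(a for _, a in contacts),
        distances=tuple(d for d, _ in contacts),
    )
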