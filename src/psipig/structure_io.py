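"""Coordinate-file I/O and cofactor classification for photosystem structures.

Reading and writing of PDB/mmCIF files is delegated to :mod:`gemmi`; this
module wraps the parsed hierarchy in a light-weight, analysis-oriented
container (:class:`StructureModel`) and classifies heteroatom residues into
pigment types (chlorophylls, carotenoids, quinones, lipids, iron-sulfur
clusters, ...) via a user-extensible ligand-code table.

The census is the entry point for the "how many pigments does this complex
bind" question: a cyanobacterial PSI monomer binds on the order of 90-96
chlorophylls and ~20 carotenoids, and comparing such counts between
structures is the first step of any pigment-site comparison.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "PigmentType",
    "LigandCodeTable",
    "StructureModel",
    "StructureError",
    "UnknownLigandWarning",
    "read_structure",
    "census",
    "census_to_tsv",
    "census_to_json",
    "write_structure",
    "site_label",
    "DEFAULT_LIGAND_TABLE",
    "AMINO_ACIDS",
]


class StructureError(ValueError):
    """Raised for unreadable, empty, or structurally inconsistent input."""


class UnknownLigandWarning(UserWarning):
    """Emitted when a chlorophyll-like residue code is not in the table."""


class PigmentType(Enum):
    CHL_A = "chl_a"
    CHL_A_PRIME = "chl_a_prime"
    CHL_F = "chl_f"
    CHL_B = "chl_b"
    CAROTENOID = "carotenoid"
    PHYLLOQUINONE = "phylloquinone"
    PG_LIPID = "pg_lipid"
    MGDG_LIPID = "mgdg_lipid"
    DETERGENT = "detergent"
    FE4S4 = "fe4s4"
    WATER = "water"
    OTHER = "other"


#: Pigment types that count as chlorophylls in census totals.
CHLOROPHYLL_TYPES = frozenset(
    {PigmentType.CHL_A, PigmentType.CHL_A_PRIME, PigmentType.CHL_F, PigmentType.CHL_B}
)

AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL MSE UNK".split()
)


@dataclass(frozen=True)
class Atom:
    """One atom record (coordinates in Angstrom)."""

    chain_id: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite(self.position)):
            raise StructureError(f"non-finite coordinates for atom {self.atom_name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(
                f"occupancy {self.occupancy} outside [0, 1] for atom {self.atom_name}"
            )

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def residue_key(self) -> "ResidueKey":
        return (self.chain_id, self.residue_number, self.insertion_code)


ResidueKey = tuple[str, int, str]


@dataclass
class Residue:
    """A residue: its key, 3-5 character code, and atom list."""

    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chain_id(self) -> str:
        return self.key[0]

    @property
    def number(self) -> int:
        return self.key[1]

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.atom_name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def is_amino_acid(self) -> bool:
        return self.name in AMINO_ACIDS


@dataclass
class LigandCodeTable:
    """Residue-code -> :class:`PigmentType` lookup, user-extensible.

    Unknown codes map to ``OTHER``; codes that look chlorophyll-like (the
    residue carries a central Mg) raise :class:`UnknownLigandWarning` instead
    of being silently binned, because a missed chlorophyll code corrupts the
    census totals the downstream analyses depend on.
    """

    codes: dict[str, PigmentType] = field(default_factory=dict)

    def classify(self, residue: Residue) -> PigmentType:
        ptype = self.codes.get(residue.name)
        if ptype is not None:
            return ptype
        if residue.atom("MG") is not None:
            warnings.warn(
                f"residue code {residue.name!r} is not in the ligand table but "
                "carries a central Mg (chlorophyll-like); classified as OTHER — "
                "extend the table if this is a chlorophyll variant",
                UnknownLigandWarning,
                stacklevel=2,
            )
        return PigmentType.OTHER

    def with_codes(self, extra: Mapping[str, PigmentType]) -> "LigandCodeTable":
        merged = dict(self.codes)
        merged.update(extra)
        return LigandCodeTable(merged)


DEFAULT_LIGAND_TABLE = LigandCodeTable(
    {
        "CLA": PigmentType.CHL_A,
        "CL0": PigmentType.CHL_A_PRIME,
        "CHL": PigmentType.CHL_B,
        "F6C": PigmentType.CHL_F,
        "BCR": PigmentType.CAROTENOID,
        "ECN": PigmentType.CAROTENOID,
        "PQN": PigmentType.PHYLLOQUINONE,
        "PHQ": PigmentType.PHYLLOQUINONE,
        "LHG": PigmentType.PG_LIPID,
        "LMG": PigmentType.MGDG_LIPID,
        "LMT": PigmentType.DETERGENT,
        "SF4": PigmentType.FE4S4,
        "HOH": PigmentType.WATER,
    }
)


class StructureModel:
    """Atoms grouped by chain and residue, with an optional monomer grouping.

    Residue keys ``(chain_id, residue_number, insertion_code)`` are unique
    within a model; coordinates are Angstrom and residue numbering is taken
    verbatim from the source file.
    """

    def __init__(
        self,
        residues: Iterable[Residue],
        source_format: str = "memory",
        monomers: Optional[Mapping[str, Sequence[str]]] = None,
    ) -> None:
        self._residues: dict[ResidueKey, Residue] = {}
        for res in residues:
            if res.key in self._residues:
                raise StructureError(f"duplicate residue key {res.key}")
            self._residues[res.key] = res
        self.source_format = source_format
        self.monomers = (
            {name: frozenset(chains) for name, chains in monomers.items()}
            if monomers
            else None
        )

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self._residues.values())

    def __getitem__(self, key: ResidueKey) -> Residue:
        return self._residues[key]

    def get(self, key: ResidueKey) -> Optional[Residue]:
        return self._residues.get(key)

    @property
    def residues(self) -> list[Residue]:
        return list(self._residues.values())

    def atoms(self) -> Iterator[Atom]:
        for res in self:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for res in self:
            seen.setdefault(res.chain_id, None)
        return list(seen)

    def select_chains(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = set(chain_ids)
        missing = wanted - set(self.chains())
        if missing:
            raise StructureError(f"chains absent from model: {sorted(missing)}")
        return StructureModel(
            (r for r in self if r.chain_id in wanted), self.source_format
        )

    def pigment_residues(
        self, table: LigandCodeTable = DEFAULT_LIGAND_TABLE
    ) -> list[tuple[Residue, PigmentType]]:
        """All non-amino-acid residues with their classified pigment type."""
        out = []
        for res in self:
            if res.is_amino_acid:
                continue
            out.append((res, table.classify(res)))
        return out

    def chlorophylls(
        self, table: LigandCodeTable = DEFAULT_LIGAND_TABLE
    ) -> list[Residue]:
        return [
            res
            for res, ptype in self.pigment_residues(table)
            if ptype in CHLOROPHYLL_TYPES
        ]


# -- reading ----------------------------------------------------------------


def _resolve_alt_locs(atoms: list[Atom]) -> list[Atom]:
    """Keep the highest-occupancy alternate conformer per atom name.

    Ties break to the alphabetically first alt-loc id so that the census is
    deterministic regardless of file ordering.
    """
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.atom_name not in by_name:
            order.append(a.atom_name)
        by_name.setdefault(a.atom_name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.alt_loc))
        kept.append(replace(best, alt_loc=""))
    return kept


def read_structure(
    path: str | Path,
    format: Optional[str] = None,
    monomers: Optional[Mapping[str, Sequence[str]]] = None,
) -> StructureModel:
    """Read a PDB or mmCIF coordinate file into a :class:`StructureModel`.

    Parameters
    ----------
    path : str or Path
        Coordinate file. The format is inferred from the extension
        (``.pdb``/``.ent`` vs ``.cif``/``.mmcif``) unless given explicitly.
    format : {"pdb", "mmcif"}, optional
    monomers : mapping of name -> chain ids, optional
        Biological-monomer grouping (e.g. ``{"mono1": ["A", "B", ...]}``) for
        multi-copy depositions; the asymmetric unit of a PSI monomer needs
        none.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            format = "pdb"
        elif suffix in (".cif", ".mmcif"):
            format = "mmcif"
        else:
            raise StructureError(f"cannot infer format from extension {suffix!r}")
    if format not in ("pdb", "mmcif"):
        raise StructureError(f"unknown format {format!r}")

    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc

    residues: list[Residue] = []
    if len(st) > 0:
        model = st[0]  # first model only
        for chain in model:
            for res in chain:
                key = (
                    chain.name,
                    res.seqid.num,
                    (res.seqid.icode or " ").strip(),
                )
                atoms = [
                    Atom(
                        chain_id=chain.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or " ").strip(),
                        atom_name=atom.name,
                        element=atom.element.name.upper(),
                        position=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_factor=atom.b_iso,
                        alt_loc=(atom.altloc or "").strip(),
                    )
                    for atom in res
                ]
                residues.append(Residue(key, res.name, _resolve_alt_locs(atoms)))

    model_out = StructureModel(residues, source_format=format, monomers=monomers)
    if model_out.n_atoms == 0:
        raise StructureError(f"zero atoms in {path}")
    return model_out


# -- census -----------------------------------------------------------------


def census(
    model: StructureModel,
    table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
    monomer: Optional[Iterable[str]] = None,
) -> dict[PigmentType, int]:
    """Count cofactor residues per pigment type.

    ``monomer`` restricts the count to a chain subset (raises if any chain is
    absent). Amino-acid residues are never counted. The chlorophyll total of
    a model is the sum of the CHL_A, CHL_A_PRIME, CHL_F and CHL_B entries.
    """
    sub = model.select_chains(monomer) if monomer is not None else model
    counts: Counter[PigmentType] = Counter()
    for _res, ptype in sub.pigment_residues(table):
        counts[ptype] += 1
    return dict(counts)


def chlorophyll_total(counts: Mapping[PigmentType, int]) -> int:
    return sum(counts.get(t, 0) for t in CHLOROPHYLL_TYPES)


def census_to_tsv(counts: Mapping[PigmentType, int]) -> str:
    lines = ["pigment_type\tcount"]
    for ptype in PigmentType:
        if ptype in counts:
            lines.append(f"{ptype.value}\t{counts[ptype]}")
    return "\n".join(lines) + "\n"


def census_to_json(counts: Mapping[PigmentType, int]) -> str:
    return json.dumps(
        {ptype.value: counts[ptype] for ptype in PigmentType if ptype in counts},
        indent=2,
    )


# -- writing ----------------------------------------------------------------


def write_structure(
    model: StructureModel,
    path: str | Path,
    per_residue_scalar: Optional[Mapping[ResidueKey, float]] = None,
) -> None:
    """Write the model as PDB; optionally recolour the B-factor column.

    ``per_residue_scalar`` replaces every atom's B factor by the residue's
    value clamped to [0, 999.99] — the conventional trick for painting a
    per-residue quantity (e.g. a sequence-identity track) onto a structure in
    molecular viewers. Residues missing from the map get sentinel 0.00 and a
    warning.
    """
    st = gemmi.Structure()
    st.name = "psipig"
    gm = gemmi.Model("1")
    missing: list[ResidueKey] = []
    chain_map: dict[str, gemmi.Chain] = {}
    for res in model:
        ch = chain_map.get(res.chain_id)
        if ch is None:
            ch = gemmi.Chain(res.chain_id)
            chain_map[res.chain_id] = ch
        gr = gemmi.Residue()
        gr.name = res.name
        gr.seqid = gemmi.SeqId(res.number, res.key[2] or " ")
        if not res.is_amino_acid:
            gr.het_flag = "H"
        else:
            gr.het_flag = "A"
        if per_residue_scalar is not None:
            if res.key in per_residue_scalar:
                b = float(np.clip(per_residue_scalar[res.key], 0.0, 999.99))
            else:
                b = 0.0
                missing.append(res.key)
        else:
            b = None
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.atom_name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.position)
            ga.occ = a.occupancy
            ga.b_iso = b if b is not None else a.b_factor
            gr.add_atom(ga)
        ch.add_residue(gr)
    for ch in chain_map.values():
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    if missing:
        warnings.warn(
            f"{len(missing)} residues missing from the scalar map; wrote "
            "sentinel B-factor 0.00 for them",
            UserWarning,
            stacklevel=2,
        )
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write {path}: {exc}") from exc


# -- site labels ------------------------------------------------------------


def site_label(chain_id: str, residue_number: int) -> str:
    """Community pigment-site label: chain letter + last two digits.

    E.g. the chlorophyll numbered 1120 on PsaA in the reference cyanobacterial
    PSI structure is site "A20"; residue 1402 gives "A02".
    """
    return f"{chain_id}{residue_number % 100:02d}"
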