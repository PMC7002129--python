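"""Hydrogen-bond-donor scanning around chlorophyll C2 substituents.

Chlorophyll f differs from chlorophyll a only by a formyl group (C=O) in
place of the C2 methyl on the chlorin ring. At the resolution of typical
photosystem maps the extra oxygen is invisible, so candidate Chl f sites are
inferred indirectly: a protein or water hydrogen-bond *donor* poised next to
the C2 substituent can hydrogen-bond to a formyl oxygen and thereby confer
site specificity for Chl f over Chl a. This module enumerates donors,
scans each chlorophyll's C2 environment, and ranks candidate sites by a
transparent additive score combining three evidence channels:

* an H-bond term from the closest in-window donor,
* local sequence (non-)conservation around the site, and
* a structural site-change flag (changed axial ligand, lost/gained
  neighbouring pigment site).

No hydrogen positions are used — coordinate models carry none — so the
criterion is distance-only, over a configurable window (default 2.4-3.5
Angstrom, bracketing observed donor-acceptor distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .chlorin import (
    ChlorinError,
    ChlorinRing,
    DEFAULT_ATOM_NAME_TABLE,
    locate_c2_substituent,
    map_ring_atoms,
)
from .structure_io import (
    Atom,
    DEFAULT_LIGAND_TABLE,
    LigandCodeTable,
    Residue,
    StructureModel,
    site_label,
)

__all__ = [
    "DonorAtom",
    "FormylSiteCandidate",
    "DONOR_TABLE",
    "enumerate_donors",
    "scan_c2_environment",
    "rank_chlf_candidates",
    "candidates_to_tsv",
]

DONOR_CLASSES = (
    "SIDECHAIN_HYDROXYL",
    "SIDECHAIN_AMIDE_N",
    "SIDECHAIN_BASIC_N",
    "HIS_N",
    "BACKBONE_AMIDE_N",
    "WATER_O",
    "OTHER_POLAR",
)

#: (residue_name, atom_name) -> donor class for side-chain/water donors.
DONOR_TABLE: dict[tuple[str, str], str] = {
    ("SER", "OG"): "SIDECHAIN_HYDROXYL",
    ("THR", "OG1"): "SIDECHAIN_HYDROXYL",
    ("TYR", "OH"): "SIDECHAIN_HYDROXYL",
    ("ASN", "ND2"): "SIDECHAIN_AMIDE_N",
    ("GLN", "NE2"): "SIDECHAIN_AMIDE_N",
    ("LYS", "NZ"): "SIDECHAIN_BASIC_N",
    ("ARG", "NE"): "SIDECHAIN_BASIC_N",
    ("ARG", "NH1"): "SIDECHAIN_BASIC_N",
    ("ARG", "NH2"): "SIDECHAIN_BASIC_N",
    ("HIS", "ND1"): "HIS_N",
    ("HIS", "NE2"): "HIS_N",
    ("HOH", "O"): "WATER_O",
}

#: Carbonyl-type oxygens reported as non-donor polar contacts (never scored).
_POLAR_ACCEPTOR_NAMES = frozenset({"O", "OD1", "OD2", "OE1", "OE2", "OBD", "O1D", "O2D"})


@dataclass(frozen=True)
class DonorAtom:
    """A hydrogen-bond donor atom, optionally with a distance to a target."""

    atom: Atom
    donor_class: str
    distance: Optional[float] = None

    @property
    def strong(self) -> bool:
        return self.distance is not None and self.distance <= 3.2


@dataclass
class FormylSiteCandidate:
    """A chlorophyll site scored as a candidate chlorophyll-f location."""

    label: str
    residue_key: tuple
    donors: list[DonorAtom] = field(default_factory=list)
    polar_contacts: list[DonorAtom] = field(default_factory=list)
    local_conservation: Optional[float] = None
    site_change: bool = False
    hbond_term: float = 0.0
    conservation_term: float = 0.0
    change_term: float = 0.0
    score: float = 0.0

    @property
    def min_donor_distance(self) -> Optional[float]:
        return self.donors[0].distance if self.donors else None

    @property
    def n_donors(self) -> int:
        return len(self.donors)


# -- donor enumeration ------------------------------------------------------


def enumerate_donors(model: StructureModel) -> list[DonorAtom]:
    """All hydrogen-bond donor atoms in the model.

    Side-chain donors come from :data:`DONOR_TABLE`; every amino-acid
    backbone nitrogen is a donor as well (the amide N-H).
    """
    donors: list[DonorAtom] = []
    for res in model:
        for a in res.atoms:
            cls = DONOR_TABLE.get((res.name, a.atom_name))
            if cls is None and res.is_amino_acid and a.atom_name == "N":
                cls = "BACKBONE_AMIDE_N"
            if cls is not None:
                donors.append(DonorAtom(a, cls))
    return donors


def donor_counts(donors: Sequence[DonorAtom]) -> dict[str, int]:
    out: dict[str, int] = {}
    for d in donors:
        out[d.donor_class] = out.get(d.donor_class, 0) + 1
    return out


# -- per-site scan ----------------------------------------------------------


def scan_c2_environment(
    pigment: Residue,
    model: StructureModel,
    window: tuple[float, float] = (2.4, 3.5),
    atom_name_table: Mapping[str, str] = DEFAULT_ATOM_NAME_TABLE,
) -> FormylSiteCandidate:
    """Donors near a chlorophyll's C2 substituent (formyl-oxygen proxy).

    The C2 substituent heavy atom stands in for the formyl oxygen of a
    hypothetical Chl f in this site (the real formyl oxygen would sit up to
    ~0.5 Angstrom further out). Donors with proxy distance inside ``window``
    are reported sorted by distance; donors at <= 3.2 Angstrom are flagged
    strong. Carbonyl-type oxygens in the window are listed separately as
    non-donor polar contacts and never enter the score.
    """
    ring = map_ring_atoms(pigment, atom_name_table)
    target = locate_c2_substituent(ring).xyz
    lo, hi = window
    hits: list[DonorAtom] = []
    for d in enumerate_donors(model):
        if d.atom.residue_key == pigment.key:
            continue
        dist = float(np.linalg.norm(d.atom.xyz - target))
        if lo <= dist <= hi:
            hits.append(DonorAtom(d.atom, d.donor_class, dist))
    hits.sort(key=lambda d: (d.distance, d.atom.residue_key, d.atom.atom_name))

    polar: list[DonorAtom] = []
    for res in model:
        if res.key == pigment.key:
            continue
        for a in res.heavy_atoms():
            if a.atom_name in _POLAR_ACCEPTOR_NAMES and a.element == "O":
                dist = float(np.linalg.norm(a.xyz - target))
                if lo <= dist <= hi:
                    polar.append(DonorAtom(a, "OTHER_POLAR", dist))
    polar.sort(key=lambda d: (d.distance, d.atom.residue_key, d.atom.atom_name))

    return FormylSiteCandidate(
        label=site_label(pigment.key[0], pigment.key[1]),
        residue_key=pigment.key,
        donors=hits,
        polar_contacts=polar,
    )


# -- ranking ----------------------------------------------------------------


def hbond_term_from_distance(
    distance: Optional[float],
    full_at: float = 2.6,
    zero_at: float = 3.5,
) -> float:
    """H-bond evidence: 1 at <= ``full_at``, linear decay to 0 at ``zero_at``."""
    if distance is None:
        return 0.0
    if distance <= full_at:
        return 1.0
    if distance >= zero_at:
        return 0.0
    return (zero_at - distance) / (zero_at - full_at)


def rank_chlf_candidates(
    model: StructureModel,
    conservation_track: Optional[Mapping[tuple, float]] = None,
    site_comparison: Optional[Mapping[str, bool]] = None,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    window: tuple[float, float] = (2.4, 3.5),
    ligand_table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
    atom_name_table: Mapping[str, str] = DEFAULT_ATOM_NAME_TABLE,
    local_conservation: Optional[Mapping[str, float]] = None,
) -> list[FormylSiteCandidate]:
    """Score and rank every chlorophyll as a candidate Chl f site.

    score = w1 * hbond_term + w2 * (1 - local_conservation) + w3 * site_change

    Any missing evidence channel contributes 0. ``site_comparison`` maps the
    site label to a boolean "structurally changed" flag (changed axial
    ligand, neighbouring site lost/gained, or absent from the reference).
    ``local_conservation`` maps site labels to identity fractions in [0, 1];
    alternatively ``conservation_track`` keyed by residue key may be given
    and is averaged by the caller beforehand. Ties order alphabetically by
    site label (stable, input-order independent).
    """
    if any(w < 0 for w in weights):
        raise ValueError(f"weights must be non-negative, got {weights}")
    w1, w2, w3 = weights
    candidates: list[FormylSiteCandidate] = []
    for res in model.chlorophylls(ligand_table):
        try:
            cand = scan_c2_environment(res, model, window, atom_name_table)
        except ChlorinError:
            continue  # unmappable ring: not scoreable
        cons = None
        if local_conservation is not None:
            cons = local_conservation.get(cand.label)
        if cons is None and conservation_track is not None:
            cons = conservation_track.get(res.key)
        cand.local_conservation = cons
        cand.site_change = bool(site_comparison.get(cand.label, False)) if site_comparison else False
        cand.hbond_term = hbond_term_from_distance(
            cand.min_donor_distance, full_at=2.6, zero_at=window[1]
        )
        cand.conservation_term = (1.0 - cons) if cons is not None else 0.0
        cand.change_term = 1.0 if cand.site_change else 0.0
        cand.score = w1 * cand.hbond_term + w2 * cand.conservation_term + w3 * cand.change_term
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.score, c.label))
    return candidates


def candidates_to_tsv(candidates: Sequence[FormylSiteCandidate]) -> str:
    lines = ["site\tn_donors\tmin_dist\tconservation\tsite_change\tscore"]
    for c in candidates:
        md = f"{c.min_donor_distance:.3f}" if c.min_donor_distance is not None else "NA"
        cons = f"{c.local_conservation:.3f}" if c.local_conservation is not None else "NA"
        lines.append(
            f"{c.label}\t{c.n_donors}\t{md}\t{cons}\t{int(c.site_change)}\t{c.score:.4f}"
        )
    return "\n".join(lines) + "\n"
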