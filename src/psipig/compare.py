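"""Homologous-structure superposition and pigment-site correspondence.

Workflow: superpose a query photosystem monomer onto a reference using the
Kabsch algorithm on C-alpha atoms of alignment-paired residues (pigments are
never fit targets — their displacements are the measurement), then pair
pigment sites by nearest transformed Mg (or residue centroid for Mg-free
pigments such as carotenoids), classify each site as conserved / lost /
gained, transfer the community site labels from the reference, and tabulate
axial-ligand changes at conserved sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .chlorin import detect_axial_ligands
from .structure_io import (
    CHLOROPHYLL_TYPES,
    DEFAULT_LIGAND_TABLE,
    LigandCodeTable,
    PigmentType,
    Residue,
    ResidueKey,
    StructureModel,
    site_label,
)

__all__ = [
    "ChainPairing",
    "SuperpositionResult",
    "SiteCorrespondence",
    "SuperpositionError",
    "kabsch_superpose",
    "match_pigment_sites",
    "transfer_site_labels",
    "compare_axial_ligands",
    "paired_calpha_coords",
    "correspondences_to_tsv",
]


class SuperpositionError(ValueError):
    pass


@dataclass(frozen=True)
class ChainPairing:
    """Residue-level pairing between a query chain and a reference chain."""

    query_chain: str
    reference_chain: str
    residue_pairs: tuple[tuple[ResidueKey, ResidueKey], ...]

    def __post_init__(self) -> None:
        q_nums = [q[1] for q, _ in self.residue_pairs]
        r_nums = [r[1] for _, r in self.residue_pairs]
        if any(b <= a for a, b in zip(q_nums, q_nums[1:])) or any(
            b <= a for a, b in zip(r_nums, r_nums[1:])
        ):
            raise SuperpositionError("residue pairs must strictly increase in both chains")


@dataclass(frozen=True)
class SuperpositionResult:
    """Rigid transform mapping query coordinates onto the reference frame."""

    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise SuperpositionError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise SuperpositionError("rotation has negative determinant (reflection)")
        if self.rmsd < 0:
            raise SuperpositionError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def to_json(self) -> str:
        return json.dumps(
            {
                "rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "rmsd": self.rmsd,
                "n_atoms": self.n_atoms,
            },
            indent=2,
        )


@dataclass(frozen=True)
class SiteCorrespondence:
    """One pigment site pairing: conserved, lost (ref only) or gained (query only)."""

    query_site: Optional[ResidueKey]
    reference_site: Optional[ResidueKey]
    status: str  # conserved | lost | gained
    mg_displacement: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == "conserved":
            ok = self.query_site is not None and self.reference_site is not None
        elif self.status == "lost":
            ok = self.query_site is None and self.reference_site is not None
        elif self.status == "gained":
            ok = self.query_site is not None and self.reference_site is None
        else:
            ok = False
        if not ok:
            raise SuperpositionError(f"inconsistent correspondence: {self}")


# -- Kabsch -----------------------------------------------------------------


def kabsch_superpose(
    query_coords: np.ndarray, reference_coords: np.ndarray
) -> SuperpositionResult:
    """Least-squares rigid superposition (Kabsch, reflection-corrected).

    Returns the proper rotation R and translation t minimising
    ``|| q @ R.T + t - r ||`` over the paired coordinates, and the rmsd of
    the post-fit residuals.
    """
    q = np.asarray(query_coords, dtype=float)
    r = np.asarray(reference_coords, dtype=float)
    if q.shape != r.shape or q.ndim != 2 or q.shape[1] != 3:
        raise SuperpositionError(f"coordinate shapes differ or are not (n, 3): {q.shape} vs {r.shape}")
    n = q.shape[0]
    if n < 3:
        raise SuperpositionError(f"need at least 3 paired atoms, got {n}")
    qc, rc = q.mean(axis=0), r.mean(axis=0)
    q0, r0 = q - qc, r - rc
    # collinearity check: centred points must span a plane
    if np.linalg.matrix_rank(q0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear) point configuration")
    h = q0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ qc
    resid = q @ rot.T + t - r
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return SuperpositionResult(rot, t, rmsd, n)


def paired_calpha_coords(
    query: StructureModel,
    reference: StructureModel,
    pairings: Sequence[ChainPairing],
) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinate arrays for the paired residues of chain pairings."""
    q_pts, r_pts = [], []
    for pairing in pairings:
        for q_key, r_key in pairing.residue_pairs:
            q_res, r_res = query.get(q_key), reference.get(r_key)
            if q_res is None or r_res is None:
                continue
            qa, ra = q_res.atom("CA"), r_res.atom("CA")
            if qa is None or ra is None:
                continue
            q_pts.append(qa.position)
            r_pts.append(ra.position)
    return np.asarray(q_pts, dtype=float), np.asarray(r_pts, dtype=float)


# -- site matching ----------------------------------------------------------


def _representative_point(res: Residue) -> np.ndarray:
    mg = res.atom("MG")
    if mg is not None:
        return mg.xyz
    return res.coords().mean(axis=0)


def _category(ptype: PigmentType) -> Optional[str]:
    if ptype in CHLOROPHYLL_TYPES:
        return "chlorophyll"
    if ptype in (PigmentType.CAROTENOID, PigmentType.PHYLLOQUINONE,
                 PigmentType.PG_LIPID, PigmentType.MGDG_LIPID):
        return ptype.value if ptype != PigmentType.CAROTENOID else "carotenoid"
    return None


def match_pigment_sites(
    query: StructureModel,
    reference: StructureModel,
    transform: Optional[SuperpositionResult] = None,
    cutoff: float = 2.5,
    ligand_table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
) -> list[SiteCorrespondence]:
    """Greedy nearest-site matching of pigments after superposition.

    Chlorophylls are represented by their Mg, Mg-free pigments by their
    centroid; only like categories (chlorophyll-chlorophyll,
    carotenoid-carotenoid, ...) are matched. Candidate pairs under
    ``cutoff`` (Angstrom, after applying ``transform`` to the query) are
    taken shortest-first with each site used at most once; leftovers are
    classified lost (reference-only) or gained (query-only).
    """
    def sites(model: StructureModel, apply_tf: bool):
        out = []
        for res, ptype in model.pigment_residues(ligand_table):
            cat = _category(ptype)
            if cat is None:
                continue
            pt = _representative_point(res)
            if apply_tf and transform is not None:
                pt = transform.apply(pt)
            out.append((res.key, cat, pt))
        return out

    q_sites = sites(query, True)
    r_sites = sites(reference, False)
    pairs = []
    for qk, qcat, qp in q_sites:
        for rk, rcat, rp in r_sites:
            if qcat != rcat:
                continue
            d = float(np.linalg.norm(qp - rp))
            if d <= cutoff:
                pairs.append((d, qk, rk))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_q: set[ResidueKey] = set()
    used_r: set[ResidueKey] = set()
    out: list[SiteCorrespondence] = []
    for d, qk, rk in pairs:
        if qk in used_q or rk in used_r:
            continue
        used_q.add(qk)
        used_r.add(rk)
        out.append(SiteCorrespondence(qk, rk, "conserved", d))
    for rk, _, _ in r_sites:
        if rk not in used_r:
            out.append(SiteCorrespondence(None, rk, "lost"))
    for qk, _, _ in q_sites:
        if qk not in used_q:
            out.append(SiteCorrespondence(qk, None, "gained"))
    out.sort(key=lambda c: (c.reference_site or c.query_site))
    return out


def transfer_site_labels(
    query: StructureModel,
    reference: StructureModel,
    correspondences: Sequence[SiteCorrespondence],
) -> dict[ResidueKey, str]:
    """Label query pigments by their reference site (chain + last 2 digits).

    Conserved pigments inherit the reference naming rule (reference chain
    letter + last two digits of the reference residue number, e.g. PsaA
    residue 1120 -> "A20"); gained pigments get "<chain>new<i>" with a
    deterministic sequential suffix.
    """
    labels: dict[ResidueKey, str] = {}
    gained = []
    for corr in correspondences:
        if corr.status == "conserved":
            ref_chain, ref_num, _ = corr.reference_site
            labels[corr.query_site] = site_label(ref_chain, ref_num)
        elif corr.status == "gained":
            gained.append(corr.query_site)
    for i, qk in enumerate(sorted(gained), start=1):
        labels[qk] = f"{qk[0]}new{i}"
    return labels


def compare_axial_ligands(
    correspondences: Sequence[SiteCorrespondence],
    query: StructureModel,
    reference: StructureModel,
    window: tuple[float, float] = (1.9, 3.0),
    ligand_table: LigandCodeTable = DEFAULT_LIGAND_TABLE,
) -> list[dict]:
    """Axial-ligand class at each conserved chlorophyll site, both models.

    Returns one row per conserved site with an Mg: the closest-ligand class
    in the query and in the reference ("none" when the coordination sphere
    is empty) and a changed flag. A changed axial ligand is one of the
    structural signals used by the chlorophyll-f site ranking.
    """
    rows = []
    for corr in correspondences:
        if corr.status != "conserved":
            continue
        q_res = query.get(corr.query_site)
        r_res = reference.get(corr.reference_site)
        if q_res is None or r_res is None:
            continue
        if q_res.atom("MG") is None or r_res.atom("MG") is None:
            continue
        q_ligs = detect_axial_ligands(q_res, query, window, ligand_table)
        r_ligs = detect_axial_ligands(r_res, reference, window, ligand_table)
        q_cls = q_ligs[0].ligand_class if q_ligs else "none"
        r_cls = r_ligs[0].ligand_class if r_ligs else "none"
        rows.append(
            {
                "query_site": corr.query_site,
                "reference_site": corr.reference_site,
                "query_ligand": q_cls,
                "reference_ligand": r_cls,
                "changed": q_cls != r_cls,
            }
        )
    return rows


def correspondences_to_tsv(
    correspondences: Sequence[SiteCorrespondence],
    labels: Optional[Mapping[ResidueKey, str]] = None,
) -> str:
    lines = ["query_site\treference_site\tstatus\tmg_displacement"]
    for c in correspondences:
        def fmt(key: Optional[ResidueKey]) -> str:
            if key is None:
                return "-"
            if labels and key in labels:
                return labels[key]
            return f"{key[0]}:{key[1]}"
        disp = f"{c.mg_displacement:.3f}" if c.mg_displacement is not None else "-"
        lines.append(f"{fmt(c.query_site)}\t{fmt(c.reference_site)}\t{c.status}\t{disp}")
    return "\n".join(lines) + "\n"
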