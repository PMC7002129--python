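"""Deterministic generators for toy structures and chromatograms.

Every downstream stage of the package is testable offline against these
generators because they emit complete ground truth alongside the data:

* :func:`ideal_chlorin_template` — an exactly planar, idealised chlorin
  macrocycle (24 heavy atoms + Mg + a C2 methyl carbon + the 13^1-keto
  group), built analytically rather than copied from any deposition, so
  planarity, bond lengths and substituent geometry are known in closed form;
* :func:`build_toy_structure` — pigments placed by rigid transforms with
  hydrogen-bond donors, axial ligands and stacking partners planted at
  exactly specified distances;
* :func:`simulate_chromatogram` — multi-channel HPLC traces whose peak
  areas are generated by inverting the Beer-Lambert quantitation equation
  from a chosen pigment stoichiometry (phylloquinone fixed at 2 copies per
  monomer), plus linear baseline drift and seeded Gaussian noise.

All outputs are reproducible from (spec, seed); the default seed is 7521.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .chlorin import DEFAULT_ATOM_NAME_TABLE
from .quant import (
    Chromatogram,
    EXTINCTION_COEFFICIENTS,
    DEFAULT_RETENTION_WINDOWS,
    QuantError,
    SQRT_2PI,
)
from .structure_io import Atom, Residue, StructureModel

__all__ = [
    "DEFAULT_SEED",
    "DonorSpec",
    "AxialSpec",
    "PlacementSpec",
    "ChromatogramSpec",
    "ideal_chlorin_template",
    "build_toy_structure",
    "random_placements",
    "simulate_chromatogram",
]

DEFAULT_SEED = 7521

# Idealised pyrrole geometry (Angstrom), local frame: ring axis along +x.
_N_RADIUS = 2.05
_CA = (2.837, 1.121)  # alpha carbon
_CB = (4.206, 0.675)  # beta carbon
_MESO_RADIUS = 3.45
_SUB_BOND = 1.50  # C2 -> substituent carbon
_KETO_BOND = 1.23  # keto C=O


def _rot2(xy: tuple[float, float], phi_deg: float) -> tuple[float, float]:
    phi = math.radians(phi_deg)
    c, s = math.cos(phi), math.sin(phi)
    x, y = xy
    return (c * x - s * y, s * x + c * y)


def _template_positions() -> dict[str, tuple[float, float, float]]:
    """IUPAC position -> ideal coordinates, macrocycle in the z = 0 plane."""
    pos: dict[str, tuple[float, float, float]] = {"MG": (0.0, 0.0, 0.0)}
    # rings A-D at axes 0/90/180/270 deg, meso carbons at 45/135/225/315
    ring_atoms = {
        0.0: ("N21", "C1", "C2", "C3", "C4"),
        90.0: ("N22", "C6", "C7", "C8", "C9"),
        180.0: ("N23", "C11", "C12", "C13", "C14"),
        270.0: ("N24", "C16", "C17", "C18", "C19"),
    }
    for phi, (n, ca1, cb1, cb2, ca2) in ring_atoms.items():
        pos[n] = (*_rot2((_N_RADIUS, 0.0), phi), 0.0)
        pos[ca1] = (*_rot2((_CA[0], -_CA[1]), phi), 0.0)
        pos[cb1] = (*_rot2((_CB[0], -_CB[1]), phi), 0.0)
        pos[cb2] = (*_rot2((_CB[0], _CB[1]), phi), 0.0)
        pos[ca2] = (*_rot2((_CA[0], _CA[1]), phi), 0.0)
    for phi, meso in ((45.0, "C5"), (135.0, "C10"), (225.0, "C15"), (315.0, "C20")):
        pos[meso] = (*_rot2((_MESO_RADIUS, 0.0), phi), 0.0)
    return pos


def _radial_extension(origin: tuple[float, float, float], bond: float) -> tuple[float, float, float]:
    v = np.asarray(origin, dtype=float)
    u = v / np.linalg.norm(v)
    out = v + bond * u
    return (float(out[0]), float(out[1]), float(out[2]))


def ideal_chlorin_template(
    chain_id: str = "P",
    residue_number: int = 1,
    residue_name: str = "CLA",
) -> Residue:
    """An idealised, exactly planar chlorin residue with CCD atom names.

    Contains the 24 macrocycle heavy atoms + MG, a methyl carbon bonded to
    the IUPAC C2 at 1.50 Angstrom, and the 13^1-keto carbonyl (CAD/OBD).
    Ring bond lengths fall in [1.33, 1.55] Angstrom and the macrocycle lies
    exactly in z = 0.
    """
    iupac_pos = _template_positions()
    # substituents: C2 methyl (formyl carbon in Chl f), 13^1 keto C=O
    sub_c = _radial_extension(iupac_pos["C2"], _SUB_BOND)
    keto_c = _radial_extension(iupac_pos["C13"], _SUB_BOND)
    keto_o = _radial_extension(keto_c, _KETO_BOND)

    atoms: list[Atom] = []

    def add(name: str, element: str, position: tuple[float, float, float]) -> None:
        atoms.append(
            Atom(
                chain_id=chain_id,
                residue_name=residue_name,
                residue_number=residue_number,
                atom_name=name,
                element=element,
                position=position,
            )
        )

    add("MG", "MG", iupac_pos["MG"])
    for iupac, ccd_name in DEFAULT_ATOM_NAME_TABLE.items():
        if iupac == "MG":
            continue
        element = "N" if iupac.startswith("N") else "C"
        add(ccd_name, element, iupac_pos[iupac])
    add("CMB", "C", sub_c)  # IUPAC C2 substituent (methyl carbon)
    add("CAD", "C", keto_c)  # 13^1 carbon
    add("OBD", "O", keto_o)  # 13^1 keto oxygen
    return Residue((chain_id, residue_number, ""), residue_name, atoms)


# -- toy structure assembly -------------------------------------------------


@dataclass(frozen=True)
class DonorSpec:
    """A hydrogen-bond donor planted at an exact distance from the C2 substituent.

    ``direction`` is a vector in the pigment's local template frame; it is
    rotated with the pigment, normalised, and the donor atom is placed
    ``distance`` Angstrom from the substituent carbon along it.
    """

    distance: float
    residue_name: str = "TYR"
    atom_name: str = "OH"
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("donor distance must be positive")


@dataclass(frozen=True)
class AxialSpec:
    """An axial ligand planted along the ring normal at an exact Mg distance."""

    distance: float
    residue_name: str = "HIS"
    atom_name: str = "NE2"
    side: int = 1  # +1 above the ring plane, -1 below

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("axial distance must be positive")


@dataclass(frozen=True)
class PlacementSpec:
    """Rigid placement of one template pigment plus planted probe atoms."""

    rotation: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    residue_name: str = "CLA"
    donors: tuple[DonorSpec, ...] = ()
    axial: Optional[AxialSpec] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if np.linalg.det(r) < 0:
            raise ValueError("rotation must be proper (determinant +1)")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.rotation, dtype=float)


def _transform_atom(atom: Atom, rot: np.ndarray, trans: np.ndarray, **updates) -> Atom:
    p = rot @ atom.xyz + trans
    return replace(atom, position=(float(p[0]), float(p[1]), float(p[2])), **updates)


def build_toy_structure(
    specs: Sequence[PlacementSpec],
    min_clearance: float = 1.0,
) -> tuple[StructureModel, dict]:
    """Assemble pigments + planted probes into a model with ground truth.

    Pigments become chain "P" residues 1..n; donors chain "D"; axial
    ligands chain "L". The ground-truth dict records, per pigment, the
    planted donor distances, axial ligand, Mg position and ring normal, and
    globally the Mg-Mg distance table — enough to score every downstream
    geometric operation without re-deriving geometry. Raises if two
    pigments come closer than ``min_clearance`` (overlapping placement).
    """
    residues: list[Residue] = []
    truth: dict = {"pigments": {}, "mg_mg": {}}
    pigment_coords: list[np.ndarray] = []
    donor_counter = 0
    axial_counter = 0
    donor_residues: list[Residue] = []
    axial_residues: list[Residue] = []

    for idx, spec in enumerate(specs, start=1):
        rot = spec.matrix
        trans = np.asarray(spec.translation, dtype=float)
        template = ideal_chlorin_template(
            chain_id="P", residue_number=idx, residue_name=spec.residue_name
        )
        placed = [_transform_atom(a, rot, trans) for a in template.atoms]
        res = Residue(("P", idx, ""), spec.residue_name, placed)
        residues.append(res)
        coords = res.coords()
        pigment_coords.append(coords)

        sub_local = np.asarray(_radial_extension(_template_positions()["C2"], _SUB_BOND))
        sub_world = rot @ sub_local + trans
        normal_world = rot @ np.array([0.0, 0.0, 1.0])

        entry: dict = {
            "mg": tuple(rot @ np.zeros(3) + trans),
            "normal": tuple(normal_world),
            "c2_substituent": tuple(sub_world),
            "donors": [],
            "axial": None,
            "residue_key": ("P", idx, ""),
        }

        for dspec in spec.donors:
            donor_counter += 1
            direction = rot @ np.asarray(dspec.direction, dtype=float)
            direction = direction / np.linalg.norm(direction)
            p = sub_world + dspec.distance * direction
            donor_residues.append(
                Residue(
                    ("D", donor_counter, ""),
                    dspec.residue_name,
                    [
                        Atom(
                            chain_id="D",
                            residue_name=dspec.residue_name,
                            residue_number=donor_counter,
                            atom_name=dspec.atom_name,
                            element=dspec.atom_name[0],
                            position=(float(p[0]), float(p[1]), float(p[2])),
                        )
                    ],
                )
            )
            entry["donors"].append(
                {"distance": dspec.distance, "residue_name": dspec.residue_name,
                 "atom_name": dspec.atom_name, "key": ("D", donor_counter, "")}
            )

        if spec.axial is not None:
            axial_counter += 1
            p = (rot @ np.zeros(3) + trans) + spec.axial.side * spec.axial.distance * normal_world
            axial_residues.append(
                Residue(
                    ("L", axial_counter, ""),
                    spec.axial.residue_name,
                    [
                        Atom(
                            chain_id="L",
                            residue_name=spec.axial.residue_name,
                            residue_number=axial_counter,
                            atom_name=spec.axial.atom_name,
                            element=spec.axial.atom_name[0],
                            position=(float(p[0]), float(p[1]), float(p[2])),
                        )
                    ],
                )
            )
            entry["axial"] = {
                "distance": spec.axial.distance,
                "residue_name": spec.axial.residue_name,
                "atom_name": spec.axial.atom_name,
                "key": ("L", axial_counter, ""),
            }

        truth["pigments"][idx] = entry

    for i in range(len(pigment_coords)):
        for j in range(i + 1, len(pigment_coords)):
            diff = pigment_coords[i][:, None, :] - pigment_coords[j][None, :, :]
            dmin = float(np.sqrt((diff ** 2).sum(axis=2).min()))
            if dmin < min_clearance:
                raise ValueError(
                    f"pigments {i + 1} and {j + 1} overlap (closest atoms "
                    f"{dmin:.2f} A < {min_clearance} A)"
                )
            mg_i = np.asarray(truth["pigments"][i + 1]["mg"])
            mg_j = np.asarray(truth["pigments"][j + 1]["mg"])
            truth["mg_mg"][(i + 1, j + 1)] = float(np.linalg.norm(mg_i - mg_j))

    model = StructureModel(residues + donor_residues + axial_residues)
    return model, truth


def random_placements(
    n: int,
    seed: int = DEFAULT_SEED,
    spacing: float = 25.0,
    donor_distance_range: Optional[tuple[float, float]] = None,
) -> list[PlacementSpec]:
    """n well-separated random rigid placements (optionally with one donor each).

    Pigments sit on a jittered line with ``spacing`` Angstrom pitch (far
    beyond stacking range) and uniformly random proper rotations. When
    ``donor_distance_range`` is given, each pigment gets one donor at a
    uniform random distance in that range, along a random direction pointing
    away from the ring.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        # random proper rotation via QR of a Gaussian matrix
        m = rng.normal(size=(3, 3))
        q, r = np.linalg.qr(m)
        q = q @ np.diag(np.sign(np.diag(r)))
        if np.linalg.det(q) < 0:
            q[:, 2] = -q[:, 2]
        trans = np.array([i * spacing, 0.0, 0.0]) + rng.uniform(-2, 2, size=3)
        donors: tuple[DonorSpec, ...] = ()
        if donor_distance_range is not None:
            lo, hi = donor_distance_range
            d = float(rng.uniform(lo, hi))
            direction = np.array([1.0, 0.0, 0.0]) + rng.uniform(-0.3, 0.3, size=3)
            donors = (DonorSpec(distance=d, direction=tuple(direction)),)
        specs.append(
            PlacementSpec(
                rotation=tuple(map(tuple, q)),
                translation=tuple(trans),
                donors=donors,
            )
        )
    return specs


# -- chromatogram simulation ------------------------------------------------


#: Measured far-red photosystem I stoichiometry used as the generator default
#: (copies per monomer): chlorophylls from HPLC quantitation, carotenoids
#: split by the measured beta-carotene/echinenone ratio of 1.82.
DEFAULT_STOICHIOMETRY: dict[str, float] = {
    "chl_a": 89.1,
    "chl_f": 7.1,
    "beta_carotene": 10.2,
    "echinenone": 5.6,
    "phylloquinone": 2.0,
}

DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "chl_f": 24.0,
    "chl_a": 32.0,
    "phylloquinone": 42.0,
    "echinenone": 54.0,
    "beta_carotene": 62.0,
}

DEFAULT_SIGMAS: dict[str, float] = {
    "chl_f": 0.45,
    "chl_a": 0.55,
    "phylloquinone": 0.50,
    "echinenone": 0.50,
    "beta_carotene": 0.50,
}


@dataclass
class ChromatogramSpec:
    """Everything needed to invert the quantitation equation into traces."""

    stoichiometry: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STOICHIOMETRY)
    )
    psi_umol: float = 1.0e-4  # photosystem monomer amount per injection
    flow_rate_ml_min: float = 0.5
    path_length_cm: float = 0.98
    dilution: float = 1.0
    retention_times: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION_TIMES)
    )
    sigmas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMAS))
    noise_sd_mOD: float = 0.0
    noise_relative: float = 0.0  # noise sd as a fraction of the channel's max amplitude
    baseline_slope: float = 0.02  # mOD per min
    baseline_intercept: float = 2.0  # mOD
    cis_satellites: bool = False
    time_range: tuple[float, float] = (0.0, 75.0)
    dt_min: float = 0.05
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.noise_sd_mOD < 0 or self.noise_relative < 0:
            raise QuantError("noise sd must be non-negative")
        phq = self.stoichiometry.get("phylloquinone")
        if phq != 2.0:
            raise QuantError(
                f"phylloquinone copies must be fixed at 2 per monomer, got {phq}"
            )
        if self.psi_umol < 0:
            raise QuantError("psi_umol must be non-negative")
        per_channel: dict[int, list[float]] = {}
        for sp, rt in self.retention_times.items():
            wl = DEFAULT_RETENTION_WINDOWS[sp][0]
            per_channel.setdefault(wl, []).append(rt)
        for wl, rts in per_channel.items():
            if len(set(rts)) != len(rts):
                raise QuantError(f"retention times on channel {wl} nm must be distinct")


def simulate_chromatogram(
    spec: ChromatogramSpec,
) -> tuple[dict[int, Chromatogram], dict]:
    """Generate one chromatogram per wavelength channel, plus ground truth.

    Per species: amount = copies * psi_umol; the peak area is the exact
    inversion of the quantitation equation,
    ``area = amount * eps * l / (FR * dilution)``, so running the full
    detect-fit-quantify-normalise pipeline on the traces must recover the
    specified stoichiometry. The trace is the sum of the channel's Gaussian
    peaks, a linear baseline and seeded Gaussian noise. Ground truth holds
    per-species areas, amounts (umol) and copies.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.time_range[0], spec.time_range[1] + spec.dt_min / 2, spec.dt_min)
    truth: dict = {"areas": {}, "amounts_umol": {}, "copies": dict(spec.stoichiometry)}
    channels: dict[int, np.ndarray] = {}

    for species, copies in spec.stoichiometry.items():
        if species not in EXTINCTION_COEFFICIENTS:
            raise QuantError(f"no extinction coefficient for species {species!r}")
        wl = DEFAULT_RETENTION_WINDOWS[species][0]
        amount = copies * spec.psi_umol
        area = (
            amount
            * EXTINCTION_COEFFICIENTS[species]
            * spec.path_length_cm
            / (spec.flow_rate_ml_min * spec.dilution)
        )
        truth["amounts_umol"][species] = amount
        truth["areas"][species] = area
        sigma = spec.sigmas[species]
        mu = spec.retention_times[species]
        amplitude = area / (sigma * SQRT_2PI)
        y = channels.setdefault(wl, np.zeros_like(t))
        y += amplitude * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
        if spec.cis_satellites and species in ("beta_carotene", "echinenone"):
            # later-eluting cis isomer: smaller, resolved from the all-trans peak
            sat_amp = 0.15 * amplitude
            y += sat_amp * np.exp(-0.5 * ((t - (mu + 2.2)) / sigma) ** 2)

    out: dict[int, Chromatogram] = {}
    for wl in sorted(channels):
        y = channels[wl] + spec.baseline_intercept + spec.baseline_slope * t
        sd = max(spec.noise_sd_mOD, spec.noise_relative * float(channels[wl].max()))
        if sd > 0:
            y = y + rng.normal(0.0, sd, size=t.shape)
        out[wl] = Chromatogram(
            wavelength_nm=wl,
            times=t.copy(),
            absorbance=y,
            flow_rate_ml_min=spec.flow_rate_ml_min,
            path_length_cm=spec.path_length_cm,
            dilution=spec.dilution,
        )
    return out, truth
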