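"""Sequence conservation: global alignment, identity matrices, residue tracks.

Subunit swaps are central to far-red photoacclimation: half the photosystem
subunits are replaced by paralogs of sometimes only ~40% identity, and the
regions of lowest identity are exactly where pigment sites change. This
module provides:

* a Needleman-Wunsch global aligner with affine gap penalties (Gotoh's
  three-matrix recurrence, deterministic traceback), implemented in-repo so
  scores and tracebacks are reproducible;
* percent-identity summaries and all-vs-all identity matrices;
* per-residue windowed identity tracks, mappable onto a structure's chains
  (and from there onto the B-factor channel for visualisation) and averaged
  over the protein environment of a pigment.

The substitution matrix defaults to BLOSUM62 (loaded from Biopython's copy);
gap penalties default to open 10, extend 0.5, with a gap of length L costing
``open + (L - 1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .structure_io import Residue, ResidueKey, StructureModel

__all__ = [
    "SequenceRecord",
    "PairwiseAlignment",
    "ResidueIdentityTrack",
    "AlignmentError",
    "read_fasta",
    "global_align",
    "percent_identity",
    "identity_matrix",
    "windowed_identity",
    "map_track_to_chain",
    "local_environment_identity",
    "blosum62",
]

AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_NEG_INF = float("-inf")


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence (one-letter codes, 20 amino acids + X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - AMINO_ALPHABET
        if bad:
            raise AlignmentError(f"illegal characters in {self.id!r}: {sorted(bad)}")
        if not self.sequence:
            raise AlignmentError(f"empty sequence: {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped strings of equal length plus the alignment score."""

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise AlignmentError("gapped strings differ in length")

    @property
    def sequence_a(self) -> str:
        return self.gapped_a.replace("-", "")

    @property
    def sequence_b(self) -> str:
        return self.gapped_b.replace("-", "")

    def columns(self) -> Iterable[tuple[str, str]]:
        return zip(self.gapped_a, self.gapped_b)


@dataclass(frozen=True)
class ResidueIdentityTrack:
    """Per-residue identity fraction keyed by ungapped query position (1-based)."""

    query_id: str
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)

    def value(self, position: int) -> float:
        return self.values[position - 1]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return records


def blosum62():
    return substitution_matrices.load("BLOSUM62")


# -- global alignment (Gotoh) -----------------------------------------------


def global_align(
    a: str | SequenceRecord,
    b: str | SequenceRecord,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap penalties.

    Three-state dynamic programme (match M, gap-in-b Ix, gap-in-a Iy); a gap
    of length L costs ``gap_open + (L - 1) * gap_extend``; switching gap
    strands opens a new gap. Traceback ties resolve diagonal > up > left so
    the alignment string is deterministic.
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else a
    sb = b.sequence if isinstance(b, SequenceRecord) else b
    sa, sb = sa.upper(), sb.upper()
    for name, s in (("a", sa), ("b", sb)):
        if not s:
            raise AlignmentError(f"sequence {name} is empty")
        bad = set(s) - AMINO_ALPHABET
        if bad:
            raise AlignmentError(f"illegal characters in sequence {name}: {sorted(bad)}")
    if matrix is None:
        matrix = blosum62()
    n, m = len(sa), len(sb)

    def sub(x: str, y: str) -> float:
        return float(matrix[x, y])

    M = np.full((n + 1, m + 1), _NEG_INF)
    Ix = np.full((n + 1, m + 1), _NEG_INF)  # gap in b: consumes a (up)
    Iy = np.full((n + 1, m + 1), _NEG_INF)  # gap in a: consumes b (left)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + (j - 1) * gap_extend)

    for i in range(1, n + 1):
        si = sa[i - 1]
        for j in range(1, m + 1):
            M[i, j] = sub(si, sb[j - 1]) + max(
                M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]
            )
            Ix[i, j] = max(
                M[i - 1, j] - gap_open,
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - gap_open,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open,
                Ix[i, j - 1] - gap_open,
                Iy[i, j - 1] - gap_extend,
            )

    # end state preference on ties: M (diagonal) > Ix (up) > Iy (left)
    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    score = max(end_scores)
    state = ("M", "Ix", "Iy")[end_scores.index(score)]

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            prev = sub(sa[i - 1], sb[j - 1])
            target = M[i, j] - prev
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            for cand, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if mat[i, j] == target:
                    state = cand
                    break
        elif state == "Ix":
            out_a.append(sa[i - 1])
            out_b.append("-")
            val = Ix[i, j]
            i -= 1
            if M[i, j] - gap_open == val:
                state = "M"
            elif Ix[i, j] - gap_extend == val:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            out_a.append("-")
            out_b.append(sb[j - 1])
            val = Iy[i, j]
            j -= 1
            if M[i, j] - gap_open == val:
                state = "M"
            elif Ix[i, j] - gap_open == val:
                state = "Ix"
            else:
                state = "Iy"

    aln = PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), float(score))
    if aln.sequence_a != sa or aln.sequence_b != sb:
        raise AlignmentError("traceback produced inconsistent alignment (internal error)")
    return aln


# -- identity summaries -----------------------------------------------------


def _core_columns(aln: PairwiseAlignment) -> tuple[int, int]:
    """Column range [start, stop) excluding terminal gap overhangs."""
    ncol = len(aln.gapped_a)
    start, stop = 0, ncol
    for s in (aln.gapped_a, aln.gapped_b):
        lead = len(s) - len(s.lstrip("-"))
        trail = len(s) - len(s.rstrip("-"))
        start = max(start, lead)
        stop = min(stop, ncol - trail)
    return start, max(start, stop)


def percent_identity(aln: PairwiseAlignment, mode: str = "aligned_columns") -> float:
    """Percent identical columns of a pairwise alignment.

    ``aligned_columns`` (default): identities / number of columns after
    stripping terminal gap overhangs (internal gap columns still count in the
    denominator). ``shorter_seq``: identities / length of the shorter input
    sequence.
    """
    identities = sum(
        1 for x, y in aln.columns() if x == y and x != "-"
    )
    if mode == "aligned_columns":
        start, stop = _core_columns(aln)
        ncol = stop - start
        if ncol == 0:
            return 0.0
        core_ident = sum(
            1
            for x, y in zip(aln.gapped_a[start:stop], aln.gapped_b[start:stop])
            if x == y and x != "-"
        )
        return 100.0 * core_ident / ncol
    if mode == "shorter_seq":
        denom = min(len(aln.sequence_a), len(aln.sequence_b))
        return 100.0 * identities / denom
    raise AlignmentError(f"unknown percent-identity mode {mode!r}")


def identity_matrix(
    records: Sequence[SequenceRecord],
    mode: str = "aligned_columns",
    **align_kwargs,
) -> pd.DataFrame:
    """All-vs-all percent identity (symmetric, diagonal 100)."""
    if len(records) < 2:
        raise AlignmentError("identity matrix needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate sequence ids")
    mat = pd.DataFrame(np.full((len(ids), len(ids)), 100.0), index=ids, columns=ids)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            pid = percent_identity(
                global_align(records[i], records[j], **align_kwargs), mode
            )
            mat.iloc[i, j] = pid
            mat.iloc[j, i] = pid
    return mat


# -- residue tracks ---------------------------------------------------------


def windowed_identity(aln: PairwiseAlignment, window: int = 11) -> ResidueIdentityTrack:
    """Per-query-residue identity fraction over a centred column window.

    For each ungapped residue of the first sequence, the track value is the
    fraction of identical columns within ``window`` alignment columns centred
    on that residue's column (truncated at the alignment ends). Gap columns
    count as mismatches. ``window`` must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise AlignmentError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    cols = list(aln.columns())
    ident = np.array([1.0 if x == y and x != "-" else 0.0 for x, y in cols])
    values = []
    for col, (x, _y) in enumerate(cols):
        if x == "-":
            continue
        lo, hi = max(0, col - half), min(len(cols), col + half + 1)
        values.append(float(ident[lo:hi].mean()))
    return ResidueIdentityTrack(query_id="query", values=tuple(values))


def map_track_to_chain(
    track: ResidueIdentityTrack,
    chain_id: str,
    offset: int = 0,
) -> dict[ResidueKey, float]:
    """Key track values by structure residue: number = position + offset.

    The offset reconciles author residue numbering with the 1-based sequence
    positions (partial models, leading tags).
    """
    return {
        (chain_id, pos + offset, ""): val
        for pos, val in enumerate(track.values, start=1)
    }


def local_environment_identity(
    pigment: Residue,
    model: StructureModel,
    track_values: Mapping[ResidueKey, float],
    radius: float = 8.0,
    pigment_coords: Optional[np.ndarray] = None,
) -> float:
    """Mean track value over protein residues near a pigment.

    A residue is in the environment if any of its atoms lies within
    ``radius`` Angstrom of any pigment atom (``pigment_coords`` may restrict
    the pigment side to e.g. the macrocycle atoms). Raises when no residue
    with a track value is in range.
    """
    pcoords = (
        np.asarray(pigment_coords, dtype=float)
        if pigment_coords is not None
        else pigment.coords()
    )
    vals = []
    for res in model:
        if not res.is_amino_acid or res.key not in track_values:
            continue
        rc = res.coords()
        d2 = ((rc[:, None, :] - pcoords[None, :, :]) ** 2).sum(axis=2)
        if d2.min() <= radius * radius:
            vals.append(track_values[res.key])
    if not vals:
        raise AlignmentError(
            f"no residues with conservation values within {radius} A of {pigment.key}"
        )
    return float(np.mean(vals))
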