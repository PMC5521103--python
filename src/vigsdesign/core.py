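"""Domain types, sequence utilities and FASTA I/O.

The central objects are :class:`GeneRecord` (one gene-family member with a
design role), :class:`GeneFamily` (the family plus its lazily computed
percent-identity matrix) and :class:`DesignConstraints` (the knobs of the
fragment-selection method: siRNA window length, the per-window mismatch
threshold that prevents off-target silencing, and fragment / insert length
bounds).

Coordinates are 0-based half-open throughout the API; report renderers
convert to 1-based inclusive positions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Role",
    "GeneRecord",
    "GeneFamily",
    "DesignConstraints",
    "read_family",
    "write_family",
    "revcomp",
    "pairwise_identity",
    "encode",
]

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# numeric encoding shared by the window/miRNA engines
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class Role(str, enum.Enum):
    """Design role of a family member."""

    INTENDED = "intended"  #: gene the fragment must co-silence
    OFFTARGET = "offtarget"  #: gene the fragment must not silence
    NEUTRAL = "neutral"  #: not part of the current design question


def _validate_seq(seq: str, record_id: str) -> str:
    if not seq:
        raise ValueError(f"record {record_id!r}: empty sequence")
    seq = seq.upper()
    for pos, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(
                f"record {record_id!r}: invalid character {base!r} at "
                f"position {pos + 1} (only A/C/G/T are allowed; ambiguity "
                "codes make exact window mismatch counts ill-defined)"
            )
    return seq


@dataclass(frozen=True)
class GeneRecord:
    """One gene-family member: ID, validated DNA sequence, design role."""

    id: str
    seq: str
    role: Role = Role.NEUTRAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", _validate_seq(self.seq, self.id))
        object.__setattr__(self, "role", Role(self.role))

    def __len__(self) -> int:
        return len(self.seq)

    def with_role(self, role: Role | str) -> "GeneRecord":
        return replace(self, role=Role(role))


@dataclass
class GeneFamily:
    """An ordered collection of homologous genes.

    The percent-identity matrix (global alignment identity, symmetric,
    diagonal 100) is computed on first access and cached.
    """

    members: list[GeneRecord]
    _identity: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate member IDs: {sorted(dupes)}")
        self._by_id = {m.id: m for m in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, member_id: str) -> GeneRecord:
        return self._by_id[member_id]

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    def with_roles(self, roles: Mapping[str, Role | str]) -> "GeneFamily":
        """Return a copy with the given roles; unmapped IDs become neutral."""
        unknown = set(roles) - set(self.ids)
        if unknown:
            raise KeyError(f"role assigned to unknown member ID(s): {sorted(unknown)}")
        new = [
            m.with_role(roles.get(m.id, Role.NEUTRAL)) for m in self.members
        ]
        return GeneFamily(new)

    def by_role(self, role: Role | str) -> list[GeneRecord]:
        role = Role(role)
        return [m for m in self.members if m.role is role]

    @property
    def identity_matrix(self) -> pd.DataFrame:
        """Symmetric percent-identity matrix (lazily computed)."""
        if self._identity is None:
            n = len(self.members)
            mat = np.full((n, n), 100.0)
            for i in range(n):
                for j in range(i + 1, n):
                    mat[i, j] = mat[j, i] = pairwise_identity(
                        self.members[i].seq, self.members[j].seq
                    )
            self._identity = pd.DataFrame(mat, index=self.ids, columns=self.ids)
        return self._identity


@dataclass(frozen=True)
class DesignConstraints:
    """Parameters of the fragment-selection method.

    window_len
        siRNA window length in nt; 21 is the most conservative choice in
        the 21-24 nt siRNA size range.
    min_mismatch
        minimum mismatches required in *every* window against every
        off-target; 3, because windows with only 1-2 mismatches still
        silence off-targets.
    min_fragment_len / max_fragment_len
        fragment length bounds in nt; ~70 bp is the shortest fragment
        shown to silence efficiently.
    insert_len_bounds
        length bounds for the whole chimeric insert carried by the TRV
        vector (200-1500 bp).
    both_strands
        screen both polarities (VIGS produces dsRNA, so siRNAs of both
        strands arise).
    apply_mirna_rules
        additionally reject windows that could act as functional
        miRNA-like triggers on an off-target.
    """

    window_len: int = 21
    min_mismatch: int = 3
    min_fragment_len: int = 70
    max_fragment_len: int = 400
    insert_len_bounds: tuple[int, int] = (200, 1500)
    both_strands: bool = True
    apply_mirna_rules: bool = True

    def __post_init__(self) -> None:
        if not 21 <= self.window_len <= 24:
            raise ValueError("window_len must be in [21, 24] (siRNA size range)")
        if self.min_mismatch < 1:
            raise ValueError("min_mismatch must be >= 1")
        if self.min_fragment_len < self.window_len:
            raise ValueError("min_fragment_len must be >= window_len")
        if self.max_fragment_len < self.min_fragment_len:
            raise ValueError("max_fragment_len must be >= min_fragment_len")
        lo, hi = self.insert_len_bounds
        if lo > hi:
            raise ValueError("insert_len_bounds must be (low, high) with low <= high")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (strict ACGT)."""
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid character(s) for DNA: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


def _make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Percent identity of two DNA sequences over a global alignment.

    identity = identical columns / alignment columns * 100.  The default
    scoring (match +1, mismatch -1, gap open -2, gap extend -1) avoids
    gaps on the near-identical inputs this tool targets, so for equal
    lengths it usually reduces to Hamming identity.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a.upper(), b.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def read_family(
    fasta_source: str | Path | IO[str],
    roles: Mapping[str, Role | str] | None = None,
) -> GeneFamily:
    """Read a gene family from FASTA and assign design roles.

    Sequences are validated (strict ACGT, uppercased); IDs must be unique;
    IDs absent from ``roles`` default to neutral.
    """
    records = list(SeqIO.parse(fasta_source, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_source!r}")
    members = [GeneRecord(r.id, str(r.seq)) for r in records]
    family = GeneFamily(members)
    if roles:
        family = family.with_roles(roles)
    return family


def write_family(family: GeneFamily | Iterable[GeneRecord], dest: str | Path | IO[str]) -> None:
    """Write family members as single-line FASTA."""
    records = [
        SeqRecord(Seq(m.seq), id=m.id, description="") for m in family
    ]
    SeqIO.write(records, dest, "fasta-2line")
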