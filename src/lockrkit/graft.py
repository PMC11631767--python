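"""Enumerate threadings of a sensing motif into an α-helical latch segment.

A LOCKR sensor gains its specificity from a target-binding motif embedded
in the latch helix.  Because an α-helix presents a different face every
residue (3.6 residues/turn, approximated by the 7-residue heptad), each
start offset of the motif within the latch is a distinct geometric
placement.  This module enumerates every (prefix length, start offset)
threading of a motif into a latch window — e.g. a 35-residue latch
(residues 610–644) with motif prefixes of length 7–11 yields
29+28+27+26+25 = 135 candidates — and writes the candidates to FASTA.

Energetic ranking of the candidates is out of scope; downstream selection
is expected to use structure-based scoring.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "LatchSegment",
    "BindingMotif",
    "GraftCandidate",
    "enumerate_placements",
    "thread_motif",
    "register_class",
    "write_candidates_fasta",
    "read_candidates_fasta",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Residues per heptad repeat used to label helical faces.
HEPTAD = 7


def _check_sequence(seq: str, what: str) -> str:
    seq = seq.upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"{what} contains non-standard residues: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class LatchSegment:
    """The latch window open to grafting, in protein residue numbering."""

    sequence: str
    start_residue: int  # 1-based residue number of sequence[0]
    end_residue: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "latch"))
        expected = self.end_residue - self.start_residue + 1
        if len(self.sequence) != expected:
            raise ValueError(
                f"latch length {len(self.sequence)} != residue span {expected}"
            )

    @property
    def span(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingMotif:
    """Sensing motif whose N-terminal prefixes are threaded into the latch."""

    sequence: str
    min_len: int = 7
    max_len: int = 11

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, "motif"))
        if not (0 < self.min_len <= self.max_len <= len(self.sequence)):
            raise ValueError("require 0 < min_len <= max_len <= len(sequence)")


@dataclass(frozen=True)
class GraftCandidate:
    """One threading of a motif prefix into the latch."""

    threaded_sequence: str
    start_offset: int  # 0-based within the latch
    motif_len: int
    register_class: int

    def start_residue(self, latch: LatchSegment) -> int:
        """1-based residue number where the motif begins."""
        return latch.start_residue + self.start_offset


def register_class(start_offset: int) -> int:
    """Heptad class (offset mod 7) labelling the helical face of a placement.

    The 3.6-residue/turn helix is approximated by the 7-residue heptad
    repeat, so placements sharing a class present the motif on roughly the
    same face.  This is a labelling convenience, not a filter.
    """
    if start_offset < 0:
        raise ValueError("offset must be non-negative")
    return start_offset % HEPTAD


def thread_motif(latch: LatchSegment, motif_prefix: str, start_offset: int) -> str:
    """Substitute ``motif_prefix`` into the latch at ``start_offset``.

    Flanking latch residues are preserved verbatim; the output has the
    latch's length.
    """
    motif_prefix = _check_sequence(motif_prefix, "motif prefix")
    L = len(motif_prefix)
    if start_offset < 0 or start_offset + L > latch.span:
        raise ValueError(
            f"placement [{start_offset}, {start_offset + L}) outside latch "
            f"of span {latch.span}"
        )
    s = latch.sequence
    return s[:start_offset] + motif_prefix + s[start_offset + L :]


def enumerate_placements(
    latch: LatchSegment, motif: BindingMotif
) -> list[GraftCandidate]:
    """All (prefix length, start offset) threadings, deterministically ordered.

    For each prefix length L in [min_len, max_len] every start offset in
    [0, span - L] is emitted, length ascending then offset ascending, giving
    sum over L of (span - L + 1) candidates.  A motif longer than the latch
    yields an empty list with a warning.
    """
    candidates: list[GraftCandidate] = []
    for L in range(motif.min_len, motif.max_len + 1):
        prefix = motif.sequence[:L]
        for p in range(latch.span - L + 1):
            candidates.append(
                GraftCandidate(
                    threaded_sequence=thread_motif(latch, prefix, p),
                    start_offset=p,
                    motif_len=L,
                    register_class=register_class(p),
                )
            )
    if not candidates:
        warnings.warn(
            f"no placements: latch span {latch.span} < min motif length "
            f"{motif.min_len}",
            stacklevel=2,
        )
    return candidates


_HEADER_RE = re.compile(
    r"graft_res(?P<res>\d+)_off(?P<off>\d+)_len(?P<len>\d+)_reg(?P<reg>\d+)"
)


def _candidate_id(cand: GraftCandidate, latch: LatchSegment) -> str:
    return (
        f"graft_res{cand.start_residue(latch)}_off{cand.start_offset}"
        f"_len{cand.motif_len}_reg{cand.register_class}"
    )


def write_candidates_fasta(
    candidates: Sequence[GraftCandidate],
    latch: LatchSegment,
    path: str | Path,
) -> int:
    """Write candidates as FASTA; headers encode placement coordinates.

    Header ids look like ``graft_res612_off2_len7_reg2`` (1-based start
    residue, 0-based offset, motif length, heptad class) and round-trip
    through :func:`read_candidates_fasta`.  Returns the record count.
    """
    if not candidates:
        raise ValueError("refusing to write an empty candidate list")
    records = [
        SeqRecord(
            Seq(c.threaded_sequence),
            id=_candidate_id(c, latch),
            description=(
                f"latch {latch.start_residue}-{latch.end_residue} "
                f"motif@[{c.start_offset},{c.start_offset + c.motif_len})"
            ),
        )
        for c in candidates
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_candidates_fasta(path: str | Path) -> list[GraftCandidate]:
    """Parse a candidates FASTA written by :func:`write_candidates_fasta`."""
    out: list[GraftCandidate] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _HEADER_RE.match(rec.id)
        if m is None:
            raise ValueError(f"unparseable candidate header: {rec.id}")
        out.append(
            GraftCandidate(
                threaded_sequence=str(rec.seq),
                start_offset=int(m.group("off")),
                motif_len=int(m.group("len")),
                register_class=int(m.group("reg")),
            )
        )
    return out
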