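"""Sequence input/output, CDS translation and signal-peptide handling.

Precursor transcripts arrive as FASTA; an optional ``cds=start..end`` header
token (1-based inclusive, as printed in GenBank feature tables) pins the
coding region, otherwise the longest ATG-initiated open reading frame on the
forward strand is used (RACE products are already oriented). Translation
uses the standard genetic code. Mature proteins are the precursor minus a
fixed-length N-terminal signal peptide (20 residues for SPF precursors).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import STANDARD_RESIDUES

_IUPAC_NT = set("ACGTN")
_CDS_TOKEN = re.compile(r"\bcds=(\d+)\.\.(\d+)\b")

DEFAULT_SIGNAL_LEN = 20


class SequenceError(ValueError):
    """Raised for malformed sequence input (bad characters, bad CDS, stops)."""


@dataclass(frozen=True)
class PrecursorTranscript:
    """A precursor cDNA with its coding region.

    ``length_bp`` is the full transcript length (UTRs included); it is the
    gene-length denominator used for RPKM, not the CDS length.
    """

    id: str
    cdna: str
    cds_start: int  # 0-based inclusive
    cds_end: int  # 0-based exclusive

    def __post_init__(self) -> None:
        bad = [(i, c) for i, c in enumerate(self.cdna) if c not in _IUPAC_NT]
        if bad:
            i, c = bad[0]
            raise SequenceError(
                f"{self.id}: non-IUPAC nucleotide {c!r} at position {i}"
            )
        n = self.cds_end - self.cds_start
        if n <= 0 or n % 3:
            raise SequenceError(
                f"{self.id}: CDS length {n} is not a positive multiple of 3"
            )
        if self.cds_start < 0 or self.cds_end > len(self.cdna):
            raise SequenceError(f"{self.id}: CDS range outside sequence")

    @property
    def length_bp(self) -> int:
        return len(self.cdna)

    @property
    def cds(self) -> str:
        return self.cdna[self.cds_start : self.cds_end]


@dataclass(frozen=True)
class PrecursorProtein:
    """Translated precursor, stop removed, with its signal-peptide length."""

    id: str
    sequence: str
    signal_len: int = DEFAULT_SIGNAL_LEN

    def __post_init__(self) -> None:
        if "*" in self.sequence:
            raise SequenceError(f"{self.id}: precursor contains a stop symbol")
        if not 0 <= self.signal_len < len(self.sequence):
            raise SequenceError(
                f"{self.id}: signal length {self.signal_len} not shorter than "
                f"protein ({len(self.sequence)} aa)"
            )


@dataclass(frozen=True)
class MatureProtein:
    """A secreted mature protein with its cysteine positions cached."""

    id: str
    sequence: str
    cys_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        expected = tuple(i for i, r in enumerate(self.sequence) if r == "C")
        if self.cys_positions != expected:
            object.__setattr__(self, "cys_positions", expected)


def _find_longest_orf(seq: str) -> tuple[int, int]:
    """Longest ATG-initiated ORF on the forward strand; tie broken leftmost.

    The ORF runs from ATG to the first in-frame stop (stop included in the
    coordinates so the CDS is stop-terminated, as in GenBank CDS features).
    """
    best = (0, -1)  # (length, start)
    stops = {"TAA", "TAG", "TGA"}
    for start in range(len(seq) - 2):
        if seq[start : start + 3] != "ATG":
            continue
        for j in range(start, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                length = j + 3 - start
                if length > best[0]:
                    best = (length, start)
                break
    if best[1] < 0:
        raise SequenceError("no ATG-initiated ORF with a stop codon found")
    return best[1], best[1] + best[0]


def read_fasta(path: str | Path) -> list[PrecursorTranscript]:
    """Read precursor transcripts from FASTA.

    Sequences are uppercased and U converted to T. A ``cds=a..b`` token in
    the description (1-based inclusive) fixes the coding region; otherwise
    the longest forward-strand ATG-initiated ORF is used.
    """
    records: list[PrecursorTranscript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        m = _CDS_TOKEN.search(rec.description)
        if m:
            start, end = int(m.group(1)) - 1, int(m.group(2))
        else:
            start, end = _find_longest_orf(seq)
        records.append(PrecursorTranscript(rec.id, seq, start, end))
    return records


def write_fasta(
    path: str | Path, transcripts: Iterable[PrecursorTranscript]
) -> None:
    """Write transcripts to FASTA, 60-column wrapped, with cds= tokens."""
    recs = [
        SeqRecord(
            Seq(t.cdna),
            id=t.id,
            description=f"cds={t.cds_start + 1}..{t.cds_end}",
        )
        for t in transcripts
    ]
    SeqIO.write(recs, str(path), "fasta")


def translate_cds(
    t: PrecursorTranscript, signal_len: int = DEFAULT_SIGNAL_LEN
) -> PrecursorProtein:
    """Translate the coding region with the standard genetic code.

    The trailing stop codon, if present, is dropped; an internal stop or a
    codon containing N is an error.
    """
    cds = t.cds
    for j in range(0, len(cds), 3):
        if "N" in cds[j : j + 3]:
            raise SequenceError(
                f"{t.id}: ambiguous codon {cds[j:j + 3]!r} at codon {j // 3}"
            )
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise SequenceError(
            f"{t.id}: internal stop at codon {protein.index('*')}"
        )
    return PrecursorProtein(t.id, protein, signal_len)


def strip_signal(
    p: PrecursorProtein, signal_len: int | None = None
) -> MatureProtein:
    """Remove the N-terminal signal peptide, yielding the mature protein."""
    k = p.signal_len if signal_len is None else signal_len
    if k >= len(p.sequence):
        raise SequenceError(
            f"{p.id}: signal length {k} >= protein length {len(p.sequence)}"
        )
    return MatureProtein(p.id, p.sequence[k:])


def pairwise_p_distance(
    a: MatureProtein | str, b: MatureProtein | str, aligned: bool = True
) -> float:
    """Uncorrected p-distance between two aligned protein sequences.

    Columns containing a gap ('-') in either sequence are excluded
    pairwise. Unaligned input is rejected: alignment is out of scope here,
    so equal lengths are required.
    """
    sa = a.sequence if isinstance(a, MatureProtein) else a
    sb = b.sequence if isinstance(b, MatureProtein) else b
    if not aligned:
        raise ValueError("unaligned sequences are not supported; align first")
    if len(sa) != len(sb):
        raise ValueError(
            f"aligned sequences differ in length ({len(sa)} vs {len(sb)})"
        )
    compared = mismatch = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        compared += 1
        mismatch += x != y
    if compared == 0:
        raise ValueError("no gap-free columns to compare")
    return mismatch / compared


def validate_protein(seq: str) -> None:
    """Reject sequences containing anything but the 20 standard residues."""
    bad = [(i, c) for i, c in enumerate(seq) if c not in STANDARD_RESIDUES]
    if bad:
        i, c = bad[0]
        raise SequenceError(f"nonstandard residue {c!r} at position {i}")
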