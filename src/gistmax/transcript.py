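"""Transcript model for the MAX locus.

A minimal exon/CDS model sufficient to interpret HGVS coding-DNA (c.)
variant descriptions: exon segmentation of the mature transcript, CDS
boundaries, and the underlying sequence.  Both alternatively spliced
MAX isoforms are represented: the canonical 160-aa form and the 151-aa
form lacking a 27-nt in-frame segment.

The packaged sequence is a synthetic stand-in with the correct length
arithmetic (483-nt CDS, 160 codons plus stop), not the genuine
NM_002382 mRNA; the classification logic depends only on structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq


@dataclass(frozen=True)
class ExonSpan:
    """One exon in transcript coordinates (1-based, inclusive)."""

    label: str
    tx_start: int
    tx_end: int

    def __len__(self) -> int:
        return self.tx_end - self.tx_start + 1


@dataclass
class TranscriptModel:
    transcript_id: str
    strand: str
    exons: list[ExonSpan]
    cds_start: int  # transcript coordinate of c.1 (A of ATG), 1-based
    cds_end: int  # transcript coordinate of the last stop-codon base
    sequence: str  # mature transcript sequence, 5'->3'
    isoforms: dict[str, int] = field(default_factory=dict)  # name -> aa length

    def __post_init__(self) -> None:
        prev_end = 0
        for ex in self.exons:
            if ex.tx_start != prev_end + 1:
                raise ValueError(f"exons must tile the transcript; gap before {ex.label}")
            prev_end = ex.tx_end
        if prev_end != len(self.sequence):
            raise ValueError("exon spans do not cover the transcript sequence")
        if not 1 <= self.cds_start < self.cds_end <= len(self.sequence):
            raise ValueError("CDS must lie within the transcript")
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length (including stop) must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start + 1

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start - 1 : self.cds_end]

    def protein(self) -> str:
        """Translation of the CDS, stop stripped."""
        return str(Seq(self.cds).translate()).rstrip("*")

    # -- coordinate helpers -------------------------------------------------

    def tx_pos(self, coding_pos: int) -> int:
        """Transcript coordinate (1-based) of coding position c.N / c.-N."""
        if coding_pos == 0:
            raise ValueError("HGVS coding positions have no zero")
        if coding_pos > 0:
            t = self.cds_start + coding_pos - 1
        else:
            t = self.cds_start + coding_pos  # c.-1 is the base before c.1
        if not 1 <= t <= len(self.sequence):
            raise ValueError(f"coding position {coding_pos} outside the transcript")
        return t

    def base_at(self, coding_pos: int) -> str:
        return self.sequence[self.tx_pos(coding_pos) - 1]

    def exon_of(self, coding_pos: int) -> ExonSpan:
        t = self.tx_pos(coding_pos)
        for ex in self.exons:
            if ex.tx_start <= t <= ex.tx_end:
                return ex
        raise ValueError(f"position {coding_pos} not exonic")  # pragma: no cover

    def exon_number(self, exon: ExonSpan) -> int:
        return self.exons.index(exon) + 1

    def boundary_intron(self, coding_pos: int, offset: int) -> int | None:
        """Intron number adjacent to an exonic position carrying an
        intronic offset, or None if the position is not at the
        appropriate exon boundary (donor for +offsets, acceptor for -).
        """
        t = self.tx_pos(coding_pos)
        for i, ex in enumerate(self.exons):
            if offset > 0 and t == ex.tx_end and i < len(self.exons) - 1:
                return i + 1  # intron i+1 follows exon i+1
            if offset < 0 and t == ex.tx_start and i > 0:
                return i  # intron i precedes exon i+1
        return None


# exon lengths of the packaged model (sum 603: 60-nt UTRs + 483-nt CDS)
_EXON_LENGTHS = (150, 130, 90, 100, 133)


def load_max_transcript() -> TranscriptModel:
    """The packaged MAX transcript model (synthetic stand-in sequence)."""
    ref = resources.files("gistmax.data") / "max_transcript_synthetic.fasta"
    with ref.open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    seq = str(record.seq).upper()
    exons = []
    pos = 1
    for i, n in enumerate(_EXON_LENGTHS, start=1):
        exons.append(ExonSpan(f"exon{i}", pos, pos + n - 1))
        pos += n
    return TranscriptModel(
        transcript_id="NM_002382",
        strand="-",
        exons=exons,
        cds_start=61,
        cds_end=543,
        sequence=seq,
        isoforms={"160aa": 160, "151aa": 151},
    )


def toy_transcript(cds: str, utr5: str = "GGGACT", utr3: str = "TGCACT") -> TranscriptModel:
    """Single-exon model around an arbitrary CDS, for oracle testing."""
    seq = utr5 + cds + utr3
    return TranscriptModel(
        transcript_id="TOY",
        strand="+",
        exons=[ExonSpan("exon1", 1, len(seq))],
        cds_start=len(utr5) + 1,
        cds_end=len(utr5) + len(cds),
        sequence=seq,
        isoforms={"toy": len(cds) // 3 - 1},
    )
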