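"""Amplicon panel and depth-profile containers.

The panel is the coordinate backbone of the copy-number analysis: an
ordered list of targeted-PCR amplicons over the MAX gene (coding exons
plus ~1 kb of upstream sequence) and the two flanking chromosome-14q
genes FNTB and FUT8, which are used as diploid reference anchors.
Coordinates are 0-based half-open, BED convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ALLOWED_GENES = ("MAX", "FNTB", "FUT8")


@dataclass(frozen=True)
class Amplicon:
    """One targeted amplicon interval."""

    chrom: str
    start: int
    end: int
    gene: str
    exon: str
    index: int

    @property
    def name(self) -> str:
        """BED name field, ``gene|exon|index``."""
        return f"{self.gene}|{self.exon}|{self.index}"

    def __post_init__(self) -> None:
        if self.gene not in ALLOWED_GENES:
            raise ValueError(f"gene {self.gene!r} not in {ALLOWED_GENES}")
        if self.end <= self.start:
            raise ValueError(
                f"amplicon {self.gene}|{self.exon}: end ({self.end}) must exceed "
                f"start ({self.start}); input may be 1-based"
            )


@dataclass
class AmpliconPanel:
    """Ordered amplicon panel, sorted by (chrom, start).

    ``gene_strand`` records each gene's transcriptional orientation so
    that "5' end" and "3' end" of a gene can be resolved from panel
    (genomic) order.
    """

    amplicons: list[Amplicon]
    gene_strand: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [(a.chrom, a.start) for a in self.amplicons]
        if keys != sorted(keys):
            raise ValueError("panel amplicons must be sorted by (chrom, start)")
        for i, a in enumerate(self.amplicons):
            if a.index != i:
                raise ValueError(
                    f"order indices must be consecutive from 0; got {a.index} at {i}"
                )
        for g in self.genes():
            self.gene_strand.setdefault(g, "+")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def genes(self) -> list[str]:
        seen: list[str] = []
        for a in self.amplicons:
            if a.gene not in seen:
                seen.append(a.gene)
        return seen

    def gene_indices(self, gene: str) -> np.ndarray:
        """Order indices of one gene's amplicons (ascending)."""
        idx = np.array([a.index for a in self.amplicons if a.gene == gene], dtype=int)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} has no amplicons in the panel")
        return idx

    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]


@dataclass
class DepthProfile:
    """Per-amplicon read counts for one sample, aligned to panel order."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("read counts must be non-negative")
        self.counts = self.counts.astype(np.int64)

    def check_panel(self, panel: AmpliconPanel) -> None:
        if len(self.counts) != len(panel):
            raise ValueError(
                f"profile {self.sample_id!r} has {len(self.counts)} counts for a "
                f"panel of {len(panel)} amplicons"
            )


def default_panel() -> AmpliconPanel:
    """The packaged 33-amplicon MAX/FNTB/FUT8 panel.

    Layout mirrors a targeted-PCR design over the MAX locus: three
    amplicons per flanking reference gene (FNTB, FUT8) and 27 MAX
    amplicons covering ~1 kb of upstream/promoter sequence and the five
    coding exons.  Coordinates are synthetic but ordered and disjoint;
    the analysis only depends on order, gene and exon labels.
    """
    spans = [
        ("FNTB", "exon1", 3),
        ("MAX", "upstream", 3),
        ("MAX", "exon1", 5),
        ("MAX", "exon2", 5),
        ("MAX", "exon3", 4),
        ("MAX", "exon4", 4),
        ("MAX", "exon5", 6),
        ("FUT8", "exon1", 3),
    ]
    amplicons: list[Amplicon] = []
    pos = 65_000_000
    idx = 0
    for gene, exon, n in spans:
        for _ in range(n):
            amplicons.append(
                Amplicon("chr14", pos, pos + 200, gene, exon, idx)
            )
            pos += 300
            idx += 1
        pos += 5_000  # inter-segment gap
    return AmpliconPanel(amplicons, gene_strand={"MAX": "+", "FNTB": "+", "FUT8": "+"})
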