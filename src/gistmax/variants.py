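"""MAX point-mutation interpretation.

Two independent questions are answered for each variant:

* **Consequence** — what the mutation does to the transcript/protein,
  determined against the packaged transcript model (nonsense, start
  loss, frameshift, splice site, 5'-UTR, missense, synonymous,
  intronic, intragenic deletion).  Splice-site calls at the invariant
  GT/AG dinucleotides list both canonical aberrant outcomes (skip of
  the adjacent exon, retention of the adjacent intron) as candidates;
  which one a tumour actually produces is an experimental question.

* **Zygosity / somatic status** — what the observed variant allele
  fraction (VAF) implies about the tumour genotype once admixed
  diploid non-neoplastic cells are accounted for.  With tumour purity
  t, the expected VAF is t/2 for a heterozygous mutation, t/(2−t) for
  a hemizygous mutation after loss of the other allele (LOH), and t
  for a copy-neutral homozygous mutation.  At t = 0.8 a hemizygous
  mutation is expected at VAF 0.8/1.2 ≈ 0.67.

HGVS support covers coding-DNA (c.) substitutions and small
deletions/insertions/duplications with intronic offsets.  Positions in
the 3'-UTR (``c.*``) are outside the targeted region and rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .transcript import TranscriptModel

CONSEQUENCE_CLASSES = (
    "nonsense",
    "frameshift",
    "start_loss",
    "splice_site",
    "utr5",
    "missense",
    "synonymous",
    "intronic",
    "intragenic_deletion",
)

ZYGOSITY_CLASSES = ("heterozygous", "hemizygous_LOH", "homozygous")

NORMAL_GENOTYPES = ("wild_type", "variant", "unavailable")


class HgvsParseError(ValueError):
    """The HGVS string is malformed or inconsistent with the transcript."""


@dataclass(frozen=True)
class HgvsPosition:
    coding_pos: int  # c. coordinate; negative for 5'-UTR
    offset: int = 0  # intronic offset (c.64+1 -> offset 1)


@dataclass
class VariantRecord:
    hgvs_c: str
    case_id: str = ""
    specimen_id: str = ""
    vaf: float | None = None
    normal_genotype: str = "unavailable"

    def __post_init__(self) -> None:
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")
        if self.normal_genotype not in NORMAL_GENOTYPES:
            raise ValueError(f"unknown normal genotype {self.normal_genotype!r}")


@dataclass
class Consequence:
    kind: str
    region: str  # e.g. "exon3", "intron4", "5'UTR"
    splice_candidates: tuple[str, ...] = ()
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in CONSEQUENCE_CLASSES:
            raise ValueError(f"unknown consequence class {self.kind!r}")


_POS = r"(?P<{0}>-?\d+)(?P<{0}_off>[+-]\d+)?"
_SUB_RE = re.compile(
    r"^c\." + _POS.format("p1") + r"(?P<ref>[ACGT])>(?P<alt>[ACGT])$"
)
_DELDUP_RE = re.compile(
    r"^c\."
    + _POS.format("p1")
    + r"(?:_" + _POS.format("p2") + r")?"
    + r"(?P<op>del|dup)(?P<seq>[ACGT]*)$"
)
_INS_RE = re.compile(
    r"^c\." + _POS.format("p1") + r"_" + _POS.format("p2") + r"ins(?P<seq>[ACGT]+)$"
)


def _parse_pos(m: re.Match, key: str) -> HgvsPosition:
    pos = int(m.group(key))
    if pos == 0:
        raise HgvsParseError("HGVS coding coordinates have no position 0")
    off = m.group(f"{key}_off")
    return HgvsPosition(pos, int(off) if off else 0)


@dataclass
class ParsedHgvs:
    kind: str  # sub | del | dup | ins
    start: HgvsPosition
    end: HgvsPosition
    ref: str = ""
    alt: str = ""


def parse_hgvs_c(hgvs: str) -> ParsedHgvs:
    hgvs = hgvs.strip()
    if "*" in hgvs:
        raise HgvsParseError(
            f"{hgvs!r}: 3'-UTR (c.*) positions are outside the targeted region"
        )
    m = _SUB_RE.match(hgvs)
    if m:
        p = _parse_pos(m, "p1")
        return ParsedHgvs("sub", p, p, ref=m.group("ref"), alt=m.group("alt"))
    m = _DELDUP_RE.match(hgvs)
    if m:
        p1 = _parse_pos(m, "p1")
        p2 = _parse_pos(m, "p2") if m.group("p2") else p1
        return ParsedHgvs(m.group("op"), p1, p2, ref=m.group("seq"))
    m = _INS_RE.match(hgvs)
    if m:
        return ParsedHgvs(
            "ins", _parse_pos(m, "p1"), _parse_pos(m, "p2"), alt=m.group("seq")
        )
    raise HgvsParseError(f"unsupported or malformed HGVS description {hgvs!r}")


def _validate_against_transcript(
    parsed: ParsedHgvs, tx: TranscriptModel, hgvs: str
) -> None:
    for p in (parsed.start, parsed.end):
        if p.offset == 0:
            tx.tx_pos(p.coding_pos)  # raises if out of range
        else:
            if abs(p.offset) >= 1 and tx.boundary_intron(p.coding_pos, p.offset) is None:
                raise HgvsParseError(
                    f"{hgvs!r}: position {p.coding_pos}{p.offset:+d} is not at an "
                    f"exon/intron boundary of {tx.transcript_id}"
                )
    if parsed.kind == "sub" and parsed.start.offset == 0:
        actual = tx.base_at(parsed.start.coding_pos)
        if actual != parsed.ref:
            raise HgvsParseError(
                f"{hgvs!r}: reference base at c.{parsed.start.coding_pos} is "
                f"{actual}, not {parsed.ref}"
            )


def classify_consequence(variant: VariantRecord, tx: TranscriptModel) -> Consequence:
    """Deterministic consequence class for one variant.

    Precedence: splice site (invariant ±1/±2 intronic offsets) and
    deeper intronic positions are resolved first; then 5'-UTR; then
    coding-sequence effects by mutating and retranslating the codon.
    """
    parsed = parse_hgvs_c(variant.hgvs_c)
    _validate_against_transcript(parsed, tx, variant.hgvs_c)
    start, end = parsed.start, parsed.end

    if start.offset != 0 or end.offset != 0:
        off = start.offset if start.offset != 0 else end.offset
        pos = start if start.offset != 0 else end
        intron = tx.boundary_intron(pos.coding_pos, off)
        if abs(off) <= 2:
            # invariant GT/AG dinucleotide; both canonical aberrant
            # outcomes are candidates
            skipped_exon = intron if off > 0 else intron + 1
            return Consequence(
                "splice_site",
                region=f"intron{intron}",
                splice_candidates=(
                    f"exon{skipped_exon}_skipping",
                    f"intron{intron}_retention",
                ),
            )
        return Consequence("intronic", region=f"intron{intron}")

    if start.coding_pos < 0:
        return Consequence("utr5", region="5'UTR")

    exon_label = tx.exon_of(start.coding_pos).label

    if parsed.kind == "sub":
        return _classify_substitution(parsed, tx, exon_label)

    # length-changing variants
    if parsed.kind == "ins":
        length_change = len(parsed.alt)
        span = (start.coding_pos, end.coding_pos)
    else:
        span = (start.coding_pos, end.coding_pos)
        n = span[1] - span[0] + 1
        length_change = n if parsed.kind == "dup" else -n

    if _spans_whole_exon(span, tx) and parsed.kind == "del":
        return Consequence("intragenic_deletion", region=exon_label)
    if length_change % 3 != 0:
        return Consequence("frameshift", region=exon_label)
    if parsed.kind == "del":
        # in-frame deletion of coding material
        return Consequence("intragenic_deletion", region=exon_label)
    raise HgvsParseError(
        f"{variant.hgvs_c!r}: in-frame insertions/duplications are not supported"
    )


def _spans_whole_exon(span: tuple[int, int], tx: TranscriptModel) -> bool:
    t1 = tx.tx_pos(span[0])
    t2 = tx.tx_pos(span[1])
    return any(t1 <= ex.tx_start and ex.tx_end <= t2 for ex in tx.exons)


def _classify_substitution(
    parsed: ParsedHgvs, tx: TranscriptModel, exon_label: str
) -> Consequence:
    pos = parsed.start.coding_pos
    cds = tx.cds
    if pos > len(cds):
        raise HgvsParseError(f"c.{pos} beyond the CDS of {tx.transcript_id}")
    codon_idx = (pos - 1) // 3
    within = (pos - 1) % 3
    codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    mutated = codon[:within] + parsed.alt + codon[within + 1 :]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(mutated).translate())
    change = f"p.{old_aa}{codon_idx + 1}{new_aa}"
    if codon_idx == 0 and mutated != "ATG":
        return Consequence("start_loss", region=exon_label, protein_change=change)
    if new_aa == "*" and old_aa != "*":
        return Consequence("nonsense", region=exon_label, protein_change=change)
    if new_aa == old_aa:
        return Consequence("synonymous", region=exon_label, protein_change=change)
    return Consequence("missense", region=exon_label, protein_change=change)


# -- purity / zygosity model ------------------------------------------------


def expected_vaf(zygosity: str, purity: float) -> float:
    """Expected tumour VAF for a zygosity class at tumour purity t.

    heterozygous: t/2 — one of two alleles, diluted by 2 normal alleles;
    hemizygous_LOH: t/(2−t) — one tumour allele of (t + 2(1−t)) total;
    homozygous: t — both tumour alleles mutant, copy-neutral.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    if zygosity == "heterozygous":
        return purity / 2.0
    if zygosity == "hemizygous_LOH":
        return purity / (2.0 - purity)
    if zygosity == "homozygous":
        return purity
    raise ValueError(f"unknown zygosity class {zygosity!r}")


def _purity_range(zygosity: str, vaf: float, tolerance: float) -> tuple[float, float] | None:
    """Purity interval (clipped to (0, 1]) where the class expectation is
    within ``tolerance`` of the observed VAF, or None if empty."""
    lo_v, hi_v = max(vaf - tolerance, 0.0), min(vaf + tolerance, 1.0)
    if zygosity == "heterozygous":
        lo, hi = 2 * lo_v, 2 * hi_v
    elif zygosity == "hemizygous_LOH":
        lo, hi = 2 * lo_v / (1 + lo_v), 2 * hi_v / (1 + hi_v)
    elif zygosity == "homozygous":
        lo, hi = lo_v, hi_v
    else:
        raise ValueError(f"unknown zygosity class {zygosity!r}")
    lo, hi = max(lo, 1e-9), min(hi, 1.0)
    return (lo, hi) if lo <= hi else None


@dataclass
class ZygosityInference:
    observed_vaf: float
    purity: float | None
    tolerance: float
    classes: tuple[str, ...]  # compatible classes, best first
    expected: dict[str, float] = field(default_factory=dict)
    purity_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return len(self.classes) > 1

    @property
    def best(self) -> str | None:
        return self.classes[0] if self.classes else None


def infer_zygosity(
    observed_vaf: float,
    purity: float | None = None,
    tolerance: float = 0.05,
) -> ZygosityInference:
    """Classify an observed VAF under the purity model.

    With known purity the nearest-expectation class is returned; every
    class within ``tolerance`` of the observation joins the ambiguous
    set (e.g. a VAF of 0.7 with no matched normal is consistent with
    either a hemizygous or a homozygous somatic mutation).  With
    unknown purity, the purity interval compatible with each class is
    reported instead.
    """
    if not 0.0 <= observed_vaf <= 1.0:
        raise ValueError("observed VAF must be in [0, 1]")
    if purity is None:
        ranges = {}
        for z in ZYGOSITY_CLASSES:
            r = _purity_range(z, observed_vaf, tolerance)
            if r is not None:
                ranges[z] = r
        return ZygosityInference(
            observed_vaf, None, tolerance, tuple(ranges), purity_ranges=ranges
        )
    expected = {z: expected_vaf(z, purity) for z in ZYGOSITY_CLASSES}
    by_dist = sorted(ZYGOSITY_CLASSES, key=lambda z: abs(expected[z] - observed_vaf))
    within = tuple(z for z in by_dist if abs(expected[z] - observed_vaf) <= tolerance)
    classes = within if within else (by_dist[0],)
    return ZygosityInference(observed_vaf, purity, tolerance, classes, expected)


def somatic_status(
    variant: VariantRecord,
    plausible_purity: tuple[float, float] = (0.5, 1.0),
    tolerance: float = 0.05,
) -> str:
    """Somatic vs germline call for one variant.

    A matched-normal genotype decides directly.  Without a normal, a
    VAF incompatible with a heterozygous germline variant but
    compatible with a hemizygous or homozygous state at plausible
    tumour purity is ``consistent_with_somatic``; anything else is
    ``indeterminate``.
    """
    if variant.normal_genotype == "wild_type":
        return "somatic"
    if variant.normal_genotype == "variant":
        return "germline"
    if variant.vaf is None:
        return "indeterminate"
    inf = infer_zygosity(variant.vaf, purity=None, tolerance=tolerance)

    def overlaps(z: str) -> bool:
        r = inf.purity_ranges.get(z)
        return r is not None and r[0] <= plausible_purity[1] and r[1] >= plausible_purity[0]

    if overlaps("heterozygous"):
        return "indeterminate"
    if overlaps("hemizygous_LOH") or overlaps("homozygous"):
        return "consistent_with_somatic"
    return "indeterminate"


@dataclass
class ConcordanceReport:
    concordant: bool
    shared: tuple[str, ...]
    discordant: dict[str, tuple[str, ...]]  # specimen -> private variants


def concordance_across_specimens(
    specimen_variants: dict[str, list[str] | set[str]],
) -> ConcordanceReport:
    """Compare variant sets (by HGVS string) across specimens of one patient.

    Anatomically distinct specimens of a clonal tumour are expected to
    share identical mutations; any variant private to a subset of
    specimens is listed as discordant.
    """
    if len(specimen_variants) < 2:
        raise ValueError("concordance requires at least two specimens")
    sets = {k: frozenset(v) for k, v in specimen_variants.items()}
    shared = frozenset.intersection(*sets.values())
    discordant = {
        k: tuple(sorted(s - shared)) for k, s in sets.items() if s - shared
    }
    return ConcordanceReport(
        concordant=not discordant,
        shared=tuple(sorted(shared)),
        discordant=discordant,
    )
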