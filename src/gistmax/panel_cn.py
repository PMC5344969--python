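"""Homozygous-deletion calling from targeted-amplicon read depths.

Tumour depths are normalized against a paired non-neoplastic profile
(median-of-ratios library scaling) to give a per-amplicon ratio track.
A tumour with purity t (non-neoplastic fraction f = 1 − t) and tumour
copy state c at an amplicon has expected ratio ``t·c/2 + (1 − t)``: a
homozygous deletion therefore floors at f, not at zero, and the calling
cutoff is purity-informed — f + margin, i.e. 0.4 at 30% non-neoplastic
content and 0.3 at 20%.

Two criteria define a homozygous deletion, applied as a union:

* run criterion — at least ``min_run`` (default 9) consecutive
  amplicons of one gene below the cutoff;
* gene-end criterion — the mean ratio of the terminal amplicons at
  either gene end, relative to the mean over all of the case's
  markers, below an end threshold (default 0.4).

Flanking-gene amplicons (FNTB, FUT8) act as diploid anchors and never
join a MAX run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import AmpliconPanel, DepthProfile

#: flanking genes serving as diploid anchors for library scaling
REFERENCE_GENES = ("FNTB", "FUT8")

#: non-neoplastic fraction assumed per risk class
RISK_CLASS_NORMAL_FRACTION = {
    "low": 0.30,
    "intermediate": 0.30,
    "high": 0.20,
    "metastatic": 0.20,
}

DEFAULT_MIN_RUN = 9
DEFAULT_END_SIZE = 5
DEFAULT_MARGIN = 0.10
DEFAULT_END_THRESHOLD = 0.4
MASK_FRACTION_LIMIT = 0.20


class CutoffConflictWarning(UserWarning):
    """The homozygous cutoff reaches the hemizygous expectation."""


@dataclass
class RatioTrack:
    """Per-amplicon normalized tumour/normal depth ratios."""

    ratios: np.ndarray
    mask: np.ndarray  # True where the amplicon is unusable (zero normal depth)
    method: str
    reference_id: str
    sample_id: str = ""
    quality_failed: bool = False

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.ratios.shape != self.mask.shape:
            raise ValueError("ratios and mask must align")
        if np.any(self.ratios[~self.mask] < 0):
            raise ValueError("ratios must be non-negative")


@dataclass
class DeletionCall:
    gene: str
    criteria: tuple[str, ...]  # subset of {"consecutive_run", "end_ratio"}
    first_index: int
    last_index: int
    mean_ratio: float
    cutoff: float
    zygosity: str = "homozygous"

    @property
    def span_length(self) -> int:
        return self.last_index - self.first_index + 1


@dataclass
class Run:
    gene: str
    first_index: int
    last_index: int
    mean_ratio: float

    @property
    def length(self) -> int:
        return self.last_index - self.first_index + 1


def normalize_depths(
    tumour: DepthProfile, normal: DepthProfile, panel: AmpliconPanel
) -> RatioTrack:
    """Normalized per-amplicon tumour/normal ratio track.

    Library-size scaling is the median of per-amplicon count ratios
    over the flanking diploid anchor genes (FNTB, FUT8) — the copy
    state of the target gene must not influence the scale, or a large
    deletion would bias its own ratios upward.  With fewer than four
    usable anchor amplicons the median over the whole panel is used
    instead, and total-count scaling when more than half the amplicons
    are masked.  Amplicons with zero normal depth are masked, never
    silently dropped; a track with >20% masked amplicons is flagged as
    quality-failed.
    """
    tumour.check_panel(panel)
    normal.check_panel(panel)
    t = tumour.counts.astype(float)
    n = normal.counts.astype(float)
    if not np.any(t > 0):
        raise ValueError(f"tumour profile {tumour.sample_id!r} has no reads")
    mask = n == 0
    usable = ~mask
    raw = np.full_like(t, np.nan)
    raw[usable] = t[usable] / n[usable]
    anchor = usable & np.array([a.gene in REFERENCE_GENES for a in panel])
    if anchor.sum() >= 4:
        method = "median_of_ratios_anchor"
        size_factor = float(np.median(raw[anchor]))
    elif mask.mean() > 0.5:
        method = "total_count"
        size_factor = t[usable].sum() / n[usable].sum()
    else:
        method = "median_of_ratios"
        size_factor = float(np.median(raw[usable]))
    if size_factor <= 0:
        raise ValueError("degenerate library-size factor; tumour depths all zero?")
    ratios = raw / size_factor
    ratios[mask] = np.nan
    return RatioTrack(
        ratios=np.where(mask, 0.0, ratios),
        mask=mask,
        method=method,
        reference_id=normal.sample_id,
        sample_id=tumour.sample_id,
        quality_failed=bool(mask.mean() > MASK_FRACTION_LIMIT),
    )


def expected_ratio(copy_state: int, purity: float) -> float:
    """Expected depth ratio for a tumour copy state under admixture.

    ``t·c/2 + (1 − t)`` — e.g. a homozygous deletion (c = 0) at purity
    0.70 leaves a ratio of 0.30, contributed entirely by the
    non-neoplastic cells.
    """
    if copy_state not in (0, 1, 2):
        raise ValueError(f"copy state must be 0, 1 or 2; got {copy_state}")
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must be in (0, 1]")
    return purity * copy_state / 2.0 + (1.0 - purity)


def hom_del_cutoff(non_neoplastic_fraction: float, margin: float = DEFAULT_MARGIN) -> float:
    """Ratio cutoff for homozygous deletion at a given admixture level.

    ``fraction + margin``: 30% non-neoplastic content with the default
    0.10 margin gives the working cutoff of 0.4; 20% gives 0.3.  A
    cutoff at or above the hemizygous expectation for the same purity
    would conflate single-copy loss with homozygous deletion and
    triggers a warning (the value is capped just below it).
    """
    if not 0.0 <= non_neoplastic_fraction < 1.0:
        raise ValueError("non-neoplastic fraction must be in [0, 1)")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    cutoff = non_neoplastic_fraction + margin
    hemi = expected_ratio(1, 1.0 - non_neoplastic_fraction)
    if cutoff >= hemi:
        warnings.warn(
            f"cutoff {cutoff:.3f} reaches the hemizygous expectation {hemi:.3f}; "
            "criteria would conflate hemizygous and homozygous loss",
            CutoffConflictWarning,
            stacklevel=2,
        )
        cutoff = np.nextafter(hemi, 0.0)
    return float(cutoff)


def scan_consecutive(
    track: RatioTrack,
    panel: AmpliconPanel,
    cutoff: float,
    min_run: int = DEFAULT_MIN_RUN,
) -> list[Run]:
    """Maximal runs of consecutive below-cutoff amplicons within one gene.

    Runs never cross gene boundaries and are broken by masked
    amplicons (conservative: no interpolation across missing data).
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    runs: list[Run] = []
    for gene in panel.genes():
        idx = panel.gene_indices(gene)
        start = None
        for pos, i in enumerate(idx):
            below = (not track.mask[i]) and track.ratios[i] < cutoff
            breaks = pos > 0 and idx[pos - 1] != i - 1  # non-adjacent order index
            if start is not None and (not below or breaks):
                _close_run(runs, gene, idx, start, pos - 1, track, min_run)
                start = None
            if below and start is None:
                start = pos
        if start is not None:
            _close_run(runs, gene, idx, start, len(idx) - 1, track, min_run)
    return runs


def _close_run(runs, gene, idx, start_pos, end_pos, track, min_run) -> None:
    length = end_pos - start_pos + 1
    if length >= min_run:
        span = idx[start_pos : end_pos + 1]
        runs.append(
            Run(gene, int(span[0]), int(span[-1]), float(track.ratios[span].mean()))
        )


@dataclass
class EndRatioResult:
    gene: str
    five_prime: float
    three_prime: float
    end_size: int
    five_prime_span: tuple[int, int]
    three_prime_span: tuple[int, int]


def end_ratio(
    track: RatioTrack,
    panel: AmpliconPanel,
    gene: str = "MAX",
    end_size: int = DEFAULT_END_SIZE,
) -> EndRatioResult:
    """Gene-end statistics: mean ratio of the terminal ``end_size``
    amplicons at each gene end, relative to the mean ratio over all of
    the case's (unmasked) markers.

    Ends are labelled 5'/3' by the gene's strand.
    """
    idx = panel.gene_indices(gene)
    if end_size < 1 or 2 * end_size > len(idx):
        raise ValueError(
            f"end_size {end_size} needs a gene with >= {2 * end_size} amplicons; "
            f"{gene} has {len(idx)}"
        )
    usable = ~track.mask
    if not np.any(usable):
        raise ValueError("track has no usable amplicons")
    overall = float(track.ratios[usable].mean())
    low_end = idx[:end_size]
    high_end = idx[-end_size:]

    def stat(span: np.ndarray) -> float:
        ok = span[usable[span]]
        if ok.size == 0:
            return float("nan")
        return float(track.ratios[ok].mean() / overall)

    strand = panel.gene_strand.get(gene, "+")
    if strand == "+":
        five, three = low_end, high_end
    else:
        five, three = high_end, low_end
    return EndRatioResult(
        gene=gene,
        five_prime=stat(five),
        three_prime=stat(three),
        end_size=end_size,
        five_prime_span=(int(five[0]), int(five[-1])),
        three_prime_span=(int(three[0]), int(three[-1])),
    )


@dataclass
class CallerParams:
    """Cutoff resolution for :func:`call_deletions`.

    One of ``cutoff``, ``purity``, ``non_neoplastic_fraction`` or
    ``risk_class`` must determine the run cutoff; an explicit cutoff
    wins.  The gene-end criterion uses the fixed published threshold
    by default, or the derived cutoff when ``end_threshold`` is None.
    """

    purity: float | None = None
    non_neoplastic_fraction: float | None = None
    risk_class: str | None = None
    cutoff: float | None = None
    margin: float = DEFAULT_MARGIN
    min_run: int = DEFAULT_MIN_RUN
    end_size: int = DEFAULT_END_SIZE
    end_threshold: float | None = DEFAULT_END_THRESHOLD

    def resolve_cutoff(self) -> float:
        if self.cutoff is not None:
            return self.cutoff
        f = self.non_neoplastic_fraction
        if f is None and self.purity is not None:
            f = 1.0 - self.purity
        if f is None and self.risk_class is not None:
            try:
                f = RISK_CLASS_NORMAL_FRACTION[self.risk_class]
            except KeyError:
                raise ValueError(f"unknown risk class {self.risk_class!r}") from None
        if f is None:
            raise ValueError(
                "caller params need a cutoff, purity, non-neoplastic fraction "
                "or risk class"
            )
        return hom_del_cutoff(f, self.margin)


@dataclass
class QualityError:
    sample_id: str
    reason: str


def call_deletions(
    track: RatioTrack,
    panel: AmpliconPanel,
    params: CallerParams | None = None,
    gene: str = "MAX",
) -> tuple[list[DeletionCall], list[QualityError]]:
    """Homozygous-deletion calls for one case (run ∪ gene-end criteria).

    Calls from the two criteria that overlap by at least one amplicon
    are merged into a single call annotated with both criteria.  A
    quality-failed track yields no calls plus a quality error record.
    """
    params = params or CallerParams()
    if track.quality_failed:
        return [], [
            QualityError(
                track.sample_id,
                f">{MASK_FRACTION_LIMIT:.0%} of amplicons masked; track fails QC",
            )
        ]
    cutoff = params.resolve_cutoff()
    end_threshold = params.end_threshold if params.end_threshold is not None else cutoff

    calls: list[DeletionCall] = []
    for run in scan_consecutive(track, panel, cutoff, params.min_run):
        if run.gene != gene:
            continue
        calls.append(
            DeletionCall(
                gene, ("consecutive_run",), run.first_index, run.last_index,
                run.mean_ratio, cutoff,
            )
        )

    er = end_ratio(track, panel, gene=gene, end_size=params.end_size)
    for stat, span in (
        (er.five_prime, er.five_prime_span),
        (er.three_prime, er.three_prime_span),
    ):
        if np.isfinite(stat) and stat < end_threshold:
            lo, hi = min(span), max(span)
            sub = np.arange(lo, hi + 1)
            ok = sub[~track.mask[sub]]
            calls.append(
                DeletionCall(
                    gene, ("end_ratio",), lo, hi,
                    float(track.ratios[ok].mean()) if ok.size else float("nan"),
                    end_threshold,
                )
            )

    return _merge_overlapping(calls, track), []


def _merge_overlapping(calls: list[DeletionCall], track: RatioTrack) -> list[DeletionCall]:
    calls = sorted(calls, key=lambda c: (c.first_index, c.last_index))
    merged: list[DeletionCall] = []
    for call in calls:
        if merged and call.first_index <= merged[-1].last_index:
            prev = merged[-1]
            lo = min(prev.first_index, call.first_index)
            hi = max(prev.last_index, call.last_index)
            span = np.arange(lo, hi + 1)
            ok = span[~track.mask[span]]
            merged[-1] = DeletionCall(
                prev.gene,
                tuple(dict.fromkeys(prev.criteria + call.criteria)),
                lo,
                hi,
                float(track.ratios[ok].mean()) if ok.size else float("nan"),
                min(prev.cutoff, call.cutoff),
            )
        else:
            merged.append(call)
    return merged
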