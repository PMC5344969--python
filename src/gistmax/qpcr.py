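"""Relative copy-number estimation from qPCR threshold cycles.

MAX copy number is estimated by the comparative-Ct (ΔΔCt) method: the
target assays are MAX exons 1, 3 and 4 and the reference assays are the
flanking 14q genes FNTB and FUT8, with a non-neoplastic DNA sample as
the calibrator.  Copies per diploid genome are ``2 * E**(-ΔΔCt)`` with
amplification efficiency E (default 2.0, i.e. perfect doubling per
cycle).  Mixture utilities model the dilution of a tumour deletion
signal by non-neoplastic DNA, as in 30:70 and 20:80 normal:tumour
control mixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

MAX_TARGETS = ("MAX_ex1", "MAX_ex3", "MAX_ex4")
REFERENCE_TARGETS = ("FNTB", "FUT8")
ALL_TARGETS = MAX_TARGETS + REFERENCE_TARGETS
SAMPLE_TYPES = ("tumour", "normal_control", "mixture", "NTC")

#: Ct beyond which amplification is treated as absent (censored).
DEFAULT_LATE_CUTOFF = 38.0
#: replicate standard deviation above which a group is flagged.
DEFAULT_SD_THRESHOLD = 0.5


class QpcrContaminationError(RuntimeError):
    """A no-template control amplified earlier than the late cutoff."""


@dataclass(frozen=True)
class QpcrWell:
    well: str
    sample_id: str
    sample_type: str
    target: str
    replicate: int
    ct: float | None  # None = no amplification

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.target not in ALL_TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.ct is not None and self.ct < 0:
            raise ValueError("Ct must be non-negative")


@dataclass
class QpcrRun:
    wells: list[QpcrWell]

    def samples(self) -> list[str]:
        seen: list[str] = []
        for w in self.wells:
            if w.sample_type != "NTC" and w.sample_id not in seen:
                seen.append(w.sample_id)
        return seen

    def sample_type(self, sample_id: str) -> str:
        for w in self.wells:
            if w.sample_id == sample_id and w.sample_type != "NTC":
                return w.sample_type
        raise KeyError(sample_id)


@dataclass
class CtSummary:
    """Mean replicate Ct for one (sample, target) group."""

    sample_id: str
    target: str
    mean_ct: float
    sd_ct: float
    n_replicates: int
    flags: list[str] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return "censored" in self.flags


@dataclass
class CopyNumberEstimate:
    sample_id: str
    target: str
    ddct: float
    copies: float
    flags: list[str] = field(default_factory=list)

    @property
    def is_upper_bound(self) -> bool:
        return "upper_bound" in self.flags


def aggregate_replicates(
    run: QpcrRun,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    late_cutoff: float = DEFAULT_LATE_CUTOFF,
) -> dict[tuple[str, str], CtSummary]:
    """Collapse replicate wells to per-(sample, target) mean Ct.

    Absent Ct values are censored at ``late_cutoff`` and the group is
    flagged ``censored``; groups with replicate sd above
    ``sd_threshold`` are flagged ``high_dispersion``.  Any NTC well
    amplifying before ``late_cutoff`` aborts the whole run.
    """
    for w in run.wells:
        if w.sample_type == "NTC" and w.ct is not None and w.ct < late_cutoff:
            raise QpcrContaminationError(
                f"NTC well {w.well} amplified at Ct {w.ct:.2f} "
                f"(< late cutoff {late_cutoff:.1f}); run is contaminated"
            )

    groups: dict[tuple[str, str], list[float | None]] = {}
    for w in run.wells:
        if w.sample_type == "NTC":
            continue
        groups.setdefault((w.sample_id, w.target), []).append(w.ct)

    out: dict[tuple[str, str], CtSummary] = {}
    for (sid, target), cts in groups.items():
        flags: list[str] = []
        vals = []
        for ct in cts:
            if ct is None or ct > late_cutoff:
                vals.append(late_cutoff)
                if "censored" not in flags:
                    flags.append("censored")
            else:
                vals.append(ct)
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=0))
        if sd > sd_threshold:
            flags.append("high_dispersion")
        out[(sid, target)] = CtSummary(sid, target, float(arr.mean()), sd, len(arr), flags)
    return out


def _delta_ct(
    summaries: dict[tuple[str, str], CtSummary],
    sample_id: str,
    target: str,
    reference_targets: tuple[str, ...],
) -> tuple[float, list[str]]:
    """ΔCt = Ct(target) - mean Ct(references) for one sample."""
    try:
        tgt = summaries[(sample_id, target)]
    except KeyError:
        raise KeyError(f"no wells for sample {sample_id!r}, target {target!r}") from None
    refs = []
    for r in reference_targets:
        try:
            refs.append(summaries[(sample_id, r)])
        except KeyError:
            raise KeyError(f"no reference wells for sample {sample_id!r}, target {r!r}") from None
    flags = list(tgt.flags)
    for r in refs:
        for f in r.flags:
            tag = f"reference_{f}"
            if tag not in flags:
                flags.append(tag)
    # arithmetic mean of reference Ct == geometric mean of template quantity
    ref_ct = float(np.mean([r.mean_ct for r in refs]))
    return tgt.mean_ct - ref_ct, flags


def copy_number(
    run: QpcrRun,
    target: str = "MAX_ex1",
    reference_targets: tuple[str, ...] = REFERENCE_TARGETS,
    normal_sample: str | None = None,
    efficiency: float = 2.0,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    late_cutoff: float = DEFAULT_LATE_CUTOFF,
) -> list[CopyNumberEstimate]:
    """ΔΔCt copy-number estimate for every non-control sample.

    ``ΔΔCt = ΔCt(sample) − ΔCt(normal control)``;
    ``copies = 2·efficiency**(−ΔΔCt)``.  A censored target Ct makes the
    estimate an upper bound (flag ``upper_bound``).
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    if not reference_targets:
        raise ValueError("at least one reference target is required")
    summaries = aggregate_replicates(run, sd_threshold=sd_threshold, late_cutoff=late_cutoff)

    if normal_sample is None:
        normals = [s for s in run.samples() if run.sample_type(s) == "normal_control"]
        if not normals:
            raise ValueError("run has no normal_control sample; ΔΔCt needs a calibrator")
        normal_sample = normals[0]
    dct_normal, _ = _delta_ct(summaries, normal_sample, target, reference_targets)

    out: list[CopyNumberEstimate] = []
    for sid in run.samples():
        if sid == normal_sample:
            continue
        dct, flags = _delta_ct(summaries, sid, target, reference_targets)
        ddct = dct - dct_normal
        copies = 2.0 * efficiency ** (-ddct)
        if "censored" in flags:
            flags = [f for f in flags if f != "censored"] + ["upper_bound"]
        out.append(CopyNumberEstimate(sid, target, ddct, copies, flags))
    return out


def copy_number_summary(
    run: QpcrRun,
    targets: tuple[str, ...] = MAX_TARGETS,
    **kwargs,
) -> dict[str, float]:
    """Mean copy number per sample across the MAX target assays."""
    per_sample: dict[str, list[float]] = {}
    for t in targets:
        for est in copy_number(run, target=t, **kwargs):
            per_sample.setdefault(est.sample_id, []).append(est.copies)
    return {sid: float(np.mean(v)) for sid, v in per_sample.items()}


def mixture_expected_cn(normal_fraction: float, tumour_copies: float) -> float:
    """Copies per diploid genome of a normal:tumour DNA mixture.

    Linear in both arguments: ``2·f + (1−f)·c`` for normal fraction f
    and tumour copy number c.
    """
    if not 0.0 <= normal_fraction <= 1.0:
        raise ValueError("normal_fraction must be in [0, 1]")
    if tumour_copies < 0:
        raise ValueError("tumour_copies must be non-negative")
    return 2.0 * normal_fraction + (1.0 - normal_fraction) * tumour_copies


def estimate_normal_fraction(copies: float, tumour_copies: float = 0.0) -> float:
    """Invert :func:`mixture_expected_cn` at a known tumour copy state.

    For a homozygous deletion (tumour copies 0) this recovers the
    non-neoplastic DNA fraction of the specimen from its measured
    copy number.
    """
    if math.isclose(tumour_copies, 2.0):
        raise ValueError("tumour copy 2 carries no mixture information")
    f = (copies - tumour_copies) / (2.0 - tumour_copies)
    return float(min(1.0, max(0.0, f)))
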