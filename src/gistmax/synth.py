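"""Synthetic-data generators for the MAX/GIST analysis.

Everything the pipeline consumes can be simulated here with the
statistical structure the analysis assumes:

* paired tumour/non-neoplastic amplicon depth profiles with shared
  per-amplicon efficiency factors and negative-binomial count noise,
  under configurable tumour purity and per-amplicon copy genotypes
  (defaults 0.70/0.80 purity, matching the 30%/20% non-neoplastic
  content assumed for low-/intermediate- vs high-risk/metastatic
  tumours);
* qPCR Ct tables for normal:tumour DNA mixtures (e.g. the 30:70 and
  20:80 deletion-detection controls), with replicates and no-template
  control wells;
* stratified Bernoulli cohort tables;
* variant records consistent with the packaged transcript model.

A deterministic 76-case cohort fixture mirrors the published marginal
counts (16/76 genomic mutants; 11/64 sporadic and 5/10 NF-1; 31/64 and
9/10 protein loss; 38/75 immunoblot; 14/22 IHC; aetiology 52/8/11/2
KIT/PDGFRA/NF1/SDH; 5 unknown primary sites), together with an 8-row
micro-GIST companion table (3 with MAX loss, each with 14q deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import AmpliconPanel, DepthProfile, default_panel
from .qpcr import ALL_TARGETS, MAX_TARGETS, REFERENCE_TARGETS, QpcrRun, QpcrWell
from .transcript import TranscriptModel, load_max_transcript
from .variants import VariantRecord

__all__ = [
    "SimulationConfig",
    "gen_depth_profile",
    "gist48_genotype",
    "gen_qpcr_run",
    "CohortSpec",
    "StratumSpec",
    "gen_cohort",
    "fixture_cohort",
    "micro_gist_fixture",
    "gen_variant_set",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; identical seed + config give identical output.

    ``depth_dispersion`` is the negative-binomial overdispersion alpha
    (variance = mu + alpha·mu²); zero switches every generator to its
    deterministic expectation.  ``efficiency_sd`` is the log-normal
    sigma of per-amplicon amplification factors, drawn once per panel
    and shared between the paired tumour and normal profiles.
    """

    purity: float = 0.80
    genotype_map: dict[str, int] = field(default_factory=dict)
    mean_depth: float = 500.0
    depth_dispersion: float = 0.002
    ct_noise_sd: float = 0.2
    pcr_efficiency: float = 2.0
    efficiency_sd: float = 0.15
    ct_intercept: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must be in (0, 1]; got {self.purity}")
        for name, value in self.genotype_map.items():
            if value not in (0, 1, 2):
                raise ValueError(
                    f"genotype_map[{name!r}] must be a copy state in {{0, 1, 2}}; "
                    f"got {value}"
                )
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be non-negative")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be non-negative")
        if not 1.0 < self.pcr_efficiency <= 2.0:
            raise ValueError("pcr_efficiency must be in (1, 2]")
        if self.efficiency_sd < 0:
            raise ValueError("efficiency_sd must be non-negative")


def gist48_genotype(panel: AmpliconPanel) -> dict[str, int]:
    """Homozygous deletion of MAX exons 1 and 2 (GIST48-like genotype)."""
    return {
        a.name: 0
        for a in panel
        if a.gene == "MAX" and a.exon in ("exon1", "exon2")
    }


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative-binomial counts with variance mu + alpha·mu²; alpha 0 is
    the deterministic expectation (rounded)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    if alpha == 0:
        out[pos] = np.round(mu[pos])
    else:
        size = 1.0 / alpha
        p = size / (size + mu[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out.astype(np.int64)


def gen_depth_profile(
    panel: AmpliconPanel,
    config: SimulationConfig,
    tumour_id: str = "tumour",
    normal_id: str = "normal",
) -> tuple[DepthProfile, DepthProfile]:
    """Paired tumour and normal depth profiles over the panel.

    The normal sample is diploid everywhere; the tumour's expected
    depth at each amplicon is scaled by ``purity·c/2 + (1 − purity)``
    for tumour copy state c (default 2).  Per-amplicon efficiency
    factors are drawn once and shared by the pair, so that paired
    normalization cancels them.
    """
    if len(panel) == 0:
        raise ValueError("panel is empty")
    names = set(panel.names())
    for key in config.genotype_map:
        if key not in names:
            raise ValueError(f"genotype_map names unknown amplicon {key!r}")
    rng = np.random.default_rng(config.seed)
    if config.efficiency_sd > 0:
        eff = rng.lognormal(mean=0.0, sigma=config.efficiency_sd, size=len(panel))
    else:
        eff = np.ones(len(panel))
    copies = np.array(
        [config.genotype_map.get(a.name, 2) for a in panel], dtype=float
    )
    scale = config.purity * copies / 2.0 + (1.0 - config.purity)
    mu_normal = config.mean_depth * eff
    mu_tumour = mu_normal * scale
    normal = DepthProfile(
        normal_id, _nb_counts(rng, mu_normal, config.depth_dispersion)
    )
    tumour = DepthProfile(
        tumour_id, _nb_counts(rng, mu_tumour, config.depth_dispersion)
    )
    return tumour, normal


def gen_qpcr_run(
    config: SimulationConfig,
    mixture_normal_fraction: float,
    tumour_copy_state: int,
    n_replicates: int = 3,
    sample_id: str = "mixture",
) -> QpcrRun:
    """Simulated qPCR plate for one normal:tumour DNA mixture.

    Template quantity at the MAX targets is the mixture copy number
    ``2·f + (1 − f)·c``; reference targets (FNTB, FUT8) always carry
    two copies.  Ct follows textbook kinetics,
    ``Ct = intercept − log(q)/log(E)`` plus Gaussian replicate noise;
    zero template never amplifies.  The plate carries the mixture
    sample, a normal control and no-template control wells.
    """
    if not 0.0 <= mixture_normal_fraction <= 1.0:
        raise ValueError("mixture fraction must be in [0, 1]")
    if tumour_copy_state not in (0, 1, 2):
        raise ValueError("tumour copy state must be 0, 1 or 2")
    if n_replicates < 1:
        raise ValueError("at least one replicate is required")
    rng = np.random.default_rng(config.seed)
    f = mixture_normal_fraction
    mix_copies = 2.0 * f + (1.0 - f) * tumour_copy_state
    sample_type = "normal_control" if f == 1.0 else "mixture"

    def ct_for(quantity: float) -> float | None:
        if quantity <= 0:
            return None
        ct = config.ct_intercept - math.log(quantity) / math.log(config.pcr_efficiency)
        if config.ct_noise_sd > 0:
            ct += rng.normal(0.0, config.ct_noise_sd)
        return max(ct, 0.0)

    wells: list[QpcrWell] = []
    well_no = 0

    def add(sample: str, stype: str, target: str, quantity: float | None) -> None:
        nonlocal well_no
        for rep in range(1, n_replicates + 1):
            well_no += 1
            ct = None if quantity is None else ct_for(quantity)
            wells.append(
                QpcrWell(f"W{well_no:03d}", sample, stype, target, rep, ct)
            )

    for target in ALL_TARGETS:
        quantity = mix_copies if target in MAX_TARGETS else 2.0
        add(sample_id, sample_type, target, quantity)
    if sample_type != "normal_control":
        for target in ALL_TARGETS:
            add("normal", "normal_control", target, 2.0)
    for target in ALL_TARGETS:
        well_no += 1
        wells.append(QpcrWell(f"W{well_no:03d}", "NTC", "NTC", target, 1, None))
    return QpcrRun(wells)


# -- cohort generation ------------------------------------------------------

RISK_CLASSES = ("low", "intermediate", "high", "metastatic")

COHORT_COLUMNS = [
    "case_id",
    "aetiology",
    "group",
    "site",
    "risk_class",
    "genomic_max",
    "immunoblot_expression",
    "ihc_status",
]


@dataclass(frozen=True)
class StratumSpec:
    """Per-stratum case count and event probabilities."""

    name: str
    n: int
    p_genomic: float
    p_protein_loss: float
    p_gastric: float = 0.5
    aetiology: str = "KIT"
    risk_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.35, 0.15)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("case count must be non-negative")
        for p in (self.p_genomic, self.p_protein_loss, self.p_gastric):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    strata: tuple[StratumSpec, ...]


def default_cohort_spec() -> CohortSpec:
    """Probabilities matching the published stratum frequencies."""
    return CohortSpec(
        strata=(
            StratumSpec("sporadic", 64, p_genomic=11 / 64, p_protein_loss=31 / 64,
                        p_gastric=0.6, aetiology="KIT"),
            StratumSpec("nf1_syndromic", 10, p_genomic=0.5, p_protein_loss=0.9,
                        p_gastric=0.0, aetiology="NF1"),
        )
    )


def gen_cohort(spec: CohortSpec, seed: int = 0) -> pd.DataFrame:
    """Stratified Bernoulli cohort table (one row per case)."""
    rng = np.random.default_rng(seed)
    rows = []
    case = 0
    for stratum in spec.strata:
        for _ in range(stratum.n):
            case += 1
            mutant = rng.random() < stratum.p_genomic
            loss = rng.random() < stratum.p_protein_loss
            gastric = rng.random() < stratum.p_gastric
            risk = RISK_CLASSES[
                rng.choice(len(RISK_CLASSES), p=np.asarray(stratum.risk_weights))
            ]
            # immunoblot expression consistent with the loss state
            expr = rng.uniform(0.05, 0.35) if loss else rng.uniform(0.5, 1.2)
            rows.append(
                {
                    "case_id": f"S{case:03d}",
                    "aetiology": stratum.aetiology,
                    "group": stratum.name,
                    "site": "gastric" if gastric else "non_gastric",
                    "risk_class": risk,
                    "genomic_max": "mutant" if mutant else "wild_type",
                    "immunoblot_expression": round(float(expr), 3),
                    "ihc_status": "untested",
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def fixture_cohort() -> pd.DataFrame:
    """Deterministic 76-case cohort reproducing every printed marginal.

    Construction (not sampled): 64 sporadic cases (52 KIT, 8 PDGFRA,
    1 somatic NF1, 3 quadruple-wild-type), 10 NF-1-syndromic cases and
    2 SDH-deficient cases.  Within these: 16 genomic mutants (11
    sporadic, 5 NF-1); 38/75 immunoblot losses plus one IHC-only case
    and one mosaic case detected only by IHC, yielding 31 sporadic and
    9 NF-1 protein losses; 22 IHC-tested cases with 14 losses; 5 cases
    of unknown primary site.
    """
    rows: list[dict] = []

    def add(case_id, aetiology, group, site, risk, mutant, expr, ihc):
        rows.append(
            {
                "case_id": case_id,
                "aetiology": aetiology,
                "group": group,
                "site": site,
                "risk_class": risk,
                "genomic_max": "mutant" if mutant else "wild_type",
                "immunoblot_expression": expr,
                "ihc_status": ihc,
            }
        )

    # low/retained expression values cycle for a little realism
    lo = [0.05, 0.12, 0.18, 0.25, 0.31, 0.35, 0.08, 0.22]
    hi = [0.52, 0.64, 0.78, 0.91, 1.05, 0.58, 0.85, 1.16]

    for i in range(1, 65):  # sporadic cases S001..S064
        cid = f"S{i:03d}"
        aet = "KIT" if i <= 52 else ("PDGFRA" if i <= 60 else ("NF1" if i == 61 else "unknown"))
        mutant = i <= 9 or i == 53 or i == 62
        # protein truth: 31 losses = mutants (11) + non-mutants 10..27 (18)
        #                + IHC-only case 28 + mosaic case 29
        loss = mutant or 10 <= i <= 29
        if i == 28:
            expr = None  # the single case without an immunoblot
        elif i == 29:
            expr = 0.55  # mosaic loss: blot diluted by non-neoplastic cells
        elif loss:
            expr = lo[i % len(lo)]
        else:
            expr = hi[i % len(hi)]
        if i == 28 or i == 29:
            ihc = "loss"
        elif i <= 5 or 10 <= i <= 14:  # 10 blot-loss cases also IHC-tested
            ihc = "loss"
        elif 30 <= i <= 36:  # 7 blot-retained cases IHC-tested
            ihc = "retained"
        else:
            ihc = "untested"
        if i in (1, 2):
            site = "gastric"
        elif 3 <= i <= 9:
            site = "non_gastric"
        elif i in (53, 62, 63, 64, 30):
            site = "unknown"
        else:
            # remaining 50 sporadic cases: 36 gastric, 14 non-gastric
            others = [j for j in range(10, 65) if j not in (30, 53, 62, 63, 64)]
            site = "gastric" if others.index(i) < 36 else "non_gastric"
        if 10 <= i <= 18:
            risk = "low"
        elif 19 <= i <= 25:
            risk = "intermediate"
        elif loss:
            risk = "high" if i % 2 else "metastatic"
        else:
            risk = ("low", "intermediate", "high", "metastatic")[i % 4]
        add(cid, aet, "sporadic", site, risk, mutant, expr, ihc)

    for i in range(65, 75):  # NF-1-syndromic cases S065..S074
        cid = f"S{i:03d}"
        mutant = i <= 69  # 5 mutants
        loss = i <= 73  # 9 losses
        expr = lo[i % len(lo)] if loss else 0.80
        ihc = "loss" if i in (65, 66) else ("retained" if i == 70 else "untested")
        risk = "high" if loss else "low"
        add(cid, "NF1", "nf1_syndromic", "non_gastric", risk, mutant, expr, ihc)

    for i, expr in ((75, 0.92), (76, 1.10)):  # SDH-deficient cases
        add(f"S{i:03d}", "SDH", "other_syndromic", "gastric", "low", False, expr, "untested")

    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    _check_fixture_marginals(df)
    return df


def _check_fixture_marginals(df: pd.DataFrame) -> None:
    """Internal consistency assertions for the packaged fixture."""
    assert len(df) == 76
    aet = df["aetiology"].value_counts()
    assert (aet["KIT"], aet["PDGFRA"], aet["NF1"], aet["SDH"]) == (52, 8, 11, 2)
    assert (df["genomic_max"] == "mutant").sum() == 16
    assert (df["site"] == "unknown").sum() == 5
    assert df["immunoblot_expression"].notna().sum() == 75
    assert (df["ihc_status"] != "untested").sum() == 22


def micro_gist_fixture() -> pd.DataFrame:
    """Eight micro-GISTs; three with MAX protein loss, each 14q-deleted."""
    rows = []
    for i in range(1, 9):
        loss = i <= 3
        rows.append(
            {
                "case_id": f"M{i}",
                "max_protein": "loss" if loss else "retained",
                "chr14q_deletion": "yes" if loss else "no",
            }
        )
    return pd.DataFrame(rows)


# -- variant records --------------------------------------------------------


def gen_variant_set(
    tx: TranscriptModel | None = None, vaf_purity: float = 0.80
) -> list[VariantRecord]:
    """Eight mononucleotide variant records matching the published class
    mix (3 nonsense, 1 start loss, 1 frameshift, 2 splice site,
    1 5'-UTR), constructed against the packaged transcript so every
    HGVS string validates.

    Seven records carry a wild-type matched normal; the eighth (the
    case-19 analogue, the 5'-UTR mutation) has no normal and VAF 0.7.
    """
    tx = tx or load_max_transcript()
    cds = tx.cds
    stops = {"TAA", "TAG", "TGA"}
    nonsense: list[str] = []
    for codon_idx in range(1, len(cds) // 3 - 1):
        codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
        for within in range(3):
            for alt in "ACGT":
                if alt == codon[within]:
                    continue
                if codon[:within] + alt + codon[within + 1 :] in stops:
                    pos = codon_idx * 3 + within + 1
                    nonsense.append(f"c.{pos}{codon[within]}>{alt}")
        if len(nonsense) >= 3:
            break
    if len(nonsense) < 3:  # pragma: no cover - property of the fixed sequence
        raise RuntimeError("packaged CDS has too few stop-creatable codons")

    hemi_vaf = round(vaf_purity / (2.0 - vaf_purity), 2)
    donor3 = tx.exons[2].tx_end - tx.cds_start + 1  # last coding base of exon 3
    donor4 = tx.exons[3].tx_end - tx.cds_start + 1
    fs_pos = 30
    utr_pos = -23
    records = [
        VariantRecord(nonsense[0], "case01", "case01_a", hemi_vaf, "wild_type"),
        VariantRecord(nonsense[1], "case02", "case02_a", hemi_vaf, "wild_type"),
        VariantRecord(nonsense[2], "case03", "case03_a", 0.62, "wild_type"),
        VariantRecord("c.1A>G", "case04", "case04_a", hemi_vaf, "wild_type"),
        VariantRecord(
            f"c.{fs_pos}del{tx.base_at(fs_pos)}", "case05", "case05_a", 0.65, "wild_type"
        ),
        VariantRecord(f"c.{donor3}+1G>T", "case07", "case07_a", hemi_vaf, "wild_type"),
        VariantRecord(f"c.{donor4}+2T>C", "case59", "case59_a", 0.64, "wild_type"),
        VariantRecord(
            f"c.{utr_pos}{tx.base_at(utr_pos)}>A", "case19", "case19_a", 0.70,
            "unavailable",
        ),
    ]
    return records


def wild_type_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: diploid tumour at default purity."""
    return SimulationConfig(seed=seed, **overrides)


def gist48_config(panel: AmpliconPanel | None = None, seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: GIST48-like homozygous deletion of MAX exons 1-2."""
    panel = panel or default_panel()
    return SimulationConfig(genotype_map=gist48_genotype(panel), seed=seed, **overrides)
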