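"""End-to-end pipeline: simulate → call deletions → qPCR copy number →
annotate variants → cohort statistics.

The pipeline is a thin orchestration over the library modules; every
stage failure aborts with the stage name and the underlying cause, and
identical seeds reproduce identical report bundles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as gio
from .cohort import associate, cohort_report
from .panel import default_panel
from .panel_cn import CallerParams, call_deletions, normalize_depths
from .qpcr import copy_number_summary, estimate_normal_fraction
from .synth import (
    SimulationConfig,
    fixture_cohort,
    gen_depth_profile,
    gen_qpcr_run,
    gen_variant_set,
    gist48_genotype,
    micro_gist_fixture,
)
from .transcript import load_max_transcript
from .variants import classify_consequence, infer_zygosity, somatic_status

log = logging.getLogger("gistmax")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    simulate: bool = True
    purity: float = 0.80
    mean_depth: float = 500.0
    depth_dispersion: float = 0.02
    ct_noise_sd: float = 0.2
    mixture_normal_fractions: tuple[float, ...] = (0.3, 0.2)
    caller: CallerParams = field(default_factory=CallerParams)
    # input paths, used when simulate is False
    panel_path: Path | None = None
    depths_path: Path | None = None
    ct_paths: tuple[Path, ...] = ()
    cohort_path: Path | None = None
    variants_path: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        caller = CallerParams(**raw.pop("caller", {}))
        paths = {
            k: Path(v)
            for k, v in list(raw.items())
            if k.endswith("_path") and v is not None
        }
        for k in paths:
            raw.pop(k)
        ct_paths = tuple(Path(p) for p in raw.pop("ct_paths", []))
        cfg = cls(
            out_dir=Path(raw.pop("out_dir", "results")),
            caller=caller,
            ct_paths=ct_paths,
            **paths,
            **raw,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("panel_path", "depths_path", "cohort_path", "variants_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config {name} missing or absent: {p}")
            for p in self.ct_paths:
                if not Path(p).exists():
                    raise FileNotFoundError(f"Ct table not found: {p}")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("inputs")
        if config.simulate:
            panel = default_panel()
            sim = SimulationConfig(
                purity=config.purity,
                genotype_map=gist48_genotype(panel),
                mean_depth=config.mean_depth,
                depth_dispersion=config.depth_dispersion,
                ct_noise_sd=config.ct_noise_sd,
                seed=config.seed,
            )
            tumour, normal = gen_depth_profile(panel, sim)
            gio.write_panel(panel, out / "panel.bed")
            gio.write_depths([tumour, normal], panel, out / "depths.tsv")
            runs = [
                gen_qpcr_run(
                    SimulationConfig(
                        ct_noise_sd=config.ct_noise_sd, seed=config.seed + i + 1
                    ),
                    f,
                    0,
                    sample_id=f"mix_{int(f * 100)}_{int((1 - f) * 100)}",
                )
                for i, f in enumerate(config.mixture_normal_fractions)
            ]
            for run in runs:
                sid = run.samples()[0]
                gio.write_ct(run, out / f"ct_{sid}.csv")
            cohort = fixture_cohort()
            gio.write_cohort(cohort, out / "cohort.csv")
            variants = gen_variant_set()
            gio.write_variants(variants, out / "variants.csv")
        else:
            panel = gio.read_panel(config.panel_path)
            profiles = gio.read_depths(config.depths_path, panel)
            try:
                tumour, normal = profiles["tumour"], profiles["normal"]
            except KeyError as exc:
                raise ValueError(f"depth table lacks sample {exc}") from exc
            runs = [gio.read_ct(p) for p in config.ct_paths]
            cohort = gio.read_cohort(config.cohort_path)
            variants = gio.read_variants(config.variants_path)
    except Exception as exc:
        raise StageError("inputs", exc) from exc

    try:
        stage("call-deletions")
        track = normalize_depths(tumour, normal, panel)
        params = config.caller
        if params.cutoff is None and params.purity is None and params.risk_class is None:
            params = CallerParams(purity=config.purity, min_run=params.min_run,
                                  end_size=params.end_size, margin=params.margin,
                                  end_threshold=params.end_threshold)
        calls, errors = call_deletions(track, panel, params)
        report["deletion_calls"] = [
            {
                "gene": c.gene,
                "criteria": list(c.criteria),
                "first_index": c.first_index,
                "last_index": c.last_index,
                "mean_ratio": c.mean_ratio,
                "cutoff": c.cutoff,
                "zygosity": c.zygosity,
            }
            for c in calls
        ]
        report["deletion_quality_errors"] = [e.reason for e in errors]
    except Exception as exc:
        raise StageError("call-deletions", exc) from exc

    try:
        stage("qpcr-cn")
        report["qpcr"] = {}
        for run in runs:
            for sid, copies in copy_number_summary(run).items():
                report["qpcr"][sid] = {
                    "copies": copies,
                    "normal_fraction_if_deleted": estimate_normal_fraction(copies),
                }
    except Exception as exc:
        raise StageError("qpcr-cn", exc) from exc

    try:
        stage("annotate-variants")
        tx = load_max_transcript()
        annotated = []
        for v in variants:
            cons = classify_consequence(v, tx)
            zyg = (
                infer_zygosity(v.vaf, purity=config.purity) if v.vaf is not None else None
            )
            annotated.append(
                {
                    "case_id": v.case_id,
                    "hgvs_c": v.hgvs_c,
                    "consequence": cons.kind,
                    "region": cons.region,
                    "splice_candidates": list(cons.splice_candidates),
                    "zygosity": list(zyg.classes) if zyg else [],
                    "somatic_status": somatic_status(v),
                }
            )
        report["variants"] = annotated
    except Exception as exc:
        raise StageError("annotate-variants", exc) from exc

    try:
        stage("cohort-stats")
        freqs = cohort_report(cohort)
        report["cohort"] = {
            k: {"count": r.count, "denominator": r.denominator, "percent": r.percent}
            for k, r in freqs.items()
        }
        assoc = associate(cohort, ("genomic_max", "mutant"), ("site", "non_gastric"))
        report["site_association"] = {
            "table": list(assoc.table.cells),
            "p_value": assoc.p_value,
            "n_used": assoc.n_used,
            "n_excluded": assoc.n_excluded,
        }
        micro = micro_gist_fixture()
        report["micro_gist"] = {
            "n": int(len(micro)),
            "max_loss": int((micro["max_protein"] == "loss").sum()),
        }
    except Exception as exc:
        raise StageError("cohort-stats", exc) from exc

    gio.write_report(report, out / "report.json")
    return report
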