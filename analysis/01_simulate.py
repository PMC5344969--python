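#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes, under results/data/: the amplicon panel BED; paired
tumour/normal depth tables for a GIST48-like tumour (homozygous
deletion of MAX exons 1-2, purity 0.80) and a wild-type tumour; qPCR
Ct plates for the 30:70 and 20:80 normal:tumour deletion-control
mixtures; the 76-case cohort fixture with its micro-GIST companion;
and the 8-variant mononucleotide mutation set.
"""

from pathlib import Path

from gistmax import SimulationConfig, gen_depth_profile, gen_qpcr_run, gen_variant_set
from gistmax import io as gio
from gistmax.panel import default_panel
from gistmax.synth import fixture_cohort, gist48_genotype, micro_gist_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20170308

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = default_panel()
    gio.write_panel(panel, OUT / "panel.bed")

    cfg_del = SimulationConfig(purity=0.80, genotype_map=gist48_genotype(panel), seed=SEED)
    t_del, n_del = gen_depth_profile(panel, cfg_del, "gist48_like", "normal_gist48")
    cfg_wt = SimulationConfig(purity=0.80, seed=SEED + 1)
    t_wt, n_wt = gen_depth_profile(panel, cfg_wt, "wild_type", "normal_wt")
    gio.write_depths([t_del, n_del, t_wt, n_wt], panel, OUT / "depths.tsv")

    for i, f in enumerate((0.3, 0.2)):
        run = gen_qpcr_run(
            SimulationConfig(ct_noise_sd=0.2, seed=SEED + 10 + i), f, 0,
            sample_id=f"mix_{int(f * 100)}_{int((1 - f) * 100)}",
        )
        gio.write_ct(run, OUT / f"ct_mix_{int(f * 100)}_{int((1 - f) * 100)}.csv")

    gio.write_cohort(fixture_cohort(), OUT / "cohort.csv")
    micro_gist_fixture().to_csv(OUT / "micro_gist.csv", index=False)
    gio.write_variants(gen_variant_set(), OUT / "variants.csv")
    print(f"wrote panel (33 amplicons), 4 depth profiles, 2 Ct plates, "
          f"76-case cohort + 8 micro-GISTs, 8 variants -> {OUT}")

if __name__ == "__main__":
    main()
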