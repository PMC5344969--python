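#!/usr/bin/env python
"""Call homozygous MAX deletions on the simulated depth tables.

Normalizes each tumour against its paired normal (anchor-gene
median-of-ratios), applies the purity-informed cutoff (0.3 at purity
0.80) with the 9-consecutive-amplicon and gene-end criteria, and
writes the calls as BED plus a CSV report.  Expected outcome: exactly
one call spanning the exon 1-2 amplicons of the GIST48-like tumour and
none for the wild type.
"""

import csv
from pathlib import Path

from gistmax import CallerParams, call_deletions, normalize_depths
from gistmax import io as gio

BASE = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    panel = gio.read_panel(BASE / "data" / "panel.bed")
    profiles = gio.read_depths(BASE / "data" / "depths.tsv", panel)
    pairs = [("gist48_like", "normal_gist48"), ("wild_type", "normal_wt")]
    rows = []
    with open(BASE / "deletions.bed", "w") as bed:
        for tumour_id, normal_id in pairs:
            track = normalize_depths(profiles[tumour_id], profiles[normal_id], panel)
            calls, errors = call_deletions(track, panel, CallerParams(purity=0.80))
            print(f"{tumour_id}: {len(calls)} call(s), {len(errors)} QC error(s)")
            for c in calls:
                first, last = panel.amplicons[c.first_index], panel.amplicons[c.last_index]
                exons = sorted({panel.amplicons[i].exon
                                for i in range(c.first_index, c.last_index + 1)})
                print(f"  {c.gene} {'+'.join(c.criteria)} amplicons "
                      f"{c.first_index}-{c.last_index} ({', '.join(exons)}) "
                      f"mean ratio {c.mean_ratio:.3f} < cutoff {c.cutoff:.2f}")
                bed.write(f"{first.chrom}\t{first.start}\t{last.end}\t"
                          f"{c.gene}:{'+'.join(c.criteria)}\t{round(1000 * c.mean_ratio)}\n")
                rows.append({"tumour": tumour_id, "gene": c.gene,
                             "criteria": "+".join(c.criteria),
                             "first_index": c.first_index, "last_index": c.last_index,
                             "mean_ratio": round(c.mean_ratio, 4), "cutoff": c.cutoff,
                             "zygosity": c.zygosity})
    with open(BASE / "deletion_calls.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {BASE / 'deletions.bed'} and deletion_calls.csv")

if __name__ == "__main__":
    main()
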