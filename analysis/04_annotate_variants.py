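#!/usr/bin/env python
"""Annotate the mononucleotide variant set.

For each variant: consequence class against the packaged transcript
model (with both candidate splice outcomes for invariant-site
mutations), zygosity inference from the observed VAF at purity 0.80,
and somatic status from the matched normal (or, for the case-19
analogue, from the VAF alone).  Expected class mix: 3 nonsense,
1 start loss, 1 frameshift, 2 splice site, 1 5'-UTR.
"""

import csv
from collections import Counter
from pathlib import Path

from gistmax import classify_consequence, infer_zygosity, load_max_transcript, somatic_status
from gistmax import io as gio

BASE = Path(__file__).resolve().parent.parent / "results"

def main() -> None:
    tx = load_max_transcript()
    records = gio.read_variants(BASE / "data" / "variants.csv")
    rows = []
    for v in records:
        cons = classify_consequence(v, tx)
        zyg = infer_zygosity(v.vaf, purity=0.80) if v.vaf is not None else None
        rows.append({
            "case_id": v.case_id,
            "hgvs_c": v.hgvs_c,
            "consequence": cons.kind,
            "region": cons.region,
            "splice_candidates": "|".join(cons.splice_candidates),
            "vaf": v.vaf,
            "zygosity": "|".join(zyg.classes) if zyg else "",
            "somatic_status": somatic_status(v),
        })
        print(f"{v.case_id}: {v.hgvs_c} -> {cons.kind} ({cons.region}) "
              f"VAF {v.vaf} zygosity {'|'.join(zyg.classes) if zyg else '-'} "
              f"{somatic_status(v)}")
    print("class mix:", dict(Counter(r["consequence"] for r in rows)))
    with open(BASE / "variant_annotation.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {BASE / 'variant_annotation.csv'}")

if __name__ == "__main__":
    main()
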