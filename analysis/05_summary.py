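"""Headline bookkeeping: DE counts per genotype, Venn regions, percentages.

Assembles the study-style summary from the per-genotype DE tables and the
category assignments: the universe of jasmonate-responsive genes (WT DE
count), each category's share of it to one decimal, and the 4-set Venn
region counts over the genotype DE sets.  Writes results/summary/.
"""

import json
from pathlib import Path

import pandas as pd

from jacatlas import report

ROOT = Path(__file__).resolve().parents[1]
DE = ROOT / "results" / "de"
CLS = ROOT / "results" / "classification"
OUT = ROOT / "results" / "summary"


def main() -> None:
    de_results = {
        geno: pd.read_csv(DE / f"{geno}_JA_vs_Mock.tsv", sep="\t", index_col=0)
        for geno in ("WT", "myc2", "ein3eil1", "myc2ein3eil1")
    }
    cat_summary = pd.read_csv(CLS / "category_summary.tsv", sep="\t")
    summary = report.summarize(de_results, cat_summary)

    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    text = report.render_summary_text(summary)
    (OUT / "summary.txt").write_text(text)
    print(text)
    print("4-set Venn regions (exclusive membership -> count):")
    for key, n in sorted(summary["venn_regions"].items()):
        print(f"  {key}: {n}")


if __name__ == "__main__":
    main()
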