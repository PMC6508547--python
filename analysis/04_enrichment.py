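"""Over-representation of category gene lists against synthetic gene sets.

The real study tested its category lists against Gene Ontology terms; no
annotation ships with a simulation, so this step constructs a synthetic
GMT (labelled as such): for each planted archetype one "marker" term that
samples 60% of that archetype's genes plus background, and twenty random
terms.  Enrichment of each classified category list is then computed with
the EASE-modified Fisher tail, expecting the matching marker terms to
dominate and the random terms to stay flat.  Writes per-category tables
under results/enrichment/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from jacatlas import enrichment, io

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
CLS = ROOT / "results" / "classification"
OUT = ROOT / "results" / "enrichment"
SEED = 42


def synthetic_gmt(truth: pd.DataFrame, rng) -> dict[str, set[str]]:
    """Synthetic stand-in annotation derived from the simulation truth."""
    sets = {}
    universe = truth.index.to_numpy()
    for arch, group in truth.groupby("archetype"):
        if arch == "NULL":
            continue
        members = rng.choice(group.index, size=int(0.6 * len(group)), replace=False)
        background = rng.choice(universe, size=40, replace=False)
        sets[f"MARKER_{arch}"] = set(members) | set(background)
    for t in range(20):
        sets[f"RANDOM_{t:02d}"] = set(
            rng.choice(universe, size=int(rng.integers(30, 120)), replace=False)
        )
    return sets


def main() -> None:
    truth = pd.read_csv(SIM / "truth.tsv", sep="\t", index_col=0)
    assignments = pd.read_csv(CLS / "assignments.tsv", sep="\t", index_col=0)
    assignments["labels"] = assignments["labels"].fillna("")
    rng = np.random.default_rng(SEED)
    annotation = synthetic_gmt(truth, rng)

    OUT.mkdir(parents=True, exist_ok=True)
    with open(OUT / "synthetic_sets.gmt", "w") as fh:
        for term, members in annotation.items():
            fh.write("\t".join([term, "synthetic gene set", *sorted(members)]) + "\n")

    universe = list(truth.index)
    for category in ("EIN3_INDEP", "MYC2_INDEP", "SYNERGY",
                     "EIN3_UP_MYC2_REPRESSED", "MYC2_UP_EIN3_REPRESSED"):
        genes = assignments.index[
            assignments["labels"].str.split(";").apply(lambda ls: category in ls)
        ]
        if len(genes) == 0:
            print(f"{category}: empty list, skipped")
            continue
        result = enrichment.enrich(genes, annotation, universe, mode="ease")
        io.write_tsv(result, OUT / f"{category}.tsv", index=False)
        top = result.iloc[0]
        n_enriched = int(result["enriched"].sum())
        print(f"{category} (n={len(genes)}): {n_enriched} enriched terms; top = "
              f"{top['term_id']} (fold {top['fold_enrichment']:.1f}, "
              f"p {top['p']:.2e})")


if __name__ == "__main__":
    main()
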