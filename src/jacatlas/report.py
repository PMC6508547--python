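"""Summary arithmetic and the end-to-end pipeline.

The summary mirrors the headline bookkeeping of this kind of factorial
study: per-genotype up/down/total DE counts, a 4-set Venn over the DE gene
sets, and per-category counts expressed as percentages of the "universe" —
the set of JA-responsive genes in wild type (the WT DE count).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import categories, detest, io, sim
from .categories import ClassifyConfig
from .detest import ContrastSpec, group_samples

GENOTYPES = ("WT", "myc2", "ein3eil1", "myc2ein3eil1")


def percent_of_universe(count: int, universe: int) -> float:
    """Share of the universe, rounded to one decimal (e.g. 374/1495 -> 25.0)."""
    if universe <= 0:
        raise ValueError("universe must be positive")
    return round(100.0 * count / universe, 1)


def format_percent(value: float) -> str:
    """Display form: drop the decimal when it is .0 ('25%', '4.2%')."""
    return f"{value:.0f}%" if float(value).is_integer() else f"{value:.1f}%"


def summarize(
    de_results: dict[str, pd.DataFrame],
    category_summary: pd.DataFrame,
    universe: int | None = None,
) -> dict:
    """Assemble the report: per-genotype DE counts, category percentages, Venn.

    ``de_results`` maps genotype -> per-gene contrast result (its ``de_call``
    column defines that genotype's DE set).  The universe defaults to the WT
    DE gene count.
    """
    per_genotype = {}
    de_sets = {}
    for geno, res in de_results.items():
        call = res["de_call"]
        n_up = int((call == "UP").sum())
        n_down = int((call == "DOWN").sum())
        per_genotype[geno] = {
            "n_up": n_up,
            "n_down": n_down,
            "n_total": n_up + n_down,
            "n_undifferentiated": int((call == "NONE").sum()),
        }
        de_sets[geno] = set(res.index[call != "NONE"])

    if universe is None:
        if "WT" not in de_results:
            raise ValueError("universe unspecified and no WT contrast present")
        universe = per_genotype["WT"]["n_total"]
    if universe == 0:
        raise ValueError("empty universe: no WT DE genes")

    per_category = {}
    for _, row in category_summary.iterrows():
        pct = percent_of_universe(int(row["count"]), universe)
        per_category[row["category"]] = {
            "count": int(row["count"]),
            "n_up": int(row["n_up"]),
            "n_down": int(row["n_down"]),
            "percent_of_universe": pct,
            "percent_display": format_percent(pct),
        }

    return {
        "universe": int(universe),
        "per_genotype": per_genotype,
        "per_category": per_category,
        "venn_regions": categories.venn_overlaps(de_sets),
    }


def render_summary_text(summary: dict) -> str:
    lines = [f"universe (WT DE genes): {summary['universe']}", "", "per genotype:"]
    for geno, d in summary["per_genotype"].items():
        lines.append(
            f"  {geno}: {d['n_total']} DE ({d['n_up']} up, {d['n_down']} down), "
            f"{d['n_undifferentiated']} unchanged"
        )
    lines.append("")
    lines.append("per category:")
    for cat, d in summary["per_category"].items():
        lines.append(
            f"  {cat}: {d['count']} ({d['n_up']} up, {d['n_down']} down) = "
            f"{d['percent_display']} of universe"
        )
    return "\n".join(lines) + "\n"


def run_pipeline(
    out_dir,
    counts: pd.DataFrame | None = None,
    samples: pd.DataFrame | None = None,
    sim_config: sim.SimConfig | None = None,
    classify_config: ClassifyConfig | None = None,
    use_raw_p: bool = False,
) -> dict:
    """simulate (optionally) -> contrasts -> classify -> summarize; write TSVs.

    Returns the summary dict; writes counts/samples/truth (when simulated),
    per-genotype DE tables, the fold-change table, assignments, the summary
    (TSV-ish JSON + text), and a resolved-parameter log under ``out_dir``.
    Outputs are a pure function of (inputs, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    classify_config = classify_config or ClassifyConfig()

    truth = None
    if counts is None or samples is None:
        sim_config = sim_config or sim.SimConfig()
        counts, samples, truth = sim.simulate_counts(sim_config)
        io.write_tsv(counts, out / "counts.tsv")
        io.write_tsv(samples, out / "samples.tsv", index=False)
        io.write_tsv(truth, out / "truth.tsv")
    io.validate_design(counts, samples)

    contrasts = categories.within_genotype_contrasts(samples)
    factors = detest.estimate_size_factors_deges(counts, contrasts)
    de_results = {}
    for spec, geno in zip(contrasts, GENOTYPES):
        res = detest.run_contrast(counts, spec, factors, use_raw_p=use_raw_p)
        de_results[geno] = res
        io.write_tsv(res, out / f"de_{geno}.tsv")

    table = categories.build_fold_change_table(counts, samples)
    io.write_tsv(table, out / "fold_change_table.tsv")
    assignments, cat_summary = categories.classify_all(table, classify_config)
    io.write_tsv(assignments.join(table), out / "assignments.tsv")

    summary = summarize(de_results, cat_summary)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(render_summary_text(summary))

    if truth is not None:
        recovery = score_recovery(assignments, truth)
        io.write_tsv(recovery, out / "recovery.tsv", index=False)
        summary["recovery"] = recovery.to_dict("records")

    log = {
        "classify_mode": classify_config.mode,
        "classify_criteria": classify_config.criteria,
        "use_raw_p": use_raw_p,
        "simulated": truth is not None,
    }
    if sim_config is not None and truth is not None:
        log["sim"] = {
            "n_genes": sim_config.n_genes,
            "replicates": sim_config.replicates,
            "seed": sim_config.seed,
            "delta": sim_config.delta,
            "delta_antag": sim_config.delta_antag,
        }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return summary


def score_recovery(assignments: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-archetype sensitivity plus NULL false-assignment rate.

    A planted gene is recovered when its label set contains the category
    its archetype was generated under; a NULL gene is a false assignment
    when it receives any label.
    """
    merged = assignments.join(truth["archetype"])
    rows = []
    for arch, group in merged.groupby("archetype"):
        expected = sim.ARCHETYPE_CATEGORY[arch]
        n = len(group)
        if expected is None:
            hits = int((group["labels"] != "").sum())
            rows.append(("NULL", n, hits, hits / n if n else 0.0, "false_assignment"))
        else:
            hits = int(
                group["labels"].str.split(";").apply(lambda ls: expected in ls).sum()
            )
            rows.append((arch, n, hits, hits / n if n else 0.0, "sensitivity"))
    return pd.DataFrame(
        rows, columns=["archetype", "n_genes", "n_hit", "rate", "metric"]
    )
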