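"""Five-way regulatory classification from the six-ratio fold-change table.

Each gene is described by six log2 ratios: the four within-genotype
JA-vs-mock responses (fc_wt, fc_myc2, fc_ein, fc_triple) and the two
cross-genotype same-treatment ratios (x_myc2 = log2 myc2,JA / WT,JA and
x_ein = log2 ein3eil1,JA / WT,JA) that detect amplitude shifts.  The five
rule-sets (all inequalities strict):

1. EIN3_INDEP — responds in WT and myc2, unaltered elsewhere:
   |fc_wt|>1, |fc_myc2|>1, |x_myc2|<1, |fc_ein|<1, |fc_triple|<1,
   and sign(fc_wt) == sign(fc_myc2).
2. MYC2_INDEP — mirrored: |fc_wt|>1, |fc_ein|>1, |x_ein|<1, |fc_myc2|<1,
   |fc_triple|<1, sign(fc_wt) == sign(fc_ein).
3. SYNERGY — responds only in WT: |fc_wt|>1, |fc_myc2|<1, |fc_ein|<1,
   |fc_triple|<1.
4. EIN3_UP_MYC2_REPRESSED — induced in WT, more strongly in myc2, not in
   either ein3 eil1 background: fc_wt>1, x_myc2>1, x_ein<-1, |fc_ein|<1,
   |fc_triple|<1.
5. MYC2_UP_EIN3_REPRESSED — mirrored: fc_wt>1, x_ein>1, x_myc2<-1,
   |fc_myc2|<1, |fc_triple|<1.

"Changed" legs (the ratios required to exceed 1 within a genotype) by
default additionally require the BH-adjusted p of that genotype's JA-vs-mock
contrast to be < .05; "not altered" legs are fold-change-only.  The rules
are not mutually exclusive (e.g. 3 and 4 can co-fire), so the default
``rule_literal`` mode reports every matching label; ``priority`` mode keeps
one label per gene in the order 4, 5, 1, 2, 3 (most constrained first).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import detest
from .detest import ContrastSpec, group_samples

CATEGORIES = (
    "EIN3_INDEP",
    "MYC2_INDEP",
    "SYNERGY",
    "EIN3_UP_MYC2_REPRESSED",
    "MYC2_UP_EIN3_REPRESSED",
)
PRIORITY_ORDER = (
    "EIN3_UP_MYC2_REPRESSED",
    "MYC2_UP_EIN3_REPRESSED",
    "EIN3_INDEP",
    "MYC2_INDEP",
    "SYNERGY",
)

RATIO_COLUMNS = ("fc_wt", "fc_myc2", "fc_ein", "fc_triple", "x_myc2", "x_ein")
PADJ_COLUMNS = ("padj_wt", "padj_myc2", "padj_ein", "padj_triple")


@dataclass(frozen=True)
class ClassifyConfig:
    mode: str = "rule_literal"  # or "priority"
    criteria: str = "fc_and_padj"  # or "fc_only"
    lfc_threshold: float = 1.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.mode not in ("rule_literal", "priority"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.criteria not in ("fc_and_padj", "fc_only"):
            raise ValueError(f"unknown criteria {self.criteria!r}")


def within_genotype_contrasts(samples: pd.DataFrame) -> list[ContrastSpec]:
    """The four JA-vs-mock contrasts, one per genotype."""
    return [
        ContrastSpec(
            f"{geno}_JA_vs_Mock",
            group_samples(samples, geno, "JA"),
            group_samples(samples, geno, "Mock"),
        )
        for geno in ("WT", "myc2", "ein3eil1", "myc2ein3eil1")
    ]


def build_fold_change_table(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = detest.DEFAULT_PSEUDOCOUNT,
    normalization: str = "deges",
) -> pd.DataFrame:
    """Assemble the six ratios and four within-genotype padj per gene.

    Runs the four JA-vs-mock contrasts (one per genotype) and the two
    mutant-vs-WT contrasts under JA, all with shared size factors.  The
    default normalization is median-of-ratios with iterative DE-gene
    elimination, which stays calibrated even when a large fraction of the
    transcriptome responds to the treatment; ``normalization='plain'``
    uses the one-shot median-of-ratios.
    """
    contrasts = within_genotype_contrasts(samples)
    if normalization == "deges":
        factors = detest.estimate_size_factors_deges(counts, contrasts)
    elif normalization == "plain":
        factors = detest.estimate_size_factors(counts)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    within = {}
    for spec, col in zip(contrasts, ("wt", "myc2", "ein", "triple")):
        within[col] = detest.run_contrast(counts, spec, factors, pseudocount)

    cross = {}
    for geno, col in (("myc2", "myc2"), ("ein3eil1", "ein")):
        spec = ContrastSpec(
            f"{geno}_vs_WT_JA",
            group_samples(samples, geno, "JA"),
            group_samples(samples, "WT", "JA"),
        )
        cross[col] = detest.log2_fold_change(counts, spec, factors, pseudocount)

    table = pd.DataFrame(
        {
            "fc_wt": within["wt"]["log2fc"],
            "fc_myc2": within["myc2"]["log2fc"],
            "fc_ein": within["ein"]["log2fc"],
            "fc_triple": within["triple"]["log2fc"],
            "x_myc2": cross["myc2"],
            "x_ein": cross["ein"],
            "padj_wt": within["wt"]["padj"],
            "padj_myc2": within["myc2"]["padj"],
            "padj_ein": within["ein"]["padj"],
            "padj_triple": within["triple"]["padj"],
        },
        index=counts.index,
    )
    return table


def _rule_matrix(table: pd.DataFrame, config: ClassifyConfig) -> pd.DataFrame:
    """Boolean gene x category matrix of rule satisfaction (vectorized)."""
    t = config.lfc_threshold
    fc_wt = table["fc_wt"].to_numpy(float)
    fc_myc2 = table["fc_myc2"].to_numpy(float)
    fc_ein = table["fc_ein"].to_numpy(float)
    fc_triple = table["fc_triple"].to_numpy(float)
    x_myc2 = table["x_myc2"].to_numpy(float)
    x_ein = table["x_ein"].to_numpy(float)

    if config.criteria == "fc_and_padj":
        sig_wt = table["padj_wt"].to_numpy(float) < config.alpha
        sig_myc2 = table["padj_myc2"].to_numpy(float) < config.alpha
        sig_ein = table["padj_ein"].to_numpy(float) < config.alpha
    else:
        ones = np.ones(len(table), dtype=bool)
        sig_wt = sig_myc2 = sig_ein = ones

    # "changed" legs carry the significance requirement; "not altered" and
    # cross-genotype legs are fold-change-only
    chg_wt = (np.abs(fc_wt) > t) & sig_wt
    chg_myc2 = (np.abs(fc_myc2) > t) & sig_myc2
    chg_ein = (np.abs(fc_ein) > t) & sig_ein
    up_wt = (fc_wt > t) & sig_wt

    flat_myc2 = np.abs(fc_myc2) < t
    flat_ein = np.abs(fc_ein) < t
    flat_triple = np.abs(fc_triple) < t
    flat_x_myc2 = np.abs(x_myc2) < t
    flat_x_ein = np.abs(x_ein) < t

    rules = {
        "EIN3_INDEP": chg_wt
        & chg_myc2
        & flat_x_myc2
        & flat_ein
        & flat_triple
        & (np.sign(fc_wt) == np.sign(fc_myc2)),
        "MYC2_INDEP": chg_wt
        & chg_ein
        & flat_x_ein
        & flat_myc2
        & flat_triple
        & (np.sign(fc_wt) == np.sign(fc_ein)),
        "SYNERGY": chg_wt & flat_myc2 & flat_ein & flat_triple,
        "EIN3_UP_MYC2_REPRESSED": up_wt
        & (x_myc2 > t)
        & (x_ein < -t)
        & flat_ein
        & flat_triple,
        "MYC2_UP_EIN3_REPRESSED": up_wt
        & (x_ein > t)
        & (x_myc2 < -t)
        & flat_myc2
        & flat_triple,
    }
    return pd.DataFrame(rules, index=table.index)


def classify_gene(row: pd.Series, config: ClassifyConfig | None = None) -> set[str]:
    """Labels satisfied by a single fold-change-table row."""
    config = config or ClassifyConfig()
    matrix = _rule_matrix(row.to_frame().T, config)
    labels = set(matrix.columns[matrix.iloc[0]])
    if config.mode == "priority" and labels:
        for cat in PRIORITY_ORDER:
            if cat in labels:
                return {cat}
    return labels


def classify_all(
    table: pd.DataFrame, config: ClassifyConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene; return (assignments, per-category summary).

    Assignments carry semicolon-joined labels, the direction (sign of the
    WT response, for the non-antagonistic categories), and a multi-label
    flag so overlapping rule-sets are reported rather than dropped.
    The summary splits categories 1-3 into UP/DOWN by the WT direction;
    the antagonistic classes are induction-type by definition.
    """
    config = config or ClassifyConfig()
    matrix = _rule_matrix(table, config)
    if config.mode == "priority":
        ordered = matrix[list(PRIORITY_ORDER)].to_numpy(bool)
        first = np.argmax(ordered, axis=1)
        any_hit = ordered.any(axis=1)
        pruned = np.zeros_like(ordered)
        pruned[np.arange(len(ordered)), first] = any_hit
        matrix = pd.DataFrame(pruned, index=matrix.index, columns=PRIORITY_ORDER)
        matrix = matrix[list(CATEGORIES)]

    direction = np.where(
        table["fc_wt"].to_numpy(float) > 0, "UP", "DOWN"
    )
    labels = [
        ";".join(c for c in CATEGORIES if row[c]) for _, row in matrix.iterrows()
    ]
    assignments = pd.DataFrame(
        {
            "labels": labels,
            "direction": np.where([bool(l) for l in labels], direction, ""),
            "n_labels": matrix.sum(axis=1).astype(int),
        },
        index=table.index,
    )
    assignments["multi_label"] = assignments["n_labels"] > 1

    rows = []
    directed = {"EIN3_INDEP", "MYC2_INDEP", "SYNERGY"}
    for cat in CATEGORIES:
        hit = matrix[cat].to_numpy(bool)
        n = int(hit.sum())
        if cat in directed:
            n_up = int((hit & (direction == "UP")).sum())
            rows.append((cat, n, n_up, n - n_up))
        else:
            rows.append((cat, n, n, 0))
    summary = pd.DataFrame(rows, columns=["category", "count", "n_up", "n_down"])
    return assignments, summary


def venn_overlaps(sets: dict[str, set]) -> dict[str, int]:
    """Region counts of the 4-set (or k-set) Venn diagram.

    Keys are '+'-joined member names of each non-empty region (exclusive
    membership pattern); counts over all regions sum to |union|.
    """
    names = list(sets)
    union = set().union(*sets.values()) if sets else set()
    regions: dict[str, int] = {}
    for element in union:
        members = tuple(n for n in names if element in sets[n])
        key = "+".join(members)
        regions[key] = regions.get(key, 0) + 1
    return regions
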