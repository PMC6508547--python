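"""Differential expression for two-group contrasts on a count matrix.

Normalization is the median-of-ratios procedure: per sample, the median over
genes (positive in every sample) of the ratio of that sample's count to the
gene's geometric mean across samples.  Fold changes are ratios of
pseudocounted group means of normalized counts.  Significance comes from a
closed-form, moment-based negative-binomial Wald test: per-gene dispersion is
the average of the two within-group method-of-moments estimates, and the Wald
statistic compares the log ratio of group means to its delta-method standard
error.  P-values are Benjamini-Hochberg adjusted per contrast, and a gene is
called differentially expressed when |log2 fold change| > 1 and adjusted
p < .05 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-8
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison, numerator over denominator."""

    name: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self):
        num, den = set(self.numerator), set(self.denominator)
        if not num or not den:
            raise ValueError(f"contrast {self.name!r}: empty group")
        if num & den:
            raise ValueError(f"contrast {self.name!r}: groups overlap")


def group_samples(
    samples: pd.DataFrame, genotype: str, treatment: str
) -> tuple[str, ...]:
    """Sample ids of one genotype x treatment cell, in sheet order."""
    mask = (samples["genotype"] == genotype) & (samples["treatment"] == treatment)
    ids = tuple(samples.loc[mask, "sample_id"])
    if not ids:
        raise ValueError(f"no samples for {genotype},{treatment}")
    return ids


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive factor per sample.

    Only genes with positive counts in every sample enter the median;
    appending all-zero genes therefore leaves the factors unchanged.
    Raises if no gene qualifies.
    """
    values = counts.to_numpy(dtype=float)
    positive = (values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    sub = values[positive]
    log_geo_mean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = np.exp(np.log(sub) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_size_factors_deges(
    counts: pd.DataFrame,
    contrasts: list["ContrastSpec"],
    iterations: int = 2,
    min_retained: int = 100,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Median-of-ratios with iterative DE-gene elimination.

    Plain median-of-ratios assumes most genes are unchanged between
    samples; when a large share of the transcriptome responds, the median
    lands inside the responding block and the factors absorb part of the
    signal.  This estimator alternates: (1) call DE genes in the given
    contrasts with the current factors, (2) re-estimate the factors from
    the genes called DE in none of them.  Falls back to the previous
    factors if fewer than ``min_retained`` genes survive the elimination.
    """
    factors = estimate_size_factors(counts)
    for _ in range(iterations):
        is_de = np.zeros(len(counts), dtype=bool)
        for spec in contrasts:
            wald = nb_wald_test(counts, spec, factors)
            lfc = wald["beta"].to_numpy() / np.log(2.0)
            padj = bh_adjust(wald["p"].to_numpy())
            is_de |= call_de(lfc, padj, lfc_threshold, alpha) != "NONE"
        retained = counts.loc[~is_de]
        if len(retained) < min_retained:
            break
        try:
            factors = estimate_size_factors(retained)
        except ValueError:
            break
    return factors


def _group_means(
    counts: pd.DataFrame, contrast: ContrastSpec, factors: pd.Series
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    num = counts[list(contrast.numerator)].to_numpy(float)
    den = counts[list(contrast.denominator)].to_numpy(float)
    num = num / factors[list(contrast.numerator)].to_numpy(float)
    den = den / factors[list(contrast.denominator)].to_numpy(float)
    return num, den, num.mean(axis=1), den.mean(axis=1)


def log2_fold_change(
    counts: pd.DataFrame,
    contrast: ContrastSpec,
    factors: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 of pseudocounted normalized group means, numerator/denominator."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    _, _, m_num, m_den = _group_means(counts, contrast, factors)
    lfc = np.log2((m_num + pseudocount) / (m_den + pseudocount))
    return pd.Series(lfc, index=counts.index, name=f"log2fc_{contrast.name}")


def nb_wald_test(
    counts: pd.DataFrame,
    contrast: ContrastSpec,
    factors: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Moment-based NB Wald test; returns beta (natural-log FC), se, p.

    Per gene: alpha = max(mean of the two within-group (v - m)/m^2
    estimates, 1e-8); beta = ln((m_A + pc)/(m_B + pc));
    se^2 = (1/n_A)(1/(m_A + pc) + alpha) + (1/n_B)(1/(m_B + pc) + alpha);
    p = 2 * (1 - Phi(|beta/se|)).  Genes that are all zero in both groups
    get p = 1 by convention.
    """
    if len(contrast.numerator) < 2 or len(contrast.denominator) < 2:
        raise ValueError(f"contrast {contrast.name!r}: need >= 2 replicates per group")
    num, den, m_a, m_b = _group_means(counts, contrast, factors)
    pc = pseudocount

    with np.errstate(divide="ignore", invalid="ignore"):
        v_a = num.var(axis=1, ddof=1)
        v_b = den.var(axis=1, ddof=1)
        alpha_a = np.where(m_a > 0, (v_a - m_a) / np.square(m_a), 0.0)
        alpha_b = np.where(m_b > 0, (v_b - m_b) / np.square(m_b), 0.0)
    alpha = np.maximum((alpha_a + alpha_b) / 2.0, DISPERSION_FLOOR)

    beta = np.log((m_a + pc) / (m_b + pc))
    n_a, n_b = num.shape[1], den.shape[1]
    se = np.sqrt(
        (1.0 / n_a) * (1.0 / (m_a + pc) + alpha)
        + (1.0 / n_b) * (1.0 / (m_b + pc) + alpha)
    )
    z = np.abs(beta) / se
    p = 2.0 * stats.norm.sf(z)
    all_zero = (m_a == 0) & (m_b == 0)
    p = np.where(all_zero, 1.0, np.minimum(p, 1.0))
    return pd.DataFrame(
        {"beta": beta, "se": se, "p": p}, index=counts.index
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: np.ndarray,
    padj: np.ndarray,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> np.ndarray:
    """UP / DOWN / NONE per gene; both inequalities strict."""
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be > 0")
    log2fc = np.asarray(log2fc, float)
    padj = np.asarray(padj, float)
    sig = padj < alpha
    out = np.where(
        sig & (log2fc > lfc_threshold),
        "UP",
        np.where(sig & (log2fc < -lfc_threshold), "DOWN", "NONE"),
    )
    return out


def run_contrast(
    counts: pd.DataFrame,
    contrast: ContrastSpec,
    factors: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    lfc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Full per-gene contrast: log2fc, se (log2 scale), p, padj, de_call.

    BH correction is applied within this contrast.  ``use_raw_p`` switches
    the significance leg of the DE call to the unadjusted p-value.
    """
    if factors is None:
        factors = estimate_size_factors(counts)
    wald = nb_wald_test(counts, contrast, factors, pseudocount)
    lfc = wald["beta"].to_numpy() / np.log(2.0)
    padj = bh_adjust(wald["p"].to_numpy())
    p_for_call = wald["p"].to_numpy() if use_raw_p else padj
    res = pd.DataFrame(
        {
            "log2fc": lfc,
            "se": wald["se"].to_numpy() / np.log(2.0),
            "p": wald["p"].to_numpy(),
            "padj": padj,
            "de_call": call_de(lfc, p_for_call, lfc_threshold, alpha),
        },
        index=counts.index,
    )
    res.attrs["contrast"] = contrast.name
    return res
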