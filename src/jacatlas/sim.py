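"""Seeded synthetic RNA-seq counts for the 4-genotype x 2-treatment design.

Counts are negative binomial with variance mu + alpha * mu**2 (gamma-Poisson
mixture).  Each gene carries a baseline log2 mean, a log-normal dispersion
alpha, and a planted per-genotype log2 jasmonate effect taken from one of
nine regulatory archetypes (eight signal classes plus NULL).  Mock baselines
are equal across genotypes, so a planted gene satisfies its category's
fold-change inequalities in expectation and the classifier can be scored
against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "myc2", "ein3eil1", "myc2ein3eil1")
TREATMENTS = ("JA", "Mock")

ARCHETYPES = (
    "EIN3_INDEP_UP",
    "EIN3_INDEP_DOWN",
    "MYC2_INDEP_UP",
    "MYC2_INDEP_DOWN",
    "SYNERGY_UP",
    "SYNERGY_DOWN",
    "EIN3_UP_MYC2_REPRESSED",
    "MYC2_UP_EIN3_REPRESSED",
    "NULL",
)

#: archetype -> category label expected from the rule classifier
ARCHETYPE_CATEGORY = {
    "EIN3_INDEP_UP": "EIN3_INDEP",
    "EIN3_INDEP_DOWN": "EIN3_INDEP",
    "MYC2_INDEP_UP": "MYC2_INDEP",
    "MYC2_INDEP_DOWN": "MYC2_INDEP",
    "SYNERGY_UP": "SYNERGY",
    "SYNERGY_DOWN": "SYNERGY",
    "EIN3_UP_MYC2_REPRESSED": "EIN3_UP_MYC2_REPRESSED",
    "MYC2_UP_EIN3_REPRESSED": "MYC2_UP_EIN3_REPRESSED",
    "NULL": None,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic factorial RNA-seq experiment.

    Attributes
    ----------
    n_genes : total number of genes.
    replicates : biological replicates per genotype x treatment cell (>= 2).
    archetype_fractions : archetype -> fraction of genes planted in it;
        non-negative, summing to <= 1; the remainder are NULL genes.
    delta : primary jasmonate effect in log2 units for planted genes.
    delta_antag : amplified effect for the antagonistic archetypes; must
        exceed ``delta`` by more than 1 so the cross-genotype inequality
        (amplitude shift > 1 log2 unit) holds in expectation.
    baseline_log2_mean_range : per-gene baseline drawn uniformly on this
        log2 interval; the default [3, 12] spans ~8 to ~4000 mean counts.
    dispersion_log_mean, dispersion_log_sd : natural-log-normal parameters
        of the per-gene NB dispersion alpha (defaults ln 0.05 and 0.5).
    libsize_log2_sd : sd of the per-sample log2 library-size jitter.
    seed : RNG seed; identical configs with identical seeds give
        bit-identical output.
    """

    n_genes: int = 2000
    replicates: int = 3
    archetype_fractions: dict[str, float] = field(
        default_factory=lambda: {a: 0.10 for a in ARCHETYPES if a != "NULL"}
    )
    delta: float = 2.0
    delta_antag: float = 3.5
    baseline_log2_mean_range: tuple[float, float] = (3.0, 12.0)
    dispersion_log_mean: float = float(np.log(0.05))
    dispersion_log_sd: float = 0.5
    libsize_log2_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name, frac in self.archetype_fractions.items():
            if name not in ARCHETYPES or name == "NULL":
                raise ValueError(f"unknown archetype in fractions: {name!r}")
            if frac < 0:
                raise ValueError(f"negative fraction for {name}")
        total = sum(self.archetype_fractions.values())
        if total > 1 + 1e-12:
            raise ValueError(f"archetype fractions sum to {total:.3f} > 1")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates per cell")
        if not (self.delta > 1 and self.delta_antag - self.delta > 1):
            raise ValueError(
                "require delta > 1 and delta_antag - delta > 1 so planted "
                "genes satisfy the strict classification inequalities"
            )
        lo, hi = self.baseline_log2_mean_range
        if not lo < hi:
            raise ValueError("empty baseline range")


def archetype_template(
    archetype: str, delta: float = 2.0, delta_antag: float = 3.5
) -> np.ndarray:
    """Planted log2 JA effect per genotype (WT, myc2, ein3eil1, triple).

    The templates invert the classification rules: e.g. an
    EIN3/EIL1-independent gene responds in WT and *myc2* (MYC2 is
    dispensable) but not in either *ein3 eil1* background; an
    EIN3-induced / MYC2-repressed gene responds more strongly in *myc2*
    (``delta_antag``) because the repressor is gone, and not at all when
    EIN3/EIL1 are absent.
    """
    d, da = float(delta), float(delta_antag)
    templates = {
        "EIN3_INDEP_UP": (d, d, 0.0, 0.0),
        "MYC2_INDEP_UP": (d, 0.0, d, 0.0),
        "SYNERGY_UP": (d, 0.0, 0.0, 0.0),
        "EIN3_UP_MYC2_REPRESSED": (d, da, 0.0, 0.0),
        "MYC2_UP_EIN3_REPRESSED": (d, 0.0, da, 0.0),
        "NULL": (0.0, 0.0, 0.0, 0.0),
    }
    if archetype in templates:
        return np.asarray(templates[archetype], dtype=float)
    if archetype.endswith("_DOWN"):
        up = archetype[: -len("_DOWN")] + "_UP"
        if up in templates:
            return -np.asarray(templates[up], dtype=float)
    raise ValueError(f"unknown archetype label: {archetype!r}")


def _assign_archetypes(config: SimConfig) -> list[str]:
    labels = []
    for name in ARCHETYPES:
        if name == "NULL":
            continue
        frac = config.archetype_fractions.get(name, 0.0)
        labels.extend([name] * int(round(frac * config.n_genes)))
    if len(labels) > config.n_genes:
        raise ValueError("archetype fractions exceed the gene count")
    labels.extend(["NULL"] * (config.n_genes - len(labels)))
    return labels


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the full factorial experiment.

    Returns
    -------
    counts : DataFrame, genes x samples, non-negative integers.
    samples : sample sheet with sample_id, genotype, treatment, replicate
        and the true library factor (``lib_factor``, for oracle checks of
        size-factor estimation).
    truth : per-gene archetype, baseline log2 mean, dispersion and the
        four planted per-genotype log2 JA effects.

    Counts for gene g in sample j are NB with mean
    ``2**(baseline_g + effect_{g,geno(j)} * [treat(j)==JA]) * lib_factor_j``
    and variance ``mu + alpha_g * mu**2``, drawn as a gamma-Poisson mixture.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"G{i + 1:06d}" for i in range(n)]

    archetypes = _assign_archetypes(config)
    effects = np.vstack(
        [
            archetype_template(a, config.delta, config.delta_antag)
            for a in archetypes
        ]
    )  # n_genes x 4 genotypes

    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=n)
    alpha = rng.lognormal(
        config.dispersion_log_mean, config.dispersion_log_sd, size=n
    )

    sample_rows = []
    for geno in GENOTYPES:
        for treat in TREATMENTS:
            for rep in range(1, config.replicates + 1):
                sample_rows.append((f"{geno}_{treat}_r{rep}", geno, treat, rep))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "genotype", "treatment", "replicate"]
    )
    n_samples = len(samples)
    lib_log2 = (
        rng.normal(0.0, config.libsize_log2_sd, size=n_samples)
        if config.libsize_log2_sd > 0
        else np.zeros(n_samples)
    )
    lib_factor = np.exp2(lib_log2)
    samples["lib_factor"] = lib_factor

    geno_idx = samples["genotype"].map({g: i for i, g in enumerate(GENOTYPES)})
    is_ja = (samples["treatment"] == "JA").to_numpy()
    # n_genes x n_samples mean matrix
    eff = effects[:, geno_idx.to_numpy()] * is_ja[None, :]
    mu = np.exp2(baseline[:, None] + eff) * lib_factor[None, :]

    # gamma-Poisson: lambda ~ Gamma(1/alpha, alpha*mu) has mean mu,
    # var alpha*mu^2; Poisson(lambda) has var mu + alpha*mu^2
    tiny = 1e-12
    a = np.broadcast_to((1.0 / np.maximum(alpha, tiny))[:, None], mu.shape)
    if np.all(alpha < 1e-10):
        lam = mu
    else:
        lam = rng.gamma(shape=a, scale=mu / a)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples["sample_id"].to_list())
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "archetype": archetypes,
            "baseline_log2_mean": baseline,
            "dispersion": alpha,
            "effect_WT": effects[:, 0],
            "effect_myc2": effects[:, 1],
            "effect_ein3eil1": effects[:, 2],
            "effect_myc2ein3eil1": effects[:, 3],
        }
    ).set_index("gene_id")
    return counts_df, samples, truth
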