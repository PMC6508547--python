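"""Five-way rule classifier, fold-change table assembly, Venn regions."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jacatlas import categories, sim
from jacatlas.categories import CATEGORIES, ClassifyConfig


def make_row(fc_wt=0.0, fc_myc2=0.0, fc_ein=0.0, fc_triple=0.0,
             x_myc2=0.0, x_ein=0.0, sig=True):
    padj = 0.001 if sig else 0.9
    return pd.Series(
        {
            "fc_wt": fc_wt, "fc_myc2": fc_myc2, "fc_ein": fc_ein,
            "fc_triple": fc_triple, "x_myc2": x_myc2, "x_ein": x_ein,
            "padj_wt": padj, "padj_myc2": padj, "padj_ein": padj,
            "padj_triple": padj,
        }
    )


ratio_values = st.floats(min_value=-5, max_value=5, allow_nan=False)


class TestClassifyGene:
    def test_ein3_independent_up(self):
        row = make_row(fc_wt=2.5, fc_myc2=2.2, fc_ein=0.3, fc_triple=0.1,
                       x_myc2=0.2, x_ein=-0.4)
        assert categories.classify_gene(row) == {"EIN3_INDEP"}

    def test_rules_are_not_mutually_exclusive(self):
        # a synergy-shaped WT response with an amplified myc2 response under
        # JA satisfies both rule-set 3 and rule-set 4
        row = make_row(fc_wt=2.0, fc_myc2=0.4, fc_ein=0.2, fc_triple=0.0,
                       x_myc2=1.6, x_ein=-1.8)
        assert categories.classify_gene(row) == {"SYNERGY", "EIN3_UP_MYC2_REPRESSED"}

    def test_null_row_gets_no_category(self):
        assert categories.classify_gene(make_row()) == set()

    def test_boundary_ratio_exactly_one_matches_nothing(self):
        # strict inequalities: |ratio| = 1 satisfies neither >1 nor <1
        for row in (
            make_row(fc_wt=1.0, fc_myc2=1.0),
            make_row(fc_wt=2.0, fc_myc2=1.0),
            make_row(fc_wt=-1.0, fc_myc2=-1.0),
        ):
            assert categories.classify_gene(row) == set()

    def test_myc2_independent_down_with_sign_consistency(self):
        row = make_row(fc_wt=-2.0, fc_ein=-1.8, fc_myc2=0.2, x_ein=0.1)
        assert categories.classify_gene(row) == {"MYC2_INDEP"}
        # opposite directions in WT and ein3 eil1 are not "regulated in both"
        flipped = make_row(fc_wt=-2.0, fc_ein=1.8, fc_myc2=0.2, x_ein=0.1)
        assert "MYC2_INDEP" not in categories.classify_gene(flipped)

    def test_antagonistic_myc2_up_ein3_repressed(self):
        # fc_ein is unconstrained by rule-set 5 (only the mirrored rule-set 4
        # pins it); fc_ein = 1.5 here keeps SYNERGY from co-firing
        row = make_row(fc_wt=1.5, fc_myc2=0.3, fc_ein=1.5, fc_triple=0.2,
                       x_ein=1.4, x_myc2=-1.3)
        assert categories.classify_gene(row) == {"MYC2_UP_EIN3_REPRESSED"}

    def test_changed_legs_require_significance_by_default(self):
        row = make_row(fc_wt=2.5, fc_myc2=2.2, sig=False)
        assert categories.classify_gene(row) == set()
        cfg = ClassifyConfig(criteria="fc_only")
        assert categories.classify_gene(row, cfg) == {"EIN3_INDEP"}

    def test_priority_mode_keeps_most_constrained_label(self):
        row = make_row(fc_wt=2.0, fc_myc2=0.4, fc_ein=0.2, fc_triple=0.0,
                       x_myc2=1.6, x_ein=-1.8)
        cfg = ClassifyConfig(mode="priority")
        assert categories.classify_gene(row, cfg) == {"EIN3_UP_MYC2_REPRESSED"}

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(fc_wt=ratio_values, fc_myc2=ratio_values, fc_ein=ratio_values,
           fc_triple=ratio_values, x_myc2=ratio_values, x_ein=ratio_values)
    def test_provable_exclusivities_hold(self, fc_wt, fc_myc2, fc_ein,
                                         fc_triple, x_myc2, x_ein):
        labels = categories.classify_gene(
            make_row(fc_wt, fc_myc2, fc_ein, fc_triple, x_myc2, x_ein)
        )
        # each pair is contradicted by one shared ratio's two-sided constraint
        assert not {"EIN3_INDEP", "SYNERGY"} <= labels  # |fc_myc2| both sides
        assert not {"EIN3_INDEP", "EIN3_UP_MYC2_REPRESSED"} <= labels  # x_myc2
        assert not {"MYC2_INDEP", "SYNERGY"} <= labels  # |fc_ein|
        assert not {"MYC2_INDEP", "MYC2_UP_EIN3_REPRESSED"} <= labels  # x_ein


class TestClassifyAll:
    def _table(self, rows):
        return pd.DataFrame([make_row(**r) for r in rows],
                            index=[f"G{i}" for i in range(len(rows))])

    def test_empty_table(self):
        table = self._table([]).reindex(columns=make_row().index)
        assignments, summary = categories.classify_all(table)
        assert len(assignments) == 0
        assert (summary["count"] == 0).all()

    def test_summary_splits_up_down_and_flags_multilabel(self):
        table = self._table(
            [
                dict(fc_wt=2.5, fc_myc2=2.2),            # EIN3_INDEP up
                dict(fc_wt=-2.5, fc_myc2=-2.2),          # EIN3_INDEP down
                dict(fc_wt=2.0, x_myc2=1.6, x_ein=-1.8), # SYNERGY + antag 4
                dict(),                                   # null
            ]
        )
        assignments, summary = categories.classify_all(table)
        s = summary.set_index("category")
        assert s.loc["EIN3_INDEP", ["count", "n_up", "n_down"]].tolist() == [2, 1, 1]
        assert s.loc["SYNERGY", "count"] == 1
        assert s.loc["EIN3_UP_MYC2_REPRESSED", "count"] == 1
        assert assignments["multi_label"].sum() == 1
        assert assignments.loc["G3", "labels"] == ""

    def test_priority_mode_partitions(self):
        rng = np.random.default_rng(0)
        rows = [
            dict(zip(
                ("fc_wt", "fc_myc2", "fc_ein", "fc_triple", "x_myc2", "x_ein"),
                rng.uniform(-4, 4, 6),
            ))
            for _ in range(300)
        ]
        table = self._table(rows)
        assignments, summary = categories.classify_all(
            table, ClassifyConfig(mode="priority")
        )
        assert (assignments["n_labels"] <= 1).all()
        assert summary["count"].sum() <= len(table)

    def test_gene_order_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        rows = [
            dict(zip(
                ("fc_wt", "fc_myc2", "fc_ein", "fc_triple", "x_myc2", "x_ein"),
                rng.uniform(-4, 4, 6),
            ))
            for _ in range(50)
        ]
        table = self._table(rows)
        shuffled = table.sample(frac=1, random_state=3)
        a1, _ = categories.classify_all(table)
        a2, _ = categories.classify_all(shuffled)
        pd.testing.assert_frame_equal(a1.loc[shuffled.index], a2)


class TestFoldChangeTable:
    def test_no_signal_input_gives_zero_ratios(self, rng):
        samples = []
        for geno in sim.GENOTYPES:
            for treat in ("JA", "Mock"):
                for rep in (1, 2, 3):
                    samples.append((f"{geno}_{treat}_r{rep}", geno, treat, rep))
        samples = pd.DataFrame(
            samples, columns=["sample_id", "genotype", "treatment", "replicate"]
        )
        col = rng.poisson(100, 30) + 1
        counts = pd.DataFrame(
            {s: col for s in samples["sample_id"]},
            index=[f"G{i}" for i in range(30)],
        )
        table = categories.build_fold_change_table(counts, samples)
        for c in categories.RATIO_COLUMNS:
            np.testing.assert_allclose(table[c].to_numpy(), 0.0)

    def test_swapping_treatment_labels_negates_within_ratios(self, small_sim):
        _, counts, samples, _ = small_sim
        table = categories.build_fold_change_table(counts, samples,
                                                   normalization="plain")
        swapped = samples.copy()
        swapped["treatment"] = swapped["treatment"].map({"JA": "Mock", "Mock": "JA"})
        table_swapped = categories.build_fold_change_table(counts, swapped,
                                                           normalization="plain")
        for c in ("fc_wt", "fc_myc2", "fc_ein", "fc_triple"):
            np.testing.assert_allclose(
                table_swapped[c].to_numpy(), -table[c].to_numpy(), atol=1e-9
            )

    def test_planted_template_recovered_at_high_replication(self):
        # EIN3-independent up template (2,2,0,0) at low noise, r=50: the four
        # table ratios land close to their expectations
        cfg = sim.SimConfig(
            n_genes=60,
            replicates=50,
            archetype_fractions={"EIN3_INDEP_UP": 0.4},
            dispersion_log_mean=np.log(1e-3),
            dispersion_log_sd=0.0,
            libsize_log2_sd=0.0,
            baseline_log2_mean_range=(7.0, 10.0),
            seed=17,
        )
        counts, samples, truth = sim.simulate_counts(cfg)
        table = categories.build_fold_change_table(counts, samples,
                                                   normalization="plain")
        planted = truth["archetype"] == "EIN3_INDEP_UP"
        sub = table[planted.to_numpy()]
        assert np.allclose(sub["fc_wt"], 2.0, atol=0.3)
        assert np.allclose(sub["fc_myc2"], 2.0, atol=0.3)
        assert np.allclose(sub["fc_ein"], 0.0, atol=0.3)
        assert np.allclose(sub["x_myc2"], 0.0, atol=0.3)

    def test_missing_genotype_cell_fails(self, small_sim):
        _, counts, samples, _ = small_sim
        crippled = samples[samples["genotype"] != "myc2"]
        with pytest.raises(ValueError, match="myc2"):
            categories.build_fold_change_table(counts, crippled)


class TestVennOverlaps:
    def test_identical_sets_concentrate_in_center(self):
        genes = {f"g{i}" for i in range(25)}
        regions = categories.venn_overlaps({k: set(genes) for k in "ABCD"})
        assert regions == {"A+B+C+D": 25}

    def test_disjoint_sets_fill_exclusive_regions(self):
        sets = {k: {f"{k}{i}" for i in range(5)} for k in "ABCD"}
        regions = categories.venn_overlaps(sets)
        assert regions == {"A": 5, "B": 5, "C": 5, "D": 5}

    def test_matches_membership_enumeration(self, rng):
        universe = [f"g{i}" for i in range(200)]
        sets = {
            k: set(rng.choice(universe, size=rng.integers(10, 120), replace=False))
            for k in "ABCD"
        }
        regions = categories.venn_overlaps(sets)
        # brute force over all 2^4 membership patterns
        expected = {}
        for pattern in itertools.product([False, True], repeat=4):
            if not any(pattern):
                continue
            members = set(universe)
            for k, inside in zip("ABCD", pattern):
                members = members & sets[k] if inside else members - sets[k]
            if members:
                key = "+".join(k for k, inside in zip("ABCD", pattern) if inside)
                expected[key] = len(members)
        assert regions == expected
        assert sum(regions.values()) == len(set().union(*sets.values()))
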