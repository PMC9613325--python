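"""BH correction, Kruskal-Wallis screening, Dunn post-hoc, trend summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import milknet as mn

from .conftest import brute_force_bh, toy_design


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            mn.benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mn.benjamini_hochberg([0.3]), [0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mn.benjamini_hochberg([0.5, 1.2])

    def test_thousand_random_vectors_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(
                mn.benjamini_hochberg(p), brute_force_bh(p), atol=1e-12
            )

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_oracle_and_dominates_raw(self, p_list):
        p = np.array(p_list)
        adjusted = mn.benjamini_hochberg(p)
        np.testing.assert_allclose(adjusted, brute_force_bh(p), atol=1e-12)
        assert (adjusted >= p - 1e-15).all()
        assert (adjusted <= 1.0).all()


def _three_group_table(values_by_group: dict[str, list[float]]):
    rows, ids, design_rows = [], [], []
    for g, values in values_by_group.items():
        for i, v in enumerate(values):
            ids.append(f"{g}_{i}")
            rows.append(v)
            design_rows.append(("+" if "M+" in g else "-", "+" if "C+" in g else "-"))
    design = mn.StudyDesign(
        pd.DataFrame(
            design_rows,
            index=pd.Index(ids, name="sample_id"),
            columns=["mother_allergy", "child_allergy"],
        )
    )
    table = mn.AbundanceTable(
        pd.DataFrame({"P1": rows}, index=ids), state="log10-imputed"
    )
    return table, design


class TestKruskalWallis:
    def test_textbook_h_value(self):
        """Groups {1,2},{3,4},{5,6}: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 32/7."""
        table, design = _three_group_table(
            {"M-C-": [1, 2], "M+C-": [3, 4], "M-C+": [5, 6]}
        )
        out = mn.kruskal_wallis_screen(table, design)
        np.testing.assert_allclose(out.loc["P1", "h_statistic"], 32.0 / 7.0)

    def test_complete_ties_give_h_zero_p_one(self):
        table, design = _three_group_table(
            {"M-C-": [5, 5], "M+C-": [5, 5], "M-C+": [5, 5]}
        )
        out = mn.kruskal_wallis_screen(table, design)
        assert out.loc["P1", "h_statistic"] == 0.0
        assert out.loc["P1", "p_value"] == 1.0

    def test_rank_invariance_under_exp(self, imputed_small):
        table, design, _, _ = imputed_small
        base = mn.kruskal_wallis_screen(table, design)
        warped = table.with_data(np.exp(table.data), state="log10-imputed")
        out = mn.kruskal_wallis_screen(warped, design)
        np.testing.assert_allclose(
            out["h_statistic"], base["h_statistic"], atol=1e-10
        )

    def test_small_group_rejected(self):
        table, design = _three_group_table({"M-C-": [1.0], "M+C-": [2, 3]})
        with pytest.raises(ValueError, match="fewer than 2"):
            mn.kruskal_wallis_screen(table, design)

    def test_global_null_fdr_controlled(self):
        """No planted shifts: BH-adjusted discoveries stay near zero."""
        design = toy_design(15)
        rng = np.random.default_rng(7)
        fractions = []
        for _ in range(50):
            data = pd.DataFrame(
                rng.normal(6, 1, size=(60, 40)),
                index=design.sample_ids,
                columns=[f"P{j}" for j in range(40)],
            )
            out = mn.kruskal_wallis_screen(
                mn.AbundanceTable(data, state="log10-imputed"), design
            )
            fractions.append(float((out["p_adjusted"] < 0.05).mean()))
        assert np.mean(fractions) <= 0.05 + 0.03


class TestDunnPosthoc:
    def test_identical_groups_give_z_zero_p_one(self):
        table, design = _three_group_table(
            {"M-C-": [4, 4, 4], "M+C-": [4, 4, 4]}
        )
        kw = mn.kruskal_wallis_screen(table, design)
        kw.loc["P1", "p_value"] = 0.01  # force through the candidate gate
        out = mn.dunn_posthoc(table, design, kw_results=kw)
        assert (out["z"] == 0).all()
        assert (out["p_value"] == 1.0).all()

    def test_ordered_groups_extreme_pair_has_largest_z(self):
        table, design = _three_group_table(
            {"M-C-": [1, 2, 3], "M+C-": [4, 5, 6], "M-C+": [7, 8, 9]}
        )
        out = mn.dunn_posthoc(table, design, candidate_alpha=1.1)
        out = out.set_index(["group_a", "group_b"])
        z_extreme = abs(out.loc[("M-C-", "M-C+"), "z"])
        assert z_extreme > abs(out.loc[("M-C-", "M+C-"), "z"])
        assert z_extreme > abs(out.loc[("M+C-", "M-C+"), "z"])

    def test_pair_reversal_negates_z_and_flips_trend(self, imputed_small):
        table, design, _, _ = imputed_small
        out = mn.dunn_posthoc(table, design, candidate_alpha=1.1)
        row = out.iloc[0]
        a, b, protein = row["group_a"], row["group_b"], row["protein_id"]
        values = table.data[protein].to_numpy()
        labels = design.groups.reindex(table.sample_ids).to_numpy()
        from milknet.univariate import _dunn_z

        assert _dunn_z(values, labels, b, a) == pytest.approx(-row["z"], abs=1e-12)

    def test_empty_candidate_set_gives_empty_output(self):
        table, design = _three_group_table(
            {"M-C-": [1, 2, 3], "M+C-": [1.5, 2.5, 3.5]}
        )
        kw = mn.kruskal_wallis_screen(table, design)
        kw["p_value"] = 0.9
        out = mn.dunn_posthoc(table, design, kw_results=kw)
        assert out.empty

    def test_per_protein_family_adjusts_within_protein(self, imputed_small):
        table, design, _, _ = imputed_small
        pooled = mn.dunn_posthoc(table, design, candidate_alpha=0.5)
        per = mn.dunn_posthoc(
            table, design, candidate_alpha=0.5, bh_family="per-protein"
        )
        assert len(pooled) == len(per)
        # same raw p-values; only the correction family differs
        np.testing.assert_allclose(pooled["p_value"], per["p_value"])
        assert (per["p_adjusted"] >= per["p_value"] - 1e-15).all()


class TestTrendSummary:
    def test_log10_mean_ratio_definition(self):
        """Group means 10^6 vs 10^5 on the raw scale -> log10-mean ratio 1.2."""
        design = toy_design(2, groups=("M-C-", "M+C-"))
        data = pd.DataFrame(
            {"P1": [6.0, 6.0, 5.0, 5.0]}, index=design.sample_ids
        )
        annotation = pd.DataFrame({"protein_id": ["P1"], "keyword": ["Ig"]})
        per_protein, per_keyword = mn.abundance_trend_summary(
            mn.AbundanceTable(data, state="log10-imputed"),
            design, annotation, ("M-C-", "M+C-"),
        )
        assert per_protein.loc["P1", "ratio"] == pytest.approx(1.2)
        assert per_protein.loc["P1", "higher_in"] == "M-C-"
        assert per_keyword.loc["Ig", "higher_in_M-C-"] == 1

    def test_equal_means_give_ratio_one_no_trend(self):
        design = toy_design(2, groups=("M-C-", "M+C-"))
        data = pd.DataFrame({"P1": [5.0, 5.0, 5.0, 5.0]}, index=design.sample_ids)
        annotation = pd.DataFrame({"protein_id": ["P1"], "keyword": ["x"]})
        per_protein, _ = mn.abundance_trend_summary(
            mn.AbundanceTable(data, state="log10-imputed"),
            design, annotation, ("M-C-", "M+C-"),
        )
        assert per_protein.loc["P1", "ratio"] == 1.0
        assert per_protein.loc["P1", "higher_in"] == "none"

    def test_keyword_counts_recover_planted_shift_structure(self):
        """83 tagged proteins, 77 shifted up in one group -> the summary counts
        77 of 83 higher in that group (the immunoglobulin-trend structure)."""
        shifted = tuple(range(77))
        cfg = mn.SyntheticConfig(
            n_per_group=40, n_proteins=100,
            shifted_set=mn.ShiftSpec(shifted, "Ig", "M-C+", 0.6),
            seed=19,
        )
        table, design, annotation, truth = mn.generate_lfq_dataset(cfg)
        # tag 6 extra unshifted proteins so the keyword set has 83 members
        annotation.loc[77:82, "keyword"] = "Ig"
        logged = mn.log10_transform(table)
        complete = logged.with_data(truth.true_log10, state="log10-imputed")
        per_protein, per_keyword = mn.abundance_trend_summary(
            complete, design, annotation, ("M-C+", "M-C-")
        )
        assert per_keyword.loc["Ig", "total"] == 83
        ig = per_protein[per_protein["keyword"] == "Ig"]
        shifted_ids = set(truth.differential_proteins)
        higher = ig.index[ig["higher_in"] == "M-C+"]
        assert shifted_ids <= set(higher)
        assert per_keyword.loc["Ig", "higher_in_M-C+"] >= 77

    def test_unannotated_proteins_counted_separately(self, imputed_small):
        table, design, _, _ = imputed_small
        annotation = pd.DataFrame(
            {"protein_id": table.protein_ids[:3], "keyword": ["a", "a", "b"]}
        )
        per_protein, per_keyword = mn.abundance_trend_summary(
            table, design, annotation, ("M-C-", "M+C+")
        )
        assert (per_protein["keyword"] == "unannotated").sum() == table.n_proteins - 3
        assert "unannotated" in per_keyword.index
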