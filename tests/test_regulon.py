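"""Replicate averaging, fold-change ratios, and regulon scoring."""

import numpy as np
import pandas as pd
import pytest

from phshock import regulon, simulate
from phshock.pipeline import _default_synthetic_regulons
from phshock.regulon import RegulonSet


@pytest.fixture
def toy_condition_matrix():
    genes = [f"g{i}" for i in range(6)]
    return pd.DataFrame({
        "mock|allowed|active": [10.0, 10, 10, 10, 10, 10],
        "shock|allowed|active": [100.0, 10, 10, 10, 10, 10],
        "shock|allowed|cycloheximide": [40.0, 40, 10, 10, 10, 10],
        "shock|prevented|cycloheximide": [10.0, 10, 10, 10, 10, 10],
    }, index=pd.Index(genes, name="gene"))


class TestCombineReplicates:
    def test_identical_replicates_unchanged(self):
        tpm = pd.DataFrame({"s1": [2.0, 4.0], "s2": [2.0, 4.0]},
                           index=["g1", "g2"])
        samples = pd.DataFrame({
            "sample": ["s1", "s2"], "temperature": ["mock"] * 2,
            "acidification": ["allowed"] * 2, "translation": ["active"] * 2,
            "replicate": [1, 2],
        })
        cond = regulon.combine_replicates(tpm, samples)
        np.testing.assert_allclose(cond["mock|allowed|active"], [2.0, 4.0])

    def test_mean_of_two_replicates(self):
        tpm = pd.DataFrame({"s1": [2.0], "s2": [4.0]}, index=["g1"])
        samples = pd.DataFrame({
            "sample": ["s1", "s2"], "temperature": ["mock"] * 2,
            "acidification": ["allowed"] * 2, "translation": ["active"] * 2,
        })
        cond = regulon.combine_replicates(tpm, samples)
        assert cond.iloc[0, 0] == pytest.approx(3.0)

    def test_replicate_averaging_reduces_noise(self, truth):
        regs = _default_synthetic_regulons(np.random.default_rng(1))
        cfg = simulate.SimConfig(tpm_cv=0.2, n_replicates=2, n_background_genes=500)
        tpm, samples = simulate.simulate_expression(regs, cfg, truth, renormalize=False)
        cond = regulon.combine_replicates(tpm, samples)
        reps = tpm[["mock_allowed_rep1", "mock_allowed_rep2"]]
        resid_single = np.log(reps.iloc[:, 0]).std()
        resid_mean = np.log(cond["mock|allowed|cycloheximide"]).std()
        assert resid_mean <= resid_single  # averaging cannot inflate spread

    def test_missing_condition_errors(self):
        tpm = pd.DataFrame({"s1": [2.0]}, index=["g1"])
        samples = pd.DataFrame({
            "sample": ["other"], "temperature": ["mock"],
            "acidification": ["allowed"], "translation": ["active"],
        })
        with pytest.raises(ValueError, match="matching"):
            regulon.combine_replicates(tpm, samples)


class TestFoldChanges:
    def test_equal_abundance_gives_unity(self, toy_condition_matrix):
        fc = regulon.induction_fold_change(toy_condition_matrix, pseudo=0.0)
        assert fc.loc["g1"] == pytest.approx(1.0)

    def test_ten_vs_one_without_pseudocount(self):
        cond = pd.DataFrame({
            "shock|allowed|active": [10.0], "mock|allowed|active": [1.0],
        }, index=["g"])
        fc = regulon.induction_fold_change(cond, pseudo=0.0)
        assert fc.loc["g"] == pytest.approx(10.0)

    def test_acidification_ratio_exact_construction(self, toy_condition_matrix):
        ratio = regulon.acidification_fold_change(toy_condition_matrix, pseudo=0.0)
        np.testing.assert_allclose(ratio, [4.0, 4.0, 1.0, 1.0, 1.0, 1.0])

    def test_missing_condition_named_in_error(self, toy_condition_matrix):
        with pytest.raises(ValueError, match="glucose-withdrawal"):
            regulon.acidification_fold_change(
                toy_condition_matrix, translation="glucose-withdrawal")

    def test_renormalization_compresses_but_preserves_ratio_of_medians(self, truth):
        """tpm is compositional: a 4x induced set occupying part of the
        transcriptome pulls member ratios slightly below 4 and non-members
        slightly below 1, while the member/non-member median ratio stays 4."""
        regs = [RegulonSet("Hsf1", tuple(f"H{i}" for i in range(60)))]
        cfg = simulate.SimConfig(tpm_cv=0.0, n_background_genes=800)
        tpm, samples = simulate.simulate_expression(regs, cfg, truth, renormalize=True)
        cond = regulon.combine_replicates(tpm, samples)
        ratio = regulon.acidification_fold_change(cond, pseudo=0.0)
        members = [f"H{i}" for i in range(60)]
        member_med = ratio.loc[members].median()
        others_med = ratio.drop(members).median()
        assert member_med < 4.0 and others_med < 1.0
        assert member_med / others_med == pytest.approx(4.0, rel=1e-9)


class TestScoreRegulons:
    def make_stats(self, rng, n_bg=300):
        genes = [f"H{i}" for i in range(10)] + [f"b{i}" for i in range(n_bg)]
        induction = pd.Series(1.0, index=pd.Index(genes, name="gene"))
        acid = pd.Series(
            np.concatenate([np.full(10, 4.0) * np.exp(0.1 * rng.standard_normal(10)),
                            np.exp(0.1 * rng.standard_normal(n_bg))]),
            index=induction.index)
        return induction, acid

    def test_small_regulon_dropped(self, rng):
        induction, acid = self.make_stats(rng)
        regs = [RegulonSet("Tiny", ("b1", "b2", "b3")),
                RegulonSet("Hsf1", tuple(f"H{i}" for i in range(10)))]
        table = regulon.score_regulons(induction, acid, regs)
        assert "Tiny" not in set(table["tf"])
        assert table.attrs["dropped"][0]["tf"] == "Tiny"

    def test_median_of_ratios(self):
        genes = ["a", "b", "c"] + [f"b{i}" for i in range(10)]
        induction = pd.Series(1.0, index=pd.Index(genes, name="gene"))
        acid = pd.Series([2.0, 4.0, 8.0] + [1.0] * 10, index=induction.index)
        table = regulon.score_regulons(
            induction, acid, [RegulonSet("R", ("a", "b", "c"))], min_size=3)
        assert table["median_acid_fold"].iloc[0] == pytest.approx(4.0)

    def test_core_genes_excluded_from_other_regulons(self, rng):
        induction, acid = self.make_stats(rng)
        hsf_genes = tuple(f"H{i}" for i in range(10))
        regs = [
            RegulonSet("Hsf1", hsf_genes),
            RegulonSet("Other", hsf_genes[:4] + ("b1", "b2", "b3", "b4", "b5")),
        ]
        cleaned = regulon.exclude_core_regulon_genes(regs)
        assert set(cleaned[1].genes).isdisjoint(hsf_genes)
        table = regulon.score_regulons(induction, acid, regs)
        other = table[table["tf"] == "Other"].iloc[0]
        assert other["n_genes"] == 5  # only the background genes survive

    def test_empty_regulon_list_rejected(self, rng):
        induction, acid = self.make_stats(rng)
        with pytest.raises(ValueError, match="empty"):
            regulon.score_regulons(induction, acid, [])

    def test_planted_regulon_top_ranked(self, truth):
        regs = _default_synthetic_regulons(np.random.default_rng(3))
        tpm, samples = simulate.simulate_expression(regs, simulate.SimConfig(), truth)
        cond = regulon.combine_replicates(tpm, samples)
        induction = regulon.induction_fold_change(cond, translation="cycloheximide")
        acid = regulon.acidification_fold_change(cond)
        table = regulon.score_regulons(induction, acid, regs)
        top = table.sort_values("median_acid_fold", ascending=False).iloc[0]
        assert top["tf"] == "Hsf1"
        assert top["p_vs_background"] < 1e-6


class TestRegulonVsBackground:
    def test_identical_distributions_not_significant(self, rng):
        sample = np.exp(0.2 * rng.standard_normal(100))
        _, p = regulon.test_regulon_vs_background(sample, sample.copy())
        assert p > 0.9

    def test_overlapping_gene_sets_rejected(self):
        s = pd.Series([1.0] * 10, index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="overlap"):
            regulon.test_regulon_vs_background(s.iloc[:6], s.iloc[4:])

    def test_small_regulon_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            regulon.test_regulon_vs_background([1.0, 2.0, 3.0], np.ones(100))

    def test_planted_effect_detected(self, rng):
        reg = 4.0 * np.exp(0.2 * rng.standard_normal(40))
        bg = np.exp(0.2 * rng.standard_normal(2000))
        _, p = regulon.test_regulon_vs_background(reg, bg)
        assert p < 1e-6


class TestGmt:
    def test_round_trip(self, tmp_path):
        sets = [RegulonSet("Hsf1", ("HSP104", "SSA4"), "heat-shock-annotated"),
                RegulonSet("Msn2/4", ("CTT1", "HSP12", "TPS1"))]
        path = tmp_path / "sets.gmt"
        regulon.write_gmt(sets, path)
        back = regulon.read_gmt(path)
        assert back == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError, match="malformed|GMT"):
            regulon.read_gmt(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            regulon.read_gmt(path)
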