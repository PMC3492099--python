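"""Model/Results workflow: training, scanning, classification, evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from sitelogic.encoding import EncodedDataset
from sitelogic.logic import Cube
from sitelogic.model import SitePredictor, SiteRuleModel, encode_windows
from sitelogic.pipelines import (
    EvalReport,
    SplitPlan,
    build_splits,
    evaluate,
    match_predictions,
    tfbs_experiment,
)
from sitelogic.rules import Cutoff, ScoredRule, ScoredRuleSet
from sitelogic.simulate import MotifSpec, generate_background_dna, implant_motifs


@pytest.fixture(scope="module")
def trained_tfbs():
    """A small, strong-signal binding-site model shared across tests."""
    rng = np.random.default_rng(11)
    from sitelogic.simulate import sample_motif_instance

    spec = MotifSpec(mutation_rate=0.0)
    pos = [sample_motif_instance(spec, rng) for _ in range(40)]
    bg = generate_background_dna(2000, rng=rng)
    neg = [bg[i : i + 14] for i in range(0, 40 * 14, 14)]
    model = SiteRuleModel(pos + neg, [1] * 40 + [0] * 40, kind="tfbs", k=22)
    return model.fit()


class TestFitOnEncodedTable:
    def test_worked_table_recovers_published_rules(self, table_positive_dataset):
        # append the off-set rows so both classes are present
        off_rows = [format(m, "04b") for m in (1, 4, 5, 9, 12, 13)]
        patterns = np.vstack(
            [
                table_positive_dataset.patterns,
                np.array([[int(c) for c in r] for r in off_rows]),
            ]
        )
        labels = np.array([1] * 6 + [0] * 6)
        ds = EncodedDataset(patterns=patterns, labels=labels, meanings=[])
        res = SiteRuleModel.from_encoded(ds, k=4).fit()
        assert [(r.cube.literals, r.score) for r in res.ruleset] == [
            ("--1-", 4),
            ("-0-0", 4),
        ]
        assert res.minimizer == "quine-mccluskey"

    def test_single_class_rejected(self):
        ds = EncodedDataset(
            patterns=np.array([[0, 1], [1, 0]]),
            labels=np.array([1, 1]),
            meanings=[],
        )
        with pytest.raises(ValueError, match="both classes"):
            SiteRuleModel.from_encoded(ds).fit()


class TestTrainedModel:
    def test_training_sensitivity_is_complete(self, trained_tfbs):
        assert trained_tfbs.training_sensitivity() == 1.0

    def test_rules_defined_over_selected_variables(self, trained_tfbs):
        assert trained_tfbs.ruleset.n_vars == 22
        assert len(trained_tfbs.ranking.selected) == 22

    def test_strong_consensus_rule_literals_on_consensus(self, trained_tfbs):
        sel = trained_tfbs.ranking.selected
        for rule in trained_tfbs.ruleset:
            positions = {
                sel[j] // 4 + 1
                for j, lit in enumerate(rule.cube.literals)
                if lit != "-"
            }
            assert positions <= {6, 7, 8, 9, 10}

    def test_summary_mentions_rules_and_meanings(self, trained_tfbs):
        text = trained_tfbs.summary()
        assert "Rules" in text and "Nucleotide" in text
        assert "training sensitivity" in text

    def test_ranking_table_shape(self, trained_tfbs):
        table = trained_tfbs.ranking_table()
        assert list(table.columns) == ["ranking", "variable", "meaning"]
        assert len(table) == 22
        assert table["variable"].between(1, 56).all()


class TestScanSequence:
    def test_window_count_is_length_minus_width_plus_one(self, trained_tfbs):
        for L in (14, 15, 200, 731):
            seq = generate_background_dna(L, seed=L)
            assert len(trained_tfbs.scan_sequence(seq)) == L - 14 + 1

    def test_sequence_equal_to_site_scores_at_start_one(self, trained_tfbs):
        rng = np.random.default_rng(1)
        from sitelogic.simulate import sample_motif_instance

        site = sample_motif_instance(MotifSpec(mutation_rate=0.0), rng)
        scores = trained_tfbs.scan_sequence(site)
        assert scores[0].pattern_id == 1 and scores[0].score > 0

    def test_implanted_sites_recovered(self, trained_tfbs):
        rng = np.random.default_rng(2)
        bg = generate_background_dna(4000, rng=rng)
        seq, starts = implant_motifs(
            bg, MotifSpec(mutation_rate=0.0), n_sites=5, rng=rng
        )
        pred = trained_tfbs.predict_sites(seq)
        report = match_predictions(pred, starts, tolerance=2)
        assert report.TP == 5

    def test_too_short_sequence_rejected(self, trained_tfbs):
        with pytest.raises(ValueError, match="shorter"):
            trained_tfbs.scan_sequence("ACGT")

    def test_protein_model_required_for_st_classification(self, trained_tfbs):
        with pytest.raises(ValueError, match="protein"):
            trained_tfbs.classify_st_windows("MSTSTP")


class TestClassifyStWindows:
    @pytest.fixture
    def predictor(self):
        # hand-built predictor: one rule, "position +2 is T", over 2 columns
        from sitelogic.encoding import variable_index, variable_meaning

        cols = (
            variable_index(2, "T", "protein") - 1,
            variable_index(-1, "P", "protein") - 1,
        )
        meanings = tuple(variable_meaning(c + 1, "protein") for c in cols)
        return SitePredictor(
            kind="glyco",
            window_length=11,
            center="T",
            selected=cols,
            ruleset=ScoredRuleSet(
                rules=(ScoredRule(Cube("1-"), 5),), n_vars=2, meanings=meanings
            ),
        )

    def test_no_candidate_residues_gives_empty_frame(self, predictor):
        df = predictor.classify_st_windows("MGAKLV")
        assert len(df) == 0

    def test_candidate_windows_scored(self, predictor):
        # central T with T two residues later fires the rule
        df = predictor.classify_st_windows("AAAAA" + "TAT" + "AAAAAA")
        assert df.iloc[0]["position"] == 6
        assert df.iloc[0]["score"] == 5

    def test_truncated_flank_padded_with_unknown(self, predictor):
        df = predictor.classify_st_windows("AATGGGGGGGG")
        assert df.iloc[0]["window"].startswith("XX")
        assert len(df.iloc[0]["window"]) == 11


class TestMatchPredictions:
    def test_within_tolerance_is_true_positive(self):
        r = match_predictions([102], [100], tolerance=2)
        assert (r.TP, r.FP, r.FN) == (1, 0, 0)

    def test_outside_tolerance_counts_both_errors(self):
        r = match_predictions([103], [100], tolerance=2)
        assert (r.TP, r.FP, r.FN) == (0, 1, 1)

    def test_one_to_one_matching(self):
        r = match_predictions([99, 101], [100], tolerance=2)
        assert (r.TP, r.FP, r.FN) == (1, 1, 0)

    def test_nearest_first_assignment(self):
        r = match_predictions([100, 104], [100, 103], tolerance=2)
        assert (r.TP, r.FP, r.FN) == (2, 0, 0)

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_predictions([1], [1], tolerance=-1)


class TestEvaluate:
    def test_published_counts_give_published_percentages(self):
        r = evaluate(TP=7, FP=219, FN=1)
        assert r.sensitivity == pytest.approx(87.5)
        assert r.ppv == pytest.approx(3.097, abs=5e-4)

    def test_zero_true_positives(self):
        assert evaluate(TP=0, FP=3, FN=5).sensitivity == 0.0

    def test_perfect_precision(self):
        assert evaluate(TP=4, FP=0, FN=0).ppv == 100.0

    def test_undefined_ratios_are_none_not_zero(self):
        r = EvalReport(TP=0, FP=0, FN=0)
        assert r.sensitivity is None and r.ppv is None


class TestBuildSplits:
    def test_ninety_percent_of_73_positives(self):
        rng = np.random.default_rng(0)
        pos = [f"P{i}" for i in range(73)]
        neg = [f"N{i}" for i in range(200)]
        splits = build_splits(pos, neg, SplitPlan(n_replicates=3, train_fraction=0.9), rng=rng)
        for s in splits:
            n_train_pos = int(s.train_labels.sum())
            assert n_train_pos == 66
            assert len(s.test_positives) == 7
            assert set(s.test_positives).isdisjoint(
                w for w, y in zip(s.train_windows, s.train_labels) if y
            )
            # balanced negatives
            assert (s.train_labels == 0).sum() == n_train_pos

    def test_half_split_of_ten(self):
        rng = np.random.default_rng(1)
        splits = build_splits(
            [f"P{i}" for i in range(10)],
            [f"N{i}" for i in range(40)],
            SplitPlan(n_replicates=1, train_fraction=0.5),
            rng=rng,
        )
        assert int(splits[0].train_labels.sum()) == 5
        assert len(splits[0].test_positives) == 5

    def test_insufficient_negative_pool_rejected(self):
        with pytest.raises(ValueError, match="pool"):
            build_splits(
                ["P"] * 10,
                ["N"] * 3,
                SplitPlan(n_replicates=1, train_fraction=0.5),
                seed=0,
            )


class TestExperimentSmoke:
    def test_tfbs_replicates_account_for_all_heldout_sites(self):
        reps = tfbs_experiment(
            n_sites=30,
            genome_length=4000,
            plan=SplitPlan(n_replicates=2, train_fraction=0.9),
            seed=5,
        )
        assert len(reps) == 2
        for r in reps:
            assert r.report.TP + r.report.FN == len(r.true_starts)
            assert r.results.training_sensitivity() == 1.0


class TestModelValidation:
    def test_mixed_window_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            SiteRuleModel(["ACGT", "ACGTA"], [1, 0])

    def test_mixed_glyco_centers_rejected(self):
        with pytest.raises(ValueError, match="central residue"):
            SiteRuleModel(
                ["AAAAATAAAAA", "AAAAASAAAAA"], [1, 0], kind="glyco"
            )

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            SiteRuleModel(["ACGT", "AAAA"], [1, 2])
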