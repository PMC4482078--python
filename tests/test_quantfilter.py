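import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from silacodon import quantfilter, synthdata
from silacodon.quantfilter import (FilterConfig, aggregate, consistency_filter,
                                   high_confidence, orient,
                                   probability_threshold_at_fdr,
                                   retain_proteins, run_filter)
from conftest import make_peptide_frame

BOUND = math.sqrt(2) * 0.4


class TestProbabilityThreshold:
    def test_perfect_confidence(self):
        assert probability_threshold_at_fdr([1.0] * 5, 0.01) == 1.0

    def test_hand_enumerated_prefixes(self):
        # prefix of ten 0.99s: FDR = 0.1/10 = 0.01; adding 0.5: 0.6/11 > 0.01
        probs = [0.99] * 10 + [0.5]
        assert probability_threshold_at_fdr(probs, 0.01) == 0.99

    def test_nothing_passes(self):
        assert probability_threshold_at_fdr([0.5], 0.01) == math.inf

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            probability_threshold_at_fdr([], 0.01)

    def test_monotone_in_target(self):
        rng = np.random.default_rng(1)
        probs = rng.beta(8, 1, 200)
        prev = set()
        for target in (0.001, 0.01, 0.05, 0.2):
            thr = probability_threshold_at_fdr(probs, target)
            passing = {i for i, p in enumerate(probs) if p >= thr}
            assert prev <= passing
            prev = passing


class TestOrient:
    def test_sign_identity(self):
        df = make_peptide_frame([("p", "A", "r1", 1, 0.7, 0.99)])
        assert orient(df)["oriented"].iloc[0] == pytest.approx(0.7)

    def test_sign_flip(self):
        df = make_peptide_frame([("p", "A", "r1", -1, 0.7, 0.99)])
        assert orient(df)["oriented"].iloc[0] == pytest.approx(-0.7)

    @given(st.lists(st.tuples(st.sampled_from([1, -1]),
                              st.floats(-10, 10)), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_involution(self, pairs):
        df = make_peptide_frame([
            (f"p{i}", "A", "r1", d, x, 0.99) for i, (d, x) in enumerate(pairs)])
        flipped = df.copy()
        flipped["design"] = -flipped["design"]
        flipped["log2_hl"] = -flipped["log2_hl"]
        assert np.array_equal(orient(df)["oriented"].to_numpy(),
                              orient(flipped)["oriented"].to_numpy())


class TestConsistencyFilter:
    def _table(self, m_plus, m_minus):
        return orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, m_plus, 0.99),
            ("pep1", "A", "r2", -1, -m_minus, 0.99),
        ]))

    def test_perfect_agreement_retained(self, default_filter):
        out = consistency_filter(self._table(0.3, 0.3), default_filter)
        assert len(out) == 2

    def test_disagreement_dropped(self, default_filter):
        # |0.5 - (-0.2)| = 0.7 >= sqrt(2) * 0.4
        out = consistency_filter(self._table(0.5, -0.2), default_filter)
        assert len(out) == 0

    def test_mild_disagreement_retained(self, default_filter):
        # |0.3 - (-0.1)| = 0.4 < 0.5657
        out = consistency_filter(self._table(0.3, -0.1), default_filter)
        assert len(out) == 2

    def test_single_design_dropped(self, default_filter):
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.1, 0.99),
            ("pep1", "A", "r3", 1, 0.2, 0.99),
        ]))
        assert len(consistency_filter(df, default_filter)) == 0

    def test_strict_inequality_at_bound(self):
        config = FilterConfig(c=0.4)
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, config.consistency_bound, 0.99),
            ("pep1", "A", "r2", -1, 0.0, 0.99),
        ]))
        assert len(consistency_filter(df, config)) == 0

    def test_monotone_in_c(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            rows.append((f"pep{i}", f"P{i % 40}", "r1", 1,
                         rng.normal(0, 0.6), 0.99))
            rows.append((f"pep{i}", f"P{i % 40}", "r2", -1,
                         rng.normal(0, 0.6), 0.99))
        df = orient(make_peptide_frame(rows))
        prev: set = set()
        for c in (0.1, 0.3, 0.5, 1.0, 3.0):
            out = consistency_filter(df, FilterConfig(c=c))
            kept = set(out["peptide_id"])
            assert prev <= kept
            prev = kept


class TestRetainProteins:
    def test_single_peptide_dropped(self, default_filter):
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.1, 0.99),
            ("pep1", "A", "r2", -1, 0.1, 0.99)]))
        assert retain_proteins(df, default_filter) == set()

    def test_two_peptides_both_designs_kept(self, default_filter):
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.1, 0.99),
            ("pep1", "A", "r2", -1, 0.1, 0.99),
            ("pep2", "A", "r1", 1, 0.2, 0.99),
            ("pep2", "A", "r2", -1, 0.2, 0.99)]))
        assert retain_proteins(df, default_filter) == {"A"}

    def test_membership_matches_brute_force(self, default_filter):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(300):
            rows.append((f"pep{rng.integers(60)}", f"P{rng.integers(25)}",
                         f"r{rng.integers(1, 4)}",
                         int(rng.choice([1, -1])), float(rng.normal()), 0.99))
        df = orient(make_peptide_frame(rows))
        got = retain_proteins(df, default_filter)
        expected = set()
        for protein in df["protein_id"].unique():
            grp = df[df["protein_id"] == protein]
            if grp["peptide_id"].nunique() >= 2 and \
                    set(grp["design"]) == {1, -1}:
                expected.add(protein)
        assert got == expected

    def test_design_coverage_switch(self):
        config = FilterConfig(require_both_designs=False)
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.1, 0.99),
            ("pep2", "A", "r1", 1, 0.2, 0.99)]))
        assert retain_proteins(df, config) == {"A"}
        assert retain_proteins(df, FilterConfig()) == set()


class TestAggregate:
    def test_median(self):
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.1, 0.99),
            ("pep2", "A", "r1", 1, 0.2, 0.99),
            ("pep3", "A", "r1", 1, 0.9, 0.99)]))
        matrix = aggregate(df, {"A"}, FilterConfig(normalize=False))
        assert matrix.ratios.at["A", "r1"] == pytest.approx(0.2)
        assert matrix.counts.at["A", "r1"] == 3

    def test_all_zero_stable_under_normalization(self):
        df = orient(make_peptide_frame([
            ("pep1", "A", "r1", 1, 0.0, 0.99),
            ("pep2", "A", "r1", 1, 0.0, 0.99)]))
        for normalize in (False, True):
            matrix = aggregate(df, {"A"}, FilterConfig(normalize=normalize))
            assert matrix.ratios.at["A", "r1"] == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        rows = [(f"pep{i}", f"P{rng.integers(8)}", f"r{rng.integers(1, 4)}",
                 int(rng.choice([1, -1])), float(rng.normal()), 0.99)
                for i in range(400)]
        df = orient(make_peptide_frame(rows))
        proteins = set(df["protein_id"])
        matrix = aggregate(df, proteins, FilterConfig(normalize=False))
        for protein in proteins:
            for rep in ("r1", "r2", "r3"):
                vals = df[(df["protein_id"] == protein)
                          & (df["replicate_id"] == rep)]["oriented"]
                cell = matrix.ratios.at[protein, rep]
                if len(vals) == 0:
                    assert np.isnan(cell)
                else:
                    assert cell == pytest.approx(np.median(vals))

    def test_normalization_centers_each_replicate(self):
        rng = np.random.default_rng(23)
        rows = [(f"pep{i}_{p}", f"P{p}", f"r{r}", 1, float(rng.normal() + 2.0),
                 0.99)
                for i in range(4) for p in range(9) for r in (1, 2)]
        df = orient(make_peptide_frame(rows))
        matrix = aggregate(df, set(df["protein_id"]), FilterConfig())
        for rep in matrix.ratios.columns:
            assert matrix.ratios[rep].median() == pytest.approx(0.0)


class TestFullFilterProperties:
    def test_orientation_invariance(self, small_dataset, default_filter):
        _, _, peps = small_dataset
        flipped = peps.copy()
        flipped["design"] = -flipped["design"]
        flipped["log2_hl"] = -flipped["log2_hl"]
        m1, c1 = run_filter(peps, default_filter)
        m2, c2 = run_filter(flipped, default_filter)
        assert c1 == c2
        pd.testing.assert_frame_equal(m1.ratios, m2.ratios)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_filter_enriches_for_correct_observations(self):
        config = synthdata.GeneratorConfig(n_proteins=250, frac_wrong=0.3,
                                           seed=31)
        _, _, peps = synthdata.simulate_dataset(config)
        threshold = probability_threshold_at_fdr(peps["probability"], 0.01)
        conf = high_confidence(peps, threshold)
        retained = consistency_filter(orient(conf), FilterConfig())
        frac_in = (~peps["correct"]).mean()
        frac_out = (~retained["correct"]).mean()
        assert frac_out < frac_in

    def test_fdr_monotonicity_of_high_confidence(self):
        rng = np.random.default_rng(3)
        df = make_peptide_frame([
            (f"pep{i}", "A", "r1", 1, 0.0, float(rng.beta(9, 1)))
            for i in range(500)])
        prev: set = set()
        for target in (0.005, 0.01, 0.05, 0.2):
            thr = probability_threshold_at_fdr(df["probability"], target)
            kept = set(high_confidence(df, thr)["peptide_id"])
            assert prev <= kept
            prev = kept
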