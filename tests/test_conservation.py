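import math

import numpy as np
import pytest

from mirtarget import DataError, NucSequence, SpeciesAlignment, read_newick
from mirtarget import conservation as co
from mirtarget.site_scanner import SiteType, TargetSite
from mirtarget.synthetic_fixtures import gen_alignment, gen_utr


def aln(rows, ref="A"):
    return SpeciesAlignment(rows=rows, ref_species=ref)


def site6(start):
    return TargetSite("u", "m", start, start + 6, SiteType.SIX_MER)


class TestSitePresence:
    MATCH = "CAUUCC"

    def test_identical_rows_all_present(self):
        rows = {s: "GG" + self.MATCH + "AA" for s in "ABC"}
        present = co.site_presence(aln(rows), site6(2), self.MATCH)
        assert present == {"A", "B", "C"}

    def test_substitution_inside_match_removes_species(self):
        rows = {
            "A": "GG" + self.MATCH + "AA",
            "B": "GG" + "CAGUCC" + "AA",  # U->G inside the match
        }
        present = co.site_presence(aln(rows), site6(2), self.MATCH)
        assert present == {"A"}

    def test_all_gap_row_is_absent(self):
        rows = {"A": "GG" + self.MATCH + "AA", "B": "GG" + "------" + "AA"}
        present = co.site_presence(aln(rows), site6(2), self.MATCH)
        assert present == {"A"}

    def test_alignment_jitter_within_slop_still_counts(self):
        # species B carries the match shifted one column via gaps
        rows = {
            "A": "GGA" + self.MATCH + "-AA",
            "B": "GGA" + "-" + self.MATCH + "AA",
        }
        present = co.site_presence(aln(rows), site6(3), self.MATCH)
        assert present == {"A", "B"}

    def test_site_outside_reference_rejected(self):
        rows = {"A": self.MATCH}
        with pytest.raises(DataError):
            co.site_presence(aln(rows), site6(4), self.MATCH)


class TestBls:
    def test_two_leaf_subtree_hand_sum(self, toy_tree):
        assert co.bls(toy_tree, {"A", "B"}) == pytest.approx(0.3)

    def test_all_leaves_give_total_tree_length(self, toy_tree):
        assert co.bls(toy_tree, {"A", "B", "C"}) == pytest.approx(1.0)
        assert co.bls(toy_tree, {"A", "B", "C"}) == pytest.approx(
            toy_tree.total_length()
        )

    def test_single_or_empty_set_gives_zero(self, toy_tree):
        assert co.bls(toy_tree, {"A"}) == 0.0
        assert co.bls(toy_tree, set()) == 0.0

    def test_unbalanced_pair_spans_root(self, toy_tree):
        # A to C: 0.1 + 0.3 + 0.4
        assert co.bls(toy_tree, {"A", "C"}) == pytest.approx(0.8)

    def test_normalized_variant(self, toy_tree):
        assert co.bls(toy_tree, {"A", "B"}, normalize=True) == pytest.approx(0.3)

    def test_unknown_species_rejected(self, toy_tree):
        with pytest.raises(DataError):
            co.bls(toy_tree, {"A", "Z"})

    def test_monotone_under_species_addition(self, mammal_tree):
        rng = np.random.default_rng(4)
        leaves = mammal_tree.leaf_labels()
        for _ in range(20):
            k = int(rng.integers(0, len(leaves)))
            subset = set(rng.choice(leaves, size=k, replace=False))
            extra = [l for l in leaves if l not in subset]
            if not extra:
                continue
            bigger = subset | {extra[int(rng.integers(len(extra)))]}
            assert co.bls(mammal_tree, bigger) >= co.bls(mammal_tree, subset) - 1e-12


class TestFelsenstein:
    def test_two_leaf_jc_closed_form(self):
        tree = read_newick("(A:0.3,B:0.2);")
        columns = aln({"A": "A", "B": "A"})
        t = 0.5
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        expect = math.log(0.25 * p_same)
        got = co.felsenstein_loglik(tree, columns, co.SubstitutionModel("JC69"))
        assert got == pytest.approx(expect, abs=1e-12)

    def test_columns_are_independent(self):
        tree = read_newick("(A:0.3,B:0.2);")
        one = co.felsenstein_loglik(tree, aln({"A": "A", "B": "C"}), co.SubstitutionModel())
        two = co.felsenstein_loglik(tree, aln({"A": "AA", "B": "CC"}), co.SubstitutionModel())
        assert two == pytest.approx(2 * one, abs=1e-10)

    def test_scale_to_zero_approaches_single_sequence_probability(self):
        tree = read_newick("(A:0.5,B:0.5);")
        columns = aln({"A": "ACG", "B": "ACG"})
        got = co.felsenstein_loglik(tree, columns, co.SubstitutionModel(), scale=1e-9)
        assert got == pytest.approx(3 * math.log(0.25), abs=1e-6)

    def test_alignment_only_species_ignored_with_warning(self, caplog):
        tree = read_newick("(A:0.3,B:0.2);")
        columns = aln({"A": "A", "B": "A", "Z": "G"})
        with caplog.at_level("WARNING"):
            got = co.felsenstein_loglik(tree, columns, co.SubstitutionModel())
        assert "Z" in caplog.text
        assert math.isfinite(got)

    def test_hky_reduces_to_jc_at_kappa_one_uniform_freqs(self):
        tree = read_newick("(A:0.4,B:0.1);")
        columns = aln({"A": "ACGU", "B": "AGGU"})
        jc = co.felsenstein_loglik(tree, columns, co.SubstitutionModel("JC69"))
        hky = co.felsenstein_loglik(
            tree, columns, co.SubstitutionModel("HKY85", kappa=1.0)
        )
        assert hky == pytest.approx(jc, abs=1e-9)

    def test_correct_model_beats_misspecified_frequencies_on_average(self, mammal_tree):
        rng = np.random.default_rng(17)
        skewed = co.SubstitutionModel(
            "HKY85", frequencies=np.array([0.55, 0.25, 0.15, 0.05]), kappa=1.0
        )
        jc = co.SubstitutionModel("JC69")
        diffs = []
        for _ in range(30):
            root = gen_utr(20, seed=int(rng.integers(2**31)))
            sim = gen_alignment(mammal_tree, root, jc, seed=int(rng.integers(2**31)),
                                ref_species="human")
            diffs.append(
                co.felsenstein_loglik(mammal_tree, sim, jc)
                - co.felsenstein_loglik(mammal_tree, sim, skewed)
            )
        assert np.mean(diffs) > 0


class TestPhylopScore:
    def test_identical_columns_on_long_tree_score_conserved(self, mammal_tree):
        rows = {s: "ACGUACG" for s in mammal_tree.leaf_labels()}
        res = co.phylop_score(mammal_tree, aln(rows, ref="human"))
        assert res.lam < 0.01
        assert res.phylop_score > 2
        assert res.phylop_p < 0.01

    def test_saturated_columns_score_accelerated(self, mammal_tree):
        # maximally discordant leaves push lambda above 1
        leaves = mammal_tree.leaf_labels()
        rows = {s: ("ACGU" * 3)[i : i + 5] for i, s in enumerate(leaves)}
        res = co.phylop_score(mammal_tree, aln(rows, ref="human"))
        assert res.lam > 1
        assert res.phylop_score < 0
        assert res.phylop_p > 0.5

    def test_needs_two_species(self, mammal_tree):
        with pytest.raises(DataError):
            co.phylop_score(mammal_tree, aln({"human": "ACG"}, ref="human"))

    def test_type_one_error_roughly_calibrated(self, mammal_tree):
        rng = np.random.default_rng(101)
        n, rejected = 300, 0
        for _ in range(n):
            root = gen_utr(7, seed=int(rng.integers(2**31)))
            sim = gen_alignment(mammal_tree, root, seed=int(rng.integers(2**31)),
                                ref_species="human")
            if co.phylop_score(mammal_tree, sim).phylop_p < 0.05:
                rejected += 1
        assert abs(rejected / n - 0.05) < 0.04

    def test_power_increases_with_stronger_conservation(self, mammal_tree):
        rng = np.random.default_rng(55)
        rates = {}
        for lam in (0.8, 0.4, 0.1):
            rejected = 0
            n = 120
            for _ in range(n):
                root = gen_utr(7, seed=int(rng.integers(2**31)))
                sim = gen_alignment(
                    mammal_tree, root, window_scales={(0, 7): lam},
                    seed=int(rng.integers(2**31)), ref_species="human",
                )
                if co.phylop_score(mammal_tree, sim).phylop_p < 0.05:
                    rejected += 1
            rates[lam] = rejected / n
        assert rates[0.1] > rates[0.4] > rates[0.8]
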