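import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heteroshift import nanopore
from oracles import signed_rank_exact_p


def calls_frame(llrs, chrom="chr1", pos=100):
    return pd.DataFrame({"chromosome": chrom, "position": pos, "llr": llrs})


class TestSiteCounts:
    def test_all_positive_llr(self):
        res = nanopore.site_counts_from_reads(calls_frame([5.0] * 10))
        row = res.sites.iloc[0]
        assert (row.modified_count, row.unmodified_count) == (10, 0)
        assert res.n_ambiguous == 0

    def test_sign_split_at_zero_cutoff(self):
        res = nanopore.site_counts_from_reads(calls_frame([1.0, -1.0]))
        row = res.sites.iloc[0]
        assert (row.modified_count, row.unmodified_count) == (1, 1)

    def test_ambiguous_band_discarded(self):
        res = nanopore.site_counts_from_reads(calls_frame([0.1, -0.1]),
                                              llr_cutoff=0.5)
        row = res.sites.iloc[0]
        assert (row.modified_count, row.unmodified_count) == (0, 0)
        assert res.n_ambiguous == 2


class TestLmrAndProb:
    def site(self, m, u):
        return pd.DataFrame({"chromosome": ["chr1"], "position": [1],
                             "modified_count": [m], "unmodified_count": [u]})

    def test_balanced_counts_give_half(self):
        out = nanopore.lmr_and_prob(self.site(5, 5))
        assert out["lmr"].iloc[0] == pytest.approx(0.0)
        assert out["prob"].iloc[0] == pytest.approx(0.5)

    def test_sigmoid_inverts_log_ratio_without_pseudocount(self):
        out = nanopore.lmr_and_prob(self.site(9, 1), pseudocount=0)
        assert out["prob"].iloc[0] == pytest.approx(0.9)

    def test_pseudocount_identity_example(self):
        out = nanopore.lmr_and_prob(self.site(3, 7), pseudocount=1)
        assert out["prob"].iloc[0] == pytest.approx(4 / 12)

    def test_zero_count_saturates_and_flags(self, caplog):
        out = nanopore.lmr_and_prob(self.site(5, 0), pseudocount=0)
        assert np.isinf(out["lmr"].iloc[0])
        assert out["prob"].iloc[0] == 1.0
        assert any("saturated" in r.message for r in caplog.records)

    @given(m=st.integers(0, 500), u=st.integers(0, 500),
           c=st.floats(0.25, 4.0))
    @settings(max_examples=200, deadline=None)
    def test_prob_equals_smoothed_count_fraction(self, m, u, c):
        out = nanopore.lmr_and_prob(self.site(m, u), pseudocount=c)
        assert out["prob"].iloc[0] == pytest.approx(
            (m + c) / (m + u + 2 * c), rel=1e-12)


class TestChromosomeSummaries:
    def sites(self, probs, chroms):
        return pd.DataFrame({"chromosome": chroms,
                             "position": range(len(probs)),
                             "modified_count": 1, "unmodified_count": 1,
                             "prob": probs})

    @pytest.mark.parametrize("probs,expected", [
        ([0.2, 0.4, 0.9], 0.4),
        ([0.7], 0.7),
        ([0.2, 0.4], pytest.approx(0.3)),  # midpoint convention for even n
    ])
    def test_median_conventions(self, probs, expected):
        out = nanopore.chromosome_summaries(
            self.sites(probs, ["chr1"] * len(probs)), "cond")
        assert out["median_prob"].iloc[0] == expected

    def test_invariant_to_site_order_and_bounded(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(0, 1, 30)
        chroms = list(rng.choice(["chr1", "chr2", "chrM"], 30))
        s = self.sites(probs, chroms)
        a = nanopore.chromosome_summaries(s, "c")
        b = nanopore.chromosome_summaries(s.sample(frac=1, random_state=1), "c")
        pd.testing.assert_frame_equal(
            a.sort_values("chromosome").reset_index(drop=True),
            b.sort_values("chromosome").reset_index(drop=True))
        for _, row in a.iterrows():
            sel = [p for p, c in zip(probs, chroms) if c == row.chromosome]
            assert min(sel) <= row.median_prob <= max(sel)


def summaries(values, condition="c"):
    return pd.DataFrame({"chromosome": [f"chr{i}" for i in range(len(values))],
                         "median_prob": values, "n_sites": 1,
                         "condition": condition})


class TestPairedWilcoxon:
    def test_identical_summaries_degenerate(self):
        s = summaries([0.1, 0.2, 0.3, 0.4, 0.5])
        res = nanopore.paired_wilcoxon(s, s)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_six_consistent_pairs_one_sided(self):
        a = summaries([0.5, 0.6, 0.55, 0.7, 0.65, 0.62])
        b = summaries([0.4, 0.5, 0.45, 0.6, 0.55, 0.52])
        res = nanopore.paired_wilcoxon(a, b, alternative="greater")
        assert res.p_value == pytest.approx(1 / 64)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a = summaries(rng.uniform(0.2, 0.8, 10))
        b = summaries(rng.uniform(0.2, 0.8, 10))
        for alt in ("two-sided", "greater", "less"):
            res = nanopore.paired_wilcoxon(a, b, alternative=alt)
            diffs = (a["median_prob"] - b["median_prob"]).to_numpy()
            assert res.p_value == pytest.approx(
                signed_rank_exact_p(diffs, alt), rel=1e-9)

    def test_mismatched_chromosome_sets(self):
        a = summaries([0.1, 0.2])
        b = summaries([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            nanopore.paired_wilcoxon(a, b)


class TestAlleleHeteroplasmy:
    @pytest.mark.parametrize("counts,expected", [
        ({"A": 70, "G": 30}, 0.7),
        ({"A": 0, "G": 50}, 0.0),
        ({"A": 33, "G": 11, "C": 6}, 0.75),  # other bases ignored
    ])
    def test_mutant_fraction(self, counts, expected):
        assert nanopore.allele_heteroplasmy(counts) == pytest.approx(expected)

    def test_zero_informative_depth(self):
        with pytest.raises(ValueError):
            nanopore.allele_heteroplasmy({"A": 0, "G": 0, "C": 10})

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            nanopore.allele_heteroplasmy({"A": -1, "G": 5})
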