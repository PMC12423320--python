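import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from heteroshift import dmr, io
from oracles import brute_force_runs, hypergeom_upper_tail


def make_matrix(test_vals, ctrl_vals, probes=None):
    """Build a BetaMatrix from per-probe lists of test/control values."""
    test_vals = np.atleast_2d(test_vals)
    ctrl_vals = np.atleast_2d(ctrl_vals)
    n_t, n_c = test_vals.shape[1], ctrl_vals.shape[1]
    samples = [f"t{i}" for i in range(n_t)] + [f"c{i}" for i in range(n_c)]
    probes = probes or [f"cg{i:03d}" for i in range(test_vals.shape[0])]
    values = pd.DataFrame(np.hstack([test_vals, ctrl_vals]),
                          index=probes, columns=samples)
    design = pd.DataFrame({"mutation_type": "mut13",
                           "load": ["high"] * n_t + ["low"] * n_c},
                          index=pd.Index(samples, name="sample_id"))
    return io.BetaMatrix(values=values, design=design)


class TestBetaFromIntensities:
    @pytest.mark.parametrize("M,U,expected", [
        (0, 1000, 0.0),
        (1000, 1000, 1000 / 2100),
        (-50, 200, 0.0),
    ])
    def test_printed_formula(self, M, U, expected):
        assert dmr.beta_from_intensities(M, U) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dmr.beta_from_intensities(float("nan"), 1.0)

    @given(M=st.floats(-1e6, 1e6), U=st.floats(0, 1e6),
           dM=st.floats(0.01, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_monotone_in_M(self, M, U, dM):
        b = dmr.beta_from_intensities(M, U)
        assert 0.0 <= b < 1.0
        if M >= 0:  # monotone increasing in M for fixed U >= 0
            assert dmr.beta_from_intensities(M + dM, U) >= b


class TestProbeDeltas:
    def test_clear_separation_gives_hyper(self):
        m = make_matrix([[0.9, 0.9, 0.9]], [[0.5, 0.5, 0.5]])
        out = dmr.probe_deltas(m, "high", "low")
        assert out["delta"].iloc[0] == pytest.approx(0.4)
        # zero within-group variance with distinct means: t -> infinity
        assert out["p_value"].iloc[0] < 0.05
        assert out["direction"].iloc[0] == "hyper"

    def test_identical_groups_give_none(self):
        m = make_matrix([[0.5, 0.5, 0.5]], [[0.5, 0.5, 0.5]])
        out = dmr.probe_deltas(m, "high", "low")
        assert out["delta"].iloc[0] == 0.0
        assert out["p_value"].iloc[0] == 1.0
        assert out["direction"].iloc[0] == "none"

    def test_below_threshold_never_called(self):
        m = make_matrix([[0.6, 0.4]], [[0.5, 0.5]])
        out = dmr.probe_deltas(m, "high", "low")
        assert out["delta"].iloc[0] == pytest.approx(0.0)
        assert out["direction"].iloc[0] == "none"

    def test_one_tailed_p_matches_t_distribution(self):
        rng = np.random.default_rng(3)
        tv = rng.uniform(0.4, 0.9, (1, 5))
        cv = rng.uniform(0.1, 0.6, (1, 5))
        out = dmr.probe_deltas(make_matrix(tv, cv), "high", "low")
        t, p_two = stats.ttest_ind(tv[0], cv[0], equal_var=True)
        expect = p_two / 2 if np.sign(t) == np.sign(out["delta"].iloc[0]) \
            else 1 - p_two / 2
        assert out["p_value"].iloc[0] == pytest.approx(expect, rel=1e-10)

    def test_welch_variant_matches_scipy(self):
        rng = np.random.default_rng(4)
        tv = rng.uniform(0.5, 0.9, (1, 4))
        cv = rng.uniform(0.1, 0.4, (1, 7))
        cfg = dmr.DmrConfig(t_variant="welch")
        out = dmr.probe_deltas(make_matrix(tv, cv), "high", "low", cfg)
        _, p_two = stats.ttest_ind(tv[0], cv[0], equal_var=False)
        assert out["p_value"].iloc[0] == pytest.approx(p_two / 2, rel=1e-10)

    def test_low_observation_probes_marked_excluded(self):
        tv = np.array([[0.9, np.nan, np.nan]])
        cv = np.array([[0.5, 0.5, 0.5]])
        out = dmr.probe_deltas(make_matrix(tv, cv), "high", "low")
        assert bool(out["excluded"].iloc[0])
        assert out["direction"].iloc[0] == "none"
        assert np.isnan(out["delta"].iloc[0])

    def test_sample_column_order_is_irrelevant(self, two_group_matrix):
        out1 = dmr.probe_deltas(two_group_matrix, "high", "low")
        perm = list(two_group_matrix.values.columns)[::-1]
        shuffled = io.BetaMatrix(values=two_group_matrix.values[perm],
                                 design=two_group_matrix.design)
        out2 = dmr.probe_deltas(shuffled, "high", "low")
        pd.testing.assert_frame_equal(out1, out2)

    def test_unknown_group_label(self, two_group_matrix):
        with pytest.raises(io.ConfigError, match="nope"):
            dmr.probe_deltas(two_group_matrix, "nope", "low")


def deltas_from_directions(directions, probes):
    """Build a probe_deltas-shaped frame with prescribed directions."""
    delta = [0.4 if d == "hyper" else -0.4 if d == "hypo" else 0.0
             for d in directions]
    return pd.DataFrame({
        "delta": delta,
        "p_value": [0.01 if d != "none" else 0.9 for d in directions],
        "direction": directions,
        "n_test": 3, "n_control": 3, "excluded": False,
    }, index=pd.Index(probes, name="probe_id"))


def manifest_for(chromosomes):
    frame = pd.DataFrame({
        "probe_id": [f"cg{i:03d}" for i in range(len(chromosomes))],
        "chromosome": chromosomes,
        "position": [100 * (i + 1) for i in range(len(chromosomes))],
        "gene_labels": "",
    })
    return io.manifest_from_frame(frame)


class TestCallDmrRuns:
    def test_interrupted_run_of_two(self):
        man = manifest_for(["chr1"] * 4)
        deltas = deltas_from_directions(
            ["hyper", "hyper", "none", "hyper"], list(man["probe_id"]))
        runs = dmr.call_dmr_runs(deltas, man)
        assert len(runs) == 1
        assert runs[0].probe_ids == ("cg000", "cg001")
        assert runs[0].direction == "hyper"

    def test_direction_flip_breaks_runs(self):
        man = manifest_for(["chr1"] * 3)
        deltas = deltas_from_directions(["hyper", "hypo", "hyper"],
                                        list(man["probe_id"]))
        assert dmr.call_dmr_runs(deltas, man) == []

    def test_runs_never_span_chromosomes(self):
        man = manifest_for(["chr1", "chr1", "chr2", "chr2"])
        deltas = deltas_from_directions(["hyper"] * 4, list(man["probe_id"]))
        runs = dmr.call_dmr_runs(deltas, man)
        assert [r.chromosome for r in runs] == ["chr1", "chr2"]

    def test_untested_manifest_probe_breaks_run(self):
        man = manifest_for(["chr1"] * 3)
        deltas = deltas_from_directions(["hyper", "hyper"],
                                        ["cg000", "cg002"])
        # cg001 sits between them in the manifest but was never tested
        assert dmr.call_dmr_runs(deltas, man) == []

    def test_max_gap_breaks_run(self):
        frame = pd.DataFrame({
            "probe_id": ["a", "b"], "chromosome": "chr1",
            "position": [100, 50_000], "gene_labels": ""})
        man = io.manifest_from_frame(frame)
        deltas = deltas_from_directions(["hyper", "hyper"], ["a", "b"])
        assert len(dmr.call_dmr_runs(deltas, man)) == 1
        cfg = dmr.DmrConfig(max_gap_bp=10_000)
        assert dmr.call_dmr_runs(deltas, man, cfg) == []

    def test_probe_absent_from_manifest(self):
        man = manifest_for(["chr1"] * 2)
        deltas = deltas_from_directions(["hyper"], ["cgXXX"])
        with pytest.raises(ValueError, match="cgXXX"):
            dmr.call_dmr_runs(deltas, man)

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        chroms = sorted(rng.choice(["chr1", "chr2"], n),
                        key=lambda c: io.chromosome_sort_key(c))
        dirs = list(rng.choice(["hyper", "hypo", "none"], n,
                               p=[0.4, 0.3, 0.3]))
        man = manifest_for(chroms)
        deltas = deltas_from_directions(dirs, list(man["probe_id"]))
        runs = dmr.call_dmr_runs(deltas, man)
        got = {(r.chromosome, r.probe_ids[0], r.probe_ids[-1], r.direction)
               for r in runs}
        expect = {(c, f"cg{i:03d}", f"cg{j:03d}", d)
                  for c, i, j, d in brute_force_runs(dirs, chroms)}
        assert got == expect

    def test_min_run_one_partitions_significant_probes(self):
        rng = np.random.default_rng(11)
        n = 40
        dirs = list(rng.choice(["hyper", "hypo", "none"], n))
        man = manifest_for(["chr1"] * n)
        deltas = deltas_from_directions(dirs, list(man["probe_id"]))
        cfg = dmr.DmrConfig(min_run=1, hyper_threshold=1e-9,
                            hypo_threshold=-1e-9)
        runs = dmr.call_dmr_runs(deltas, man, cfg)
        covered = [p for r in runs for p in r.probe_ids]
        significant = [p for p, d in zip(man["probe_id"], dirs) if d != "none"]
        assert sorted(covered) == sorted(significant)
        assert len(covered) == len(set(covered))  # each probe in one run


class TestGeneList:
    def run(self, direction, genes, n=2):
        return dmr.DmrRun(chromosome="chr1", start_pos=1, end_pos=n,
                          probe_ids=tuple(f"p{i}" for i in range(n)),
                          direction=direction, mean_delta=0.3,
                          gene_labels=frozenset(genes))

    def test_gene_in_two_runs_reported_once(self):
        out = dmr.dmr_gene_list([self.run("hyper", {"ESR1"}),
                                 self.run("hyper", {"ESR1"})])
        assert len(out) == 1
        assert out.iloc[0]["direction"] == "hyper"

    def test_empty_gene_set_contributes_nothing(self):
        assert dmr.dmr_gene_list([self.run("hyper", set())]).empty

    def test_majority_direction_and_tie(self):
        out = dmr.dmr_gene_list([self.run("hyper", {"G1"}, n=3),
                                 self.run("hypo", {"G1"}, n=1)])
        assert out.iloc[0]["direction"] == "hyper"
        tied = dmr.dmr_gene_list([self.run("hyper", {"G2"}, n=2),
                                  self.run("hypo", {"G2"}, n=2)])
        assert tied.iloc[0]["direction"] == "mixed"


class TestEnrichment:
    def test_disjoint_sets(self):
        overlap, p = dmr.enrichment_test([f"a{i}" for i in range(10)],
                                         {f"b{i}" for i in range(10)}, 100)
        assert overlap == 0
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_certain_event(self):
        genes = [f"g{i}" for i in range(5)]
        _, p = dmr.enrichment_test(genes, set(genes), 5)
        assert p == pytest.approx(1.0)

    def test_matches_direct_summation(self):
        genes = [f"g{i}" for i in range(5)]
        annot = set(genes) | {f"x{i}" for i in range(15)}
        overlap, p = dmr.enrichment_test(genes, annot, 1000)
        assert overlap == 5
        assert p == pytest.approx(hypergeom_upper_tail(5, 1000, 20, 5),
                                  rel=1e-9)

    def test_universe_too_small(self):
        with pytest.raises(ValueError):
            dmr.enrichment_test(["a"], {"b"}, 1)
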