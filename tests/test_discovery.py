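import numpy as np
import pandas as pd
import pytest
from oracles import bh_stepup, cluster_transitive_closure, ranksum_exact_p

from methmark.discovery import (DmcThresholds, assemble_dmrs, bh_adjust,
                                blood_exclude, blood_metrics,
                                differential_methylation, discover,
                                dmc_filter, rank_sum_test,
                                region_density_filter)
from methmark.io import BetaMatrix, ProbeAnnotation, SampleSheet
from methmark.simulate import simulate_beta_matrix


def annotation_of(positions):
    """Helper: ProbeAnnotation from {probe_id: (chrom, pos)}."""
    return ProbeAnnotation(pd.DataFrame(
        {"probe_id": list(positions),
         "chrom": [c for c, _ in positions.values()],
         "position": [p for _, p in positions.values()]}))


class TestRankSum:
    def test_no_separation(self):
        _, p = rank_sum_test([0.5, 0.5], [0.5, 0.5])
        assert p == 1.0

    def test_complete_separation_small(self):
        """Exact enumeration: 2 of C(6,3)=20 assignments are as extreme."""
        _, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_exact_equals_enumeration(self, rng):
        """Exact branch reproduces full enumeration for combined n <= 10."""
        for _ in range(30):
            n1 = int(rng.integers(2, 5))
            n2 = int(rng.integers(2, 11 - n1))
            vals = rng.permutation(np.arange(1.0, 20.0))[:n1 + n2]
            a, b = vals[:n1], vals[n1:]
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(ranksum_exact_p(a, b), abs=1e-12)

    def test_exact_and_approx_agree_moderate_n(self, rng):
        """At n=6 per group the normal approximation tracks the exact p."""
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            vals = rng.permutation(np.arange(1.0, 30.0))[:12]
            a, b = vals[:6], vals[6:]
            _, p_exact = rank_sum_test(a, b)
            p_approx = mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").pvalue
            assert p_exact == pytest.approx(p_approx, abs=0.02)

    def test_missing_values_dropped(self):
        _, p1 = rank_sum_test([1, 2, np.nan], [4, 5, 6])
        _, p2 = rank_sum_test([1, 2], [4, 5, 6])
        assert p1 == p2


class TestBhAdjust:
    @pytest.mark.parametrize("p_in,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.01, 0.05, 0.5], [0.004, 0.02, 0.05 * 4 / 3, 0.5]),
    ])
    def test_hand_stepup(self, p_in, expected):
        assert bh_adjust(p_in) == pytest.approx(expected)

    def test_equals_bruteforce_oracle(self, rng):
        p = rng.random(1000) * 0.999 + 1e-6
        assert bh_adjust(p) == pytest.approx(bh_stepup(p))

    def test_permutation_invariance(self, rng):
        p = rng.random(50) * 0.999 + 1e-6
        perm = rng.permutation(50)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1], [np.nan]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestDifferentialMethylation:
    def make_inputs(self, target_vals, other_vals):
        n_t, n_o = len(target_vals), len(other_vals)
        cols = [f"k{i}" for i in range(n_t)] + [f"o{i}" for i in range(n_o)]
        matrix = BetaMatrix(pd.DataFrame(
            [list(target_vals) + list(other_vals)], index=["cg1"], columns=cols))
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": cols,
            "tissue": ["Kidney"] * n_t + ["Liver"] * n_o,
            "role": "discovery"}))
        return matrix, sheet

    def test_complete_separation(self):
        matrix, sheet = self.make_inputs([0.8] * 10, [0.05] * 50)
        res = differential_methylation(matrix, sheet, "Kidney")
        row = res.iloc[0]
        assert row["delta"] == pytest.approx(0.75)
        assert row["fdr"] < 1e-10

    def test_identical_distributions(self, rng):
        vals = rng.beta(2, 2, 60)
        matrix, sheet = self.make_inputs(vals[:10], vals[:50])
        res = differential_methylation(matrix, sheet, "Kidney")
        assert abs(res.iloc[0]["delta"]) < 0.2
        assert res.iloc[0]["p_value"] > 0.01

    def test_unknown_tissue_rejected(self):
        matrix, sheet = self.make_inputs([0.5] * 5, [0.5] * 5)
        with pytest.raises(ValueError):
            differential_methylation(matrix, sheet, "Spleen")

    def test_recovers_planted_deltas(self):
        matrix, sheet, ann, truth = simulate_beta_matrix(11, delta=0.5)
        res = differential_methylation(matrix, sheet, "Kidney").set_index("probe_id")
        for dmr in truth.planted_dmrs:
            for probe in dmr.probe_ids:
                assert res.loc[probe, "delta"] == pytest.approx(0.5, abs=0.05)


class TestDmcFilter:
    def make_results(self, fdr, delta, mean_other):
        return pd.DataFrame({"probe_id": ["cg1"], "mean_target": [0.8],
                             "mean_other": [mean_other], "delta": [delta],
                             "p_value": [fdr / 2], "fdr": [fdr]})

    @pytest.mark.parametrize("fdr,delta,mean_other,passes", [
        (1e-12, 0.35, 0.05, True),    # all three criteria met
        (1e-12, 0.29, 0.05, False),   # delta not strictly > 0.3
        (1e-12, 0.30, 0.05, False),   # boundary delta excluded (strict >)
        (1e-12, 0.35, 0.10, False),   # background not strictly < 0.1
        (1e-10, 0.35, 0.05, False),   # FDR not strictly < 1e-10
    ])
    def test_strict_thresholds(self, fdr, delta, mean_other, passes):
        out = dmc_filter(self.make_results(fdr, delta, mean_other))
        assert (out == ["cg1"]) is passes

    def test_monotone_in_thresholds(self, rng):
        res = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(100)],
            "mean_target": rng.random(100),
            "mean_other": rng.random(100) * 0.2,
            "delta": rng.random(100),
            "p_value": rng.random(100),
            "fdr": rng.random(100) * 1e-9})
        tight = set(dmc_filter(res, DmcThresholds()))
        loose = set(dmc_filter(res, DmcThresholds(
            fdr_max=1e-8, delta_min=0.2, other_mean_max=0.15)))
        assert tight <= loose


class TestRegionDensityFilter:
    def test_pair_within_half_window(self):
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 3200)})
        assert region_density_filter(["a", "b"], ann) == ["a", "b"]

    def test_isolated_probe_removed(self):
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 9000)})
        assert region_density_filter(["a", "b"], ann) == []

    def test_boundary_distance_inclusive(self):
        """Exactly 2.5 kb apart counts as inside the 5 kb window."""
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 3500)})
        assert region_density_filter(["a", "b"], ann) == ["a", "b"]
        ann2 = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 3501)})
        assert region_density_filter(["a", "b"], ann2) == []

    def test_missing_annotation_rejected(self):
        ann = annotation_of({"a": ("chr1", 1000)})
        with pytest.raises(ValueError, match="b"):
            region_density_filter(["a", "b"], ann)

    def test_chromosomes_never_pool(self):
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr2", 1000)})
        assert region_density_filter(["a", "b"], ann) == []


class TestAssembleDmrs:
    def test_linkage_pair(self):
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 3200)})
        dmrs = assemble_dmrs(["a", "b"], ann)
        assert len(dmrs) == 1
        assert (dmrs[0].start, dmrs[0].end) == (1000, 3200)
        assert dmrs[0].probe_ids == ("a", "b")

    def test_chromosomes_never_merge(self):
        ann = annotation_of({"a": ("chr1", 1000), "b": ("chr1", 3200),
                             "c": ("chr2", 500), "d": ("chr2", 700)})
        assert len(assemble_dmrs(["a", "b", "c", "d"], ann)) == 2

    def test_empty_input(self):
        assert assemble_dmrs([], annotation_of({"a": ("chr1", 1)})) == []

    def test_equals_transitive_closure(self, rng):
        """Single-linkage output matches all-pairs union-find on <= 50 probes."""
        for _ in range(10):
            n = int(rng.integers(5, 51))
            pos = np.sort(rng.choice(np.arange(1, 100_000), n, replace=False))
            ids = [f"cg{i}" for i in range(n)]
            ann = annotation_of({ids[i]: ("chr1", int(pos[i])) for i in range(n)})
            dmrs = assemble_dmrs(ids, ann, DmcThresholds(min_probes_in_window=1))
            got = sorted(tuple(sorted(int(pid[2:]) for pid in d.probe_ids))
                         for d in dmrs)
            expected = cluster_transitive_closure(list(pos), 2500)
            assert got == expected
            # spans, disjointness, coverage
            covered = [i for d in dmrs for i in d.probe_ids]
            assert sorted(covered) == sorted(ids)


class TestBloodFilter:
    def matrix_of(self, values):
        values = np.asarray(values)[None, :]
        return BetaMatrix(pd.DataFrame(
            values, index=["cg1"],
            columns=[f"s{i}" for i in range(values.shape[1])]))

    def test_clean_probe(self):
        m = blood_metrics(self.matrix_of([0.05] * 100), ["cg1"])
        assert m.loc[0, "median_beta"] == pytest.approx(0.05)
        assert m.loc[0, "positivity"] == 0.0

    def test_sporadic_positivity_counted(self):
        m = blood_metrics(self.matrix_of([0.05] * 97 + [0.3] * 3), ["cg1"])
        assert m.loc[0, "positivity"] == pytest.approx(0.03)

    def test_uniformly_positive(self):
        m = blood_metrics(self.matrix_of([0.25] * 10), ["cg1"])
        assert m.loc[0, "median_beta"] == pytest.approx(0.25)
        assert m.loc[0, "positivity"] == 1.0

    def test_absent_probe_warned_and_carried(self):
        with pytest.warns(UserWarning, match="not measured"):
            m = blood_metrics(self.matrix_of([0.05]), ["cg1", "cg_missing"])
        assert not m.loc[1, "available"]
        assert blood_exclude(m) == ["cg1", "cg_missing"]

    @pytest.mark.parametrize("median,positivity,retained", [
        (0.15, 0.01, False),   # median rule: > 0.1 excludes
        (0.05, 0.03, False),   # positivity rule: > 2% excludes
        (0.10, 0.02, True),    # boundaries not exceeded: retained
        (0.05, 0.01, True),
    ])
    def test_exclusion_boundaries(self, median, positivity, retained):
        metrics = pd.DataFrame({"probe_id": ["cg1"], "median_beta": [median],
                                "positivity": [positivity],
                                "n_samples": [100], "available": [True]})
        assert (blood_exclude(metrics) == ["cg1"]) is retained

    def test_monotone_in_thresholds(self, rng):
        metrics = pd.DataFrame({
            "probe_id": [f"cg{i}" for i in range(100)],
            "median_beta": rng.random(100) * 0.2,
            "positivity": rng.random(100) * 0.05,
            "n_samples": 100, "available": True})
        tight = set(blood_exclude(metrics))
        loose = set(blood_exclude(metrics, median_max=0.15, positivity_max=0.03))
        assert tight <= loose


class TestDiscoverPipeline:
    def test_counts_conserved_and_dmrs_found(self):
        matrix, sheet, ann, truth = simulate_beta_matrix(5)
        run = discover(matrix, sheet, ann, "Kidney")
        c = run.stage_counts
        assert c["probes_in"] == len(matrix.probe_ids)
        assert c["dmc_pass"] >= c["region_pass"] >= 0
        found = {(d.chrom, d.start, d.end) for d in run.dmrs}
        planted = {(d.chrom, d.start, d.end) for d in truth.planted_dmrs}
        assert planted <= found

    def test_blood_contamination_removes_dmr(self):
        from methmark.simulate import simulate_blood_reference

        matrix, sheet, ann, truth = simulate_beta_matrix(6)
        victim = truth.planted_dmrs[0].probe_ids[0]
        blood = simulate_blood_reference(6, matrix.probe_ids,
                                         contaminated={victim: 0.3})
        run = discover(matrix, sheet, ann, "Kidney", blood=blood)
        surviving = {p for d in run.dmrs for p in d.probe_ids}
        assert victim not in surviving
        # a 2-probe DMR losing one member is dropped entirely
        assert len(run.dmrs) == len(truth.planted_dmrs) - 1
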