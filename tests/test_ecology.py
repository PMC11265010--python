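"""Normalization, occupancy, environmental range, rarefaction, redundancy."""

import itertools

import numpy as np
import pandas as pd
import pytest

import gveco as g

from conftest import make_sample_table


def small_matrix(values, phylotypes=None, samples=None, stage="normalized"):
    values = np.asarray(values, dtype=float)
    phylotypes = phylotypes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return g.CoverageMatrix(pd.DataFrame(values, index=phylotypes,
                                         columns=samples), stage=stage)


class TestNormalizeCoverage:
    def test_formula_arithmetic(self):
        """raw 4.0 at 50M reads with 100M mean reads -> 8.0."""
        t = make_sample_table(1)
        df = t.data.copy()
        # three samples: 50M, 100M, 150M -> mean 100M
        df = df.iloc[:3].copy()
        df["read_count"] = [50_000_000, 100_000_000, 150_000_000]
        samples = g.SampleTable(df)
        raw = small_matrix([[4.0, 4.0, 4.0]], samples=list(df.index), stage="raw")
        norm = g.normalize_coverage(raw, samples)
        assert norm.stage == "normalized"
        np.testing.assert_allclose(norm.values[0], [8.0, 4.0, 8 / 3])

    def test_mean_read_count_column_unchanged(self):
        t = make_sample_table(1)
        df = t.data.iloc[:2].copy()
        df["read_count"] = [10**7, 10**7]
        raw = small_matrix([[1.0, 3.0], [0.5, 2.0]], samples=list(df.index),
                           stage="raw")
        norm = g.normalize_coverage(raw, g.SampleTable(df))
        np.testing.assert_allclose(norm.values, raw.values)

    def test_zero_row_stays_zero(self, community):
        cov, samples, _ = community
        norm = g.normalize_coverage(cov, samples)
        zero_rows = (cov.values == 0).all(axis=1)
        assert (norm.values[zero_rows] == 0).all()

    def test_missing_read_count_rejected(self):
        t = make_sample_table(1)
        raw = small_matrix([[1.0]], samples=["nowhere"], stage="raw")
        with pytest.raises(ValueError, match="read counts"):
            g.normalize_coverage(raw, t)


class TestRelativeAbundance:
    def test_equal_split(self):
        rel = g.relative_abundance(small_matrix([[2.0], [2.0]]))
        np.testing.assert_allclose(rel.values[:, 0], [50.0, 50.0])
        assert rel.stage == "relative"

    def test_empty_sample_flagged_and_zero(self, caplog):
        with caplog.at_level("WARNING", logger="gveco"):
            rel = g.relative_abundance(small_matrix([[0.0, 1.0], [0.0, 3.0]]))
        assert (rel.values[:, 0] == 0).all()
        assert "empty" in caplog.text

    def test_columns_sum_to_100(self, rng):
        m = small_matrix(rng.gamma(1.0, 2.0, size=(10, 6)))
        rel = g.relative_abundance(m)
        np.testing.assert_allclose(rel.values.sum(axis=0), 100.0, atol=1e-9)

    def test_requires_normalized_stage(self):
        with pytest.raises(ValueError, match="stage"):
            g.relative_abundance(small_matrix([[1.0]], stage="raw"))


class TestOccurrenceFrequency:
    def test_fraction_of_habitat_samples(self):
        samples = make_sample_table(n_per_habitat=4)
        mine = samples.samples_in("mine")
        values = np.zeros((1, len(samples.sample_ids)))
        cols = list(samples.sample_ids)
        values[0, cols.index(mine[0])] = 5.0  # present in 1 of 4 mine samples
        m = small_matrix(values, samples=cols)
        freq = g.occurrence_frequency(m, samples)
        assert freq.loc["p0", "mine"] == pytest.approx(25.0)
        assert freq.loc["p0", "forest"] == 0.0

    def test_full_presence_is_100(self):
        samples = make_sample_table(2)
        m = small_matrix(np.ones((2, 10)), samples=list(samples.sample_ids))
        freq = g.occurrence_frequency(m, samples)
        assert (freq.to_numpy() == 100.0).all()


def presence_fixture(assignment, habitats=g.HABITATS):
    """CoverageMatrix with one sample per habitat; assignment maps
    phylotype -> tuple of habitats where present."""
    samples = make_sample_table(1)
    by_hab = {h: samples.samples_in(h)[0] for h in habitats}
    cols = list(samples.sample_ids)
    values = np.zeros((len(assignment), len(cols)))
    for i, (p, habs) in enumerate(assignment.items()):
        for h in habs:
            values[i, cols.index(by_hab[h])] = 1.0
    m = small_matrix(values, phylotypes=list(assignment), samples=cols)
    return m, samples


class TestOccupancySummary:
    def test_single_habitat_percentage_printed_precision(self):
        """381 of 533 phylotypes in exactly one habitat reports as 71%."""
        assignment = {}
        for i in range(381):
            assignment[f"u{i}"] = (g.HABITATS[i % 5],)
        for i in range(5):
            assignment[f"all{i}"] = tuple(g.HABITATS)
        for i in range(147):
            assignment[f"m{i}"] = tuple(g.HABITATS[:2 + (i % 3)])
        m, samples = presence_fixture(assignment)
        summary = g.occupancy_summary(m, samples)
        assert summary["n_phylotypes"] == 533
        assert summary["counts_by_n_habitats"][1] == 381
        assert summary["pct_single_habitat"] == 71
        assert summary["pct_fully_shared"] == 0.94

    def test_all_shared_degenerate(self):
        assignment = {f"p{i}": tuple(g.HABITATS) for i in range(4)}
        m, samples = presence_fixture(assignment)
        summary = g.occupancy_summary(m, samples)
        assert all(len(v) == 0 for v in summary["unique_by_habitat"].values())
        assert len(summary["fully_shared"]) == 4

    def test_counts_sum_and_sample_order_invariance(self, community):
        cov, samples, _ = community
        summary = g.occupancy_summary(cov, samples)
        assert sum(summary["counts_by_n_habitats"].values()) == \
            summary["n_phylotypes"]
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(cov.sample_ids))
        shuffled = g.CoverageMatrix(cov.data[perm], stage=cov.stage)
        summary2 = g.occupancy_summary(shuffled, samples)
        assert summary["counts_by_n_habitats"] == summary2["counts_by_n_habitats"]
        assert summary["unique_by_habitat"] == summary2["unique_by_habitat"]

    def test_family_breakdown_of_unique_phylotypes(self):
        """82 Pithoviridae among 248 mine-unique phylotypes reports as 33%."""
        assignment = {f"mine{i}": ("mine",) for i in range(248)}
        assignment.update({f"fa{i}": ("farmland",) for i in range(20)})
        m, samples = presence_fixture(assignment)
        summary = g.occupancy_summary(m, samples)
        family = pd.Series({f"mine{i}": ("Pithoviridae" if i < 82 else "other")
                            for i in range(248)})
        by_fam = g.habitat_unique_by_family(summary, "mine", family)
        assert by_fam["n_unique"] == 248
        assert by_fam["family_counts"]["Pithoviridae"] == 82
        assert by_fam["family_pct"]["Pithoviridae"] == 33


class TestEnvironmentalRange:
    def toy(self):
        """3 samples, V1 = (10, 20, 30), V2 constant (dropped)."""
        df = pd.DataFrame({
            "habitat": ["farmland", "forest", "mine"],
            "read_count": [10**6] * 3,
            "LON": [10.0, 20.0, 30.0], "LAT": [0.0, 0.0, 0.0],
            "ALT": [5.0, 5.0, 5.0],
        }, index=["s1", "s2", "s3"])
        return g.SampleTable(df)

    def test_sev_hand_computation(self):
        samples = self.toy()
        sev = g.sev_per_sample(samples, ["LON", "ALT"])  # ALT constant, dropped
        np.testing.assert_allclose(sev.to_numpy(), [0.0, 0.5, 1.0])

    def test_range_four_step_hand_computation(self):
        samples = self.toy()
        m = small_matrix([[1.0, 0.0, 1.0], [0.0, 1.0, 0.0]],
                         samples=["s1", "s2", "s3"])
        ert = g.environmental_range(m, samples, variables=["LON", "ALT"])
        # p0 occupies {s1, s3}: SEV range 1.0; p1 occupies {s2}: 0
        np.testing.assert_allclose(ert["raw_range"], [1.0, 0.0])
        np.testing.assert_allclose(ert["std_range"], [1.0, 0.0])

    def test_single_sample_phylotype_attains_minimum(self, community):
        cov, samples, _ = community
        ert = g.environmental_range(cov, samples)
        singles = ert["n_samples_present"] == 1
        assert singles.any()
        assert (ert.loc[singles, "raw_range"] == 0).all()
        assert (ert.loc[singles, "std_range"] == ert["std_range"].min()).all()

    def test_identical_occupancy_identical_range(self):
        samples = self.toy()
        m = small_matrix([[1.0, 0.0, 2.0], [7.0, 0.0, 9.0]],
                         samples=["s1", "s2", "s3"])
        ert = g.environmental_range(m, samples, variables=["LON"])
        assert ert["raw_range"].iloc[0] == ert["raw_range"].iloc[1]

    def test_affine_rescaling_invariance(self, community):
        """std_range is unchanged by affine rescaling of any variable:
        units cancel in the per-variable standardization."""
        cov, samples, _ = community
        ert1 = g.environmental_range(cov, samples)
        df = samples.data.copy()
        df["MAP"] = 3.7 * df["MAP"] - 120.0
        df["pH"] = df["pH"] / 14.0
        ert2 = g.environmental_range(cov, g.SampleTable(df))
        np.testing.assert_allclose(ert1["std_range"], ert2["std_range"],
                                   atol=1e-10)

    def test_occupied_set_growth_never_shrinks_range(self, community):
        """Monotonicity: adding an occupied sample cannot reduce raw_range."""
        cov, samples, _ = community
        ert1 = g.environmental_range(cov, samples)
        data = cov.data.copy()
        rng = np.random.default_rng(5)
        for p in rng.choice(cov.phylotype_ids, 20, replace=False):
            s = rng.choice(cov.sample_ids)
            data.loc[p, s] = max(data.loc[p, s], 1.0)
        ert2 = g.environmental_range(
            g.CoverageMatrix(data, stage=cov.stage), samples)
        assert (ert2["raw_range"] >= ert1["raw_range"] - 1e-12).all()

    def test_phylotype_without_samples_rejected(self):
        samples = self.toy()
        m = small_matrix([[0.0, 0.0, 0.0]], samples=["s1", "s2", "s3"])
        with pytest.raises(ValueError, match="zero samples"):
            g.environmental_range(m, samples, variables=["LON"])


class TestAbundanceOccupancyStats:
    def test_planted_negative_tradeoff_recovered(self):
        """tau < 0 yields negative correlations of average abundance with
        habitat count, site count, and environmental range (p < 0.01 at
        n = 300), across 20 seeds."""
        neg = {"avg_abundance_vs_n_habitats": 0,
               "avg_abundance_vs_log_n_sites": 0,
               "avg_abundance_vs_log_range": 0}
        for seed in range(20):
            cov, samples, _ = g.simulate_community(
                n_phylotypes=300, n_samples_per_habitat=30, tau=-0.5,
                seed=100 + seed)
            norm = g.normalize_coverage(cov, samples)
            ert = g.environmental_range(norm, samples)
            st = g.abundance_occupancy_stats(ert)
            for k in neg:
                if st[k]["r"] < 0 and st[k]["p"] < 0.01:
                    neg[k] += 1
        assert all(v == 20 for v in neg.values()), neg

    def test_null_tradeoff_centred_on_zero(self):
        rs = []
        for seed in range(12):
            cov, samples, _ = g.simulate_community(
                n_phylotypes=200, n_samples_per_habitat=12, tau=0.0,
                seed=300 + seed)
            ert = g.environmental_range(
                g.normalize_coverage(cov, samples), samples)
            rs.append(g.abundance_occupancy_stats(ert)
                      ["avg_abundance_vs_log_n_sites"]["r"])
        assert abs(np.mean(rs)) < 0.1

    def test_too_few_phylotypes_rejected(self):
        ert = pd.DataFrame({"n_samples_present": [1, 2],
                            "n_sites_present": [1, 2],
                            "n_habitats_present": [1, 2],
                            "total_abundance": [1.0, 2.0],
                            "average_abundance": [1.0, 1.0],
                            "raw_range": [0.0, 0.1],
                            "std_range": [0.0, 1.0]})
        with pytest.raises(ValueError, match="at least 3"):
            g.abundance_occupancy_stats(ert)

    def test_constant_vector_reported_undefined(self):
        ert = pd.DataFrame({"n_samples_present": [1, 2, 3],
                            "n_sites_present": [1, 2, 3],
                            "n_habitats_present": [1, 1, 1],
                            "total_abundance": [1.0, 2.0, 3.0],
                            "average_abundance": [1.0, 2.0, 0.5],
                            "raw_range": [0.0, 0.1, 0.2],
                            "std_range": [0.0, 0.5, 1.0]})
        st = g.abundance_occupancy_stats(ert)
        assert st["avg_abundance_vs_n_habitats"]["undefined"]
        assert np.isnan(st["avg_abundance_vs_n_habitats"]["r"])


class TestRarefaction:
    def test_saturated_community_flat_curve(self):
        samples = make_sample_table(3)
        ids = samples.samples_in("forest")
        m = small_matrix(np.ones((5, len(samples.sample_ids))),
                         samples=list(samples.sample_ids))
        out = g.rarefaction_curve(m, samples, "forest", n_perm=10, seed=0)
        np.testing.assert_allclose(out["mean_richness"], 5.0)
        assert out["terminal_slope_pct"] == 0.0

    def test_disjoint_samples_linear_curve(self):
        samples = make_sample_table(3)
        cols = list(samples.sample_ids)
        forest = samples.samples_in("forest")
        values = np.zeros((6, len(cols)))
        for k, s in enumerate(forest):  # 2 phylotypes unique to each sample
            values[2 * k, cols.index(s)] = 1.0
            values[2 * k + 1, cols.index(s)] = 1.0
        m = small_matrix(values, samples=cols)
        out = g.rarefaction_curve(m, samples, "forest", n_perm=5, seed=0)
        np.testing.assert_allclose(out["mean_richness"], [2.0, 4.0, 6.0])
        assert out["terminal_slope_pct"] == pytest.approx(100.0 / 3)

    def test_matches_exhaustive_ordering_oracle(self, rng):
        """Mean accumulation over all 6! orderings (computed directly)
        equals the permutation estimate in the n_perm -> all limit."""
        samples = make_sample_table(6, seed=3)
        cols = list(samples.sample_ids)
        forest = samples.samples_in("forest")
        values = (rng.random((12, len(cols))) < 0.4).astype(float)
        m = small_matrix(values, samples=cols)
        present = m.presence()[forest].to_numpy()
        n = len(forest)
        exhaustive = np.zeros(n)
        for order in itertools.permutations(range(n)):
            seen = np.cumsum(present[:, list(order)], axis=1) > 0
            exhaustive += seen.sum(axis=0)
        import math
        exhaustive /= math.factorial(n)
        out = g.rarefaction_curve(m, samples, "forest", n_perm=4000, seed=1)
        np.testing.assert_allclose(out["mean_richness"], exhaustive, atol=0.25)


class TestEnvRedundancyFilter:
    def test_perfect_pair_removes_exactly_one(self):
        df = make_sample_table(4).data.copy()
        df["TN"] = 2.0 * df["TC"] + 1.0
        retained, removed = g.env_redundancy_filter(
            g.SampleTable(df), variables=["TC", "TN", "pH"])
        assert len(removed) == 1 and removed[0] in ("TC", "TN")
        assert "pH" in retained

    def test_independent_variables_all_retained(self):
        samples = make_sample_table(8, seed=11)
        retained, removed = g.env_redundancy_filter(
            samples, variables=["pH", "EC", "clay", "TP"])
        assert removed == []
        assert retained == ["pH", "EC", "clay", "TP"]

    def test_collinear_triple_matches_minimal_removal_oracle(self):
        """One collinear triple among 5 variables: the greedy retained set
        matches the exhaustive-search solution minimizing removals."""
        rng = np.random.default_rng(7)
        n = 40
        base = rng.normal(size=n)
        df = make_sample_table(8, seed=2).data.iloc[:n].copy()
        df["TC"] = base + rng.normal(0, 0.05, n)
        df["TN"] = base + rng.normal(0, 0.05, n)
        df["CEC"] = base + rng.normal(0, 0.05, n)
        df["pH"] = rng.normal(size=n)
        df["clay"] = rng.normal(size=n)
        samples = g.SampleTable(df)
        variables = ["TC", "TN", "CEC", "pH", "clay"]
        retained, _ = g.env_redundancy_filter(samples, variables=variables)

        from scipy import stats as sps
        rho = sps.spearmanr(samples.env(variables)).statistic

        def valid(subset):
            idx = [variables.index(v) for v in subset]
            sub = rho[np.ix_(idx, idx)] ** 2
            np.fill_diagonal(sub, 0.0)
            return sub.max() <= 0.7

        best = max((s for k in range(len(variables), 0, -1)
                    for s in itertools.combinations(variables, k)
                    if valid(s)), key=len)
        assert len(retained) == len(best)
        assert valid(retained)
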