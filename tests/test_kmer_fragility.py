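"""k-meric susceptibility scoring: z-scores, posteriors, imputation,
control-region geometry, clustering and outlier analysis."""

import numpy as np
import pandas as pd
import pytest

import fragilib as fl
from fragilib._sequence import all_canonical_kmers
from fragilib.kmer_fragility import KmerCountVector, KmerScoreTable


def _counts(k, role, **kmers):
    s = pd.Series(0, index=list(all_canonical_kmers(k)))
    for km, c in kmers.items():
        s[km] = c
    return KmerCountVector(k, role, s)


class TestZscores:
    def test_hand_evaluated_proportion_z(self):
        # X_AA=30, X_AC=10 (n=40), p_AA=0.5 -> (30-20)/sqrt(40*0.25)
        case = _counts(2, "case", AA=30, AC=10)
        control = _counts(2, "control", AA=50, AC=50)
        table = fl.fragility_zscores(case, control)
        assert table.data.loc["AA", "z"] == pytest.approx(10 / np.sqrt(10), abs=1e-9)
        assert table.data.loc["AC", "z"] == pytest.approx(-10 / np.sqrt(10), abs=1e-9)

    def test_observed_equals_expected_gives_zero(self):
        case = _counts(2, "case", AA=20, AC=20)
        control = _counts(2, "control", AA=100, AC=100)
        table = fl.fragility_zscores(case, control)
        assert table.data.loc["AA", "z"] == pytest.approx(0.0)

    def test_matches_direct_formula_on_random_tables(self):
        # oracle: literal evaluation of the one-sample proportion z
        rng = np.random.default_rng(42)
        vocab = list(all_canonical_kmers(2))
        for _ in range(100):
            case_arr = rng.integers(0, 500, len(vocab))
            ctrl_arr = rng.integers(1, 500, len(vocab))
            case = KmerCountVector.from_array(2, "case", case_arr)
            ctrl = KmerCountVector.from_array(2, "control", ctrl_arr)
            table = fl.fragility_zscores(case, ctrl)
            n = case_arr.sum()
            for i, km in enumerate(vocab):
                p = ctrl_arr[i] / ctrl_arr.sum()
                if p == 0 or min(n * p, n * (1 - p)) < 5:
                    assert bool(table.data.loc[km, "insufficient"])
                    continue
                expected = (case_arr[i] - n * p) / np.sqrt(n * p * (1 - p))
                assert table.data.loc[km, "z"] == pytest.approx(expected, abs=1e-12)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError, match="k mismatch"):
            fl.fragility_zscores(_counts(2, "case", AA=10), _counts(4, "control", AAAA=10))

    def test_null_calibration_mean_zero_sd_one(self):
        # case drawn from the control distribution: z ~ N(0, 1)
        rng = np.random.default_rng(5)
        vocab = list(all_canonical_kmers(4))
        p = rng.dirichlet(np.full(len(vocab), 50.0))
        ctrl = KmerCountVector.from_array(4, "control", rng.multinomial(20_000_000, p))
        case = KmerCountVector.from_array(4, "case", rng.multinomial(1_000_000, p))
        z = fl.fragility_zscores(case, ctrl).z.dropna()
        assert abs(z.mean()) < 0.05
        assert abs(z.std(ddof=0) - 1) < 0.05

    def test_strand_symmetric_scoring(self, sim_genome):
        # scoring a breakpoint set on the reverse-complemented genome
        # yields the identical score table
        seq = sim_genome.sequences["chrS"]
        L = len(seq)
        rc = fl.GenomeSequence({"chrS": fl.revcomp(seq)})
        rng = np.random.default_rng(2)
        bonds = np.sort(rng.choice(np.arange(100, L - 100), 3000, replace=False))
        bp_fwd = fl.BreakpointSet({"chrS": bonds})
        bp_rc = fl.BreakpointSet({"chrS": L - bonds})
        case_f = fl.count_breakpoint_kmers(sim_genome, bp_fwd, 4)
        case_r = fl.count_breakpoint_kmers(rc, bp_rc, 4)
        assert case_f.counts.equals(case_r.counts)


class TestBreakProbability:
    def test_direct_bayes_arithmetic(self):
        df = pd.DataFrame(
            {"z": [1.0], "p_control": [0.5], "p_case": [0.6],
             "p_break_given_kmer": [np.nan], "imputed": [False], "insufficient": [False]},
            index=["AA"],
        )
        t = KmerScoreTable(2, df, n_case=100, n_control=100)
        fl.break_probability(t, prior_p_break=0.5)
        assert t.data.loc["AA", "p_break_given_kmer"] == pytest.approx(0.6)

    def test_identical_frequencies_return_prior(self):
        case = _counts(2, "case", AA=200, AC=200, AG=200)
        ctrl = _counts(2, "control", AA=300, AC=300, AG=300)
        t = fl.fragility_zscores(case, ctrl)
        fl.break_probability(t, prior_p_break=0.3)
        obs = t.data.loc[["AA", "AC", "AG"], "p_break_given_kmer"]
        assert np.allclose(obs, 0.3)

    @pytest.mark.parametrize("prior", [0.0, 1.0, -0.1])
    def test_degenerate_prior_rejected(self, prior):
        t = fl.fragility_zscores(_counts(2, "case", AA=50, AC=50), _counts(2, "control", AA=50, AC=50))
        with pytest.raises(ValueError):
            fl.break_probability(t, prior_p_break=prior)


class TestControlRegions:
    def _genome(self, L=30000):
        return fl.GenomeSequence({"chr1": "A" * L})

    def test_flanks_sit_beyond_span_plus_1kb(self):
        regions = fl.IntervalSet([fl.Interval("chr1", 10000, 10100)])
        ctrl = fl.build_control_regions(regions, self._genome(), long_span=400)
        got = list(ctrl)
        # width = 400 + 1000; flanks [s-2w, s-w) and [e+w, e+2w)
        assert got == [fl.Interval("chr1", 7200, 8600), fl.Interval("chr1", 11500, 12900)]

    def test_width_from_top_5pct_longest_regions(self):
        ivs = []
        pos = 0
        lengths = [100] * 98 + [1000, 2000]
        for ln in lengths:
            ivs.append(fl.Interval("chr1", pos, pos + ln))
            pos += ln + 50000
        genome = fl.GenomeSequence({"chr1": "A" * (pos + 10000)})
        with pytest.warns(UserWarning):  # the first left flank falls off the chromosome
            ctrl = fl.build_control_regions(fl.IntervalSet(ivs), genome)
        # top 5% of 100 regions = 5 longest -> mean(2000, 1000, 100, 100, 100) = 660
        width = 660
        first_right_flank = fl.Interval("chr1", 100 + width, 100 + 2 * width)
        assert first_right_flank in list(ctrl)

    def test_controls_never_intersect_break_regions(self):
        rng = np.random.default_rng(1)
        starts = np.sort(rng.choice(90000, 40, replace=False))
        regions = fl.IntervalSet(
            [fl.Interval("chr1", int(s), int(s) + 200) for s in starts]
        ).merge()
        genome = self._genome(120000)
        ctrl = fl.build_control_regions(regions, genome, long_span=300)
        for iv in ctrl:
            assert not regions.overlaps(iv.chrom, iv.start, iv.end)


class TestImputation:
    def _table_with_donors(self, donors):
        vocab = list(all_canonical_kmers(4))
        df = pd.DataFrame(
            {"z": np.nan, "p_control": 1.0 / len(vocab), "p_case": np.nan,
             "p_break_given_kmer": np.nan, "imputed": False, "insufficient": True},
            index=vocab,
        )
        for km, z in donors.items():
            df.loc[km, ["z", "insufficient"]] = [z, False]
        return KmerScoreTable(4, df)

    def test_constant_donor_field_imputes_the_constant(self):
        t = self._table_with_donors({"AAAA": 2.0, "AACC": 2.0, "ACCA": 2.0, "CCAA": 2.0, "CACA": 2.0})
        fl.impute_sparse_kmers(t)
        assert np.allclose(t.data["z"], 2.0)
        assert bool(t.data.loc["AAAT", "imputed"])

    def test_nearest_five_by_strand_aware_hamming(self):
        # all five donors at Hamming distance 1 from AAAT (ATTG via the
        # reverse-complement alignment); mean of {1,1,1,3,3} = 1.8
        t = self._table_with_donors({"AAAA": 1.0, "AAAC": 1.0, "AAAG": 1.0, "AATT": 3.0, "ATAT": 3.0})
        fl.impute_sparse_kmers(t)
        assert t.data.loc["AAAT", "z"] == pytest.approx(1.8)

    def test_donors_never_modified(self):
        donors = {"AAAA": 1.0, "AAAC": 0.5, "AAAG": -1.0, "AATT": 3.0, "ATAT": 2.0}
        t = self._table_with_donors(donors)
        fl.impute_sparse_kmers(t)
        for km, z in donors.items():
            assert t.data.loc[km, "z"] == z
            assert not t.data.loc[km, "imputed"]

    def test_fewer_than_five_donors_uses_global_mean(self):
        t = self._table_with_donors({"AAAA": 4.0, "CCCC": 2.0})
        with pytest.warns(UserWarning, match="fewer than 5 donors"):
            fl.impute_sparse_kmers(t)
        assert t.data.loc["AAAT", "z"] == pytest.approx(3.0)

    def test_completeness_after_imputation(self):
        t = self._table_with_donors({"AAAA": 1.0, "AAAC": 1.0, "AAAG": 1.0, "AATT": 1.0, "ATAT": 1.0})
        fl.impute_sparse_kmers(t)
        assert len(t.data) == fl.n_canonical_kmers(4)
        assert not t.data["z"].isna().any()


class TestScoreTableIO:
    def test_tsv_round_trip_preserves_columns(self, tmp_path):
        case = _counts(2, "case", AA=300, AC=200, CC=100)
        ctrl = _counts(2, "control", AA=200, AC=200, CC=200)
        t = fl.fragility_zscores(case, ctrl)
        fl.break_probability(t)
        p = tmp_path / "scores.tsv"
        fl.write_score_table(t, p)
        header = p.read_text().splitlines()[0]
        assert header == "kmer\tz\tp_control\tp_break_given_kmer\timputed"
        back = fl.read_score_table(p)
        assert np.allclose(back.z.dropna(), t.z.dropna())


class TestClusteringAndOutliers:
    def _table(self, z_values):
        vocab = list(all_canonical_kmers(4))
        df = pd.DataFrame(
            {"z": z_values, "p_control": 1 / len(vocab), "p_case": np.nan,
             "p_break_given_kmer": np.nan, "imputed": False, "insufficient": False},
            index=vocab,
        )
        return KmerScoreTable(4, df)

    def test_duplicated_samples_co_cluster(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=136)
        b = rng.normal(size=136) + 5
        res = fl.normalize_and_cluster(
            {"a1": self._table(a), "a2": self._table(a.copy()),
             "b1": self._table(b), "b2": self._table(b.copy())},
            n_clusters=2,
        )
        assert res.row_labels["a1"] == res.row_labels["a2"]
        assert res.row_labels["b1"] == res.row_labels["b2"]
        assert res.row_labels["a1"] != res.row_labels["b1"]

    def test_rows_standardized(self):
        rng = np.random.default_rng(1)
        res = fl.normalize_and_cluster(
            {"a": self._table(rng.normal(2, 3, 136)), "b": self._table(rng.normal(-1, 0.5, 136))},
            n_clusters=2,
        )
        assert np.allclose(res.matrix.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(res.matrix.std(axis=1, ddof=0), 1, atol=1e-9)

    def test_constant_table_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        tables = {
            "flat": self._table(np.ones(136)),
            "a": self._table(rng.normal(size=136)),
            "b": self._table(rng.normal(size=136)),
        }
        with pytest.warns(UserWarning, match="constant"):
            res = fl.normalize_and_cluster(tables, n_clusters=2)
        assert "flat" not in res.matrix.index

    def test_planted_shift_populates_susceptible_tail(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=1000)
        vocab = [f"k{i}" for i in range(1000)]

        def table(z):
            df = pd.DataFrame(
                {"z": z, "p_control": 1e-3, "p_case": np.nan,
                 "p_break_given_kmer": np.nan, "imputed": False, "insufficient": False},
                index=vocab,
            )
            return KmerScoreTable(4, df)

        shifted = base.copy()
        planted = rng.choice(1000, 10, replace=False)
        shifted[planted] += 8.0
        cmp = fl.outlier_kmer_sets([table(shifted)], [table(base)])
        assert len(cmp.susceptible) == 5  # ceil(0.005 * 1000)
        assert set(cmp.susceptible) <= {vocab[i] for i in planted}

    def test_identical_groups_give_zero_delta(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=1000)
        vocab = [f"k{i}" for i in range(1000)]
        df = pd.DataFrame(
            {"z": z, "p_control": 1e-3, "p_case": np.nan,
             "p_break_given_kmer": np.nan, "imputed": False, "insufficient": False},
            index=vocab,
        )
        t = KmerScoreTable(4, df)
        cmp = fl.outlier_kmer_sets([t], [t])
        assert np.allclose(cmp.delta, 0.0)

    def test_too_few_kmers_rejected(self):
        t = self._table(np.random.default_rng(0).normal(size=136))
        with pytest.raises(ValueError, match="200"):
            fl.outlier_kmer_sets([t], [t])

    def test_octamer_tail_sizes(self):
        assert int(np.ceil(0.005 * fl.n_canonical_kmers(8))) == 165


class TestHybridizationEnergy:
    def test_constant_table_returns_constant(self):
        table = {t: -1.5 for t in ("".join(p) for p in __import__("itertools").product("ACGT", repeat=3))}
        assert fl.hybridization_energy("ACGTACGT", table) == pytest.approx(-1.5)

    def test_homopolymer_uses_single_triplet(self):
        table = {"AAA": -2.3}
        assert fl.hybridization_energy("AAAAAAAA", table) == pytest.approx(-2.3)

    def test_hand_average_of_listed_triplets(self):
        table = {"ACG": 1.0, "CGT": 2.0, "GTA": 3.0, "TAC": 4.0}
        assert fl.hybridization_energy("ACGTAC", table) == pytest.approx(2.5)

    def test_missing_triplet_rejected(self):
        with pytest.raises(KeyError):
            fl.hybridization_energy("ACGT", {"ACG": 1.0})


class TestCorrelationNetwork:
    def _table(self, z):
        vocab = [f"k{i}" for i in range(len(z))]
        df = pd.DataFrame(
            {"z": z, "p_control": 1e-3, "p_case": np.nan,
             "p_break_given_kmer": np.nan, "imputed": False, "insufficient": False},
            index=vocab,
        )
        return KmerScoreTable(4, df)

    def test_negation_yields_single_anticorrelated_edge(self):
        z = np.random.default_rng(0).normal(size=100)
        edges = fl.score_correlation_network({"a": self._table(z), "b": self._table(-z)})
        assert len(edges) == 1
        assert edges[0][2] == pytest.approx(-1.0)

    def test_only_planted_pair_survives_cutoff(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=500)
        a = base + rng.normal(0, 0.3, 500)
        b = base + rng.normal(0, 0.3, 500)
        c = rng.normal(size=500)
        edges = fl.score_correlation_network(
            {"a": self._table(a), "b": self._table(b), "c": self._table(c)}
        )
        assert [(e[0], e[1]) for e in edges] == [("a", "b")]

    def test_zero_variance_table_excluded(self):
        z = np.random.default_rng(2).normal(size=100)
        with pytest.warns(UserWarning, match="zero variance"):
            edges = fl.score_correlation_network(
                {"a": self._table(z), "b": self._table(z.copy()), "flat": self._table(np.zeros(100))}
            )
        assert [(e[0], e[1]) for e in edges] == [("a", "b")]


class TestReplicaRealism:
    def test_replicas_share_scores_not_breakpoints(self, sim_genome):
        # independent case samples from one planted propensity model:
        # score tables correlate strongly while the exact breakpoint
        # sets barely overlap
        truth = fl.FragilityGroundTruth.random(7, effect_sd=1.0, sigmas=(0.0,), weights=(1.0,))
        b1 = fl.simulate_breakpoints(sim_genome, truth, 2000, seed=21)
        b2 = fl.simulate_breakpoints(sim_genome, truth, 2000, seed=22)
        s1, s2 = set(b1.bonds["chrS"]), set(b2.bonds["chrS"])
        overlap = len(s1 & s2) / len(s1)
        assert overlap < 0.10
        case1, ctrl = fl.simulate_count_tables(truth, 1_000_000, 10_000_000, seed=31)
        case2, _ = fl.simulate_count_tables(truth, 1_000_000, 10_000_000, seed=32)
        z1 = fl.fragility_zscores(case1, ctrl).z
        z2 = fl.fragility_zscores(case2, ctrl).z
        both = ~(z1.isna() | z2.isna())
        r = np.corrcoef(z1[both], z2[both])[0, 1]
        assert r > 0.9
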