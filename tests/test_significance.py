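import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mvgwas as mg

from conftest import prune_bruteforce


def cand(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "score"])


class TestThreshold:
    def test_minimum_of_previous_hits(self):
        bfav = pd.Series({"rs1": 4.35, "rs2": 6.2, "rs3": 9.9, "rs4": 1.0})
        prev = mg.PreviousHits(pd.DataFrame(
            {"snp_id": ["rs1", "rs2", "rs3"], "chrom": "1", "pos": [1, 2, 3]}))
        assert mg.bf_threshold_from_previous(bfav, prev) == 4.35
        single = mg.PreviousHits(prev.df.iloc[[1]])
        assert mg.bf_threshold_from_previous(bfav, single) == 6.2

    def test_empty_previous_hits_rejected(self):
        with pytest.raises(ValueError):
            mg.bf_threshold_from_previous(pd.Series(dtype=float),
                                          mg.PreviousHits(pd.DataFrame(columns=["snp_id", "chrom", "pos"])))


class TestGreedyPrune:
    def test_hand_worked_example(self):
        got = mg.greedy_prune(cand([("1", 100_000, 10.0), ("1", 400_000, 5.0),
                                    ("1", 1_200_000, 8.0)]), window=500_000)
        assert sorted(got["pos"]) == [100_000, 1_200_000]

    def test_singleton_and_distant_pairs_untouched(self):
        single = cand([("1", 50, 1.0)])
        assert len(mg.greedy_prune(single, window=500_000)) == 1
        pair = cand([("1", 100_000, 1.0), ("1", 700_000, 2.0)])
        assert len(mg.greedy_prune(pair, window=500_000)) == 2

    def test_different_chromosomes_never_interfere(self):
        got = mg.greedy_prune(cand([("1", 100, 1.0), ("2", 100, 9.0)]), window=500_000)
        assert len(got) == 2

    def test_tie_break_keeps_smaller_position(self):
        got = mg.greedy_prune(cand([("1", 300_000, 5.0), ("1", 100_000, 5.0)]), window=500_000)
        assert list(got["pos"]) == [100_000]

    def test_idempotent_and_matches_bruteforce(self, rng):
        for _ in range(40):
            k = rng.integers(1, 20)
            df = cand([( str(rng.integers(1, 3)), int(rng.integers(0, 3_000_000)),
                         float(rng.integers(1, 15))) for _ in range(k)])
            window = 500_000
            once = mg.greedy_prune(df, window)
            twice = mg.greedy_prune(once, window)
            pd.testing.assert_frame_equal(once, twice)
            expected = prune_bruteforce(list(df.itertuples(index=False, name=None)), window)
            got = sorted(map(tuple, once[["chrom", "pos", "score"]].to_numpy()),
                         key=lambda t: (str(t[0]), t[1]))
            assert [(str(c), p, s) for c, p, s in got] == expected
            # survivors pairwise separated
            for chrom, grp in once.groupby("chrom"):
                pos = np.sort(grp["pos"].to_numpy())
                assert (np.diff(pos) > window).all()


def _toy_panel(entries):
    """entries: list of (snp_id, chrom, pos, maf, z1, z2)."""
    m = len(entries)
    df = pd.DataFrame(entries, columns=["snp_id", "chrom", "pos", "maf", "z_p1", "z_p2"])
    df["allele_ref"], df["allele_alt"], df["strand_ambiguous"] = "A", "G", False
    for j in (1, 2):
        df[f"n_p{j}"] = 50_000.0
        df[f"p_p{j}"] = 2 * stats.norm.sf(np.abs(df[f"z_p{j}"]))
    return mg.MergedPanel(phenotypes=["p1", "p2"], df=df)


class TestClassifyNewHits:
    def setup_method(self):
        self.panel = _toy_panel([
            ("rs_prev", "1", 1_000_000, 0.3, 8.0, 1.0),
            ("rs_near", "1", 1_300_000, 0.3, 7.0, 2.0),     # 300 kb from previous hit
            ("rs_new", "1", 5_000_000, 0.3, 5.0, 5.0),
            ("rs_shadow", "1", 5_200_000, 0.3, 4.8, 4.8),   # weaker, within window of rs_new
            ("rs_flagged", "2", 9_000_000, 0.004, 1.0, 1.2),
            ("rs_null", "2", 1_000_000, 0.3, 0.5, 0.1),
        ])
        self.prev = mg.PreviousHits(pd.DataFrame(
            {"snp_id": ["rs_prev"], "chrom": ["1"], "pos": [1_000_000]}))
        self.bfav = pd.Series({"rs_prev": 6.0, "rs_near": 5.5, "rs_new": 5.0,
                               "rs_shadow": 4.9, "rs_flagged": 4.6, "rs_null": -0.5})

    def test_classification_prunes_and_excludes_near_previous(self):
        hits = mg.classify_new_hits(self.bfav, self.panel, self.prev, threshold=4.5)
        new = hits.df[hits.df["category"] == "new-multivariate"]
        assert sorted(new["snp_id"]) == ["rs_flagged", "rs_new"]
        assert hits.counts == {"previous_univariate": 1, "significant_non_previous": 4,
                               "after_previous_exclusion": 3, "new_multivariate": 2}

    def test_no_snp_above_threshold_gives_empty_list(self):
        hits = mg.classify_new_hits(self.bfav, self.panel, self.prev, threshold=10.0)
        assert (hits.df["category"] == "new-multivariate").sum() == 0

    def test_caution_flags_are_diagnostic_only(self):
        hits = mg.classify_new_hits(self.bfav, self.panel, self.prev, threshold=4.5)
        row = hits.df[hits.df["snp_id"] == "rs_flagged"].iloc[0]
        assert row["low_maf"] and row["weak_univariate"]  # retained, dual-flagged

    def test_threshold_monotonicity(self):
        lo = mg.classify_new_hits(self.bfav, self.panel, self.prev, threshold=4.5)
        hi = mg.classify_new_hits(self.bfav, self.panel, self.prev, threshold=5.5)
        new_lo = set(lo.df.loc[lo.df["category"] == "new-multivariate", "snp_id"])
        new_hi = set(hi.df.loc[hi.df["category"] == "new-multivariate", "snp_id"])
        assert new_hi <= new_lo


class TestRelaxationTable:
    def _hits(self, entries):
        df = pd.DataFrame(entries, columns=["snp_id", "chrom", "pos", "min_univariate_p"])
        df["category"] = "new-multivariate"
        return mg.HitList(df=df)

    def test_constructed_counts_at_the_floor(self):
        # 3 marginal-only loci and 2 multivariate-only loci, far apart
        z_marg = stats.norm.isf(5e-7 / 2)
        panel = _toy_panel([
            (f"rs_m{i}", "1", 2_000_000 * (i + 1), 0.3, z_marg, 0.0 + i * 0.1)
            for i in range(3)
        ] + [("rs_weak", "2", 50_000_000, 0.3, 1.0, 1.0)])
        hits = self._hits([("rs_x1", "2", 1_000_000, 2e-4), ("rs_x2", "2", 10_000_000, 3e-4)])
        table = mg.univariate_relaxation_table(panel, hits, gwas_threshold=5e-8)
        last = table.iloc[-1]
        assert last["cum_univariate_only"] == 3
        assert last["cum_new_multivariate"] == 2

    def test_marginal_snps_near_new_hits_are_absorbed(self):
        z_marg = stats.norm.isf(5e-7 / 2)
        panel = _toy_panel([("rs_m1", "1", 1_000_000, 0.3, z_marg, 0.0)])
        hits = self._hits([("rs_x1", "1", 1_200_000, 2e-4)])
        table = mg.univariate_relaxation_table(panel, hits, gwas_threshold=5e-8)
        assert table["cum_univariate_only"].iloc[-1] == 0
        assert table["cum_new_multivariate"].iloc[-1] == 1

    def test_floor_must_exceed_threshold(self):
        panel = _toy_panel([("rs1", "1", 1000, 0.3, 1.0, 1.0)])
        with pytest.raises(ValueError):
            mg.univariate_relaxation_table(panel, self._hits([]), gwas_threshold=1e-5)


class TestUnreportedUnivariate:
    def test_published_hits_are_not_reported_again(self):
        z_sig = stats.norm.isf(4e-9 / 2)
        panel = _toy_panel([("rs_pub", "1", 1_000_000, 0.3, z_sig, 0.0)])
        pub = mg.PreviousHits(pd.DataFrame(
            {"snp_id": ["rs_pub"], "chrom": ["1"], "pos": [1_000_000]}))
        out = mg.find_unreported_univariate(panel, pub, gwas_threshold=5e-8)
        assert len(out) == 0

    def test_proximity_annotation(self):
        z_sig = stats.norm.isf(4e-9 / 2)
        panel = _toy_panel([
            ("rs_pub", "1", 1_000_000, 0.3, z_sig, 0.0),
            ("rs_close", "1", 1_700_000, 0.3, z_sig, 0.0),   # 700 kb away
            ("rs_far", "1", 3_000_000, 0.3, z_sig, 0.0),     # 2 Mb away
        ])
        pub = mg.PreviousHits(pd.DataFrame(
            {"snp_id": ["rs_pub"], "chrom": ["1"], "pos": [1_000_000]}))
        out = mg.find_unreported_univariate(panel, pub, gwas_threshold=5e-8)
        got = out.df.set_index("snp_id")
        assert bool(got.loc["rs_close", "within_proximity"])
        assert not bool(got.loc["rs_far", "within_proximity"])
        assert got.loc["rs_close", "nearest_previous_hit_bp"] == 700_000
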