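"""Sequence statistics: haplotypes, diversity, neutrality, TN93, AMOVA."""

import itertools

import numpy as np
import pytest

from sundapop import popgen as pg
from _helpers import make_alignment


def mutate(s, pos, base):
    return s[:pos] + base + s[pos + 1:]


class TestReadAlignment:
    def test_basic(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGTACGTAC\n>b\nACGTACGTAT\n>c\nACGTACGTAA\n")
        pm = tmp_path / "m.tsv"
        pm.write_text("individual\tpopulation\na\tp1\nb\tp1\nc\tp2\n")
        aln = pg.read_alignment(fa, pm)
        assert aln.n == 3 and aln.length == 10
        assert aln.populations == ["p1", "p1", "p2"]

    def test_unknown_individual(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGT\n>zzz\nACGT\n")
        pm = tmp_path / "m.tsv"
        pm.write_text("individual\tpopulation\na\tp1\n")
        with pytest.raises(KeyError, match="zzz"):
            pg.read_alignment(fa, pm)

    def test_all_gap_column_dropped(self, tmp_path, caplog):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nA-GT\n>b\nA-GA\n")
        pm = tmp_path / "m.tsv"
        pm.write_text("individual\tpopulation\na\tp1\nb\tp1\n")
        import logging

        with caplog.at_level(logging.WARNING):
            aln = pg.read_alignment(fa, pm)
        assert aln.length == 3
        assert "dropped 1" in caplog.text

    def test_unequal_lengths(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">a\nACGT\n>b\nACG\n")
        pm = tmp_path / "m.tsv"
        pm.write_text("individual\tpopulation\na\tp1\nb\tp1\n")
        with pytest.raises(ValueError, match="unequal"):
            pg.read_alignment(fa, pm)


class TestCollapseHaplotypes:
    def test_all_identical(self):
        aln = make_alignment(["ACGT"] * 5)
        t = pg.collapse_haplotypes(aln)
        assert t.n_haplotypes == 1
        assert t.counts.iloc[0, 0] == 5

    def test_all_distinct(self):
        aln = make_alignment(["AAAA", "AAAT", "AATT", "ATTT"])
        assert pg.collapse_haplotypes(aln).n_haplotypes == 4

    def test_counts_match_string_dedup_oracle(self):
        seqs = ["ACGT", "ACGA", "ACGT", "TCGT", "ACGA", "ACGT"]
        pops = ["p1", "p1", "p2", "p2", "p2", "p1"]
        t = pg.collapse_haplotypes(make_alignment(seqs, pops))
        oracle = {}
        for s in seqs:
            oracle[s] = oracle.get(s, 0) + 1
        assert t.n_haplotypes == len(oracle)
        got = dict(zip(t.haplotypes, t.counts.sum(axis=1)))
        assert got == oracle

    def test_n_matches_any_base(self):
        aln = make_alignment(["ACGT", "ACGN", "NCGT"])
        t = pg.collapse_haplotypes(aln)
        assert t.n_haplotypes == 1
        assert t.haplotypes[0] == "ACGT"  # Ns resolved from the others

    def test_idempotent(self):
        seqs = ["AAAA", "AAAT", "AAAA", "TTTT"]
        t1 = pg.collapse_haplotypes(make_alignment(seqs))
        t2 = pg.collapse_haplotypes(
            make_alignment(t1.haplotypes, pops=["p1"] * t1.n_haplotypes)
        )
        assert t2.n_haplotypes == t1.n_haplotypes


class TestTsTv:
    def test_transition_only_is_infinite(self):
        aln = make_alignment(["AAAA", "GAAA"])
        assert pg.ts_tv_ratio(aln) == float("inf")

    def test_one_each_is_one(self):
        aln = make_alignment(["AAAA", "GTAA"])  # A<->G ts at 0, A<->T tv at 1
        assert pg.ts_tv_ratio(aln) == 1.0

    def test_exhaustive_pair_oracle(self, rng):
        bases = "ACGT"
        seqs = ["".join(rng.choice(list(bases), 20)) for _ in range(5)]
        aln = make_alignment(seqs)
        ts = tv = 0
        purines = {"A", "G"}
        for a, b in itertools.combinations(seqs, 2):
            for x, y in zip(a, b):
                if x == y:
                    continue
                if (x in purines) == (y in purines):
                    ts += 1
                else:
                    tv += 1
        assert pg.ts_tv_ratio(aln) == pytest.approx(ts / tv)


class TestDiversity:
    def test_single_haplotype(self):
        d = pg.diversity(make_alignment(["ACGT"] * 4))
        assert d.gene_diversity == 0.0
        assert d.theta_pi == 0.0

    def test_sixteen_one_split(self):
        """n=17 with counts (16,1): H = (17/16)(1-(16/17)^2-(1/17)^2)."""
        aln = make_alignment(["AAAA"] * 16 + ["AAAT"])
        d = pg.diversity(aln)
        assert d.gene_diversity == pytest.approx(0.1176, abs=5e-5)
        assert d.gene_diversity_se == pytest.approx(0.101, abs=5e-3)

    def test_theta_pi_hand_computed(self):
        # pairwise differences: d12=2 d13=1 d14=3 d23=1 d24=1 d34=2
        aln = make_alignment(["AAAA", "AATT", "AAAT", "ATTT"])
        d = pg.diversity(aln)
        assert d.theta_pi == pytest.approx(10 / 6)

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            make_alignment(["ACGT"])


class TestTajima:
    def test_s_zero_undefined(self):
        aln = make_alignment(["ACGT"] * 4)
        with pytest.raises(pg.UndefinedStatisticError):
            pg.tajimas_d(aln, n_sim=10)

    def test_constants_and_value_oracle(self):
        """D for an n=4 toy against a from-scratch constants evaluation."""
        aln = make_alignment(["AAAA", "AATT", "AAAT", "ATTT"])
        n, s = 4, 3
        pi = 10 / 6
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        expected = (pi - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))
        res = pg.tajimas_d(aln, n_sim=99, seed=0)
        assert res["D"] == pytest.approx(expected, rel=1e-12)
        assert 0 < res["p"] <= 1

    def test_seeded_p_is_reproducible(self):
        aln = make_alignment(["AAAA", "AATT", "AAAT", "ATTT"])
        p1 = pg.tajimas_d(aln, n_sim=200, seed=7)["p"]
        p2 = pg.tajimas_d(aln, n_sim=200, seed=7)["p"]
        assert p1 == p2


class TestFusFs:
    def test_degenerate_boundary(self):
        with pytest.warns(UserWarning, match="clamped"):
            v = pg.fus_fs_value(2, 1, 0.5)
        assert v > 20  # S' = 1: FS pegged at its positive boundary

    def test_ewens_brute_force_oracle(self):
        """n=4, theta=1: unsigned Stirling row (6, 11, 6, 1), rising fact 24."""
        stir = {1: 6, 2: 11, 3: 6, 4: 1}
        theta = 1.0
        rising = 1 * 2 * 3 * 4
        probs = {k: stir[k] * theta**k / rising for k in stir}
        for k_obs in (1, 2, 3, 4):
            expected = sum(probs[k] for k in range(k_obs, 5))
            assert pg.ewens_sf_prime(4, k_obs, theta) == pytest.approx(expected)

    def test_pi_zero_undefined(self):
        with pytest.raises(pg.UndefinedStatisticError):
            pg.fus_fs_value(5, 1, 0.0)

    def test_fs_matches_logit_of_sf(self):
        n, k, theta = 10, 6, 2.5
        sp = pg.ewens_sf_prime(n, k, theta)
        assert pg.fus_fs_value(n, k, theta) == pytest.approx(
            np.log(sp / (1 - sp))
        )


class TestTN93:
    def test_identical_is_zero(self):
        f = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        assert pg.tn93_distance("ACGTACGT", "ACGTACGT", f) == 0.0

    def test_correction_dominates_p_distance(self, rng):
        """Transition-only divergence: TN93 >= raw p-distance, 100 pairs."""
        bases = list("ACGT")
        ts_partner = {"A": "G", "G": "A", "C": "T", "T": "C"}
        f = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        for _ in range(100):
            s1 = "".join(rng.choice(bases, 200))
            s2 = list(s1)
            k = rng.integers(1, 40)
            for pos in rng.choice(200, size=k, replace=False):
                s2[pos] = ts_partner[s2[pos]]
            s2 = "".join(s2)
            p_dist = sum(a != b for a, b in zip(s1, s2)) / 200
            assert pg.tn93_distance(s1, s2, f) >= p_dist - 1e-12

    def test_saturation_error_names_pair(self):
        f = {"A": 0.4, "C": 0.1, "G": 0.4, "T": 0.1}
        with pytest.raises(pg.SaturationError, match="x/y"):
            pg.tn93_distance("AAAA", "GGGG", f, pair_label="x/y")

    def test_pairwise_deletion(self):
        f = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
        d_full = pg.tn93_distance("ACGTACGTAC", "ACGTACGTAT", f)
        d_gap = pg.tn93_distance("ACGTACGTACNN--", "ACGTACGTATAAAA", f)
        # the N/gap columns drop out; only the valid 10 sites count
        assert d_gap == pytest.approx(d_full)


class TestPhiST:
    def test_fixed_difference_is_one(self):
        base = "ACGT" * 10
        other = mutate(base, 39, "A")
        aln = make_alignment([base] * 5 + [other] * 5,
                             ["p1"] * 5 + ["p2"] * 5)
        r = pg.pairwise_phist(aln, n_perm=99, seed=0)
        assert r["phist"].loc["p1", "p2"] == pytest.approx(1.0)
        assert r["p"].loc["p1", "p2"] <= 0.05

    def test_two_population_hand_amova(self):
        """2+2 design with hand-tabulated squared distances."""
        # use unit Hamming distances as the molecular distance
        base = "A" * 20
        s1, s2 = base, mutate(base, 0, "T")
        s3, s4 = mutate(base, 1, "T"), mutate(mutate(base, 1, "T"), 2, "T")
        aln = make_alignment([s1, s2, s3, s4], ["p1", "p1", "p2", "p2"])
        d = pg.pairwise_differences(aln) ** 2
        sa, sw = pg.two_level_components(d, np.array(aln.populations))
        # oracle: direct sums of squares
        n, npop = 4, 2
        ssd_t = sum(d[i, j] for i in range(4) for j in range(i + 1, 4)) / n
        ssd_wp = (d[0, 1] / 2) + (d[2, 3] / 2)
        ssd_ap = ssd_t - ssd_wp
        sigma_w = ssd_wp / (n - npop)
        n0 = (n - (4 + 4) / n) / (npop - 1)
        sigma_a = (ssd_ap / (npop - 1) - sigma_w) / n0
        assert sa == pytest.approx(sigma_a)
        assert sw == pytest.approx(sigma_w)

    def test_relabelling_invariance(self, rng):
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for _ in range(12):
            s = base
            for pos in rng.choice(60, size=3, replace=False):
                s = mutate(s, pos, rng.choice([b for b in "ACGT" if b != s[pos]]))
            seqs.append(s)
        pops = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        r1 = pg.pairwise_phist(make_alignment(seqs, pops), n_perm=0)
        renamed = {"a": "z", "b": "y", "c": "x"}
        r2 = pg.pairwise_phist(
            make_alignment(seqs, [renamed[p] for p in pops]), n_perm=0
        )
        for p, q in itertools.combinations("abc", 2):
            assert r1["phist"].loc[p, q] == pytest.approx(
                r2["phist"].loc[renamed[p], renamed[q]]
            )

    def test_small_population_excluded(self, rng):
        base = "".join(rng.choice(list("ACGT"), 60))
        seqs = []
        for _ in range(5):
            s = base
            pos = int(rng.integers(60))
            seqs.append(mutate(s, pos, rng.choice([b for b in "ACGT" if b != s[pos]])))
        pops = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="'c'"):
            r = pg.pairwise_phist(make_alignment(seqs, pops), n_perm=0)
        assert list(r["phist"].index) == ["a", "b"]


class TestAMOVA:
    @staticmethod
    def _toy():
        base = "ACGT" * 10
        seqs, pops = [], []
        edits = {
            "p1": [(0, "T"), (4, "A")], "p2": [(8, "C")],
            "p3": [(12, "A"), (16, "C")], "p4": [(20, "G")],
        }
        within_pos = {"p1": 30, "p2": 32, "p3": 34, "p4": 36}
        for pop, muts in edits.items():
            for k in range(3):
                s = base
                for pos, b in muts:
                    s = mutate(s, pos, b)
                if k == 2:  # one within-pop variant each
                    s = mutate(s, within_pos[pop], "A")
                seqs.append(s)
                pops.append(pop)
        return make_alignment(seqs, pops)

    def test_components_match_direct_sums_of_squares(self):
        """2 groups x 2 populations x 3 sequences vs a brute-force oracle."""
        aln = self._toy()
        groups = {"g1": ["p1", "p2"], "g2": ["p3", "p4"]}
        d2 = pg.tn93_matrix(aln) ** 2
        res = pg.amova(aln, groups, n_perm=99, seed=0, d2=d2)

        # oracle: explicit loops over the 12 individuals
        labels = aln.populations
        group_of = {"p1": "g1", "p2": "g1", "p3": "g2", "p4": "g2"}
        glabels = [group_of[p] for p in labels]
        n = 12

        def ssd(indices):
            return sum(
                d2[i, j] for i, j in itertools.combinations(indices, 2)
            ) / len(indices)

        ssd_t = ssd(range(n))
        pops = ["p1", "p2", "p3", "p4"]
        ssd_wp = sum(ssd([i for i in range(n) if labels[i] == p]) for p in pops)
        ssd_wg = sum(
            ssd([i for i in range(n) if glabels[i] == g]) for g in ("g1", "g2")
        )
        df_ag, df_ap, df_wp = 1, 2, 8
        sigma_c = ssd_wp / df_wp
        # balanced design: n' = n'' = 3, n''' = 6
        sigma_b = ((ssd_wg - ssd_wp) / df_ap - sigma_c) / 3
        sigma_a = ((ssd_t - ssd_wg) / df_ag - sigma_c - 3 * sigma_b) / 6
        assert res.sigma_c == pytest.approx(sigma_c)
        assert res.sigma_b == pytest.approx(sigma_b)
        assert res.sigma_a == pytest.approx(sigma_a)

    def test_percentages_sum_to_100(self):
        res = pg.amova(self._toy(), {"g1": ["p1", "p2"], "g2": ["p3", "p4"]},
                       n_perm=99, seed=0)
        assert sum(res.percentages) == pytest.approx(100.0, abs=1e-9)

    def test_identical_sequences_degenerate(self):
        aln = make_alignment(["ACGT"] * 8,
                             ["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2 + ["p4"] * 2)
        with pytest.raises(ZeroDivisionError):
            pg.amova(aln, {"g1": ["p1", "p2"], "g2": ["p3", "p4"]}, n_perm=0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="no populations"):
            pg.amova(self._toy(), {"g1": ["p1", "p2", "p3", "p4"], "g2": []},
                     n_perm=0)

    def test_unknown_population_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            pg.amova(self._toy(), {"g1": ["p1", "p2"], "g2": ["p3", "nope"]},
                     n_perm=0)


class TestMismatch:
    def test_identical_pair(self):
        res = pg.mismatch(make_alignment(["ACGT", "ACGT"]))
        assert res.histogram.tolist() == [1.0]
        assert res.r2 is None

    def test_raggedness_direct_formula(self):
        from sundapop.popgen.stats import raggedness

        hist = np.array([0.25, 0.5, 0.25])
        # classes 0..2, x3 = 0: (0.5-0.25)^2+(0.25-0.5)^2+(0-0.25)^2
        assert raggedness(hist) == pytest.approx(0.25**2 + 0.25**2 + 0.25**2)

    def test_r2_hand_computation(self):
        aln = make_alignment(["AAAA", "AATT", "AAAT", "ATTT"])
        res = pg.mismatch(aln)
        # column 1: T once (seq4); column 2: A once (seq1)... tabulate:
        # col0 all A; col1 A,A,A,T -> singleton T in seq4
        # col2 A,T,A,T no singleton; col3 A,T,T,T -> singleton A in seq1
        u = np.array([1, 0, 0, 1])
        pi = 10 / 6
        s = 3
        expected = np.sqrt(((u - pi / 2) ** 2).sum() / 4) / s
        assert res.r2 == pytest.approx(expected)
        assert res.histogram.sum() == pytest.approx(1.0)


class TestInvariants:
    def test_pooled_theta_pi_at_least_mean_within_under_structure(self):
        """Structured demes (between-population divergence >= within): the
        pooled theta_pi dominates the average within-population theta_pi."""
        from sundapop.simulate import SeqSimConfig, simulate_sequences

        for seed in range(5):
            cfg = SeqSimConfig(n_sites=2, samples_per_site=8, theta=4.0,
                               migration=0.05, growth=1.0, seed=seed)
            aln = simulate_sequences(cfg)
            pooled = pg.diversity(aln).theta_pi
            within = np.mean([
                pg.diversity(aln.subset(p)).theta_pi
                for p in aln.population_names
            ])
            assert pooled >= within - 1e-9

    def test_haplotype_count_bounded_by_n(self, rng):
        seqs = ["".join(rng.choice(list("AC"), 6)) for _ in range(20)]
        t = pg.collapse_haplotypes(make_alignment(seqs))
        assert t.n_haplotypes <= 20
        assert t.total_n == 20
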