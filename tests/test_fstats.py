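"""f-statistic estimators, jackknife, Welch tests, enumeration, scans."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from swampx.fstats import (
    FStatConfig,
    FStatError,
    block_jackknife,
    compare_f3,
    contrast_autosome_x,
    enumerate_f4,
    f4_configurations,
    f4_scan,
    f_statistic,
    per_site_f2,
    per_site_f3_outgroup,
    per_site_f4,
    welch_t,
)
from swampx.genotype_data import (
    AlleleCountTable,
    assign_blocks,
)


def make_table(pops_counts: dict, chrom="chr1", chrom_class="autosome",
               spacing=10) -> AlleleCountTable:
    """Count table from {pop: (derived array, total array)}."""
    pops = list(pops_counts)
    derived = np.stack([np.asarray(pops_counts[p][0]) for p in pops])
    total = np.stack([np.asarray(pops_counts[p][1]) for p in pops])
    n = derived.shape[1]
    sites = pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, n + 1) * spacing, "ref": "A",
        "alt": "G", "chrom_class": chrom_class})
    return AlleleCountTable(sites, pops, derived, total)


def random_table(rng, n_pops=4, n_sites=200, max_copies=8, labels=None):
    pops = labels or [f"P{i}" for i in range(n_pops)]
    counts = {}
    for p in pops:
        total = rng.integers(2, max_copies + 1, size=n_sites)
        derived = rng.binomial(total, rng.uniform(0.1, 0.9, size=n_sites))
        counts[p] = (derived, total)
    return make_table(counts)


class TestPerSiteEstimators:
    def test_f2_zero_for_identical_fixed(self):
        vals = per_site_f2((np.array([0, 2]), np.array([2, 2])),
                           (np.array([0, 2]), np.array([2, 2])))
        assert np.allclose(vals, 0.0)

    def test_f2_hand_arithmetic(self):
        # (0.5)^2 - [0.5*0.5*2/1]/2 - 0 = 0
        vals = per_site_f2((np.array([1]), np.array([2])),
                           (np.array([0]), np.array([2])))
        assert vals[0] == pytest.approx(0.0, abs=1e-15)

    def test_f2_skips_singleton_copies_when_corrected(self):
        vals = per_site_f2((np.array([1]), np.array([1])),
                           (np.array([0]), np.array([2])))
        assert np.isnan(vals[0])
        raw = per_site_f2((np.array([1]), np.array([1])),
                          (np.array([0]), np.array([2])),
                          bias_correction=False)
        assert raw[0] == 1.0

    def test_f3_equals_squared_difference_when_a_is_b(self):
        dC, tC = np.array([3, 1]), np.array([4, 4])
        dA, tA = np.array([1, 2]), np.array([4, 4])
        vals = per_site_f3_outgroup((dA, tA), (dA, tA), (dC, tC),
                                    bias_correction=False)
        assert np.allclose(vals, (dC / tC - dA / tA) ** 2)
        assert (vals >= 0).all()

    def test_f3_zero_when_outgroup_matches_a(self):
        same = (np.array([2]), np.array([4]))
        other = (np.array([1]), np.array([4]))
        vals = per_site_f3_outgroup(same, other, same, bias_correction=False)
        assert vals[0] == 0.0

    def test_f4_fixed_frequencies(self):
        one = (np.array([2]), np.array([2]))
        zero = (np.array([0]), np.array([2]))
        assert per_site_f4(one, zero, one, zero)[0] == 1.0

    def test_f4_degenerate_b_equals_c_algebra(self):
        # f4(A, B; B, D) collapses to (pA - pB)(pB - pD), an f2-like
        # covariance term; such configs are rejected upstream by FStatConfig
        rng = np.random.default_rng(0)
        tA = tB = tD = np.full(50, 6)
        dA, dB, dD = (rng.integers(0, 7, 50) for _ in range(3))
        lhs = per_site_f4((dA, tA), (dB, tB), (dB, tB), (dD, tD))
        pA, pB, pD = dA / 6, dB / 6, dD / 6
        assert np.allclose(lhs, (pA - pB) * (pB - pD))


class TestBlockJackknife:
    def test_constant_values_zero_se(self):
        jk = block_jackknife(np.full(30, 0.7), np.repeat(np.arange(3), 10))
        assert jk.estimate == pytest.approx(0.7)
        assert jk.se == 0.0
        assert jk.zero_se and math.isinf(jk.z)

    def test_equal_blocks_reduce_to_textbook_jackknife(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=60)
        ids = np.repeat(np.arange(6), 10)
        jk = block_jackknife(vals, ids)
        deleted = np.array([vals[ids != b].mean() for b in range(6)])
        se_textbook = math.sqrt((6 - 1) / 6
                                * ((deleted - deleted.mean()) ** 2).sum())
        assert jk.se == pytest.approx(se_textbook, abs=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 10 ** 6), st.integers(3, 12), st.integers(30, 120))
    def test_matches_brute_force_weighted_oracle(self, seed, g, n):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=n)
        ids = rng.integers(0, g, size=n)
        if len(np.unique(ids)) < 2:
            ids[: 2] = [0, 1]
        jk = block_jackknife(vals, ids)
        # explicit leave-one-block-out recomputation
        blocks = np.unique(ids)
        theta = vals.mean()
        m = np.array([(ids == b).sum() for b in blocks], dtype=float)
        theta_del = np.array([vals[ids != b].mean() for b in blocks])
        h = n / m
        tau = h * theta - (h - 1) * theta_del
        theta_j = len(blocks) * theta - ((1 - m / n) * theta_del).sum()
        se = math.sqrt((((tau - theta_j) ** 2) / (h - 1)).sum() / len(blocks))
        assert jk.estimate == pytest.approx(theta, abs=1e-12)
        assert jk.se == pytest.approx(se, abs=1e-12)

    def test_single_block_rejected(self):
        with pytest.raises(FStatError, match="2 non-empty blocks"):
            block_jackknife(np.ones(5), np.zeros(5, dtype=int))


class TestFStatistic:
    def test_f4_antisymmetry_and_exchange(self):
        rng = np.random.default_rng(2)
        table = random_table(rng)
        part = assign_blocks(table.sites, 500)
        a, b, c, d = table.populations

        def f4(p):
            return f_statistic(table, FStatConfig("f4", p), part)

        base = f4((a, b, c, d))
        assert f4((a, b, d, c)).estimate == pytest.approx(-base.estimate)
        assert f4((b, a, c, d)).estimate == pytest.approx(-base.estimate)
        assert f4((b, a, c, d)).z == pytest.approx(-base.z)
        assert f4((c, d, a, b)).estimate == pytest.approx(base.estimate)
        assert f4((c, d, a, b)).se == pytest.approx(base.se)

    def test_repeated_population_rejected(self):
        with pytest.raises(FStatError, match="repeated"):
            FStatConfig("f4", ("A", "A", "C", "D"))

    def test_estimate_is_weighted_block_combination(self):
        rng = np.random.default_rng(3)
        table = random_table(rng)
        part = assign_blocks(table.sites, 700)
        res = f_statistic(table, FStatConfig(
            "f4", tuple(table.populations)), part)
        pb = res.per_block
        combined = (pb["value"] * pb["weight"]).sum() / pb["weight"].sum()
        assert res.estimate == pytest.approx(combined, abs=1e-12)
        assert res.z == pytest.approx(res.estimate / res.se)


class TestEnumeration:
    def test_macaque_combinatorics(self):
        pops = ["OLB", "CMT", "CMV", "CMM", "CMA1", "CMA2", "RMC", "RMI",
                "JPM", "TWM", "TIM", "ASM", "STM"]
        assert len(f4_configurations(pops, "OLB")) == 220

    def test_four_populations_give_four_triples(self):
        assert len(f4_configurations(list("OABCD"), "O")) == 4

    def test_enumeration_rows_and_orientation(self):
        rng = np.random.default_rng(4)
        table = random_table(rng, n_pops=5, labels=list("OBCDE"))
        part = assign_blocks(table.sites, 500)
        df = enumerate_f4(table, "O", part, alpha=0.05)
        assert len(df) == 4
        # reported orientation has the smallest |z| among the three
        for _, row in df.iterrows():
            zs = []
            for b, c, d in [(row.B, row.C, row.D), (row.C, row.B, row.D),
                            (row.D, row.B, row.C)]:
                r = f_statistic(table, FStatConfig("f4", ("O", b, c, d)),
                                part)
                zs.append(abs(r.z))
            assert abs(row.z) == pytest.approx(min(zs))

    def test_planted_edge_flags_only_spanning_triples(self):
        from swampx.genotype_data import (allele_counts_by_population,
                                          filter_complete_cases)
        from swampx.synthetic_data import gene_flow_scenario

        _, gm, _ = gene_flow_scenario(seed=21, target="C", m=0.01)
        table = allele_counts_by_population(filter_complete_cases(gm))
        part = assign_blocks(table.sites, classes=["autosome"])
        df = enumerate_f4(table, "O", part, alpha=0.0001)
        flagged = df[df["significant"]]
        # the only triple is {B, C, D}; with B->C flow it must be flagged
        assert len(df) == 1 and len(flagged) == 1


class TestScan:
    def test_constant_frequencies_flat(self):
        n = 40
        fixed = (np.full(n, 4), np.full(n, 8))
        table = make_table({"A": (np.full(n, 8), np.full(n, 8)),
                            "B": (np.full(n, 0), np.full(n, 8)),
                            "C": fixed, "D": (np.full(n, 2), np.full(n, 8))})
        scan = f4_scan(table, FStatConfig("f4", ("A", "B", "C", "D")), "chr1")
        assert scan["value"].nunique() == 1

    def test_whole_chromosome_window_equals_pooled_mean(self):
        rng = np.random.default_rng(5)
        table = random_table(rng)
        cfg = FStatConfig("f4", tuple(table.populations))
        per_site = f4_scan(table, cfg, "chr1")
        windowed = f4_scan(table, cfg, "chr1", window=10 ** 9)
        assert len(windowed) == 1
        assert windowed["value"].iloc[0] == pytest.approx(
            per_site["value"].mean())

    def test_planted_segment_shows_local_excursion(self):
        # clean tree (O,B)(C,D) gives f4 = 0; B ancestry planted into C in
        # the second half of the chromosome drives f4(O,B;C,D) negative there
        rng = np.random.default_rng(6)
        n = 400

        def drift(scale=0.15):
            return rng.normal(0, scale, n)

        p = rng.uniform(0.25, 0.75, n)
        clip = lambda a: np.clip(a, 0.01, 0.99)
        p_o, p_b = clip(p + drift()), clip(p + drift())
        p_cd = clip(p + drift())
        p_c_base, p_d = clip(p_cd + drift(0.1)), clip(p_cd + drift(0.1))
        planted = np.arange(n) >= n // 2
        p_c = np.where(planted, p_b, p_c_base)   # full replacement by B
        total = np.full(n, 40)
        table = make_table({
            "O": (rng.binomial(40, p_o), total),
            "B": (rng.binomial(40, p_b), total),
            "C": (rng.binomial(40, p_c), total),
            "D": (rng.binomial(40, p_d), total)})
        scan = f4_scan(table, FStatConfig("f4", ("O", "B", "C", "D")),
                       "chr1", window=1000)
        mid = len(scan) // 2
        assert scan["value"].iloc[mid:].mean() < -0.01
        assert abs(scan["value"].iloc[:mid].mean()) < 0.01


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_matches_scipy_reference(self):
        x = [0.1, 0.2, 0.15, 0.05]
        y = [0.3, 0.4, 0.35]
        t, df, p = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert df == pytest.approx(ref.df, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=6), rng.normal(1, 1, size=9)
        t1, df1, p1 = welch_t(x, y)
        t2, df2, p2 = welch_t(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_too_small_sample_rejected(self):
        with pytest.raises(FStatError, match="at least 2"):
            welch_t([1.0], [1.0, 2.0])

    def test_degenerate_zero_variance_unequal_means_flagged(self):
        with pytest.raises(FStatError, match="degenerate"):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestContrast:
    def test_identical_counts_on_both_classes_give_p1(self):
        rng = np.random.default_rng(9)
        n = 100
        counts = {p: (rng.integers(0, 9, n), np.full(n, 8))
                  for p in "ABCD"}
        auto = make_table(counts, chrom="chr1", chrom_class="autosome")
        x = make_table(counts, chrom="chrX", chrom_class="X")
        table = AlleleCountTable(
            pd.concat([auto.sites, x.sites], ignore_index=True),
            auto.populations,
            np.concatenate([auto.derived, x.derived], axis=1),
            np.concatenate([auto.total, x.total], axis=1))
        pa = assign_blocks(auto.sites, 300, ["autosome"])
        px = assign_blocks(x.sites, 300, ["X"])
        cr = contrast_autosome_x(table, FStatConfig("f4", tuple("ABCD")),
                                 pa, px)
        assert cr.p_value == pytest.approx(1.0)
        assert cr.direction == "none"

    def test_female_biased_mirror_reverses_direction(self):
        # male-only vs female-only migration flips which class is more
        # strongly pulled toward the donor
        from swampx.genotype_data import (allele_counts_by_population,
                                          filter_complete_cases)
        from swampx.synthetic_data import (ContinuousMigration,
                                           DemographicModel, LocusPlan,
                                           Split, simulate)

        def scenario(m_f, m_m, seed):
            pops = {p: 500 for p in
                    ["A", "B", "C", "D", "Dp", "root", "anc1", "ancD"]}
            pops["ancBC"] = 100
            model = DemographicModel(
                populations=pops, root="root",
                events=[Split(0, "root", ("A", "anc1")),
                        Split(30, "anc1", ("ancBC", "ancD")),
                        Split(60, "ancD", ("D", "Dp")),
                        Split(210, "ancBC", ("B", "C")),
                        ContinuousMigration("Dp", "C", m_f, m_m, 230, 380)],
                end_time=400,
                sample_plan={p: (2, 2) for p in ["A", "B", "C", "D"]})
            gm, _ = simulate(model, LocusPlan(n_mito=0), seed)
            table = allele_counts_by_population(filter_complete_cases(gm))
            pa = assign_blocks(table.sites, classes=["autosome"])
            px = assign_blocks(table.sites, classes=["X"])
            return contrast_autosome_x(
                table, FStatConfig("f4", ("A", "B", "C", "D")), pa, px)

        male = scenario(0.0, 0.02, seed=31)
        female = scenario(0.02, 0.0, seed=31)
        assert male.direction == "x_more_negative"
        # female-biased flow hits X harder than autosomes: X keeps LESS of
        # the original (B-shared) ancestry, so f4_X is closer to zero
        assert female.x.estimate > female.autosome.estimate
        assert female.direction == "x_less_negative"


class TestCompareF3:
    def test_same_config_twice_p1(self):
        rng = np.random.default_rng(10)
        table = random_table(rng, n_pops=3, labels=["A", "B", "O"])
        part = assign_blocks(table.sites, 500)
        cfg = FStatConfig("f3_outgroup", ("A", "B", "O"))
        t, df, p, _ = compare_f3(table, cfg, cfg, part)
        assert p == pytest.approx(1.0)

    def test_sister_pair_has_larger_shared_drift(self):
        from swampx.genotype_data import (allele_counts_by_population,
                                          filter_complete_cases)
        from swampx.synthetic_data import treeness_null_scenario

        # topology (O,(B,(C,D))): f3(C,D;O) > f3(C,B;O)
        _, gm, _ = treeness_null_scenario(seed=17)
        table = allele_counts_by_population(filter_complete_cases(gm))
        part = assign_blocks(table.sites, classes=["autosome"])
        sisters = FStatConfig("f3_outgroup", ("C", "D", "O"))
        split = FStatConfig("f3_outgroup", ("C", "B", "O"))
        t, df, p, larger = compare_f3(table, sisters, split, part)
        assert larger == str(sisters)
        assert p < 0.01

    def test_outgroups_must_match(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_pops=4, labels=["A", "B", "O", "Q"])
        part = assign_blocks(table.sites, 500)
        with pytest.raises(FStatError, match="outgroup"):
            compare_f3(table,
                       FStatConfig("f3_outgroup", ("A", "B", "O")),
                       FStatConfig("f3_outgroup", ("A", "B", "Q")), part)
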