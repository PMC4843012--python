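"""Differential tests: rank-sum, NB exact, Fisher, BH, DM gene calls."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaconcord import (
    BinaryAlterationMatrix,
    ExpressionMatrix,
    MethylationMatrix,
    bh_adjust,
    call_dm_genes,
    fisher_binary_de,
    nb_exact_de,
    wilcoxon_de,
)
from metaconcord.datatypes import Group, GroupAssignment, Policy
from metaconcord.differential import (
    DOWN,
    TIED,
    UP,
    conditional_nb_pvalue,
    median_of_ratios_factors,
)


def assigns_for(met_ids, nonmet_ids):
    pol = Policy.TNM_ONLY
    return [
        *[GroupAssignment(s, Group.METASTASIS, pol, "") for s in met_ids],
        *[GroupAssignment(s, Group.NON_METASTASIS, pol, "") for s in nonmet_ids],
    ]


def matrix_from_rows(rows, met_n, nonmet_n, scale="log2_intensity"):
    cols = [f"m{i}" for i in range(met_n)] + [f"c{i}" for i in range(nonmet_n)]
    df = pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))], columns=cols)
    m = ExpressionMatrix(df, scale)
    groups = assigns_for(cols[:met_n], cols[met_n:])
    return m, groups


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def rank_sum_exact_oracle(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in x)
    center = n1 * (len(pooled) + 1) / 2
    total = 0
    extreme = 0
    for combo in itertools.combinations(pooled, n1):
        w = sum(ranks[v] for v in combo)
        total += 1
        if abs(w - center) >= abs(obs - center) - 1e-12:
            extreme += 1
    return Fraction(extreme, total)


class TestWilcoxon:
    def test_separated_triplets_exact_p(self):
        """met=[4,5,6] vs nonmet=[1,2,3]: 2 of C(6,3)=20 assignments as extreme."""
        m, groups = matrix_from_rows([[4, 5, 6, 1, 2, 3]], 3, 3)
        dt = wilcoxon_de(m, groups)
        assert dt.table.loc[0, "p_raw"] == pytest.approx(0.1, abs=1e-12)
        assert dt.table.loc[0, "direction"] == UP
        assert dt.test_name == "wilcoxon_rank_sum"
        assert (dt.n_met, dt.n_nonmet) == (3, 3)

    def test_constant_feature_is_null(self):
        m, groups = matrix_from_rows([[2.0] * 6, [4, 5, 6, 1, 2, 3]], 3, 3)
        dt = wilcoxon_de(m, groups)
        assert dt.table.loc[0, "p_raw"] == 1.0
        assert dt.table.loc[0, "direction"] == TIED

    def test_empty_group_error_names_group(self):
        m, _ = matrix_from_rows([[1, 2, 3, 4]], 2, 2)
        groups = assigns_for(["m0", "m1"], [])
        with pytest.raises(ValueError, match="non_metastasis"):
            wilcoxon_de(m, groups)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 3, 1), (5, 4, 2), (6, 6, 3)])
    def test_exact_path_matches_enumeration_oracle(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        m, groups = matrix_from_rows([list(x) + list(y)], n1, n2)
        dt = wilcoxon_de(m, groups, method="exact")
        expected = float(rank_sum_exact_oracle(x, y))
        assert dt.table.loc[0, "p_raw"] == pytest.approx(expected, rel=1e-10)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        rows = rng.normal(7, 1, (5, 40))
        m1, groups = matrix_from_rows(rows.tolist(), 20, 20)
        m2, _ = matrix_from_rows((np.exp(rows / 3)).tolist(), 20, 20)
        t1 = wilcoxon_de(m1, groups).table
        t2 = wilcoxon_de(m2, groups).table
        np.testing.assert_allclose(t1["p_raw"], t2["p_raw"], rtol=1e-12)
        assert (t1["direction"] == t2["direction"]).all()

    def test_swapping_groups_flips_direction_not_p(self):
        rng = np.random.default_rng(10)
        rows = rng.normal(0, 1, (6, 30)) + np.linspace(0, 1, 6)[:, None] * (
            np.arange(30) < 15
        )
        m, groups = matrix_from_rows(rows.tolist(), 15, 15)
        swapped = assigns_for([f"c{i}" for i in range(15)], [f"m{i}" for i in range(15)])
        t1 = wilcoxon_de(m, groups).table
        t2 = wilcoxon_de(m, swapped).table
        np.testing.assert_allclose(t1["p_raw"], t2["p_raw"], rtol=1e-9)
        flip = {UP: DOWN, DOWN: UP, TIED: TIED}
        assert list(t2["direction"]) == [flip[d] for d in t1["direction"]]

    def test_exact_and_asymptotic_agree_for_small_n(self):
        rng = np.random.default_rng(12)
        rows = rng.normal(0, 1, (20, 12))
        m, groups = matrix_from_rows(rows.tolist(), 6, 6)
        pe = wilcoxon_de(m, groups, method="exact").table["p_raw"]
        pa = wilcoxon_de(m, groups, method="asymptotic").table["p_raw"]
        assert np.max(np.abs(pe - pa)) < 0.05
        assert np.corrcoef(pe, pa)[0, 1] > 0.99


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

BH_FIXTURES = [
    # (raw p, expected q) computed with the independent step-up rule
    # q_i = min_{j >= i} p_(j) * n / j, capped at 1
    ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ([0.005, 0.011, 0.02, 0.04, 0.5], [0.025, 0.0275, 0.05 / 1.5, 0.05, 0.5]),
    ([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0], [1.0] * 10),
    ([0.04, 0.01, 0.03, 0.005], [0.04, 0.02, 0.04, 0.02]),
    ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
]


def bh_stepup_oracle(p):
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (p[order] * n / np.arange(1, n + 1))[::-1]
    )[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("p_raw,expected", BH_FIXTURES)
    def test_hand_computed_fixtures(self, p_raw, expected):
        np.testing.assert_allclose(bh_adjust(p_raw), expected, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_matches_stepup_oracle_and_bounds(self, p_raw):
        q = bh_adjust(p_raw)
        np.testing.assert_allclose(q, bh_stepup_oracle(p_raw), rtol=1e-12)
        p = np.asarray(p_raw)
        assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        # q is monotone in the sorted raw p
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_rejection_set_reproduces_stepup_rule(self):
        rng = np.random.default_rng(21)
        p = np.concatenate([rng.uniform(0, 0.01, 20), rng.uniform(0, 1, 180)])
        alpha = 0.2
        q = bh_adjust(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        below = np.nonzero(p[order] <= alpha * np.arange(1, n + 1) / n)[0]
        stepup = set(order[: below[-1] + 1]) if below.size else set()
        assert set(np.nonzero(q <= alpha)[0]) == stepup


# ---------------------------------------------------------------------------
# NB conditional exact test
# ---------------------------------------------------------------------------


def nb_conditional_oracle(y_a, y_b, n_a, n_b, phi):
    """Conditional two-sided p via per-sample pmf convolution.

    Builds each group's total pmf by repeated np.convolve of the
    single-sample NB pmf (computed from lgamma), then applies the
    minimum-likelihood two-sided rule — an independent route from the
    closed-form sum-NB used by the implementation.
    """
    t = y_a + y_b
    mu = t / (n_a + n_b)
    r = 1.0 / phi
    p = r / (r + mu)
    x = np.arange(t + 1)
    logf = (
        np.array([math.lgamma(xi + r) for xi in x])
        - np.array([math.lgamma(xi + 1) for xi in x])
        - math.lgamma(r)
        + r * math.log(p)
        + x * math.log1p(-p)
    )
    f = np.exp(logf)

    def group_pmf(n):
        g = f.copy()
        for _ in range(n - 1):
            g = np.convolve(g, f)[: t + 1]
        return g

    ga, gb = group_pmf(n_a), group_pmf(n_b)
    joint = ga * gb[::-1]
    joint = joint / joint.sum()
    obs = joint[y_a]
    return float(min(1.0, joint[joint <= obs * (1 + 1e-7)].sum()))


class TestNbExact:
    def test_binomial_limit_single_samples(self):
        """dispersion 0, equal libraries, counts (A=0, B=10): p = 2*(1/2)^10."""
        rows = [[0, 10], [10, 0]]  # second gene balances the library sizes
        m, groups = matrix_from_rows(rows, 1, 1, scale="raw_count")
        dt = nb_exact_de(m, groups, dispersion=0.0)
        assert dt.table.loc[0, "p_raw"] == pytest.approx(2 * 0.5**10, rel=1e-9)
        assert dt.table.loc[0, "direction"] == DOWN

    def test_identical_columns_are_null(self):
        rows = [[5, 7, 5, 7], [3, 3, 3, 3]]
        m, groups = matrix_from_rows(rows, 2, 2, scale="raw_count")
        dt = nb_exact_de(m, groups)
        assert dt.table.loc[0, "p_raw"] == 1.0
        assert dt.table.loc[0, "direction"] == TIED

    def test_all_zero_gene_p1(self):
        rows = [[0, 0, 0, 0], [4, 6, 3, 7]]
        m, groups = matrix_from_rows(rows, 2, 2, scale="raw_count")
        dt = nb_exact_de(m, groups)
        assert dt.table.loc[0, "p_raw"] == 1.0

    def test_non_count_matrix_rejected(self):
        m, groups = matrix_from_rows([[1.0, 2.0]], 1, 1)
        with pytest.raises(ValueError, match="raw_count"):
            nb_exact_de(m, groups)

    @pytest.mark.parametrize("y_a,y_b", [(0, 20), (5, 15), (8, 12), (10, 10), (17, 3)])
    def test_matches_convolution_oracle(self, y_a, y_b):
        p_impl = conditional_nb_pvalue(y_a, y_b, 2, 2, 0.1)
        p_oracle = nb_conditional_oracle(y_a, y_b, 2, 2, 0.1)
        assert p_impl == pytest.approx(p_oracle, rel=1e-9)

    def test_zero_dispersion_equals_conditional_binomial(self):
        """With phi=0 the conditional law is Binomial(t, n_a/(n_a+n_b))."""
        for y_a, y_b, n_a, n_b in [(3, 9, 2, 4), (0, 12, 3, 3), (7, 5, 5, 2)]:
            t = y_a + y_b
            pr = Fraction(n_a, n_a + n_b)
            pmf = [
                Fraction(math.comb(t, a)) * pr**a * (1 - pr) ** (t - a)
                for a in range(t + 1)
            ]
            obs = pmf[y_a]
            expected = float(sum(q for q in pmf if q <= obs))
            got = conditional_nb_pvalue(y_a, y_b, n_a, n_b, 0.0)
            assert got == pytest.approx(expected, rel=1e-9)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(3)
        rows = rng.poisson(30, (8, 6)).tolist()
        m, groups = matrix_from_rows(rows, 3, 3, scale="raw_count")
        swapped = assigns_for([f"c{i}" for i in range(3)], [f"m{i}" for i in range(3)])
        t1 = nb_exact_de(m, groups).table
        t2 = nb_exact_de(m, swapped).table
        np.testing.assert_allclose(t1["p_raw"], t2["p_raw"], rtol=1e-9)
        flip = {UP: DOWN, DOWN: UP, TIED: TIED}
        assert list(t2["direction"]) == [flip[d] for d in t1["direction"]]

    def test_median_of_ratios_scale_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.poisson(50, (30, 4)).astype(float) + 1
        df = pd.DataFrame(base, columns=list("abcd"))
        sf1 = median_of_ratios_factors(df)
        df2 = df * np.array([1.0, 2.0, 4.0, 0.5])
        sf2 = median_of_ratios_factors(df2)
        ratio = sf2 / sf1
        scaled = np.array([1.0, 2.0, 4.0, 0.5])
        np.testing.assert_allclose(
            ratio / ratio[0], scaled / scaled[0], rtol=1e-9
        )


# ---------------------------------------------------------------------------
# Fisher's exact test on binary calls
# ---------------------------------------------------------------------------


def fisher_two_sided_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        return Fraction(
            math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1)
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = table_prob(a)
    cutoff = obs * Fraction(10_000_001, 10_000_000)
    return float(sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= cutoff))


class TestFisherBinary:
    def test_diagonal_2x2(self):
        calls = BinaryAlterationMatrix(
            pd.DataFrame(
                [[1, 1, 0, 0]], index=["peak1"], columns=["m0", "m1", "c0", "c1"]
            )
        )
        groups = assigns_for(["m0", "m1"], ["c0", "c1"])
        dt = fisher_binary_de(calls, groups)
        assert dt.table.loc[0, "p_raw"] == pytest.approx(1 / 3, rel=1e-12)
        assert dt.test_name == "fisher_exact"

    def test_never_altered_feature_p1(self):
        calls = BinaryAlterationMatrix(
            pd.DataFrame([[0, 0, 0, 0]], index=["f"], columns=["m0", "m1", "c0", "c1"])
        )
        dt = fisher_binary_de(calls, assigns_for(["m0", "m1"], ["c0", "c1"]))
        assert dt.table.loc[0, "p_raw"] == 1.0
        assert dt.table.loc[0, "direction"] == TIED

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_rational_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 9, size=2)
        rows = rng.integers(0, 2, size=(12, n_a + n_b))
        cols = [f"m{i}" for i in range(n_a)] + [f"c{i}" for i in range(n_b)]
        calls = BinaryAlterationMatrix(
            pd.DataFrame(rows, index=[f"f{i}" for i in range(12)], columns=cols)
        )
        dt = fisher_binary_de(calls, assigns_for(cols[:n_a], cols[n_a:]))
        for i in range(12):
            a = int(rows[i, :n_a].sum())
            c = int(rows[i, n_a:].sum())
            expected = fisher_two_sided_oracle(a, n_a - a, c, n_b - c)
            assert dt.table.loc[i, "p_raw"] == pytest.approx(expected, abs=1e-10)


# ---------------------------------------------------------------------------
# DM gene calls
# ---------------------------------------------------------------------------


def _meth_fixture():
    # cg1, cg2 -> geneH (both higher in met); cg3, cg4 -> geneB (opposite);
    # cg5, cg6 -> geneL (both lower in met)
    betas = pd.DataFrame(
        {
            "m0": [0.8, 0.7, 0.9, 0.1, 0.2, 0.3],
            "m1": [0.9, 0.8, 0.8, 0.2, 0.1, 0.2],
            "c0": [0.3, 0.2, 0.2, 0.8, 0.6, 0.7],
            "c1": [0.2, 0.3, 0.3, 0.9, 0.7, 0.8],
        },
        index=[f"cg{i}" for i in range(1, 7)],
    )
    pmap = pd.DataFrame(
        {
            "locus_id": [f"cg{i}" for i in range(1, 7)],
            "gene_id": ["geneH", "geneH", "geneB", "geneB", "geneL", "geneL"],
        }
    )
    return MethylationMatrix(betas, pmap)


class TestCallDmGenes:
    def test_calls_and_bidirectional_exclusion(self):
        meth = _meth_fixture()
        groups = assigns_for(["m0", "m1"], ["c0", "c1"])
        dm_loci = pd.DataFrame({"feature_id": [f"cg{i}" for i in range(1, 7)]})
        genes = call_dm_genes(dm_loci, meth, groups).set_index("gene_id")
        assert genes.loc["geneH", "call"] == "hypermethylated"
        assert genes.loc["geneH", "n_dm_loci"] == 2
        assert genes.loc["geneB", "call"] == "excluded_bidirectional"
        assert genes.loc["geneL", "call"] == "hypomethylated"
        assert genes.loc["geneL", "n_dm_loci"] == 2
        assert 0 <= genes["mean_beta_met"].min() <= genes["mean_beta_met"].max() <= 1

    def test_single_hyper_locus(self):
        meth = _meth_fixture()
        groups = assigns_for(["m0", "m1"], ["c0", "c1"])
        genes = call_dm_genes(pd.DataFrame({"feature_id": ["cg1"]}), meth, groups)
        assert list(genes["call"]) == ["hypermethylated"]

    def test_locus_missing_from_map_is_error(self):
        meth = _meth_fixture()
        groups = assigns_for(["m0", "m1"], ["c0", "c1"])
        with pytest.raises(ValueError, match="cg99"):
            call_dm_genes(pd.DataFrame({"feature_id": ["cg99"]}), meth, groups)

    def test_empty_input_gives_empty_table(self):
        meth = _meth_fixture()
        groups = assigns_for(["m0", "m1"], ["c0", "c1"])
        genes = call_dm_genes(pd.DataFrame({"feature_id": []}), meth, groups)
        assert genes.empty


class TestExternalTableAdapter:
    def test_from_frame_recomputes_q_and_feeds_concordance(self):
        from metaconcord import signed_list_from_differential
        from metaconcord.differential import DifferentialTable

        ext = pd.DataFrame(
            {
                "feature_id": ["g1", "g2", "g3", "g4"],
                "p_raw": [0.01, 0.02, 0.03, 0.04],
                "direction": [UP, DOWN, UP, TIED],
            }
        )
        dt = DifferentialTable.from_frame(ext, "edger_import")
        np.testing.assert_allclose(dt.table["q_bh"], [0.04] * 4)
        lst = signed_list_from_differential(dt, 0.05, "ext")
        assert set(lst.signs) == {"g1", "g2", "g3"}

    def test_from_frame_requires_core_columns(self):
        from metaconcord.differential import DifferentialTable

        with pytest.raises(ValueError, match="direction"):
            DifferentialTable.from_frame(
                pd.DataFrame({"feature_id": ["g1"], "p_raw": [0.5]})
            )
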