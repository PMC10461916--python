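"""Epistasis statistics, SGoF, clustering, structure and conservation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from folatedms import (
    active_site_distance,
    active_site_distances,
    alignment_conservation,
    cluster_distance_cdf,
    cluster_positions,
    column_conservation,
    compute_epistasis,
    conservation_enrichment,
    sgof_threshold,
    welch_test,
)


def records(rows):
    return pd.DataFrame(
        [
            {
                "mutant": m,
                "position": pos,
                "aa": "A",
                "rel_growth": np.mean([r for r in reps if r is not None])
                if not any(r is None for r in reps)
                else np.nan,
                "sem": 0.01,
                "null_flag": any(r is None for r in reps),
                "replicate_rates": list(reps),
                "background": None,
            }
            for m, pos, reps in rows
        ]
    )


class TestEpistasis:
    def test_additive_difference(self):
        bg = records([("m", 1, (0.9, 0.9, 0.9))])
        wt = records([("m", 1, (0.3, 0.3, 0.3))])
        eps = compute_epistasis(bg, wt)
        assert eps["eps"].iloc[0] == pytest.approx(0.6)

    def test_equal_rates_zero(self):
        bg = records([("m", 1, (0.8, 0.85, 0.9))])
        eps = compute_epistasis(bg, bg.copy())
        assert eps["eps"].iloc[0] == pytest.approx(0.0)

    def test_null_in_either_background_excluded(self):
        bg = records([("m", 1, (0.9, None, 0.9)), ("k", 2, (1.0, 1.0, 1.0))])
        wt = records([("m", 1, (0.3, 0.3, 0.3)), ("k", 2, (1.0, 1.0, 1.0))])
        eps = compute_epistasis(bg, wt)
        assert list(eps["mutant"]) == ["k"]

    def test_wt_reference_rates_give_zero(self):
        wt = records([("WT", None, (1.0, 1.0, 1.0))])
        eps = compute_epistasis(wt, wt.copy())
        assert eps["eps"].iloc[0] == 0.0


class TestWelch:
    def welch_oracle(self, a, b):
        """Closed-form Welch t and Satterthwaite df, independent route."""
        a, b = np.asarray(a, float), np.asarray(b, float)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        return t, p

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(1.0, 0.1, rng.integers(3, 8))
        b = rng.normal(0.8, 0.2, rng.integers(3, 8))
        t, p = welch_test(a, b)
        t0, p0 = self.welch_oracle(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert p == pytest.approx(p0, abs=1e-10)

    def test_identical_samples_p_one(self):
        assert welch_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == (0.0, 1.0)

    def test_separated_samples_p_near_zero(self):
        rng = np.random.default_rng(0)
        a = 1.0 + rng.normal(0, 1e-6, 3)
        b = 0.0 + rng.normal(0, 1e-6, 3)
        _, p = welch_test(a, b)
        assert p < 1e-6

    def test_zero_variance_unequal_means(self):
        t, p = welch_test([1.0, 1.0], [0.0, 0.0])
        assert p == 0.0 and t == np.inf

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [0.9, 1.0])


def sgof_oracle(p_values, alpha=0.05):
    """Independent enumeration of the sequential binomial-excess rule."""
    p = sorted(p_values)
    n = len(p)
    r = sum(1 for x in p if x <= alpha)
    declared = 0
    while r - declared > 0:
        n_rem = n - declared
        r_rem = r - declared
        # P(Bin(n_rem, alpha) >= r_rem) by direct pmf summation
        tail = sum(
            math.comb(n_rem, k) * alpha**k * (1 - alpha) ** (n_rem - k)
            for k in range(r_rem, n_rem + 1)
        )
        if tail <= alpha:
            declared += 1
        else:
            break
    return declared


class TestSGoF:
    def test_all_large_p_no_discoveries(self):
        res = sgof_threshold([0.9] * 100)
        assert res.n_significant == 0
        assert math.isnan(res.threshold)

    def test_all_tiny_p_all_discovered(self):
        res = sgof_threshold([1e-6] * 100)
        assert res.n_significant == 100
        assert res.threshold == 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        # a mixture of genuine signals and uniform nulls
        p = np.concatenate(
            [rng.uniform(0, 0.01, n // 4), rng.uniform(0, 1, n - n // 4)]
        )
        res = sgof_threshold(p)
        assert res.n_significant == sgof_oracle(p)

    def test_discovery_set_is_prefix_of_ranking(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 0.2, 80)
        res = sgof_threshold(p)
        if res.n_significant:
            declared = np.sort(p[res.significant])
            rest = p[~res.significant]
            assert declared.max() <= rest.min() + 1e-15
            assert res.threshold == pytest.approx(declared.max())

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            sgof_threshold([])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sgof_threshold([0.5, 1.2])


def eps_table_from_blobs(seed=0):
    """Four archetypal position profiles with well-separated epistasis."""
    rng = np.random.default_rng(seed)
    rows = []
    archetypes = {
        "negative": (-0.4, 0.9),
        "insignificant": (0.0, 0.05),
        "positive": (0.35, 0.9),
        "strong positive": (0.85, 1.0),
    }
    pos = 1
    for label, (mean_eps, frac_sig) in archetypes.items():
        for _ in range(6):
            for k in range(8):
                sig = rng.random() < frac_sig
                eps = mean_eps + rng.normal(0, 0.02)
                rows.append(
                    {
                        "position": pos,
                        "background": "BG" if label != "strong positive" else "R166Q",
                        "aa": "ACDEFGHK"[k],
                        "eps": eps,
                        "pvalue": 10 ** rng.uniform(-8, -4) if sig else rng.uniform(0.2, 1),
                        "significant": sig,
                        "true_label": label,
                    }
                )
            pos += 1
    return pd.DataFrame(rows)


class TestClustering:
    def test_separated_blobs_recovered(self):
        table = eps_table_from_blobs()
        clusters = cluster_positions(table, k=4, seed=0)
        truth = table.drop_duplicates("position").set_index("position")["true_label"]
        merged = clusters.set_index("position").join(truth)
        agreement = (merged["cluster"] == merged["true_label"]).mean()
        assert agreement == 1.0

    def test_strong_positive_only_from_rescuing_background(self):
        table = eps_table_from_blobs()
        clusters = cluster_positions(table, k=4, seed=0)
        strong = clusters[clusters["cluster"] == "strong positive"]
        assert set(strong["background"]) == {"R166Q"}

    def test_order_invariance(self):
        table = eps_table_from_blobs()
        shuffled = table.sample(frac=1.0, random_state=3)
        a = cluster_positions(table, k=4, seed=1).set_index(["position", "background"])
        b = cluster_positions(shuffled, k=4, seed=1).set_index(
            ["position", "background"]
        )
        assert (a["cluster"] == b.loc[a.index, "cluster"]).all()

    def test_degenerate_profiles_rejected(self):
        table = eps_table_from_blobs()
        table["eps"] = 0.1
        table["pvalue"] = 0.5
        table["significant"] = False
        with pytest.raises(ValueError):
            cluster_positions(table, k=4)

    def test_k_larger_than_points_rejected(self):
        table = eps_table_from_blobs()
        small = table[table["position"] <= 2]
        with pytest.raises(ValueError):
            cluster_positions(small, k=4)


class TestStructure:
    def test_three_four_five_distance(self, toy_pdb):
        assert active_site_distance(toy_pdb, 1) == pytest.approx(5.0, abs=1e-6)

    def test_minimum_over_heavy_atoms(self, toy_pdb):
        # residue 1 has atoms at distance 5 and 10; the minimum wins
        d = active_site_distances(toy_pdb, [1, 2])
        assert d[1] == pytest.approx(5.0, abs=1e-6)
        assert d[2] == pytest.approx(9.0, abs=1e-6)

    def test_missing_residue_raises(self, toy_pdb):
        with pytest.raises(ValueError):
            active_site_distance(toy_pdb, 99)

    def test_missing_ligand_atom_named_in_error(self, toy_pdb):
        with pytest.raises(ValueError, match="C9"):
            active_site_distance(toy_pdb, 1, ligand_atom="C9")

    def test_cdf_single_position_step(self):
        clusters = pd.DataFrame(
            [{"position": 1, "cluster": "negative"}]
        )
        cdf = cluster_distance_cdf(clusters, {1: 4.2})
        d, f = cdf["negative"]
        assert list(d) == [4.2] and list(f) == [1.0]

    def test_cdf_matches_sort_and_count(self):
        rng = np.random.default_rng(0)
        clusters = pd.DataFrame(
            {
                "position": range(20),
                "cluster": rng.choice(["a", "b"], 20),
            }
        )
        dist = {p: float(rng.uniform(0, 30)) for p in range(20)}
        cdf = cluster_distance_cdf(clusters, dist)
        for label, grp in clusters.groupby("cluster"):
            d_sorted = np.sort([dist[p] for p in grp["position"]])
            np.testing.assert_allclose(cdf[label][0], d_sorted)
            np.testing.assert_allclose(
                cdf[label][1], np.arange(1, len(d_sorted) + 1) / len(d_sorted)
            )

    def test_missing_distance_raises(self):
        clusters = pd.DataFrame([{"position": 1, "cluster": "a"}])
        with pytest.raises(ValueError):
            cluster_distance_cdf(clusters, {})


class TestConservation:
    def test_background_equal_column_zero(self):
        bg = {a: 1 / 20 for a in "ACDEFGHIKLMNPQRSTVWY"}
        col = list("ACDEFGHIKLMNPQRSTVWY")
        assert column_conservation(col, bg) == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_uniform_background(self):
        assert column_conservation("AAAAAA") == pytest.approx(np.log(20), abs=1e-9)

    def test_mixed_column_matches_manual_sum(self):
        col = "AAAGGC"
        bg = {a: 1 / 20 for a in "ACDEFGHIKLMNPQRSTVWY"}
        p = {"A": 3 / 6, "G": 2 / 6, "C": 1 / 6}
        manual = sum(v * np.log(v / (1 / 20)) for v in p.values())
        assert column_conservation(col, bg) == pytest.approx(manual, abs=1e-12)

    def test_gaps_excluded(self):
        assert column_conservation("AA--AA") == pytest.approx(
            column_conservation("AAAA")
        )

    def test_all_gap_column_is_nan(self):
        assert math.isnan(column_conservation("----"))

    def test_alignment_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            alignment_conservation(["AAA", "AA"])

    def test_per_column_vectorization(self):
        cols = alignment_conservation(["AC", "AC", "AD"])
        assert cols[0] == pytest.approx(np.log(20))
        assert cols[1] == pytest.approx(column_conservation("CCD"))


def fisher_oracle(n11, n10, n01, n00):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    row1, col1 = n11 + n10, n11 + n01
    n = n11 + n10 + n01 + n00

    def pmf(k):
        return (
            math.comb(col1, k)
            * math.comb(n - col1, row1 - k)
            / math.comb(n, row1)
        )

    p_obs = pmf(n11)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def test_hand_built_table_matches_enumeration(self):
        total = 100
        set_a = set(range(12))  # 10 overlap + 2
        set_b = set(range(10)) | set(range(50, 53))  # 10 overlap + 3
        odds, p = conservation_enrichment(set_a, set_b, total)
        assert odds == pytest.approx((10 * 85) / (2 * 3))
        assert p == pytest.approx(fisher_oracle(10, 2, 3, 85), rel=1e-9)

    def test_independent_random_sets_odds_near_one(self):
        rng = np.random.default_rng(0)
        odds = []
        for _ in range(30):
            a = set(rng.choice(400, 100, replace=False))
            b = set(rng.choice(400, 100, replace=False))
            o, _ = conservation_enrichment(a, b, 400)
            odds.append(o)
        assert np.median(odds) == pytest.approx(1.0, abs=0.35)

    def test_degenerate_margin_p_one(self):
        _, p = conservation_enrichment(set(), {1, 2}, 10)
        assert p == 1.0

    def test_oversized_sets_rejected(self):
        with pytest.raises(ValueError):
            conservation_enrichment({1, 2, 3}, {4, 5, 6}, 4)
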