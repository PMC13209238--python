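"""Rank normalization, RR scoring, concordance, paired tests, hit filtering."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from kinsel.selectivity import (
    BEST_RANK,
    concordance,
    drug_likeness_flags,
    normalize_ranks,
    paired_component_test,
    prioritize_hits,
    relative_rank,
    selectivity_table,
)


def score_table(scores_by_conformer):
    rows = []
    for conf, scores in scores_by_conformer.items():
        for lig, s in scores.items():
            rows.append(
                {"ligand_id": lig, "conformer_id": conf, "kinase_id": "kA", "total": s}
            )
    return pd.DataFrame(rows)


class TestNormalizeRanks:
    def test_distinct_scores_quarter_steps(self):
        table = score_table({"c1": {"a": -4.0, "b": -3.0, "c": -2.0, "d": -1.0}})
        r = normalize_ranks(table)
        assert list(r.loc[["a", "b", "c", "d"]]) == [0.25, 0.5, 0.75, 1.0]

    def test_tied_best_gets_midrank(self):
        table = score_table({"c1": {"a": -4.0, "b": -4.0, "c": -2.0, "d": -1.0}})
        r = normalize_ranks(table)
        assert r["a"] == pytest.approx(0.375)  # (1+2)/2 / 4
        assert r["b"] == pytest.approx(0.375)

    def test_single_ligand_rank_one(self):
        r = normalize_ranks(score_table({"c1": {"only": -2.0}}))
        assert r["only"] == 1.0

    def test_best_rank_consensus(self):
        table = score_table(
            {"c1": {"a": -4.0, "b": -1.0}, "c2": {"a": -1.0, "b": -4.0}}
        )
        mean = normalize_ranks(table)
        best = normalize_ranks(table, consensus=BEST_RANK)
        assert mean["a"] == mean["b"]  # symmetric under mean consensus
        assert best["a"] == best["b"]

    def test_empty_conformer_selection_rejected(self):
        table = score_table({"c1": {"a": -1.0}})
        with pytest.raises(ValueError):
            normalize_ranks(table, conformers=[])
        with pytest.raises(ValueError):
            normalize_ranks(table, conformers=["missing"])


class TestRelativeRank:
    def test_equal_ranks_zero(self):
        assert relative_rank(0.4, 0.4) == 0.0

    def test_strong_kinase_a_preference_negative(self):
        assert relative_rank(0.1, 0.9) == pytest.approx(-0.8)

    def test_swapping_roles_negates(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 1.0, size=2)
            assert relative_rank(a, b) == pytest.approx(-relative_rank(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            relative_rank(0.0, 0.5)
        with pytest.raises(ValueError):
            relative_rank(0.5, 1.5)

    def test_rr_linearity_over_sets(self, rng):
        n = 30
        ids = [f"l{i}" for i in range(n)]
        ra = pd.Series(rng.permutation(n) / n + 1 / n, index=ids).clip(upper=1.0)
        rb = pd.Series(rng.permutation(n) / n + 1 / n, index=ids).clip(upper=1.0)
        df = selectivity_table(ra, rb)
        assert df["rr"].sum() == pytest.approx(df["R_A"].sum() - df["R_B"].sum())


def kendall_pair_oracle(a, b):
    """All-pairs concordant/discordant count with tie correction (τ-b)."""
    conc = disc = ties_a = ties_b = 0
    for (x1, y1), (x2, y2) in itertools.combinations(zip(a, b), 2):
        dx, dy = x1 - x2, y1 - y2
        if dx == 0 and dy == 0:
            ties_a += 1
            ties_b += 1
        elif dx == 0:
            ties_a += 1
        elif dy == 0:
            ties_b += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n_pairs = len(a) * (len(a) - 1) // 2
    denom = np.sqrt((n_pairs - ties_a) * (n_pairs - ties_b))
    return (conc - disc) / denom


class TestConcordance:
    def _series(self, values, ids=None):
        ids = ids or [f"l{i}" for i in range(len(values))]
        return pd.Series(values, index=ids)

    def test_identical_rankings(self):
        r = self._series([0.2, 0.4, 0.6, 0.8, 1.0])
        rep = concordance(r, r.copy())
        assert rep.spearman_rho == pytest.approx(1.0)
        assert rep.kendall_tau == pytest.approx(1.0)
        assert rep.delta_mean == 0.0 and rep.delta_sd == 0.0

    def test_reversed_rankings(self):
        r = self._series([0.2, 0.4, 0.6, 0.8, 1.0])
        rev = self._series([1.0, 0.8, 0.6, 0.4, 0.2])
        rep = concordance(r, rev)
        assert rep.spearman_rho == pytest.approx(-1.0)
        assert rep.kendall_tau == pytest.approx(-1.0)

    def test_tau_matches_all_pairs_oracle(self):
        a = [0.1, 0.3, 0.5, 0.6, 0.8, 1.0]
        b = [0.3, 0.1, 0.6, 0.5, 1.0, 0.8]
        rep = concordance(self._series(a), self._series(b))
        assert rep.kendall_tau == pytest.approx(kendall_pair_oracle(a, b), abs=1e-12)

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match="3 shared"):
            concordance(self._series([0.5, 1.0], ["a", "b"]),
                        self._series([0.5, 1.0], ["b", "c"]))

    def test_recovers_copula_rank_correlation(self, rng):
        """Bivariate-normal scores: Spearman ρ ≈ (6/π)·asin(r/2)."""
        r_pearson = 0.8
        n = 500
        cov = np.array([[1, r_pearson], [r_pearson, 1]])
        reps = []
        for _ in range(20):
            x = rng.multivariate_normal([0, 0], cov, size=n)
            ra = self._series((np.argsort(np.argsort(x[:, 0])) + 1) / n)
            rb = self._series((np.argsort(np.argsort(x[:, 1])) + 1) / n)
            reps.append(concordance(ra, rb).spearman_rho)
        expected = 6 / np.pi * np.arcsin(r_pearson / 2)
        se = np.std(reps, ddof=1) / np.sqrt(len(reps))
        assert abs(np.mean(reps) - expected) < 3 * se


def wilcoxon_sign_enumeration(diffs, observed_w_plus, alternative="greater"):
    """Exact null: enumerate all sign assignments of the |difference| ranks."""
    from scipy.stats import rankdata

    ranks = rankdata(np.abs(diffs))
    n = len(diffs)
    ge = total = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        total += 1
        if alternative == "greater" and w >= observed_w_plus - 1e-9:
            ge += 1
    return Fraction(ge, total)


class TestPairedComponentTest:
    def test_bonferroni_adjusted_alpha(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = paired_component_test(a, a - 1.0, m_comparisons=2)
        assert res.adjusted_alpha == 0.025

    def test_exact_one_sided_p_all_positive_n5(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.5, 0.6, 0.7, 0.8, 0.9])
        res = paired_component_test(a, b, alternative="greater")
        assert res.p_value == pytest.approx(1 / 32, rel=1e-12)
        oracle = wilcoxon_sign_enumeration(a - b, res.statistic)
        assert res.p_value == pytest.approx(float(oracle), rel=1e-12)
        two_sided = paired_component_test(a, b)
        assert two_sided.p_value == pytest.approx(1 / 16, rel=1e-12)

    def test_exact_p_matches_enumeration_on_mixed_signs(self):
        diffs = np.array([0.9, -0.4, 1.3, 0.7, -0.2, 1.1, 0.5])
        res = paired_component_test(diffs, np.zeros_like(diffs), alternative="greater")
        oracle = wilcoxon_sign_enumeration(diffs, res.statistic)
        assert res.p_value == pytest.approx(float(oracle), rel=1e-12)

    def test_symmetric_differences_not_significant(self):
        x = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        a = np.concatenate([x, -x])
        res = paired_component_test(a, np.zeros_like(a))
        assert res.p_value > 0.9

    def test_all_zero_differences_rejected(self):
        a = np.ones(6)
        with pytest.raises(ValueError, match="degenerate"):
            paired_component_test(a, a)

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(0.3, 1.0, size=60)
        res = paired_component_test(a, np.zeros_like(a))
        assert res.method == "approx"
        assert 0 <= res.p_value <= 1


class TestPrioritizeHits:
    def _ranks(self, n, rng=None, seed=0):
        rng = rng or np.random.default_rng(seed)
        ids = [f"l{i:04d}" for i in range(n)]
        ra = pd.Series((rng.permutation(n) + 1) / n, index=ids)
        rb = pd.Series((rng.permutation(n) + 1) / n, index=ids)
        return ra, rb

    def test_top_fraction_retention_count(self):
        ra, rb = self._ranks(100)
        hits = prioritize_hits(ra, rb, top_fraction=0.05, rr_cutoff=1.0,
                               separation_margin=0.0)
        assert hits.attrs["provenance"]["n_top"] == 5
        assert len(hits) == 5

    def test_positive_rr_excluded(self):
        ids = [f"l{i:02d}" for i in range(20)]
        ra = pd.Series(np.arange(1, 21) / 20, index=ids)
        rb = ra.copy()
        rb["l00"] = 0.50  # top-ranked in A, much worse in B: rr = -0.45, kept
        rb["l01"] = 0.05  # top-ranked in A, better in B: rr = +0.05, dropped
        hits = prioritize_hits(ra, rb, top_fraction=0.10, separation_margin=0.0)
        assert "l00" in set(hits["ligand_id"])
        assert "l01" not in set(hits["ligand_id"])

    def test_separation_margin_drops_marginal_rr(self):
        ids = ["a", "b", "c", "d"]
        ra = pd.Series([0.25, 0.5, 0.75, 1.0], index=ids)
        rb = pd.Series([0.27, 1.0, 0.75, 0.5], index=ids)
        hits = prioritize_hits(ra, rb, top_fraction=0.5, rr_cutoff=0.0,
                               separation_margin=0.05)
        # "a" has rr = -0.02, below the margin -> dropped; "b" has rr = -0.5
        assert list(hits["ligand_id"]) == ["b"]

    def test_library_mismatch_rejected(self):
        ra = pd.Series([0.5, 1.0], index=["a", "b"])
        rb = pd.Series([0.5, 1.0], index=["a", "c"])
        with pytest.raises(ValueError, match="different libraries"):
            prioritize_hits(ra, rb)

    def test_invariant_to_input_order(self, rng):
        ra, rb = self._ranks(200, rng)
        h1 = prioritize_hits(ra, rb)
        perm = rng.permutation(200)
        h2 = prioritize_hits(ra.iloc[perm], rb.iloc[rng.permutation(200)])
        pd.testing.assert_frame_equal(h1, h2)

    def test_planted_bias_enriches_tagged_subset(self):
        """Tagged ligands with a −1σ kinase-A shift dominate the hit list."""
        from scipy.stats import fisher_exact

        from kinsel.screening import best_poses
        from kinsel.selectivity import normalize_ranks
        from kinsel.synthetic import ScreenSpec, gen_screen_table

        spec = ScreenSpec(n_actives=500, n_inactives=500, delta=1.0, sigma=1.0,
                          beta=1.0, biased_fraction=0.2, n_conformers=2, seed=5)
        scores, truth = gen_screen_table(spec)
        scores = best_poses(scores)
        ranks = {
            k: normalize_ranks(scores[scores["kinase_id"] == k])
            for k in ("kinaseA", "kinaseB")
        }
        hits = prioritize_hits(ranks["kinaseA"], ranks["kinaseB"])
        tagged = set(truth.loc[truth["biased"], "ligand_id"])
        hit_ids = set(hits["ligand_id"])
        all_ids = set(truth["ligand_id"])
        table = [
            [len(tagged & hit_ids), len(tagged - hit_ids)],
            [len(hit_ids - tagged), len(all_ids - tagged - hit_ids)],
        ]
        _, p = fisher_exact(table, alternative="greater")
        assert p < 0.01


class TestDrugLikeness:
    def _flags(self, **kwargs):
        row = {
            "ligand_id": "x", "MW": 350.0, "logP": 2.0, "HBD": 2, "HBA": 5,
            "RotB": 5, "TPSA": 80.0, "MR": 90.0, "heavy_atoms": 25,
        }
        row.update(kwargs)
        df = pd.DataFrame([row]).set_index("ligand_id")
        return drug_likeness_flags(df).iloc[0]

    def test_all_within_bounds(self):
        f = self._flags()
        assert f["lipinski_violations"] == 0
        assert f["lipinski_pass"] and f["veber_pass"] and f["ghose_pass"]

    def test_two_lipinski_violations_fail(self):
        f = self._flags(MW=510.0, logP=5.5)
        assert f["lipinski_violations"] == 2
        assert not f["lipinski_pass"]

    def test_single_violation_still_passes_lipinski(self):
        f = self._flags(MW=510.0)
        assert f["lipinski_violations"] == 1
        assert f["lipinski_pass"]

    def test_veber_rotatable_bond_limit(self):
        assert not self._flags(RotB=11)["veber_pass"]

    def test_ghose_bounds(self):
        assert not self._flags(MW=150.0)["ghose_pass"]
        assert not self._flags(logP=-0.5)["ghose_pass"]

    def test_missing_descriptor_indeterminate(self):
        f = self._flags(TPSA=np.nan)
        assert pd.isna(f["veber_pass"])
        assert f["lipinski_pass"]  # unaffected rule still evaluated
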