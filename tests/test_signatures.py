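import numpy as np
import pandas as pd
import pytest

from coderep.diffexpr import ExpressionMatrix
from coderep.errors import ValidationError
from coderep.io import GeneSet
from coderep.signatures import (
    correlate_signatures,
    gsea_es,
    gsea_permutation,
    ssgsea_matrix,
    ssgsea_score,
    zscore_signature,
)
from coderep.synthdata import SyntheticConfig, generate_cohort, signature_gene_sets
from conftest import SMALL


def ssgsea_bruteforce(values: pd.Series, members, alpha: float) -> float:
    """Independent double-loop ECDF walk (no vectorization shared with
    the implementation)."""
    idx = list(values.index)
    order = sorted(range(len(idx)), key=lambda i: (-values.iloc[i], i))
    in_set = [idx[i] in members for i in order]
    total_in = sum((r + 1) ** alpha for r, flag in enumerate(in_set) if flag)
    n_out = len(idx) - sum(in_set)
    score, cin, cout = 0.0, 0.0, 0.0
    for r, flag in enumerate(in_set):
        if flag:
            cin += (r + 1) ** alpha / total_in
        else:
            cout += 1.0 / n_out
        score += cin - cout
    return score


class TestSsgsea:
    def test_hand_ecdf_walk(self):
        # N=3 ranked g1 > g2 > g3, S = {g1}, alpha = 0:
        # running diff = (1-0) + (1-0.5) + (1-1) = 1.5
        values = pd.Series({"g1": 3.0, "g2": 2.0, "g3": 1.0})
        gs = GeneSet("S", "d", ("g1",))
        assert ssgsea_score(values, gs, alpha=0.0) == pytest.approx(1.5)

    def test_rank_invariance_under_constant_shift(self):
        rng = np.random.default_rng(0)
        values = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        gs = GeneSet("S", "d", tuple(f"g{i}" for i in range(0, 30, 4)))
        assert ssgsea_score(values, gs) == pytest.approx(ssgsea_score(values + 7.3, gs))

    def test_identical_rankings_identical_scores(self):
        base = pd.Series({"g1": 5.0, "g2": 1.0, "g3": 3.0})
        gs = GeneSet("S", "d", ("g3",))
        assert ssgsea_score(base, gs) == ssgsea_score(base * 2 + 1, gs)

    def test_missing_member_and_universe_set_errors(self):
        values = pd.Series({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValidationError, match="S_missing"):
            ssgsea_score(values, GeneSet("S_missing", "d", ("zz",)))
        with pytest.raises(ValidationError):
            ssgsea_score(values, GeneSet("S_all", "d", ("g1", "g2")))

    def test_score_bounded_by_universe_size(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(3, 40))
            values = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            k = int(rng.integers(1, n))
            gs = GeneSet("S", "d", tuple(rng.choice(values.index, k, replace=False)))
            assert abs(ssgsea_score(values, gs)) <= n

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            values = pd.Series(
                rng.normal(size=n).round(3),  # rounded values force ties
                index=[f"g{i}" for i in range(n)],
            )
            k = int(rng.integers(1, n))
            members = tuple(rng.choice(values.index, k, replace=False))
            alpha = float(rng.choice([0.0, 0.75, 1.0]))
            gs = GeneSet("S", "d", members)
            assert ssgsea_score(values, gs, alpha) == pytest.approx(
                ssgsea_bruteforce(values, set(members), alpha), abs=1e-9
            )


class TestZscore:
    def test_hand_example(self):
        z = zscore_signature(pd.Series([1.0, 2.0, 3.0]))
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_output_mean_zero(self):
        rng = np.random.default_rng(3)
        z = zscore_signature(pd.Series(rng.normal(5, 2, 50)))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0)

    def test_constant_scores_error(self):
        with pytest.raises(ValidationError):
            zscore_signature(pd.Series([5.0, 5.0]))


class TestGseaEs:
    def test_hand_running_sum(self):
        # S = top-1 of 3, metrics (2,1,1), weight 1: running {+1, +0.5, 0}
        metric = pd.Series({"a": 2.0, "b": 1.0, "c": 1.0})
        assert gsea_es(metric, GeneSet("S", "d", ("a",))) == pytest.approx(1.0)

    def test_top_heavy_set_positive(self):
        metric = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
        es = gsea_es(metric, GeneSet("S", "d", ("a", "b", "c")))
        assert es > 0

    def test_reversed_ranking_flips_sign(self):
        metric = pd.Series({f"g{i}": float(10 - i) for i in range(10)})
        gs = GeneSet("S", "d", ("g0", "g1", "g2"))
        assert gsea_es(metric, gs) > 0 > gsea_es(-metric, gs)

    def test_bounded_by_one_at_weight_zero(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            metric = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            gs = GeneSet("S", "d", tuple(rng.choice(metric.index, 3, replace=False)))
            assert abs(gsea_es(metric, gs, weight=0.0)) <= 1.0

    def test_all_zero_in_set_metrics_error(self):
        metric = pd.Series({"a": 0.0, "b": 0.0, "c": 1.0})
        with pytest.raises(ValidationError):
            gsea_es(metric, GeneSet("S", "d", ("a", "b")))


def _two_class_matrix(rng, n_genes=200, shift_genes=(), shift=0.0, reps=3):
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"A{i}" for i in range(reps)] + [f"B{i}" for i in range(reps)]
    x = rng.normal(0, 1, (n_genes, 2 * reps))
    for g in shift_genes:
        x[genes.index(g), :reps] += shift
    values = pd.DataFrame(x, index=genes, columns=samples)
    cond = pd.Series(["class1"] * reps + ["class2"] * reps, index=samples)
    return ExpressionMatrix(values, cond)


class TestGseaPermutation:
    def test_planted_signal_hits_minimum_p(self):
        rng = np.random.default_rng(5)
        members = tuple(f"g{i}" for i in range(20))
        expr = _two_class_matrix(rng, shift_genes=members, shift=2.0)
        res = gsea_permutation(
            expr, ("class1", "class2"), GeneSet("S", "d", members), n_perm=999, seed=0
        )
        assert res.es > 0
        assert res.p_perm == pytest.approx(1.0 / (1 + res.n_null_same_sign))
        assert res.nes is not None and res.nes > 1

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(6)
        gs = GeneSet("S", "d", tuple(f"g{i}" for i in range(10)))
        expr = _two_class_matrix(rng)
        r1 = gsea_permutation(expr, ("class1", "class2"), gs, n_perm=99, seed=42)
        r2 = gsea_permutation(expr, ("class1", "class2"), gs, n_perm=99, seed=42)
        assert r1.p_perm == r2.p_perm and r1.nes == r2.nes

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(7)
        expr = _two_class_matrix(rng)
        gs = GeneSet("S", "d", ("g0",))
        with pytest.raises(ValidationError):
            gsea_permutation(expr, ("class1", "class2"), gs, n_perm=5, seed=0)


class TestCorrelation:
    def test_perfect_linear_relations(self):
        z = pd.Series([-1.2, 0.3, 0.9, -0.4, 0.4])
        r_pos, _ = correlate_signatures(z, 2 * z)
        r_neg, _ = correlate_signatures(z, -z)
        assert r_pos == pytest.approx(1.0)
        assert r_neg == pytest.approx(-1.0)

    def test_length_mismatch_and_zero_variance_errors(self):
        with pytest.raises(ValidationError):
            correlate_signatures([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError):
            correlate_signatures([1, 1, 1], [1, 2, 3])

    @staticmethod
    def _cohort_config(seed):
        return SyntheticConfig(
            **{
                **SMALL,
                "seed": seed,
                "cohort_n_normal": 0,
                "cohort_n_primary": 75,
                "cohort_n_metastatic": 75,
            }
        )

    def test_planted_signature_coupling_recovered(self):
        """Linear per-sample signature scores (mean over set members)
        recover the planted latent coupling rho = 0.7."""
        rs = []
        for seed in range(30):
            cfg = self._cohort_config(seed)
            cohort, _ = generate_cohort(cfg)
            ezh2_set, atf3_set = signature_gene_sets(cfg)
            df = cohort.df.set_index("sample")
            za = zscore_signature(df[list(ezh2_set.members)].mean(axis=1))
            zb = zscore_signature(df[list(atf3_set.members)].mean(axis=1))
            r, _ = correlate_signatures(za, zb)
            rs.append(r)
        assert np.mean(rs) == pytest.approx(0.7, abs=0.05)

    def test_ssgsea_scores_track_planted_coupling_sign(self):
        """Rank-based ssGSEA attenuates the latent coupling but must
        preserve a strong positive association."""
        rs = []
        for seed in range(5):
            cfg = self._cohort_config(seed)
            cohort, _ = generate_cohort(cfg)
            ezh2_set, atf3_set = signature_gene_sets(cfg)
            expr = cohort.df.set_index("sample")[cohort.genes].T
            za = zscore_signature(ssgsea_matrix(expr, ezh2_set))
            zb = zscore_signature(ssgsea_matrix(expr, atf3_set))
            r, _ = correlate_signatures(za, zb)
            rs.append(r)
        assert np.mean(rs) > 0.35
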