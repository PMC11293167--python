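"""KS depletion scoring and weighted GSEA, checked against brute force."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secrescreen import essentiality as ess
from secrescreen import simulate
from secrescreen.errors import DataError
from conftest import scores_from_counts


def brute_force_one_sided_D(gene, background) -> float:
    """sup_x [F_g(x) - F_b(x)] by evaluating both ECDFs at every pooled point."""
    gene, background = list(gene), list(background)
    best = 0.0
    for x in gene + background:
        fg = sum(v <= x for v in gene) / len(gene)
        fb = sum(v <= x for v in background) / len(background)
        best = max(best, fg - fb)
    return best


class TestKsDepletionTest:
    def test_identical_samples_score_zero(self):
        vals = [0.3, -1.2, 0.8, 2.0]
        d, p = ess.ks_depletion_test(vals, vals)
        assert d == 0.0
        assert p == 1.0

    def test_hand_enumerated_example(self):
        # gene fully left of background: D = 1, m = 6/5, p = exp(-2.4)
        d, p = ess.ks_depletion_test([-3, -2], [0, 1, 2])
        assert d == 1.0
        assert p == pytest.approx(math.exp(-2.4), rel=1e-12)
        assert 1 - p == pytest.approx(0.909, abs=1e-3)

    def test_exhaustive_small_instances_match_brute_force(self):
        # every split of n <= 8 distinct ranks into gene (>=2) / background (>=2)
        for n in range(4, 9):
            values = list(range(n))
            for n_gene in range(2, n - 1):
                for gene_idx in itertools.combinations(range(n), n_gene):
                    gene = [values[i] for i in gene_idx]
                    bg = [values[i] for i in range(n) if i not in gene_idx]
                    d, _ = ess.ks_depletion_test(gene, bg)
                    assert d == pytest.approx(
                        brute_force_one_sided_D(gene, bg), abs=1e-12
                    )

    def test_random_instances_with_ties_match_brute_force(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            ng, nb = rng.integers(2, 10, size=2)
            # coarse grid forces ties within and across samples
            gene = rng.integers(-3, 4, size=ng).astype(float)
            bg = rng.integers(-3, 4, size=nb).astype(float)
            d, _ = ess.ks_depletion_test(gene, bg)
            assert d == pytest.approx(brute_force_one_sided_D(gene, bg), abs=1e-12)

    def test_depletion_direction_one_sided(self):
        # gene fully right of background: no depletion evidence
        d, p = ess.ks_depletion_test([5.0, 6.0], [0.0, 1.0, 2.0])
        assert d == 0.0
        assert p == 1.0

    def test_permutation_p_close_to_asymptotic_on_clear_signal(self):
        gene = [-4.0, -3.5, -3.8, -4.2]
        bg = list(np.linspace(-1, 1, 40))
        _, p_perm = ess.ks_depletion_test(gene, bg, method="permutation",
                                          n_perm=500, seed=1)
        assert p_perm <= 5 / 501

    def test_small_or_nonfinite_samples_rejected(self):
        with pytest.raises(DataError):
            ess.ks_depletion_test([1.0], [0.0, 1.0])
        with pytest.raises(DataError):
            ess.ks_depletion_test([1.0, np.nan], [0.0, 1.0])


def _lfc_frame(per_gene: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    for gene, vals in per_gene.items():
        for i, v in enumerate(vals):
            rows.append({"guide_id": f"{gene}_g{i}", "gene_id": gene, "lfc": v})
    return pd.DataFrame(rows)


class TestEssentialityScores:
    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(14)
        per_gene = {
            f"G{i}": rng.normal(size=4).tolist() for i in range(10)
        }
        base = ess.essentiality_scores(_lfc_frame(per_gene))
        warped = {
            g: (np.expm1(np.asarray(v) / 3) * 7).tolist() for g, v in per_gene.items()
        }
        transformed = ess.essentiality_scores(_lfc_frame(warped))
        pd.testing.assert_series_equal(base["score"], transformed["score"])
        assert base["gene_id"].tolist() == transformed["gene_id"].tolist()

    def test_location_shift_increases_score(self):
        rng = np.random.default_rng(15)
        per_gene = {f"G{i}": rng.normal(size=5).tolist() for i in range(8)}
        before = ess.essentiality_scores(_lfc_frame(per_gene)).set_index("gene_id")
        per_gene["G0"] = [v - 5.0 for v in per_gene["G0"]]
        after = ess.essentiality_scores(_lfc_frame(per_gene)).set_index("gene_id")
        assert after.loc["G0", "score"] > before.loc["G0", "score"]

    def test_singleton_genes_reported_unscored(self):
        per_gene = {
            "G0": [-1.0, -2.0, 0.5],
            "G2": [0.1, 0.3, -0.2],
            "G1": [0.2],
        }
        res = ess.essentiality_scores(_lfc_frame(per_gene), min_guides=2)
        row = res.set_index("gene_id").loc["G1"]
        assert math.isnan(row["score"])
        assert row["n_guides"] == 1
        assert pd.isna(row["essential_call"])

    def test_all_genes_too_small_is_error(self):
        with pytest.raises(DataError):
            ess.essentiality_scores(
                _lfc_frame({"G0": [1.0], "G1": [2.0]}), min_guides=2
            )

    def test_null_screen_shows_no_essential_separation(self):
        # depletion_factor 1: essential labels carry no signal, so the score
        # distributions of labelled vs unlabelled genes are indistinguishable
        from scipy import stats as sps

        cfg = simulate.SimConfig(
            n_genes=80, guides_per_gene=4, depletion_factor=1.0,
            nb_mean=300.0, seed=16,
        )
        genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
        lib = pd.DataFrame(
            {
                "guide_id": [f"{g}_g{k}" for g in genes for k in range(4)],
                "gene_id": np.repeat(genes, 4),
            }
        )
        truth = simulate.make_ground_truth(cfg, genes)
        counts = simulate.simulate_screen_counts(lib, truth, cfg)
        res = scores_from_counts(counts).set_index("gene_id")
        ess_scores = res.loc[sorted(truth.essential_gene_ids), "score"]
        non_scores = res.loc[
            sorted(set(genes) - truth.essential_gene_ids), "score"
        ]
        assert sps.ks_2samp(ess_scores, non_scores).pvalue > 0.01

    def test_acceptance_simulation_recovers_known_essentials(
        self, acceptance_sim_scores
    ):
        truth, res = acceptance_sim_scores
        scored = res.set_index("gene_id")
        ess_ids = sorted(truth.essential_gene_ids)
        assert len(ess_ids) == 36
        assert scored.loc[ess_ids, "score"].median() > 0.5
        # known essentials dominate the top of the ranking
        top = res.head(36)["gene_id"]
        assert top.isin(ess_ids).mean() >= 0.9


class TestClassifyEssential:
    def test_strict_threshold_and_missing_scores(self):
        res = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C", "D"],
                "score": [0.5, 0.51, 0.1, np.nan],
            }
        )
        parts = ess.classify_essential(res)
        assert parts["essential"] == ["B"]
        assert parts["non_essential"] == ["A", "C"]
        assert parts["unclassified"] == ["D"]

    @given(st.lists(st.one_of(st.none(), st.floats(0, 1)), min_size=0, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_equals_brute_force(self, raw):
        res = pd.DataFrame(
            {
                "gene_id": [f"G{i}" for i in range(len(raw))],
                "score": [np.nan if v is None else v for v in raw],
            }
        )
        parts = ess.classify_essential(res, threshold=0.5)
        for i, v in enumerate(raw):
            g = f"G{i}"
            if v is None or np.isnan(v):
                assert g in parts["unclassified"]
            elif v > 0.5:
                assert g in parts["essential"]
            else:
                assert g in parts["non_essential"]


def unweighted_running_sum_es(ranked_genes, members) -> float:
    """Independent classic (unweighted) KS running-sum enrichment score."""
    n, k = len(ranked_genes), sum(g in members for g in ranked_genes)
    best, run = 0.0, 0.0
    for g in ranked_genes:
        run += 1.0 / k if g in members else -1.0 / (n - k)
        if abs(run) > abs(best):
            best = run
    return best


class TestWeightedGsea:
    def test_complete_set_attains_es_one(self):
        scores = pd.Series({f"G{i}": 1 - i / 20 for i in range(20)})
        sets = {"all": set(scores.index)}
        res = ess.weighted_gsea(scores, sets, n_perm=50, seed=2)
        assert res["es"].iloc[0] == pytest.approx(1.0)

    def test_exponent_zero_matches_unweighted_oracle(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            n = int(rng.integers(10, 40))
            genes = [f"G{i:02d}" for i in range(n)]
            scores = pd.Series(rng.random(n), index=genes)
            k = int(rng.integers(5, max(6, n // 2)))
            members = set(rng.choice(genes, size=k, replace=False))
            res = ess.weighted_gsea(
                scores, {"s": members}, weight_exponent=0.0, n_perm=10, seed=3
            )
            ranked = scores.reset_index()
            ranked.columns = ["g", "s"]
            ranked = ranked.sort_values(["s", "g"], ascending=[False, True])
            expected = unweighted_running_sum_es(ranked["g"].tolist(), members)
            assert res["es"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_planted_essential_set_ranks_top_with_low_fdr(
        self, acceptance_sim_scores
    ):
        truth, res = acceptance_sim_scores
        scores = pd.Series(
            res["score"].to_numpy(), index=res["gene_id"]
        ).dropna()
        rng = np.random.default_rng(19)
        planted = set(sorted(truth.essential_gene_ids)[:20])
        sets = {"planted_essential": planted}
        genes = np.array(sorted(scores.index))
        for i in range(8):
            sets[f"decoy_{i}"] = set(rng.choice(genes, size=20, replace=False))
        out = ess.weighted_gsea(scores, sets, n_perm=1000, seed=20)
        assert out.iloc[0]["set"] == "planted_essential"
        assert out.iloc[0]["fdr"] < 0.05

    def test_permutation_pvalues_bounded_below(self):
        scores = pd.Series({f"G{i}": 1 - i / 30 for i in range(30)})
        sets = {"s": set(list(scores.index)[:6])}
        res = ess.weighted_gsea(scores, sets, n_perm=100, seed=4)
        assert res["p_perm"].iloc[0] >= 1 / 101

    def test_no_qualifying_sets_is_error(self):
        scores = pd.Series({"G1": 0.5, "G2": 0.3})
        with pytest.raises(DataError):
            ess.weighted_gsea(scores, {"tiny": {"G1"}}, n_perm=10, seed=5)

    def test_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tG1\tG2\tG3\nsetB\t-\tG2\tG4\n")
        sets = ess.read_gmt(path)
        assert sets == {"setA": {"G1", "G2", "G3"}, "setB": {"G2", "G4"}}
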