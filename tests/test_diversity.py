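"""Shannon index, Tukey letters, PCA, UMAP and Pillai-trace MANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import studentized_range

import aerocore as ac
from aerocore.diversity import binarise_covariates, pillai_f_test


class TestShannon:
    def test_uniform_community(self):
        assert ac.shannon([10, 10, 10, 10]) == pytest.approx(np.log(4))

    def test_single_species_is_zero(self):
        assert ac.shannon([100]) == 0.0

    def test_hand_evaluated_two_species(self):
        # -(0.9 ln 0.9 + 0.1 ln 0.1)
        assert ac.shannon([9, 1]) == pytest.approx(0.325083, abs=1e-6)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ac.shannon([0, 0])

    @given(
        counts=st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(
            lambda c: sum(c) > 0
        ),
        scale=st.integers(2, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_count_rescaling(self, counts, scale):
        scaled = [c * scale for c in counts]
        assert ac.shannon(scaled) == pytest.approx(ac.shannon(counts), abs=1e-12)

    def test_bounded_by_log_richness(self, small_survey):
        table, _, _ = small_survey
        h = ac.shannon_per_sample(table)
        richness = (table.counts > 0).sum(axis=1)
        assert ((h >= 0) & (h <= np.log(richness) + 1e-12)).all()


class TestTukeyLetters:
    def test_identically_drawn_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, 30)
        groups = ["a"] * 10 + ["b"] * 10 + ["c"] * 10
        letters = ac.tukey_letters(values, groups)
        assert letters["a"] == letters["b"] == letters["c"] == "a"

    def test_extreme_separation_gives_distinct_letters(self):
        rng = np.random.default_rng(0)
        values = np.r_[rng.normal(0, 1, 10), rng.normal(100, 1, 10)]
        letters = ac.tukey_letters(values, ["lo"] * 10 + ["hi"] * 10)
        assert set(letters["lo"]) & set(letters["hi"]) == set()
        assert letters["hi"] == "a"  # highest mean lettered first

    def test_letter_sharing_equals_pairwise_hsd_oracle(self):
        # brute-force all-pairs Tukey-Kramer studentized-range test
        rng = np.random.default_rng(42)
        values = np.concatenate(
            [
                rng.normal(0.0, 1.0, 8),
                rng.normal(0.5, 1.0, 12),
                rng.normal(3.0, 1.0, 9),
                rng.normal(3.2, 1.0, 7),
            ]
        )
        groups = np.repeat(["g1", "g2", "g3", "g4"], [8, 12, 9, 7])
        letters = ac.tukey_letters(values, groups, alpha=0.05)
        labels = ["g1", "g2", "g3", "g4"]
        n = {g: (groups == g).sum() for g in labels}
        means = {g: values[groups == g].mean() for g in labels}
        df_err = len(values) - len(labels)
        msw = sum(
            ((values[groups == g] - means[g]) ** 2).sum() for g in labels
        ) / df_err
        for a, b in itertools.combinations(labels, 2):
            q = abs(means[a] - means[b]) / np.sqrt(
                msw / 2 * (1 / n[a] + 1 / n[b])
            )
            significant = studentized_range.sf(q, len(labels), df_err) < 0.05
            share = bool(set(letters[a]) & set(letters[b]))
            assert share == (not significant), (a, b)

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ac.tukey_letters([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(1)
        u = rng.normal(size=20)
        v = rng.normal(size=7)
        frame = pd.DataFrame(np.outer(u, v))
        scores, varexp = ac.pca_scores(frame, k=3)
        assert varexp[0] == pytest.approx(1.0, abs=1e-9)

    def test_scores_are_orthogonal(self, small_pipeline):
        scores, _ = ac.pca_scores(small_pipeline.log_air, k=5)
        gram = scores.T.to_numpy() @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_eigenvalues_match_hand_eigendecomposition(self):
        rng = np.random.default_rng(2)
        data = rng.multivariate_normal(
            [0, 0, 0], [[4, 1, 0], [1, 2, 0.5], [0, 0.5, 1]], size=200
        )
        frame = pd.DataFrame(data)
        scores, varexp = ac.pca_scores(frame, k=3)
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(data.T)))[::-1]
        assert np.allclose(varexp, eigvals / eigvals.sum(), atol=1e-9)
        # score variances reproduce the eigenvalues themselves
        assert np.allclose(scores.var(axis=0, ddof=1), eigvals, rtol=1e-9)

    def test_variance_explained_non_increasing(self, small_pipeline):
        _, varexp = ac.pca_scores(small_pipeline.log_air, k=8)
        assert (np.diff(varexp) <= 1e-12).all()


class TestUMAP:
    def test_deterministic_under_fixed_seed(self, small_pipeline):
        a = ac.umap_embed(small_pipeline.log_air, seed=42)
        b = ac.umap_embed(small_pipeline.log_air, seed=42)
        assert np.allclose(a.coordinates, b.coordinates)

    def test_too_few_samples_rejected(self, small_pipeline):
        one = small_pipeline.log_air.subset_samples(
            small_pipeline.log_air.sample_ids[:1]
        )
        with pytest.raises(ac.TableError):
            ac.umap_embed(one)


class TestBinarisation:
    def test_thresholds_strictly_greater(self):
        meta = pd.DataFrame(
            {
                "temperature": [25.0, 25.1, None],
                "humidity": [65.0, 65.1, 10.0],
                "travellers": [100, 101, None],
            }
        )
        out = binarise_covariates(meta)
        assert list(out["temperature"]) == ["below_eq", "above", None]
        assert list(out["humidity"]) == ["below_eq", "above", "below_eq"]
        assert list(out["travellers"]) == ["below_eq", "above", None]


class TestManova:
    def _univariate_fixture(self):
        scores = pd.DataFrame(
            {"PC1": [0.0, 1.0, 2.0, 3.0]}, index=["a", "b", "c", "d"]
        )
        meta = pd.DataFrame(
            {"city": ["x", "x", "y", "y"]}, index=scores.index
        )
        return scores, meta

    def test_univariate_pillai_equals_ssb_over_sst(self):
        # groups {0,1} vs {2,3}: SSB=4, SST=5 -> V = 0.8
        scores, meta = self._univariate_fixture()
        model = ac.manova_forward_select(
            scores, meta, candidate_terms=["CITY"], alpha=0.999
        )
        assert model.steps[0].pillai == pytest.approx(0.8, abs=1e-12)

    def test_pillai_matches_statsmodels_manova(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(5)
        n = 80
        city = rng.choice(["A", "B", "C"], n)
        Y = rng.normal(size=(n, 4))
        Y[:, 0] += (city == "A") * 1.2
        scores = pd.DataFrame(
            Y, columns=[f"PC{i+1}" for i in range(4)],
            index=[f"s{i}" for i in range(n)],
        )
        meta = pd.DataFrame({"city": city}, index=scores.index)
        model = ac.manova_forward_select(
            scores, meta, candidate_terms=["CITY"], alpha=0.999
        )
        df = meta.copy()
        df[["y1", "y2", "y3", "y4"]] = Y
        stat = (
            MANOVA.from_formula("y1 + y2 + y3 + y4 ~ city", data=df)
            .mv_test()
            .results["city"]["stat"]
            .loc["Pillai's trace"]
        )
        step = model.steps[0]
        assert step.pillai == pytest.approx(float(stat["Value"]), abs=1e-10)
        assert step.f_value == pytest.approx(float(stat["F Value"]), rel=1e-10)
        assert step.p_value == pytest.approx(float(stat["Pr > F"]), abs=1e-12)

    def test_independent_covariate_rarely_enters(self):
        # null covariate: inclusion rate over seeded replicates stays ~alpha
        rng = np.random.default_rng(9)
        included = 0
        for _ in range(20):
            n = 60
            Y = rng.normal(size=(n, 3))
            meta = pd.DataFrame(
                {"humidity": rng.uniform(30, 90, n)},
                index=[f"s{i}" for i in range(n)],
            )
            scores = pd.DataFrame(
                Y, columns=["PC1", "PC2", "PC3"], index=meta.index
            )
            model = ac.manova_forward_select(
                scores, meta, candidate_terms=["HUMIDITY"], alpha=0.001
            )
            included += "HUMIDITY" in model.included
        assert included == 0

    def test_interaction_requires_main_effects(self):
        rng = np.random.default_rng(3)
        n = 90
        city = rng.choice(["A", "B"], n)
        hum = rng.uniform(30, 90, n)
        Y = rng.normal(size=(n, 2)) + (city == "A")[:, None] * 3.0
        scores = pd.DataFrame(Y, columns=["PC1", "PC2"],
                              index=[f"s{i}" for i in range(n)])
        meta = pd.DataFrame({"city": city, "humidity": hum}, index=scores.index)
        model = ac.manova_forward_select(
            scores, meta, candidate_terms=["CITY", "HUMIDITY", "CITY:HUMIDITY"]
        )
        assert "CITY" in model.included
        for term in model.included:
            if ":" in term:
                assert all(p in model.included for p in term.split(":"))

    def test_missing_covariate_rows_dropped_and_counted(self):
        scores = pd.DataFrame(
            np.random.default_rng(0).normal(size=(30, 2)),
            columns=["PC1", "PC2"],
            index=[f"s{i}" for i in range(30)],
        )
        city = ["A"] * 15 + ["B"] * 15
        hum = [None] * 5 + list(np.linspace(30, 90, 25))
        meta = pd.DataFrame({"city": city, "humidity": hum}, index=scores.index)
        model = ac.manova_forward_select(
            scores, meta, candidate_terms=["CITY", "HUMIDITY"]
        )
        assert model.n_rows == 25 and model.n_dropped == 5

    def test_pillai_bounded_by_min_of_dfs(self):
        rng = np.random.default_rng(7)
        H = rng.normal(size=(3, 6)); H = H @ H.T
        E = rng.normal(size=(10, 3)); E = E.T @ E
        V, *_ = pillai_f_test(H, E, q=4, ve=30)
        assert 0.0 <= V <= min(4, 3)

    def test_forward_selection_is_deterministic(self, small_pipeline):
        p = small_pipeline
        scores, _ = ac.pca_scores(p.log_air, k=5)
        meta = p.meta.loc[p.air_ids]
        runs = [
            ac.manova_forward_select(scores, meta, candidate_terms=["CITY", "YEAR"])
            for _ in range(2)
        ]
        assert runs[0].included == runs[1].included
        assert [s.pillai for s in runs[0].steps] == [s.pillai for s in runs[1].steps]
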