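"""Screen / prune / standardize / PCA against small oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from papkit.featsel import (SelectionPipeline, Standardizer, pca_reduce,
                            pearson_prune, spearman_screen, standardize)


def rank_avg(x):
    """Independent average-rank computation (sorting based)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_avg(x), rank_avg(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearmanScreen:
    def test_monotone_transform_kept_with_r_one(self):
        df = pd.DataFrame({"t": np.linspace(1, 10, 30)})
        df["f"] = df["t"] ** 2
        rep = spearman_screen(df, "t")
        assert rep.screen["f"]["r"] == pytest.approx(1.0)
        assert rep.kept == ["f"]

    @pytest.mark.parametrize("n_seeds", [20])
    def test_independent_noise_usually_dropped(self, n_seeds):
        dropped = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"t": rng.normal(size=200),
                               "f": rng.normal(size=200)})
            rep = spearman_screen(df, "t")
            dropped += rep.screen["f"]["status"] == "dropped"
        assert dropped >= int(0.9 * n_seeds)

    def test_tie_heavy_r_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 3, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            df = pd.DataFrame({"t": y, "f": x})
            rep = spearman_screen(df, "t")
            assert rep.screen["f"]["r"] == pytest.approx(
                spearman_oracle(x, y), abs=1e-12)

    def test_too_few_pairs_flagged_unevaluable(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0, 4.0],
                           "f": [1.0, np.nan, np.nan, np.nan]})
        rep = spearman_screen(df, "t")
        assert rep.screen["f"]["reason"] == "unevaluable"

    def test_report_ordered_by_abs_r_descending(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=100)
        df = pd.DataFrame({
            "t": t,
            "strong": t + 0.1 * rng.normal(size=100),
            "weak": t + 2.0 * rng.normal(size=100),
            "none": rng.normal(size=100),
        })
        rep = spearman_screen(df, "t")
        rs = [abs(e["r"]) for e in rep.screen.values() if e["r"] is not None]
        assert rs == sorted(rs, reverse=True)


def greedy_prune_oracle(corr, target_r, names, thresh=0.9):
    """Independent re-implementation: repeatedly scan the full matrix."""
    kept = list(names)
    while True:
        worst = None
        for a, b in itertools.combinations(kept, 2):
            r = abs(corr[(a, b)])
            if r > thresh and (worst is None or r > worst[0]
                               or (r == worst[0] and (a, b) < worst[1:])):
                worst = (r, a, b)
        if worst is None:
            return kept
        _, a, b = worst
        if target_r[a] < target_r[b]:
            victim = a
        elif target_r[b] < target_r[a]:
            victim = b
        else:
            victim = max(a, b)
        kept.remove(victim)


class TestPearsonPrune:
    def test_exact_duplicate_drops_lower_target_r(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=50)
        a = t + 0.5 * rng.normal(size=50)
        df = pd.DataFrame({"t": t, "a": a, "b": a.copy(),
                           "c": rng.normal(size=50)})
        # make "b" slightly worse vs target by adding target-orthogonal noise?
        # identical copies tie -> lexicographic: "b" (later name) dropped
        kept = pearson_prune(df, "t", ["a", "b", "c"])
        assert kept == ["a", "c"]

    def test_no_pair_above_threshold_is_identity(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("tabc"))
        assert pearson_prune(df, "t", ["a", "b", "c"]) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        t = rng.normal(size=n)
        base = rng.normal(size=n)
        df = pd.DataFrame({
            "t": t,
            "a": base + 0.05 * rng.normal(size=n),
            "b": base + 0.05 * rng.normal(size=n),
            "c": base + 0.05 * rng.normal(size=n),
            "d": rng.normal(size=n),
        })
        names = ["a", "b", "c", "d"]
        corr = {}
        for x, y in itertools.combinations(names, 2):
            corr[(x, y)] = corr[(y, x)] = np.corrcoef(df[x], df[y])[0, 1]
        target_r = {f: abs(np.corrcoef(df[f], df["t"])[0, 1]) for f in names}
        assert pearson_prune(df, "t", names) == greedy_prune_oracle(
            corr, target_r, names)

    @pytest.mark.parametrize("seed", range(20))
    def test_post_prune_pairwise_r_bounded(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 50
        shared = rng.normal(size=n)
        cols = {"t": rng.normal(size=n)}
        for i in range(6):
            lam = rng.uniform(0, 1)
            cols[f"f{i}"] = lam * shared + (1 - lam) * rng.normal(size=n)
        df = pd.DataFrame(cols)
        kept = pearson_prune(df, "t", [f"f{i}" for i in range(6)])
        for a, b in itertools.combinations(kept, 2):
            assert abs(np.corrcoef(df[a], df[b])[0, 1]) <= 0.9 + 1e-12


class TestStandardize:
    def test_zero_mean_unit_population_variance(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(5, 3, size=(40, 3)), columns=list("abc"))
        scaled, _ = standardize(df)
        assert np.all(np.abs(scaled.mean()) < 1e-10)
        assert np.allclose(scaled.std(ddof=0), 1.0)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        scaled, scaler = standardize(df)
        back = scaler.inverse_transform(scaled)
        assert np.max(np.abs(back.to_numpy() - df.to_numpy())) < 1e-10

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="flat"):
            Standardizer().fit(df)


class TestPCA:
    def test_collinear_pair_gives_one_component(self):
        x = np.linspace(-1, 1, 20)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        scaled, _ = standardize(df)
        scores, rep = pca_reduce(scaled)
        assert rep.m == 1
        assert rep.explained_frac[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(50, 5)), columns=list("abcde"))
        scaled, _ = standardize(df)
        _, rep = pca_reduce(scaled, var_frac=0.99)
        L = np.asarray(rep.loadings)
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)

    def test_eigenvalues_match_direct_eigensolve(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        scaled, _ = standardize(df)
        X = scaled.to_numpy()
        evals = np.sort(np.linalg.eigvalsh(X.T @ X / len(X)))[::-1]
        _, rep = pca_reduce(scaled, var_frac=1.0)
        frac = np.asarray(rep.explained_frac)
        assert np.allclose(frac, evals[:rep.m] / evals.sum(), atol=1e-10)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        scaled, _ = standardize(df)
        _, rep1 = pca_reduce(scaled)
        _, rep2 = pca_reduce(scaled)
        L = np.asarray(rep1.loadings)
        assert rep1.loadings == rep2.loadings
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0


class TestPipeline:
    def test_deterministic_and_order_stable(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=80)
        df = pd.DataFrame({
            "mPAP": t,
            "f1": t + 0.3 * rng.normal(size=80),
            "f2": -t + 0.3 * rng.normal(size=80),
            "f3": rng.normal(size=80),
        })
        p1 = SelectionPipeline(target="mPAP").fit(df)
        p2 = SelectionPipeline(target="mPAP").fit(df)
        assert p1.report.kept == p2.report.kept
        assert p1.report.m == p2.report.m
        assert np.array_equal(p1.transform(df), p2.transform(df))

    def test_fallback_keeps_best_feature_when_none_significant(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"mPAP": rng.normal(size=30),
                           "f1": rng.normal(size=30),
                           "f2": rng.normal(size=30)})
        pipe = SelectionPipeline(target="mPAP").fit(df)
        assert len(pipe.report.kept) >= 1

    def test_report_json_round_trip(self):
        rng = np.random.default_rng(8)
        t = rng.normal(size=50)
        df = pd.DataFrame({"mPAP": t, "f1": t + 0.1 * rng.normal(size=50),
                           "f2": rng.normal(size=50)})
        pipe = SelectionPipeline(target="mPAP").fit(df)
        from papkit.featsel import SelectionReport
        back = SelectionReport.from_json(pipe.report.to_json())
        assert back.kept == pipe.report.kept
        assert back.m == pipe.report.m
        assert np.allclose(back.loadings, pipe.report.loadings)
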