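"""OLS fitting, adjusted-R2 fraction decomposition and total importance."""

import subprocess
import textwrap
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import synervar as sv
from synervar.errors import InputError
from synervar.partition import _subset_order


def nonempty_subsets(k):
    out = []
    for size in range(1, k + 1):
        out.extend(combinations(range(k), size))
    return out


def solve_fractions_linear_system(adj_r2, k):
    """Generic linear-system oracle: solve M f = r where row U states
    adjR2(U) = sum of fractions whose membership intersects U."""
    subsets = _subset_order(k)
    unions = nonempty_subsets(k)
    m = np.zeros((len(unions), len(subsets)))
    r = np.zeros(len(unions))
    for row, u in enumerate(unions):
        r[row] = adj_r2[u]
        for col, s in enumerate(subsets):
            if set(s) & set(u):
                m[row, col] = 1.0
    return np.linalg.solve(m, r)


class TestFitOLS:
    def test_perfect_fit(self, rng):
        x = rng.normal(size=(50, 2))
        y = 1.0 + x @ [2.0, -1.0]
        fit = sv.fit_ols(y, x)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)

    def test_adjusted_r2_formula(self):
        # adjR2 = 1 - (1 - 0.5) * 99 / 96
        assert sv.adjusted_r2(0.5, 100, 3) == pytest.approx(0.484375)

    def test_intercept_only_r2_zero(self, rng):
        y = rng.normal(size=30)
        fit = sv.fit_ols(y, np.empty((30, 0)))
        assert fit.r2 == pytest.approx(0.0)
        assert fit.p == 0

    def test_residuals_orthogonal_to_design(self, rng):
        x = rng.normal(size=(80, 4))
        y = x @ rng.normal(size=4) + rng.normal(size=80)
        fit = sv.fit_ols(y, x)
        np.testing.assert_allclose(x.T @ fit.residuals, 0, atol=1e-8)
        assert fit.adj_r2 <= fit.r2

    def test_insufficient_dof(self, rng):
        with pytest.raises(InputError, match="degrees of freedom"):
            sv.fit_ols(rng.normal(size=4), rng.normal(size=(4, 3)))


class TestPartition:
    def _random_problem(self, rng, k, n=120, p_each=2):
        y = rng.normal(size=n)
        sets = {
            name: rng.normal(size=(n, p_each))
            for name in ["biotic", "climatic", "topographic", "spatial"][:k]
        }
        return y, sets

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_moebius_matches_linear_system_oracle(self, k, rng):
        """The closed-form inversion equals a generic linear solve of the
        2^k-1 union equations, on many random regression problems."""
        for _ in range(50 if k == 4 else 25):
            y, sets = self._random_problem(rng, k)
            res = sv.partition(y, sets)
            oracle = solve_fractions_linear_system(
                {u: res.adj_r2_union[u] for u in res.adj_r2_union}, k
            )
            got = np.array([res.values[lab] for lab in res.labels])
            np.testing.assert_allclose(got, oracle, atol=1e-10)
            assert sum(res.values.values()) == pytest.approx(
                res.adj_r2_full, abs=1e-10
            )

    def test_two_set_closed_forms(self, rng):
        y, sets = self._random_problem(rng, 2)
        res = sv.partition(y, sets)
        a = res.adj_r2_union
        names = list(sets)
        assert res.values["a"] == pytest.approx(a[(0, 1)] - a[(1,)], abs=1e-12)
        assert res.values["b"] == pytest.approx(a[(0, 1)] - a[(0,)], abs=1e-12)
        assert res.values["c"] == pytest.approx(
            a[(0,)] + a[(1,)] - a[(0, 1)], abs=1e-12
        )

    def test_duplicated_set_has_zero_uniques(self, rng):
        n = 100
        x = rng.normal(size=(n, 2))
        y = x @ [1.0, 0.5] + rng.normal(size=n)
        with pytest.warns(UserWarning):  # rank-deficient union fit
            res = sv.partition(y, {"A": x, "B": x.copy()})
        assert res.values["a"] == pytest.approx(0.0, abs=1e-8)
        assert res.values["b"] == pytest.approx(0.0, abs=1e-8)
        assert res.values["c"] == pytest.approx(res.adj_r2_union[(0,)], abs=1e-8)

    def test_known_inclusion_exclusion_arithmetic(self):
        """adjR2(A)=0.6, adjR2(B)=0.5, adjR2(AB)=0.8 => 0.3/0.2/0.3."""
        oracle = solve_fractions_linear_system(
            {(0,): 0.6, (1,): 0.5, (0, 1): 0.8}, 2
        )
        np.testing.assert_allclose(oracle, [0.3, 0.2, 0.3], atol=1e-12)

    def test_orthogonal_sets_near_zero_shared(self, rng):
        """With orthogonal predictor sets the raw-R2 shared fractions are 0;
        adjusted R2 leaves them near zero at large n."""
        n = 1000
        q, _ = np.linalg.qr(np.column_stack([np.ones(n), rng.normal(size=(n, 4))]))
        xa, xb = q[:, 1:3], q[:, 3:5]
        y = xa @ [1.0, 0.5] + xb @ [0.7, -0.3] + rng.normal(size=n)
        res = sv.partition(y, {"A": xa, "B": xb})
        p_tot = 4
        assert abs(res.values["c"]) < 2.0 / (n - p_tot)

    def test_permutation_invariance(self, rng):
        y, sets = self._random_problem(rng, 3)
        res1 = sv.partition(y, sets)
        rev = {k: sets[k] for k in reversed(list(sets))}
        res2 = sv.partition(y, rev)
        for lab in res1.labels:
            members = frozenset(res1.membership[lab])
            lab2 = next(
                l for l in res2.labels if frozenset(res2.membership[l]) == members
            )
            assert res1.values[lab] == pytest.approx(res2.values[lab2], abs=1e-10)

    def test_four_set_letters_match_venn_convention(self, rng):
        y, sets = self._random_problem(rng, 4)
        res = sv.partition(y, sets)
        by_set = {
            name: "".join(lab for lab in res.labels if name in res.membership[lab])
            for name in res.set_names
        }
        assert by_set["biotic"] == "aeghklno"
        assert by_set["climatic"] == "befiklmo"
        assert by_set["topographic"] == "cfgjlmno"
        assert by_set["spatial"] == "dhijkmno"


class TestTotalImportance:
    def test_definition_and_identity(self, rng):
        n = 150
        xa = rng.normal(size=(n, 2))
        xb = rng.normal(size=(n, 2))
        y = xa @ [1.0, 0.3] + 0.5 * xb[:, 0] + rng.normal(size=n)
        res = sv.partition(y, {"A": xa, "B": xb})
        assert sv.total_importance(res, "A") == pytest.approx(
            res.values["a"] + res.values["c"]
        )
        # identity: total importance of a set equals adjR2 of that set alone
        assert res.total_importance("A") == pytest.approx(
            res.adj_r2_union[(0,)], abs=1e-8
        )
        with pytest.raises(InputError):
            res.total_importance("nope")

    def test_four_set_identity_against_solo_fit(self, rng):
        n = 200
        sets = {nm: rng.normal(size=(n, 2)) for nm in ["biotic", "climatic", "topographic", "spatial"]}
        y = sets["climatic"] @ [1.0, 0.2] + rng.normal(size=n)
        res = sv.partition(y, sets)
        assert res.total_importance("climatic") == pytest.approx(
            sv.fit_ols(y, sets["climatic"]).adj_r2, abs=1e-8
        )


class TestVeganCrossCheck:
    def test_matches_vegan_varpart_four_sets(self, rng, tmp_path):
        """Independent oracle: R vegan::varpart on the same data reports the
        same adjusted-R2 fractions (vegan orders its indfract rows
        differently but the multiset of values and their sum must match)."""
        n = 60
        y = rng.normal(size=n)
        sets = {nm: rng.normal(size=(n, 2)) for nm in ["b", "c", "t", "s"]}
        df = pd.DataFrame({"y": y})
        for nm, m in sets.items():
            df[f"{nm}1"], df[f"{nm}2"] = m[:, 0], m[:, 1]
        csv = tmp_path / "varpart_input.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            d <- read.csv("{csv}")
            vp <- varpart(d$y, ~ b1 + b2, ~ c1 + c2, ~ t1 + t2, ~ s1 + s2, data = d)
            f <- vp$part$indfract
            cat(f$Adj.R.square, sep = ",")
        """)
        r = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                           text=True, timeout=300)
        assert r.returncode == 0, r.stderr
        vegan_fracs = np.array([float(v) for v in r.stdout.strip().split(",")])
        res = sv.partition(y, {"biotic": sets["b"], "climatic": sets["c"],
                               "topographic": sets["t"], "spatial": sets["s"]})
        ours = np.array([res.values[lab] for lab in res.labels])
        # same multiset of fraction values and identical total
        assert vegan_fracs[:15].sum() == pytest.approx(ours.sum(), abs=1e-6)
        np.testing.assert_allclose(np.sort(ours), np.sort(vegan_fracs[:15]), atol=1e-6)
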