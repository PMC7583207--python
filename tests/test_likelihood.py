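"""Family MVN likelihood, constrained maximization, AIC/LRT machinery."""

import math

import numpy as np
import pytest

from famclock.likelihood import (
    LOG2PI,
    FamilyBlock,
    FitResult,
    PackedFamilies,
    Parameter,
    ParameterSpec,
    family_loglik,
    lrt,
    maximize,
)
from conftest import bivariate_pairs


def det3_cofactor(S):
    """3x3 determinant by cofactor expansion (independent oracle)."""
    return (
        S[0][0] * (S[1][1] * S[2][2] - S[1][2] * S[2][1])
        - S[0][1] * (S[1][0] * S[2][2] - S[1][2] * S[2][0])
        + S[0][2] * (S[1][0] * S[2][1] - S[1][1] * S[2][0])
    )


def inv3_cofactor(S):
    d = det3_cofactor(S)
    C = [[0.0] * 3 for _ in range(3)]
    for i in range(3):
        for j in range(3):
            minor = [
                [S[r][c] for c in range(3) if c != j]
                for r in range(3) if r != i
            ]
            C[i][j] = ((-1) ** (i + j)) * (minor[0][0] * minor[1][1] - minor[0][1] * minor[1][0])
    return [[C[j][i] / d for j in range(3)] for i in range(3)]


class TestFamilyLoglik:
    def test_singleton_at_mean(self):
        block = FamilyBlock("f", np.array([0.0]), ["s"])
        ll = family_loglik(block, lambda i, j: 0.0, {"s": 1.0})
        assert ll == pytest.approx(-0.5 * LOG2PI)

    def test_independent_pair_factorizes(self):
        y = np.array([0.7, -1.2])
        block = FamilyBlock("f", y, ["s", "s"])
        ll = family_loglik(block, lambda i, j: 0.0, {"s": 2.0})
        uni = sum(-0.5 * (LOG2PI + math.log(2.0) + v * v / 2.0) for v in y)
        assert ll == pytest.approx(uni, abs=1e-12)

    def test_three_member_family_vs_cofactor_oracle(self):
        S = [[2.0, 0.5, 0.3], [0.5, 1.5, 0.4], [0.3, 0.4, 1.8]]
        y = np.array([0.3, -0.2, 0.5])
        det = det3_cofactor(S)
        Sinv = inv3_cofactor(S)
        quad = sum(y[i] * Sinv[i][j] * y[j] for i in range(3) for j in range(3))
        expected = -0.5 * (3 * LOG2PI + math.log(det) + quad)
        block = FamilyBlock("f", y, ["a", "b", "c"])
        ll = family_loglik(block, lambda i, j: S[i][j], {"a": 2.0, "b": 1.5, "c": 1.8})
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_permutation_invariance(self, rng):
        S = np.array([[1.5, 0.4, 0.2], [0.4, 1.2, 0.3], [0.2, 0.3, 1.1]])
        y = rng.normal(size=3)
        ll0 = family_loglik(
            FamilyBlock("f", y, ["a", "b", "c"]),
            lambda i, j: S[i, j], {"a": 1.5, "b": 1.2, "c": 1.1},
        )
        perm = [2, 0, 1]
        Sp = S[np.ix_(perm, perm)]
        vars_p = {"x": Sp[0, 0], "y": Sp[1, 1], "z": Sp[2, 2]}
        llp = family_loglik(
            FamilyBlock("f", y[perm], ["x", "y", "z"]),
            lambda i, j: Sp[i, j], vars_p,
        )
        assert ll0 == pytest.approx(llp, abs=1e-12)

    def test_non_pd_returns_minus_inf(self):
        block = FamilyBlock("f", np.array([0.1, 0.2]), ["s", "s"])
        assert family_loglik(block, lambda i, j: 2.0, {"s": 1.0}) == -math.inf


class TestPackedFamilies:
    def build(self, rng, sizes):
        fams, edge_rows = [], 0
        edge_cov_parts = []
        for m in sizes:
            y = rng.normal(size=m)
            sidx = np.zeros(m, dtype=np.intp)
            edges = []
            for i in range(m):
                for j in range(i + 1, m):
                    edges.append((i, j, edge_rows))
                    edge_cov_parts.append(0.3 / (1 + abs(i - j)))
                    edge_rows += 1
            fams.append((y, sidx, edges))
        packed = PackedFamilies(fams, n_studies=1, n_edges=edge_rows)
        return packed, fams, np.array(edge_cov_parts)

    def test_matches_reference_loglik_for_mixed_sizes(self, rng):
        packed, fams, cov = self.build(rng, [1, 2, 3, 4, 5, 2, 2])
        total = packed.loglik(cov, np.array([1.3]))
        expected = 0.0
        for y, sidx, edges in fams:
            covmap = {(i, j): cov[row] for i, j, row in edges}
            block = FamilyBlock("f", y, ["s"] * len(y))
            expected += family_loglik(
                block, lambda i, j: covmap[(min(i, j), max(i, j))], {"s": 1.3}
            )
        assert total == pytest.approx(expected, abs=1e-9)

    def test_additivity_over_disjoint_halves(self, rng):
        packed, fams, cov = self.build(rng, [2, 3, 2, 4])
        full = packed.loglik(cov, np.array([1.0]))
        # repack halves with re-indexed edges
        def repack(subset):
            rows = sorted({row for _, _, e in subset for *_ij, row in e})
            remap = {r: k for k, r in enumerate(rows)}
            fams2 = [(y, s, [(i, j, remap[r]) for i, j, r in e]) for y, s, e in subset]
            return PackedFamilies(fams2, 1, len(rows)), cov[rows]
        p1, c1 = repack(fams[:2])
        p2, c2 = repack(fams[2:])
        assert full == pytest.approx(
            p1.loglik(c1, np.array([1.0])) + p2.loglik(c2, np.array([1.0])), abs=1e-9
        )

    def test_invalid_pair_covariance_gives_minus_inf(self, rng):
        packed, _, cov = self.build(rng, [2])
        assert packed.loglik(np.array([5.0]), np.array([1.0])) == -math.inf


class TestMaximize:
    def test_quadratic_recovery(self):
        spec = ParameterSpec([
            Parameter("x", 0.3), Parameter("y", -0.2),
        ])
        fit = maximize(lambda p: -((p["x"] - 1.7) ** 2 + 2 * (p["y"] + 0.4) ** 2), spec)
        assert fit.estimates["x"] == pytest.approx(1.7, abs=1e-5)
        assert fit.estimates["y"] == pytest.approx(-0.4, abs=1e-5)
        assert fit.converged

    def test_pair_correlation_mle_matches_grid_search(self, rng):
        y1, y2 = bivariate_pairs(rng, 300, 0.45)
        n = y1.size

        def profile_ll(r):
            # variance profiled out analytically at each rho
            s2 = np.sum(y1**2 + y2**2 - 2 * r * y1 * y2) / (2 * n * (1 - r * r))
            det = s2 * s2 * (1 - r * r)
            quad = np.sum(s2 * y1**2 - 2 * r * s2 * y1 * y2 + s2 * y2**2) / det
            return -n * LOG2PI - 0.5 * n * math.log(det) - 0.5 * quad

        grid = np.arange(-0.99, 0.99, 1e-3)
        r_grid = grid[np.argmax([profile_ll(r) for r in grid])]

        from famclock.correlation import fit_pair_correlation
        fit = fit_pair_correlation(y1, y2, seed=0)
        assert fit.estimates["rho"] == pytest.approx(r_grid, abs=1e-3)

    def test_refit_from_solution_is_fixed_point(self, rng):
        y1, y2 = bivariate_pairs(rng, 200, 0.3)
        from famclock.correlation import fit_pair_correlation, _pair_loglik
        fit = fit_pair_correlation(y1, y2, seed=0)
        spec = ParameterSpec([
            Parameter("rho", fit.estimates["rho"], transform="interval", lo=-0.99, hi=0.99),
            Parameter("var", fit.estimates["var"], transform="log"),
        ])
        refit = maximize(lambda p: _pair_loglik(y1, y2, p["rho"], p["var"]), spec, n_starts=1)
        assert refit.loglik == pytest.approx(fit.loglik, abs=1e-8)

    def test_all_starts_diverging_reports_failure(self):
        spec = ParameterSpec([Parameter("x", 1.0, transform="log")])
        fit = maximize(lambda p: -math.inf, spec, n_starts=2)
        assert not fit.converged

    def test_fixed_parameters_not_counted(self):
        spec = ParameterSpec([
            Parameter("a", 2.0, free=False), Parameter("b", 0.0),
        ])
        fit = maximize(lambda p: -((p["b"] - p["a"]) ** 2), spec)
        assert fit.n_params == 1
        assert fit.estimates["a"] == 2.0
        assert fit.estimates["b"] == pytest.approx(2.0, abs=1e-5)


class TestFitResultAndLrt:
    def test_aic_identity(self):
        fit = FitResult(loglik=-100.0, n_params=3, estimates={}, standard_errors={},
                        cis={}, converged=True)
        assert fit.aic == 206.0

    def test_equal_logliks_give_p_one(self):
        a = FitResult(-50.0, 2, {}, {}, {}, True)
        b = FitResult(-50.0, 3, {}, {}, {}, True)
        stat, p = lrt(a, b, df=1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_reference_value(self):
        null = FitResult(-100.0, 1, {}, {}, {}, True)
        alt = FitResult(-100.0 + 3.841 / 2, 2, {}, {}, {}, True)
        stat, p = lrt(null, alt, df=1)
        assert stat == pytest.approx(3.841)
        assert round(p, 3) == 0.050

    def test_negative_statistic_raises(self):
        null = FitResult(-90.0, 1, {}, {}, {}, True)
        alt = FitResult(-100.0, 2, {}, {}, {}, True)
        with pytest.raises(ValueError, match="nested"):
            lrt(null, alt, df=1)
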