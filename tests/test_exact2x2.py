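"""Exact 2x2 machinery: Fisher test, crude OR, conditional inference.

Oracles: a pure-integer enumeration of the probability-method Fisher
p-value; a dense log-spaced grid search of the conditional likelihood
for the CMLE; tail-probability evaluation at the CI bounds; and R's
``fisher.test`` (an independent implementation of both the p-value and
the conditional MLE) on a handful of tables.
"""

from __future__ import annotations

import json
import math
import subprocess
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revphewas.exact2x2 import (
    _support_weights,
    exact_2x2_inference,
    fisher_exact_batch,
    fisher_exact_two_sided,
    odds_ratio_crude,
)


def fisher_oracle(a: int, n1: int, b: int, n0: int) -> float:
    """Probability-method p by exact integer enumeration over the margin."""
    m = a + b
    lo, hi = max(0, m - n0), min(n1, m)
    weights = {k: Fraction(math.comb(n1, k) * math.comb(n0, m - k)) for k in range(lo, hi + 1)}
    total = sum(weights.values())
    w_obs = weights[a]
    kept = sum(w for w in weights.values() if w <= w_obs * (1 + Fraction(1, 10**7)))
    return float(kept / total)


def cmle_grid_oracle(a: int, n1: int, b: int, n0: int, n_grid: int = 20_001) -> float:
    """Arg-max of the conditional log-likelihood: dense log-spaced psi grid
    (1e-4..1e4) followed by golden-section refinement of the bracketing
    cell.  Independent of the score-equation route the implementation uses.
    """
    k, lw = _support_weights(n1, n0, a + b)

    def loglik(t: float | np.ndarray) -> np.ndarray:
        t = np.atleast_1d(t)
        ll = lw[:, None] + np.outer(k, t)
        mx = ll.max(axis=0)
        return (lw[k == a] + a * t) - (mx + np.log(np.exp(ll - mx).sum(axis=0)))

    grid = np.linspace(np.log(1e-4), np.log(1e4), n_grid)
    i = int(np.argmax(loglik(grid)))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    phi = (math.sqrt(5) - 1) / 2
    x1, x2 = hi - phi * (hi - lo), lo + phi * (hi - lo)
    f1, f2 = float(loglik(x1)[0]), float(loglik(x2)[0])
    while hi - lo > 1e-10:
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + phi * (hi - lo)
            f2 = float(loglik(x2)[0])
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - phi * (hi - lo)
            f1 = float(loglik(x1)[0])
    return float(np.exp((lo + hi) / 2))


class TestFisher:
    @pytest.mark.parametrize(
        "table", [(1, 2, 1, 2), (0, 10, 0, 10), (5, 10, 5, 10), (0, 1, 1, 1)]
    )
    def test_balanced_or_degenerate_tables_give_p_one(self, table):
        a, n1, b, n0 = table
        assert fisher_exact_two_sided(a, n1, b, n0) == pytest.approx(1.0)

    def test_benchmark_table_is_significant(self):
        p = fisher_exact_two_sided(9, 28, 143, 1402)
        assert p == pytest.approx(fisher_oracle(9, 28, 143, 1402), rel=1e-9)
        assert p < 0.05

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            n1 = int(rng.integers(1, 35))
            n0 = int(rng.integers(1, 120))
            a = int(rng.integers(0, n1 + 1))
            b = int(rng.integers(0, n0 + 1))
            got = fisher_exact_two_sided(a, n1, b, n0)
            want = fisher_oracle(a, n1, b, n0)
            assert got == pytest.approx(want, rel=1e-9), (a, n1, b, n0)

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        n1 = rng.integers(1, 30, size=50)
        n0 = rng.integers(1, 300, size=50)
        a = rng.integers(0, n1 + 1)
        b = rng.integers(0, n0 + 1)
        batch = fisher_exact_batch(a, n1, b, n0)
        for i in range(50):
            assert batch[i] == pytest.approx(
                fisher_exact_two_sided(int(a[i]), int(n1[i]), int(b[i]), int(n0[i])), rel=1e-12
            )

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(
        n1=st.integers(1, 25),
        n0=st.integers(1, 60),
        data=st.data(),
    )
    def test_symmetry_between_groups(self, n1, n0, data):
        a = data.draw(st.integers(0, n1))
        b = data.draw(st.integers(0, n0))
        assert fisher_exact_two_sided(a, n1, b, n0) == pytest.approx(
            fisher_exact_two_sided(b, n0, a, n1), rel=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 5, 0, 5)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(6, 5, 0, 5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(0, 0, 0, 0)


class TestCrudeOddsRatio:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((9, 28, 143, 1402), 4.2),   # published matched-control rows
            ((3, 17, 7, 964), 29.3),
            ((5, 10, 50, 100), 1.0),
        ],
    )
    def test_benchmark_values(self, table, expected):
        assert odds_ratio_crude(*table) == pytest.approx(expected, abs=0.05)

    def test_undefined_configurations_flagged(self):
        assert math.isnan(odds_ratio_crude(5, 5, 1, 10))   # a == n1
        assert math.isnan(odds_ratio_crude(0, 5, 0, 10))   # both zero
        assert math.isnan(odds_ratio_crude(1, 5, 10, 10))  # b == n0
        assert math.isinf(odds_ratio_crude(1, 5, 0, 10))   # zero control cell

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_crude(3, 2, 0, 5)


class TestExactConditionalInference:
    def test_symmetric_table_gives_unit_or_and_p_one(self):
        res = exact_2x2_inference(5, 10, 5, 10)
        assert res.or_method == "cmle"
        assert res.or_point == pytest.approx(1.0, abs=1e-6)
        assert res.p == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_control_cell_yields_finite_mue(self):
        # upper-boundary table: CMLE is infinite, MUE is reported instead
        res = exact_2x2_inference(1, 11, 0, 1279)
        assert res.or_method == "mue"
        assert math.isfinite(res.or_point) and res.or_point > 1
        assert math.isinf(res.ci_high)

    def test_zero_case_cell_is_undefined(self):
        res = exact_2x2_inference(0, 28, 7, 1402)
        assert res.or_method == "undefined"
        assert math.isnan(res.or_point)
        assert math.isfinite(res.p)  # p-value still defined

    def test_degenerate_margins_fully_undefined(self):
        res = exact_2x2_inference(0, 5, 0, 5)
        assert res.or_method == "undefined"
        assert math.isnan(res.p)

    def test_cmle_matches_grid_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 40:
            n1 = int(rng.integers(2, 31))
            n0 = int(rng.integers(2, 101))
            a = int(rng.integers(1, n1 + 1))
            b = int(rng.integers(1, n0 + 1))
            m = a + b
            lo, hi = max(0, m - n0), min(n1, m)
            if not (lo < a < hi):
                continue
            res = exact_2x2_inference(a, n1, b, n0)
            assert res.or_method == "cmle"
            oracle = cmle_grid_oracle(a, n1, b, n0)
            assert res.or_point == pytest.approx(oracle, rel=1e-4), (a, n1, b, n0)
            checked += 1

    def test_ci_bounds_invert_tail_probabilities(self):
        from revphewas.exact2x2 import _tail_ge, _tail_le

        for table in [(9, 28, 143, 1402), (4, 15, 81, 825), (2, 11, 18, 1279)]:
            a, n1, b, n0 = table
            res = exact_2x2_inference(a, n1, b, n0)
            k, lw = _support_weights(n1, n0, a + b)
            assert _tail_ge(math.log(res.ci_low), k, lw, a) == pytest.approx(0.025, abs=1e-6)
            assert _tail_le(math.log(res.ci_high), k, lw, a) == pytest.approx(0.025, abs=1e-6)

    def test_cmle_shrinks_toward_unity_relative_to_crude(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 60:
            n1 = int(rng.integers(2, 31))
            n0 = int(rng.integers(2, 101))
            a = int(rng.integers(1, n1))
            b = int(rng.integers(1, n0))
            m = a + b
            if not (max(0, m - n0) < a < min(n1, m)):
                continue
            crude = odds_ratio_crude(a, n1, b, n0)
            if not math.isfinite(crude) or crude <= 0:
                continue
            res = exact_2x2_inference(a, n1, b, n0)
            assert abs(math.log(res.or_point)) <= abs(math.log(crude)) + 1e-9, (a, n1, b, n0)
            checked += 1

    def test_mid_p_interval_is_narrower(self):
        plain = exact_2x2_inference(9, 28, 143, 1402)
        mid = exact_2x2_inference(9, 28, 143, 1402, mid_p=True)
        assert mid.ci_low > plain.ci_low
        assert mid.ci_high < plain.ci_high


class TestAgainstR:
    """fisher.test computes the same probability-method p and the CMLE."""

    def test_p_and_cmle_match_r(self, tmp_path):
        tables = [(9, 28, 143, 1402), (3, 17, 7, 964), (7, 35, 56, 1023), (4, 15, 81, 825)]
        lines = ["results <- list()"]
        for i, (a, n1, b, n0) in enumerate(tables):
            lines.append(
                f"ft <- fisher.test(matrix(c({a},{n1 - a},{b},{n0 - b}), nrow=2, byrow=TRUE));"
                f"results[[{i + 1}]] <- c(ft$p.value, unname(ft$estimate))"
            )
        lines.append('cat(jsonlite::toJSON(results, digits=12))')
        script = tmp_path / "fisher.R"
        script.write_text("\n".join(lines))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, check=True
        )
        r_results = json.loads(out.stdout)
        for (a, n1, b, n0), (r_p, r_cmle) in zip(tables, r_results):
            assert fisher_exact_two_sided(a, n1, b, n0) == pytest.approx(r_p, rel=1e-6)
            res = exact_2x2_inference(a, n1, b, n0)
            # R's fisher.test maximizes with optimize(); its tolerance is
            # ~ .Machine$double.eps^0.25, so agreement is to ~1e-3 relative
            assert res.or_point == pytest.approx(r_cmle, rel=1e-3)
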