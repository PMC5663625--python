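"""Tri-state query evaluation, the nine-cell support partition and the
quality measures, checked against hand evaluation and brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from redescribe.data_model import (IN, OUT, UNKNOWN, Condition,
                                   ConjunctiveQuery, ConfigurationError,
                                   QualityConstraints, Redescription,
                                   check_quality, evaluate_query, jaccard,
                                   partition_support, qnm_jaccard,
                                   redescription_pvalue,
                                   redescription_log10_pvalue)
from conftest import make_dataset


# -- query evaluation ---------------------------------------------------------

class TestEvaluateQuery:
    def test_empty_query_is_vacuously_true(self):
        data = make_dataset({"x": [1.0, 2.0, np.nan]}, {"y": [0.0, 0.0, 0.0]})
        out = evaluate_query(ConjunctiveQuery(1, ()), data)
        assert (out == IN).all()

    def test_per_instance_tristate(self):
        data = make_dataset({"x": [1.0, 5.0, np.nan]}, {"y": [0.0] * 3})
        q = ConjunctiveQuery(1, (Condition("x", lo=0.0, hi=2.0),))
        assert evaluate_query(q, data).tolist() == [IN, OUT, UNKNOWN]

    def test_violation_dominates_unknown(self):
        # y = 9 violates, so membership is determinable despite missing x
        data = make_dataset({"x": [np.nan], "y": [9.0]}, {"z": [0.0]})
        q = ConjunctiveQuery(1, (Condition("x", lo=0.0, hi=2.0),
                                 Condition("y", lo=0.0, hi=5.0)))
        assert evaluate_query(q, data).tolist() == [OUT]

    def test_categorical_membership(self):
        data = make_dataset({"c": ["a", "b", None]}, {"y": [0.0] * 3})
        q = ConjunctiveQuery(1, (Condition("c", values=frozenset(["a"])),))
        assert evaluate_query(q, data).tolist() == [IN, OUT, UNKNOWN]

    def test_unknown_attribute_is_configuration_error(self):
        data = make_dataset({"x": [1.0]}, {"y": [1.0]})
        q = ConjunctiveQuery(1, (Condition("nope", lo=0.0, hi=1.0),))
        with pytest.raises(ConfigurationError):
            evaluate_query(q, data)

    def test_wrong_view_is_configuration_error(self):
        data = make_dataset({"x": [1.0]}, {"y": [1.0]})
        q = ConjunctiveQuery(1, (Condition("y", lo=0.0, hi=1.0),))
        with pytest.raises(ConfigurationError):
            evaluate_query(q, data)

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_agrees_with_per_instance_interpreter(self, data_strategy):
        """Vectorized evaluation matches a literal per-instance interpreter."""
        n = data_strategy.draw(st.integers(1, 50))
        n_attr = data_strategy.draw(st.integers(1, 4))
        cells = data_strategy.draw(st.lists(
            st.lists(st.one_of(st.none(), st.integers(0, 9)),
                     min_size=n_attr, max_size=n_attr),
            min_size=n, max_size=n))
        cols = {f"x{j}": [float(row[j]) if row[j] is not None else np.nan
                          for row in cells] for j in range(n_attr)}
        data = make_dataset(cols, {"y": [0.0] * n})
        n_conds = data_strategy.draw(st.integers(1, n_attr))
        conds = []
        for j in range(n_conds):
            lo = data_strategy.draw(st.integers(0, 9))
            hi = data_strategy.draw(st.integers(lo, 9))
            conds.append(Condition(f"x{j}", lo=float(lo), hi=float(hi)))
        q = ConjunctiveQuery(1, tuple(conds))
        got = evaluate_query(q, data)
        for i in range(n):
            states = []
            for c in conds:
                v = cols[c.attribute][i]
                if np.isnan(v):
                    states.append(UNKNOWN)
                else:
                    states.append(IN if c.lo <= v <= c.hi else OUT)
            if OUT in states:
                expect = OUT
            elif UNKNOWN in states:
                expect = UNKNOWN
            else:
                expect = IN
            assert got[i] == expect

    @settings(derandomize=True, max_examples=40)
    @given(st.data())
    def test_dropping_a_condition_is_monotone(self, data_strategy):
        """Removing a conjunct never shrinks `in` and never grows `out`."""
        n = 30
        rng = np.random.default_rng(data_strategy.draw(st.integers(0, 10**6)))
        vals = rng.integers(0, 10, size=(n, 3)).astype(float)
        vals[rng.random((n, 3)) < 0.2] = np.nan
        data = make_dataset({f"x{j}": vals[:, j] for j in range(3)},
                            {"y": [0.0] * n})
        conds = tuple(Condition(f"x{j}", lo=2.0, hi=7.0) for j in range(3))
        full = evaluate_query(ConjunctiveQuery(1, conds), data)
        for drop in range(3):
            reduced = conds[:drop] + conds[drop + 1:]
            red = evaluate_query(ConjunctiveQuery(1, reduced), data)
            assert ((full == IN) <= (red == IN)).all()
            assert ((red == OUT) <= (full == OUT)).all()


# -- partition ---------------------------------------------------------------

class TestPartition:
    def test_all_in(self):
        p = partition_support(np.full(7, IN), np.full(7, IN))
        assert p.E11 == 7 and p.total == 7
        assert sum(v for k, v in p.counts().items() if k != "E11") == 0

    def test_cell_assignment(self):
        e1 = np.array([IN, IN, UNKNOWN, OUT])
        e2 = np.array([IN, OUT, IN, OUT])
        p = partition_support(e1, e2)
        assert (p.E11, p.E10, p.Eq1, p.E00) == (1, 1, 1, 1)

    def test_all_unknown(self):
        p = partition_support(np.full(4, UNKNOWN), np.full(4, UNKNOWN))
        assert p.Eqq == 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            partition_support(np.array([IN]), np.array([IN, IN]))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.sampled_from([IN, OUT, UNKNOWN]),
                              st.sampled_from([IN, OUT, UNKNOWN])),
                    min_size=1, max_size=100))
    def test_cells_partition_the_dataset(self, pairs):
        e1 = np.array([a for a, _ in pairs])
        e2 = np.array([b for _, b in pairs])
        p = partition_support(e1, e2)
        assert p.total == len(pairs)
        assert sum(p.counts().values()) == len(pairs)


# -- measures ----------------------------------------------------------------

class TestJaccard:
    def test_worked_example(self):
        assert jaccard(204, 172, 156) == pytest.approx(156 / 220)
        assert round(jaccard(204, 172, 156), 3) == 0.709

    def test_identical_and_disjoint(self):
        assert jaccard(50, 50, 50) == 1.0
        assert jaccard(10, 10, 0) == 0.0

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert jaccard(0, 0, 0) == 0.0


class TestQnmJaccard:
    def _partition(self, **counts):
        states = []
        cell_state = {"E11": (IN, IN), "E10": (IN, OUT), "E01": (OUT, IN),
                      "E00": (OUT, OUT), "E1q": (IN, UNKNOWN),
                      "Eq1": (UNKNOWN, IN), "E0q": (OUT, UNKNOWN),
                      "Eq0": (UNKNOWN, OUT), "Eqq": (UNKNOWN, UNKNOWN)}
        for cell, c in counts.items():
            states.extend([cell_state[cell]] * c)
        e1 = np.array([s[0] for s in states])
        e2 = np.array([s[1] for s in states])
        return partition_support(e1, e2)

    def test_equals_plain_jaccard_without_missing(self):
        p = self._partition(E11=156, E10=48, E01=16)
        assert qnm_jaccard(p) == pytest.approx(156 / 220)

    def test_perfect(self):
        assert qnm_jaccard(self._partition(E11=10)) == 1.0

    def test_missing_penalty(self):
        p = self._partition(E11=5, Eq1=1, E1q=2, E01=1, E10=1, E00=3, Eqq=2)
        assert qnm_jaccard(p) == 0.5

    def test_empty_denominator_is_zero(self):
        assert qnm_jaccard(self._partition(E00=5)) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from([(IN, IN), (IN, OUT), (OUT, IN),
                                     (OUT, OUT)]),
                    min_size=1, max_size=200))
    def test_reduces_to_jaccard_on_complete_data(self, pairs):
        e1 = np.array([a for a, _ in pairs])
        e2 = np.array([b for _, b in pairs])
        p = partition_support(e1, e2)
        j_qnm = qnm_jaccard(p)
        assert 0.0 <= j_qnm <= 1.0
        union = p.E11 + p.E10 + p.E01
        if union:
            assert j_qnm == pytest.approx(p.E11 / union)


def pvalue_bruteforce(n, s1, s2, overlap):
    """Exact rational term-by-term summation of the binomial upper tail."""
    p = Fraction(s1, n) * Fraction(s2, n)
    total = Fraction(0)
    for k in range(overlap, n + 1):
        total += math.comb(n, k) * p**k * (1 - p)**(n - k)
    return float(total)


class TestPvalue:
    def test_worked_example_bound(self):
        assert redescription_pvalue(820, 204, 172, 156) <= 2e-17

    def test_zero_overlap_is_one(self):
        assert redescription_pvalue(100, 30, 40, 0) == 1.0

    def test_small_case_exact(self):
        # Binomial(3, 2/3): P(X >= 2) = 3*(4/9)(1/3) + 8/27 = 20/27
        assert redescription_pvalue(3, 2, 3, 2) == pytest.approx(20 / 27)

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            redescription_pvalue(0, 0, 0, 0)

    def test_monotone_in_overlap(self):
        vals = [redescription_pvalue(200, 80, 90, k) for k in range(0, 80)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_matches_bruteforce_on_small_grid(self):
        for n in (2, 5, 11, 25):
            for s1 in range(0, n + 1, max(1, n // 4)):
                for s2 in range(0, n + 1, max(1, n // 4)):
                    for ov in range(0, min(s1, s2) + 1):
                        exact = pvalue_bruteforce(n, s1, s2, ov)
                        got = redescription_pvalue(n, s1, s2, ov)
                        assert got == pytest.approx(exact, rel=1e-10)

    def test_log_space_finite_deep_in_tail(self):
        lg = redescription_log10_pvalue(820, 204, 172, 156)
        assert math.isfinite(lg) and lg < -17


# -- quality screening --------------------------------------------------------

class TestCheckQuality:
    def _example_red(self):
        # 820 instances: 156 in both supports, 48 only q1, 16 only q2
        x = np.array([1.0] * 156 + [1.0] * 48 + [9.0] * 16 + [9.0] * 600)
        y = np.array([1.0] * 156 + [9.0] * 48 + [1.0] * 16 + [9.0] * 600)
        data = make_dataset({"x": x}, {"y": y})
        q1 = ConjunctiveQuery(1, (Condition("x", lo=0.0, hi=2.0),))
        q2 = ConjunctiveQuery(2, (Condition("y", lo=0.0, hi=2.0),))
        return Redescription(q1, q2, data)

    def test_example_shaped_redescription_passes(self):
        r = self._example_red()
        assert r.jqnm == pytest.approx(156 / 220)
        q = QualityConstraints(min_jaccard=0.2, max_pvalue=0.01,
                               support_interval=(100, 410))
        ok, reasons = check_quality(r, q)
        assert ok and not reasons

    def test_fail_reasons(self):
        r = self._example_red()
        ok, reasons = check_quality(r, QualityConstraints(min_jaccard=0.8))
        assert not ok and reasons == ["jaccard"]
        ok, reasons = check_quality(
            r, QualityConstraints(support_interval=(157, 400)))
        assert not ok and "support" in reasons
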