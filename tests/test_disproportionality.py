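"""ROR / information-component statistics against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibrovig.cohort import build_cohort
from fibrovig.disproportionality import (ContingencyTable, SignalStats,
                                         backsolve_drug_total,
                                         build_contingency, compute_ic,
                                         compute_ror, evaluate_signal,
                                         intersect_signal_sets, signal_set,
                                         signals_from_printed,
                                         table_from_aggregates)
from fibrovig.io import AggregatedCounts
from fibrovig import reference as ref

# the published methotrexate row reconstructed from aggregated counts
MTX = ContingencyTable(a=1097, b=3750, c=217662, d=3266408)


class TestRor:
    def test_symmetric_table_is_null(self):
        r = compute_ror(ContingencyTable(10, 10, 100, 100))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high

    def test_hand_arithmetic(self):
        # a*d/(b*c) = 2*4/(1*3)
        r = compute_ror(ContingencyTable(2, 1, 3, 4))
        assert r.ror == pytest.approx(8 / 3, abs=1e-12)

    def test_published_methotrexate_row(self):
        r = compute_ror(MTX)
        assert r.ror == pytest.approx(4.39, abs=0.005)
        assert r.ci_low == pytest.approx(4.11, abs=0.015)
        assert r.ci_high == pytest.approx(4.70, abs=0.015)

    def test_zero_cell_undefined_without_continuity(self):
        r = compute_ror(ContingencyTable(0, 5, 10, 100))
        assert math.isnan(r.ror) and math.isnan(r.ci_low)
        r2 = compute_ror(ContingencyTable(0, 5, 10, 100), continuity=0.5)
        assert r2.ror > 0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestIc:
    def test_observed_equals_expected_gives_zero(self):
        # (2,98,98,4802): expected = 100*100/5000 = 2
        t = ContingencyTable(2, 98, 98, 4802)
        assert compute_ic(t, shrinkage=True).ic == pytest.approx(0.0, abs=1e-12)
        assert compute_ic(t, shrinkage=False).ic == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("table, printed_ic", [
        (MTX, 1.85),
        (ContingencyTable(287, 4560, 146880, 3337190), 0.49),  # rituximab reconstruction
    ])
    def test_published_ic_values(self, table, printed_ic):
        assert round(compute_ic(table).ic, 2) == printed_ic

    def test_sign_property_without_shrinkage(self):
        for t in (ContingencyTable(5, 50, 50, 5000), ContingencyTable(1, 99, 99, 801)):
            ic = compute_ic(t, shrinkage=False)
            assert (ic.ic > 0) == (t.a > t.expected)

    def test_shrunken_ic_finite_at_zero_and_monotone_in_a(self):
        values = [compute_ic(ContingencyTable(a, 50, 100, 5000),
                             ic025_method="skip").ic for a in range(0, 30)]
        assert all(np.isfinite(values))
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_credibility_bound_strictly_below_ic(self):
        for a in (0, 1, 5, 100, 1097):
            r = compute_ic(ContingencyTable(a, 50, 100, 5000))
            assert r.ic025 < r.ic

    def test_gamma_quantile_agrees_with_monte_carlo(self):
        rng = np.random.default_rng(5)
        for t in (MTX, ContingencyTable(3, 100, 50, 9000),
                  ContingencyTable(42, 4805, 9000, 3470000)):
            g = compute_ic(t, ic025_method="gamma").ic025
            mc = compute_ic(t, ic025_method="mc", n_mc=400_000, rng=rng).ic025
            assert g == pytest.approx(mc, abs=0.02)


class TestAggregatedTables:
    def test_reconstruction_example(self):
        t = table_from_aggregates(
            AggregatedCounts("methotrexate", 1097, 218759), 4847, 3_488_917)
        assert (t.a, t.b, t.c, t.d) == (1097, 3750, 217662, 3266408)

    def test_boundary_all_reports_are_drug(self):
        t = table_from_aggregates(AggregatedCounts("x", 10, 100), 10, 100)
        assert t.b == 0 and t.d == 0

    def test_negative_derived_cell_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            table_from_aggregates(AggregatedCounts("x", 5, 10), 3, 100)

    def test_backsolved_total_inverts_published_ror(self):
        n_total = backsolve_drug_total(1097, 4.39, 4847, 3_488_917)
        t = table_from_aggregates(AggregatedCounts("methotrexate", 1097, n_total),
                                  4847, 3_488_917)
        assert compute_ror(t).ror == pytest.approx(4.39, abs=0.005)


class TestSignalCriteria:
    @staticmethod
    def _stats(n, low, high, ic025):
        return SignalStats("x", None, n, math.nan, (low, high),
                           math.nan, ic025, math.nan, False)

    def test_golimumab_discordance(self):
        # ROR CI excludes 1 but the credibility bound is negative: no signal
        assert not evaluate_signal(self._stats(71, 1.02, 1.63, -0.03))

    def test_small_count_blocks_huge_ror(self):
        assert not evaluate_signal(self._stats(2, 50.0, 500.0, 3.0))

    def test_tocilizumab_positive(self):
        assert evaluate_signal(self._stats(142, 1.08, 1.51, 0.07))

    def test_published_tables_verdicts(self):
        viga = signals_from_printed(ref.load_vigiaccess_signals())
        faers = signals_from_printed(ref.load_faers_restricted_signals())
        assert len(signal_set(viga)) == 8
        inter = intersect_signal_sets(signal_set(faers), signal_set(viga))
        assert inter == ["leflunomide", "methotrexate", "rituximab",
                         "sulfasalazine", "tocilizumab"]

    def test_intersection_algebra(self):
        assert intersect_signal_sets({"a", "b"}, set()) == []
        assert intersect_signal_sets({"a", "b"}, {"a", "b"}) == ["a", "b"]


@settings(derandomize=True, max_examples=200, deadline=None)
@given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                 st.integers(0, 500), st.integers(1, 500)))
def test_table_invariants(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    r = compute_ror(t)
    if min(a, b, c, d) > 0:
        assert r.ci_low <= r.ror <= r.ci_high
        assert r.ror == pytest.approx(float(Fraction(a * d, b * c)), rel=1e-12)
    else:
        assert math.isnan(r.ror)
    ic = compute_ic(t)
    assert np.isfinite(ic.ic)
    assert ic.ic025 < ic.ic


def test_cohort_tables_match_bruteforce_labels(full_cohort, dictionary):
    """Per-drug cells equal exhaustive report-level counting, exactly."""
    reports = full_cohort.reports
    expo = full_cohort.exposures
    for drug in ("methotrexate", "rituximab", "apremilast"):
        t = build_contingency(full_cohort, drug, dictionary)
        exposed = set(expo.loc[expo["generic"] == drug, "case_id"])
        a = b = c = d = 0
        for row in reports.itertuples(index=False):
            if row.case_id in exposed:
                a, c = (a + 1, c) if row.is_pf else (a, c + 1)
            else:
                b, d = (b + 1, d) if row.is_pf else (b, d + 1)
        assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
        # marginal conservation
        assert t.a + t.b == full_cohort.n_pf
        assert t.a + t.c == len(exposed)
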