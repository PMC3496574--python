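from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from dmetkit import (
    AnalysisOptions,
    CapacityError,
    ConfigurationError,
    analyze,
    bonferroni,
    build_contingency,
    canonicalize_genotype,
    fdr_bh,
    fisher_exact_2x2,
    fisher_exact_rxc,
    generate_dataset,
    max_frequency_difference,
    prefilter,
    sort_results,
)
from dmetkit.io import DmetDataset

from oracles import bh_adjust_exact, fisher_p_exact

OPTS = AnalysisOptions(class_a="A", class_b="B")


class TestContingency:
    def test_table1_probe1(self, table1_dataset):
        cs = build_contingency(table1_dataset, "Probe1", OPTS)
        assert cs.categories == ("C/C", "T/T")
        assert cs.counts.tolist() == [[2, 0], [0, 2]]
        assert not cs.degenerate

    def test_table1_probe3_single_category(self, table1_dataset):
        cs = build_contingency(table1_dataset, "Probe3", OPTS)
        assert cs.categories == ("C/T",)
        assert cs.counts.tolist() == [[2], [2]]

    def _with_nocall(self):
        rows = [["C/C", "NoCall", "T/T", "T/T"]]
        return DmetDataset(
            ["P1"],
            ["S1", "S2", "S3", "S4"],
            [[canonicalize_genotype(c) for c in rows[0]]],
            {"S1": "A", "S2": "A", "S3": "B", "S4": "B"},
        )

    def test_nocall_excluded_by_default(self):
        cs = build_contingency(self._with_nocall(), "P1", OPTS)
        assert cs.row_sums.tolist() == [1, 2]
        assert cs.n_excluded_nocall == (1, 0)

    def test_nocall_as_category(self):
        opts = AnalysisOptions("A", "B", nocall_policy="as_category")
        cs = build_contingency(self._with_nocall(), "P1", opts)
        assert "NoCall" in cs.categories
        assert cs.row_sums.tolist() == [2, 2]

    def test_all_nocall_class_is_degenerate(self):
        ds = DmetDataset(
            ["P1"],
            ["S1", "S2"],
            [[canonicalize_genotype("NoCall"), canonicalize_genotype("C/C")]],
            {"S1": "A", "S2": "B"},
        )
        assert build_contingency(ds, "P1", OPTS).degenerate


class TestFisher2x2:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[2, 0], [0, 2]], 1 / 3),  # enumeration over margins (2,2)/(2,2)
            ([[2, 2], [2, 2]], 1.0),
            ([[5, 0], [0, 5]], 2 / 252),  # enumeration; C(10,5)=252
            ([[1, 0], [0, 0]], 1.0),  # single-count degenerate margins
        ],
    )
    def test_frozen_examples(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [0, 0]])

    @given(
        cells=st.tuples(*[st.integers(min_value=0, max_value=12)] * 4).filter(
            lambda t: sum(t) > 0
        )
    )
    def test_matches_scipy_and_symmetries(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        p = fisher_exact_2x2(table)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(scipy_fisher(table)[1], rel=1e-7, abs=1e-12)
        assert fisher_exact_2x2([[c, d], [a, b]]) == pytest.approx(p, rel=1e-12)
        assert fisher_exact_2x2([[b, a], [d, c]]) == pytest.approx(p, rel=1e-12)


class TestFisherRxc:
    def test_single_category_returns_one(self):
        assert fisher_exact_rxc([[2], [2]]) == 1.0

    def test_reduces_to_2x2(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_rxc(t) == pytest.approx(
                fisher_exact_2x2(t), rel=1e-10
            )

    def test_matches_rational_oracle_on_2x3(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            t = rng.integers(0, 5, size=(2, 3))
            if t.sum() == 0:
                continue
            expected = float(fisher_p_exact(t))
            assert fisher_exact_rxc(t) == pytest.approx(expected, rel=1e-9)

    def test_capacity_error_for_huge_tables(self):
        big = np.full((2, 8), 40, dtype=int)
        with pytest.raises(CapacityError, match="per_symbol"):
            fisher_exact_rxc(big, max_tables=1000)


class TestPrefilter:
    def test_table1_probe1_passes_half_threshold(self, table1_dataset):
        cs = build_contingency(table1_dataset, "Probe1", OPTS)
        assert max_frequency_difference(cs) == pytest.approx(1.0)
        assert prefilter(cs, 0.5)

    def test_table1_probe3_never_passes(self, table1_dataset):
        cs = build_contingency(table1_dataset, "Probe3", OPTS)
        assert not prefilter(cs, 0.0)

    def test_zero_difference_not_kept_at_zero_threshold(self, table1_dataset):
        cs = build_contingency(table1_dataset, "Probe3", OPTS)
        assert max_frequency_difference(cs) == 0.0
        assert not prefilter(cs, 0.0)

    def test_monotone_in_threshold(self, table1_dataset):
        for pid in table1_dataset.probe_ids:
            cs = build_contingency(table1_dataset, pid, OPTS)
            kept = [prefilter(cs, t) for t in (0.0, 0.25, 0.5, 0.75, 1.0)]
            # once dropped, never re-kept at a higher threshold
            assert kept == sorted(kept, reverse=True)


class TestCorrections:
    def test_bonferroni_examples(self):
        assert bonferroni([1e-5], 1936) == [pytest.approx(0.01936)]
        assert bonferroni([0.01], 1936) == [1.0]
        assert bonferroni([0.2], 1) == [0.2]

    def test_bonferroni_rejects_small_universe(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)

    def test_bh_worked_example(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        assert fdr_bh([1.0, 1.0]) == [1.0, 1.0]
        assert fdr_bh([0.3]) == [0.3]
        assert fdr_bh([]) == []

    @given(
        ps=st.lists(
            st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
            min_size=1,
            max_size=30,
        )
    )
    def test_bh_matches_definition_and_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = fdr_bh(ps)
        brute = [float(q) for q in bh_adjust_exact(ps)]
        assert ours == pytest.approx(brute, rel=1e-9, abs=1e-12)
        sm = multipletests(ps, method="fdr_bh")[1]
        assert ours == pytest.approx(list(sm), rel=1e-9, abs=1e-12)

    @given(
        ps=st.lists(
            st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=25
        )
    )
    def test_corrections_are_ordered_and_rank_preserving(self, ps):
        bonf = bonferroni(ps, len(ps))
        bh = fdr_bh(ps)
        for raw, qb, qf in zip(ps, bonf, bh):
            assert qb >= raw - 1e-15 and qf >= raw - 1e-15
            assert qf <= qb + 1e-12
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(np.asarray(bonf)[order]) >= -1e-12)
        assert np.all(np.diff(np.asarray(bh)[order]) >= -1e-12)


class TestAnalyze:
    def test_table1_worked_example(self, table1_dataset):
        results = analyze(table1_dataset, OPTS)
        by_key = {(r.probe_id, r.tested_symbol): r for r in results}
        assert by_key[("Probe1", "C/C")].p_raw == pytest.approx(1 / 3, rel=1e-12)
        assert by_key[("Probe3", "C/T")].p_raw == 1.0
        ranked = sort_results(results, by="p_value")
        assert ranked[0].probe_id == "Probe1"

    def test_prefilter_skips_invariant_probe(self, table1_dataset):
        opts = AnalysisOptions("A", "B", prefilter_threshold=0.0)
        results = analyze(table1_dataset, opts)
        probe3 = [r for r in results if r.probe_id == "Probe3"]
        assert len(probe3) == 1 and probe3[0].prefiltered
        assert probe3[0].p_raw is None

    def test_correction_universe_counts_performed_tests(self, table1_dataset):
        results = [r for r in analyze(table1_dataset, OPTS) if not r.prefiltered]
        m = len(results)
        for r in results:
            assert r.p_bonferroni == pytest.approx(min(1.0, m * r.p_raw))
            assert r.p_fdr >= r.p_raw - 1e-15

    def test_omnibus_mode_one_test_per_probe(self, table1_dataset):
        results = analyze(table1_dataset, AnalysisOptions("A", "B", mode="omnibus"))
        assert [r.tested_symbol for r in results] == ["omnibus"] * 4
        probe1 = results[0]
        assert probe1.p_raw == pytest.approx(
            float(fisher_p_exact(probe1.table)), rel=1e-9
        )

    def test_probe_order_permutation_equivariance(self, table1_dataset):
        from dmetkit import select_probes

        perm = ["Probe3", "Probe1", "Probe4", "Probe2"]
        base = {(r.probe_id, r.tested_symbol): r.p_raw for r in analyze(table1_dataset, OPTS)}
        permuted = {
            (r.probe_id, r.tested_symbol): r.p_raw
            for r in analyze(select_probes(table1_dataset, perm), OPTS)
        }
        assert base == permuted

    def test_configuration_errors(self, table1_dataset):
        with pytest.raises(ConfigurationError):
            AnalysisOptions("A", "A")
        with pytest.raises(ConfigurationError):
            analyze(table1_dataset, AnalysisOptions("A", "Z"))

    def test_null_data_is_conservative_small(self):
        ds, _ = generate_dataset(m_null=400, m_assoc=0, n_class_a=10, n_class_b=10, seed=3)
        results = [r for r in analyze(ds, OPTS) if r.p_raw is not None]
        frac = np.mean([r.p_raw < 0.05 for r in results])
        alpha = 0.05
        assert frac <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / len(results))

    def test_sort_results_modes(self, table1_dataset):
        results = analyze(table1_dataset, OPTS)
        alpha = sort_results(results, by="probe_id")
        assert [r.probe_id for r in alpha] == sorted(r.probe_id for r in results)
        with pytest.raises(ConfigurationError):
            sort_results(results, by="effect_size")
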