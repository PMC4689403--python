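"""The filtering workflow: stages, traces, margins, set operations."""

import dataclasses

import numpy as np
import pytest

from ttnpop import consequence as cq
from ttnpop.filters import (
    FilterConfigError,
    PipelineConfig,
    compare_callsets,
    concordance_filter,
    coverage_filter,
    quality_filter,
    run_pipeline,
    transcript_filter,
)
from ttnpop.gene_model import ALL_TRANSCRIPTS
from ttnpop.variant_io import CoverageRecord, CoverageTable, VariantRecord, variant_key


def _rec(pos, status="PASS", ac=1):
    return VariantRecord(chrom="c", pos=pos, ref="A", alt="T", AC=ac, AN=100,
                         filter_status=status)


class TestQualityFilter:
    def test_pass_retained_nonpass_traced(self):
        records = [_rec(1), _rec(2), _rec(3), _rec(4, "LowQual"), _rec(5, "q10")]
        kept, trace = quality_filter(records)
        assert len(kept) == 3
        assert trace.n_in == 5 and trace.n_out == 3
        assert len(trace.removed_keys) == 2

    def test_all_pass_is_identity(self):
        records = [_rec(1), _rec(2)]
        kept, trace = quality_filter(records)
        assert kept == records
        assert trace.removed_keys == []

    def test_simulated_pass_fraction_recovered(self, sim_cohort, sim_config):
        records = sim_cohort.records_by_dataset[sim_config.superset]
        kept, trace = quality_filter(records)
        expected = sum(1 for r in records if r.filter_status == "PASS")
        assert trace.n_out == expected


class TestTranscriptFilter:
    def test_removes_isoform_and_low_psi_calls(self, sim_model, sim_cohort, sim_config):
        from ttnpop.variant_io import normalize_variant

        calls = [
            cq.classify_variant(sim_model, normalize_variant(sim_model, r))
            for r in sim_cohort.records_by_dataset[sim_config.superset]
        ]
        kept, trace = transcript_filter(calls, sim_model, 0.15)
        truth = sim_cohort.truth_by_key()
        for call in kept:
            assert truth[call.key].exon_class == ALL_TRANSCRIPTS
        removed = {k for k in trace.removed_keys}
        for call in calls:
            if truth[call.key].exon_class != ALL_TRANSCRIPTS:
                assert call.key in removed


class TestCoverageFilter:
    def _calls(self, positions):
        return [
            cq.ConsequenceCall(
                key=("c", p, "A", "T"), consequence_class=cq.NONSENSE,
                record=_rec(p),
            )
            for p in positions
        ]

    def test_low_depth_removed(self):
        table = CoverageTable([CoverageRecord("c", 1, 8.0), CoverageRecord("c", 2, 60.0)])
        kept, trace = coverage_filter(self._calls([1, 2]), table, 15)
        assert [c.key[1] for c in kept] == [2]

    def test_zero_threshold_is_identity(self):
        table = CoverageTable([CoverageRecord("c", 1, 8.0)])
        kept, trace = coverage_filter(self._calls([1]), table, 0)
        assert len(kept) == 1

    def test_uncovered_position_flagged_and_removed(self):
        table = CoverageTable([CoverageRecord("c", 1, 60.0)])
        kept, trace = coverage_filter(self._calls([1, 99]), table, 15)
        assert len(kept) == 1
        assert any(n.startswith("uncovered") for n in trace.notes)


class TestConcordanceFilter:
    def _calls(self, positions, dataset):
        return [
            cq.ConsequenceCall(
                key=("c", p, "A", "T"), consequence_class=cq.NONSENSE,
                record=dataclasses.replace(_rec(p), dataset=dataset),
            )
            for p in positions
        ]

    def test_subset_unique_removed_superset_untouched(self):
        by_ds = {
            "SUP": self._calls([1, 2, 3], "SUP"),
            "SUB": self._calls([2, 9], "SUB"),
        }
        out, traces, overlaps = concordance_filter(by_ds, "SUP")
        assert [c.key[1] for c in out["SUB"]] == [2]
        assert len(out["SUP"]) == 3
        assert traces["SUP"].removed_keys == []

    def test_subset_shared_retained_and_counted(self):
        """A key shared by two subsets survives whatever the superset holds."""
        by_ds = {
            "SUP": self._calls([1], "SUP"),
            "A": self._calls([5, 6], "A"),
            "B": self._calls([5, 7], "B"),
        }
        out, traces, overlaps = concordance_filter(by_ds, "SUP")
        assert overlaps[("A", "B")] == 1
        assert [c.key[1] for c in out["A"]] == [5]
        assert [c.key[1] for c in out["B"]] == [5]

    def test_flag_only_mode_keeps_everything(self):
        by_ds = {"SUP": self._calls([1], "SUP"), "SUB": self._calls([9], "SUB")}
        out, traces, _ = concordance_filter(by_ds, "SUP", flag_only=True)
        assert len(out["SUB"]) == 1
        assert traces["SUB"].notes

    def test_missing_superset_is_config_error(self):
        with pytest.raises(FilterConfigError):
            concordance_filter({"A": []}, "SUP")


class TestPipeline:
    def test_empty_input_emits_six_zero_traces(self, sim_model):
        result = run_pipeline({"D": []}, sim_model, PipelineConfig())
        assert result.calls_by_dataset["D"] == []
        traces = result.traces_by_dataset["D"]
        assert [t.stage for t in traces] == [
            "quality", "annotate", "truncating", "transcript", "concordance", "coverage",
        ]
        assert all(t.n_in == 0 and t.n_out == 0 for t in traces)

    def test_table1_margins(self, table1_fixture):
        """The margin-matched cohort reproduces the published workflow counts:
        470 truncating in, 247 removed as not-all-transcripts, 50 removed by
        coverage, 173 out."""
        fx = table1_fixture
        config = PipelineConfig(superset_dataset=fx.superset)
        result = run_pipeline(fx.records_by_dataset, fx.model, config, fx.coverage)
        t = {tr.stage: tr for tr in result.traces_by_dataset["ExAC"]}
        assert t["truncating"].n_out == 470
        assert t["transcript"].n_in == 470 and t["transcript"].n_out == 223
        assert len(t["transcript"].removed_keys) == 247
        assert t["coverage"].n_out == 173
        assert len(result.calls_by_dataset["ExAC"]) == 173
        assert len(result.calls_by_dataset["1KG"]) == 9
        assert len(result.calls_by_dataset["ESP"]) == 16

    def test_surviving_calls_satisfy_postconditions(self, sim_model, sim_cohort, sim_config):
        config = PipelineConfig(superset_dataset=sim_config.superset)
        result = run_pipeline(
            sim_cohort.records_by_dataset, sim_model, config, sim_cohort.coverage
        )
        for ds, calls in result.calls_by_dataset.items():
            for call in calls:
                assert cq.is_ttntv(call)
                assert call.affects_all
                assert sim_model.exon_class(call.exon_id, 0.15) == ALL_TRANSCRIPTS
                depth = sim_cohort.coverage.get(call.key[0], call.key[1]).mean_depth
                assert depth >= config.min_mean_depth

    def test_planted_false_positives_removed_by_concordance(
        self, sim_model, sim_cohort, sim_config
    ):
        config = PipelineConfig(superset_dataset=sim_config.superset)
        result = run_pipeline(
            sim_cohort.records_by_dataset, sim_model, config, sim_cohort.coverage
        )
        fp_keys = {t.key for t in sim_cohort.truth if t.false_positive}
        for ds, calls in result.calls_by_dataset.items():
            assert fp_keys.isdisjoint({c.key for c in calls})
        # and every one that survived to the concordance stage is in its trace
        for ds in result.traces_by_dataset:
            if ds == sim_config.superset:
                continue
            conc_removed = set(result.trace(ds, "concordance").removed_keys)
            assert conc_removed <= fp_keys | {
                t.key for t in sim_cohort.truth if ds not in t.datasets
            } | {t.key for t in sim_cohort.truth}

    def test_output_independent_of_record_order(self, sim_model, sim_cohort, sim_config):
        config = PipelineConfig(superset_dataset=sim_config.superset)
        res_a = run_pipeline(
            sim_cohort.records_by_dataset, sim_model, config, sim_cohort.coverage
        )
        rng = np.random.default_rng(1)
        shuffled = {}
        for ds, records in sim_cohort.records_by_dataset.items():
            perm = list(rng.permutation(len(records)))
            shuffled[ds] = [records[i] for i in perm]
        res_b = run_pipeline(shuffled, sim_model, config, sim_cohort.coverage)
        for ds in res_a.calls_by_dataset:
            assert {c.key for c in res_a.calls_by_dataset[ds]} == {
                c.key for c in res_b.calls_by_dataset[ds]
            }

    def test_rerun_on_own_output_is_identity(self, sim_model, sim_cohort, sim_config):
        config = PipelineConfig(superset_dataset=sim_config.superset)
        res = run_pipeline(
            sim_cohort.records_by_dataset, sim_model, config, sim_cohort.coverage
        )
        again_input = {
            ds: [c.record for c in calls] for ds, calls in res.calls_by_dataset.items()
        }
        res2 = run_pipeline(again_input, sim_model, config, sim_cohort.coverage)
        for ds in again_input:
            assert {c.key for c in res2.calls_by_dataset[ds]} == {
                c.key for c in res.calls_by_dataset[ds]
            }

    def test_trace_accounting_balances(self, table1_fixture):
        """Removed counts after the truncating stage plus the final count equal
        the truncating-stage output."""
        fx = table1_fixture
        config = PipelineConfig(superset_dataset=fx.superset)
        result = run_pipeline(fx.records_by_dataset, fx.model, config, fx.coverage)
        for ds, traces in result.traces_by_dataset.items():
            by_stage = {t.stage: t for t in traces}
            entering = by_stage["truncating"].n_out
            removed = sum(
                len(by_stage[s].removed_keys)
                for s in ("transcript", "concordance", "coverage")
            )
            assert entering - removed == len(result.calls_by_dataset[ds])


class TestCompareCallsets:
    def test_identical_sets(self):
        a = [_rec(1), _rec(2)]
        shared, only_a, only_b = compare_callsets(a, list(a))
        assert len(shared) == 2 and not only_a and not only_b

    def test_disjoint_sets(self):
        shared, only_a, only_b = compare_callsets([_rec(1)], [_rec(2)])
        assert not shared and len(only_a) == 1 and len(only_b) == 1

    def test_random_split_partition_sizes(self, sim_cohort, sim_config):
        records = sim_cohort.records_by_dataset[sim_config.superset]
        rng = np.random.default_rng(9)
        mask = rng.random(len(records)) < 0.5
        a = [r for r, m in zip(records, mask) if m] + records[:10]
        b = [r for r, m in zip(records, mask) if not m] + records[:10]
        shared, only_a, only_b = compare_callsets(a, b)
        keys = [variant_key(r) for r in records]
        expected_shared = set(keys[:10])
        assert shared == expected_shared
        assert len(only_a) == len({variant_key(r) for r in a}) - len(expected_shared)
        assert len(only_b) == len({variant_key(r) for r in b}) - len(expected_shared)

    def test_raw_subset_overlap_is_three_shared_splice_variants(self, table1_fixture):
        fx = table1_fixture
        shared, _, _ = compare_callsets(
            fx.records_by_dataset["1KG"], fx.records_by_dataset["ESP"]
        )
        assert len(shared) == 3
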