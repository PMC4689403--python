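"""The truncation filtering workflow.

Raw per-dataset call sets are reduced to the "affects all transcripts,
expressed in left ventricle, well covered" truncating-variant set in a fixed
stage order:

1. quality       - keep records whose FILTER is PASS
2. annotate      - normalise alleles and call consequences on the gene model
3. truncating    - keep nonsense / frameshift / essential splice calls
4. transcript    - drop calls in isoform-specific or low-PSI exons
                   (adjacent exon for splice calls)
5. concordance   - drop calls unique to a subset call set and absent from the
                   designated superset call set (likely false positives)
6. coverage      - drop calls at positions below the mean-depth threshold

Every stage emits a :class:`FilterTrace` so the effect of each filter is
reportable, and the final call sets carry full annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from ttnpop import consequence as cq
from ttnpop.gene_model import ALL_TRANSCRIPTS, GeneModel
from ttnpop.variant_io import (
    CoverageTable,
    VariantRecord,
    normalize_variant,
    variant_key,
)


class FilterConfigError(ValueError):
    pass


@dataclass
class FilterTrace:
    stage: str
    n_in: int
    n_out: int
    removed_keys: list[tuple] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_out != self.n_in - len(self.removed_keys):
            raise ValueError(
                f"trace {self.stage}: n_out {self.n_out} != n_in {self.n_in} - "
                f"{len(self.removed_keys)} removed"
            )


@dataclass
class PipelineConfig:
    psi_threshold: float = 0.15
    min_mean_depth: float = 15.0
    superset_dataset: str | None = None
    flag_only: bool = False
    reference_transcript: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


# -- individual stages -------------------------------------------------------


def quality_filter(records: list[VariantRecord]) -> tuple[list[VariantRecord], FilterTrace]:
    """Retain records that passed all upstream quality filters."""
    kept = [r for r in records if r.filter_status == "PASS"]
    removed = [variant_key(r) for r in records if r.filter_status != "PASS"]
    return kept, FilterTrace("quality", len(records), len(kept), removed)


def ttntv_filter(calls: list[cq.ConsequenceCall]) -> tuple[list[cq.ConsequenceCall], FilterTrace]:
    """Retain truncating calls: nonsense, frameshift, essential splice."""
    kept = [c for c in calls if cq.is_ttntv(c)]
    removed = [c.key for c in calls if not cq.is_ttntv(c)]
    return kept, FilterTrace("truncating", len(calls), len(kept), removed)


def transcript_filter(
    calls: list[cq.ConsequenceCall],
    model: GeneModel,
    psi_threshold: float = 0.15,
) -> tuple[list[cq.ConsequenceCall], FilterTrace]:
    """Drop calls in exons that are isoform-specific or weakly expressed.

    The call's exon is the containing exon, or the adjacent exon for splice
    calls.  Calls without any exon context are dropped too (they cannot
    affect all transcripts).
    """
    kept, removed = [], []
    for call in calls:
        if (
            call.exon_id is not None
            and model.exon_class(call.exon_id, psi_threshold) == ALL_TRANSCRIPTS
        ):
            kept.append(call)
        else:
            removed.append(call.key)
    return kept, FilterTrace("transcript", len(calls), len(kept), removed)


def coverage_filter(
    calls: list[cq.ConsequenceCall],
    coverage: CoverageTable,
    min_mean_depth: float = 15.0,
) -> tuple[list[cq.ConsequenceCall], FilterTrace]:
    """Retain calls at positions with mean depth at or above the threshold.

    Positions absent from the coverage table are flagged as "uncovered" in the
    trace notes and removed rather than silently kept.
    """
    kept, removed, notes = [], [], []
    for call in calls:
        chrom, pos, _, _ = call.key
        rec = coverage.get(chrom, pos)
        if rec is None:
            removed.append(call.key)
            notes.append(f"uncovered:{chrom}:{pos}")
        elif rec.mean_depth >= min_mean_depth:
            kept.append(call)
        else:
            removed.append(call.key)
    return kept, FilterTrace("coverage", len(calls), len(kept), removed, notes)


def concordance_filter(
    calls_by_dataset: dict[str, list[cq.ConsequenceCall]],
    superset_dataset: str,
    flag_only: bool = False,
) -> tuple[dict[str, list[cq.ConsequenceCall]], dict[str, FilterTrace], dict]:
    """Drop subset-only calls absent from the superset call set.

    Superset calls are never removed.  Calls shared between two subset call
    sets are retained whatever the superset contains, and counted in the
    returned overlap report ``{(ds_a, ds_b): shared key count}``.
    With ``flag_only`` nothing is removed; removals appear only in the traces.
    """
    if superset_dataset not in calls_by_dataset:
        raise FilterConfigError(
            f"superset dataset {superset_dataset!r} not among "
            f"{sorted(calls_by_dataset)}"
        )
    keys = {ds: {c.key for c in calls} for ds, calls in calls_by_dataset.items()}
    super_keys = keys[superset_dataset]
    subset_names = [ds for ds in calls_by_dataset if ds != superset_dataset]
    overlaps = {}
    for i, a in enumerate(subset_names):
        for b in subset_names[i + 1 :]:
            overlaps[(a, b)] = len(keys[a] & keys[b])
    shared_subset_keys: set = set()
    for i, a in enumerate(subset_names):
        for b in subset_names[i + 1 :]:
            shared_subset_keys |= keys[a] & keys[b]
    out, traces = {}, {}
    for ds, calls in calls_by_dataset.items():
        if ds == superset_dataset:
            out[ds] = list(calls)
            traces[ds] = FilterTrace("concordance", len(calls), len(calls), [])
            continue
        removable = [
            c.key
            for c in calls
            if c.key not in super_keys and c.key not in shared_subset_keys
        ]
        if flag_only:
            kept = list(calls)
            traces[ds] = FilterTrace(
                "concordance", len(calls), len(calls), [],
                notes=[f"flagged:{k}" for k in removable],
            )
        else:
            removed_set = set(removable)
            kept = [c for c in calls if c.key not in removed_set]
            traces[ds] = FilterTrace("concordance", len(calls), len(kept), removable)
        out[ds] = kept
    return out, traces, overlaps


# -- full pipeline -----------------------------------------------------------


@dataclass
class PipelineResult:
    calls_by_dataset: dict[str, list[cq.ConsequenceCall]]
    traces_by_dataset: dict[str, list[FilterTrace]]
    overlaps: dict

    def trace(self, dataset: str, stage: str) -> FilterTrace:
        for t in self.traces_by_dataset[dataset]:
            if t.stage == stage:
                return t
        raise KeyError(stage)


def run_pipeline(
    records_by_dataset: dict[str, list[VariantRecord]],
    model: GeneModel,
    config: PipelineConfig,
    coverage: CoverageTable | None = None,
) -> PipelineResult:
    """Run the whole filtering workflow over one or more datasets.

    Stage order: quality -> normalise/annotate -> truncating -> transcript ->
    concordance -> coverage.  The concordance stage needs a configured
    superset dataset when more than one dataset is present; with a single
    dataset it is an identity stage.
    """
    if len(records_by_dataset) > 1 and config.superset_dataset is None:
        raise FilterConfigError("multiple datasets require superset_dataset")
    traces: dict[str, list[FilterTrace]] = {ds: [] for ds in records_by_dataset}
    annotated: dict[str, list[cq.ConsequenceCall]] = {}
    for ds, records in records_by_dataset.items():
        passed, t_quality = quality_filter(records)
        traces[ds].append(t_quality)
        normalized = [normalize_variant(model, r) for r in passed]
        calls = cq.annotate_records(
            model, normalized, config.psi_threshold, config.reference_transcript
        )
        traces[ds].append(FilterTrace("annotate", len(calls), len(calls), []))
        calls, t_ttntv = ttntv_filter(calls)
        traces[ds].append(t_ttntv)
        calls, t_tx = transcript_filter(calls, model, config.psi_threshold)
        traces[ds].append(t_tx)
        annotated[ds] = calls
    if len(annotated) > 1:
        annotated, conc_traces, overlaps = concordance_filter(
            annotated, config.superset_dataset, config.flag_only
        )
        for ds, t in conc_traces.items():
            traces[ds].append(t)
    else:
        overlaps = {}
        for ds, calls in annotated.items():
            traces[ds].append(FilterTrace("concordance", len(calls), len(calls), []))
    final: dict[str, list[cq.ConsequenceCall]] = {}
    for ds, calls in annotated.items():
        if coverage is not None:
            calls, t_cov = coverage_filter(calls, coverage, config.min_mean_depth)
        else:
            t_cov = FilterTrace("coverage", len(calls), len(calls), [])
        traces[ds].append(t_cov)
        final[ds] = calls
    return PipelineResult(final, traces, overlaps)


def compare_callsets(a, b) -> tuple[set, set, set]:
    """Exact key partition of two call sets: (shared, only_a, only_b).

    Accepts lists of ConsequenceCall or VariantRecord.
    """
    def keys(calls):
        return {
            c.key if isinstance(c, cq.ConsequenceCall) else variant_key(c)
            for c in calls
        }

    ka, kb = keys(a), keys(b)
    return ka & kb, ka - kb, kb - ka


def traces_frame(traces_by_dataset: dict[str, list[FilterTrace]]):
    """Filter traces as a tidy DataFrame for TSV export."""
    import pandas as pd

    rows = [
        {
            "dataset": ds,
            "stage": t.stage,
            "n_in": t.n_in,
            "n_out": t.n_out,
            "n_removed": len(t.removed_keys),
            "notes": ";".join(t.notes),
        }
        for ds, ts in traces_by_dataset.items()
        for t in ts
    ]
    return pd.DataFrame(rows)
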