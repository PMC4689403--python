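"""Human-readable reports: cohort summary tables, call-set evolution, manifests.

The cohort summary mirrors the layout of published reference-population
truncation tables: rows for the total, per mutation type, per band and band x
type, one column block per dataset, each cell "count (prevalence%)" where the
count is the number of distinct variants and the prevalence is carrier-based
(allele copies minus homozygote double-counting, over the cohort size).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from ttnpop import __version__
from ttnpop import consequence as cq
from ttnpop import popstats

BAND_ORDER = ("Z", "I", "A", "M")
TYPE_LABELS = {
    cq.FRAMESHIFT: "Frameshift",
    cq.NONSENSE: "Nonsense",
    cq.ESSENTIAL_SPLICE: "Splice site",
}
TYPE_ORDER = (cq.FRAMESHIFT, cq.NONSENSE, cq.ESSENTIAL_SPLICE)


def _cell_counts(calls):
    n_variants = len(calls)
    carriers = popstats.carriers_from_calls(calls)
    return n_variants, carriers


def aggregate_counts(calls: list[cq.ConsequenceCall]) -> dict:
    """Variant and carrier counts: total, per type, per band, per band x type."""
    agg = {
        "total": _cell_counts(calls),
        "by_type": {}, "by_band": {}, "by_band_type": {},
    }
    for vtype in TYPE_ORDER:
        agg["by_type"][vtype] = _cell_counts(
            [c for c in calls if c.consequence_class == vtype]
        )
    for band in BAND_ORDER:
        in_band = [c for c in calls if c.band == band]
        agg["by_band"][band] = _cell_counts(in_band)
        for vtype in TYPE_ORDER:
            agg["by_band_type"][(band, vtype)] = _cell_counts(
                [c for c in in_band if c.consequence_class == vtype]
            )
    return agg


def _cell(counts, cohort: int, decimals: int = 3) -> str:
    n, carriers = counts
    if n == 0:
        return "-"
    return f"{n} ({popstats.prevalence(carriers, cohort):.{decimals}f})"


def table1_report(
    aggregates_by_dataset: dict[str, dict],
    cohort_sizes: dict[str, int],
    footnotes: list[str] | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Summary table with one column per dataset, cells "count (prevalence%)"."""
    datasets = list(aggregates_by_dataset)
    rows = []

    def plain_row(label, values):
        rows.append({"row": label, **{ds: str(values[ds]) for ds in datasets}})

    def cell_row(label, picker):
        rows.append(
            {
                "row": label,
                **{
                    ds: _cell(
                        picker(aggregates_by_dataset[ds]), cohort_sizes[ds], decimals
                    )
                    for ds in datasets
                },
            }
        )

    plain_row("Population size", {ds: cohort_sizes[ds] for ds in datasets})
    plain_row(
        "Total TTNtv variant",
        {ds: aggregates_by_dataset[ds]["total"][0] for ds in datasets},
    )
    plain_row(
        "Individuals", {ds: aggregates_by_dataset[ds]["total"][1] for ds in datasets}
    )
    plain_row(
        "Population prevalence (%)",
        {
            ds: f"{popstats.prevalence(aggregates_by_dataset[ds]['total'][1], cohort_sizes[ds]):.{decimals}f}"
            for ds in datasets
        },
    )
    for vtype in TYPE_ORDER:
        cell_row(TYPE_LABELS[vtype], lambda a, v=vtype: a["by_type"][v])
    for band in BAND_ORDER:
        cell_row(f"{band}-band", lambda a, b=band: a["by_band"][b])
    for band in BAND_ORDER:
        for vtype in TYPE_ORDER:
            cell_row(
                f"{band}-band {TYPE_LABELS[vtype]}",
                lambda a, b=band, v=vtype: a["by_band_type"][(b, v)],
            )
    df = pd.DataFrame(rows)
    df.attrs["footnotes"] = list(footnotes or [])
    return df


def write_table1(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for note in df.attrs.get("footnotes", []):
            fh.write(f"# {note}\n")
        df.to_csv(fh, sep="\t", index=False)


def evolution_report(
    callsets: dict[str, list],
    cohort_sizes: dict[str, int],
) -> pd.DataFrame:
    """Per-version class counts, prevalence and attrition against the
    previous version (shared / only-previous / only-current keys)."""
    from ttnpop.filters import compare_callsets

    if len(callsets) < 2:
        raise ValueError("need at least two call-set versions")
    rows = []
    prev_name = None
    for name, calls in callsets.items():
        counts = {
            label: sum(1 for c in calls if c.consequence_class == vclass)
            for vclass, label in (
                (cq.NONSENSE, "nonsense"),
                (cq.FRAMESHIFT, "frameshift"),
                (cq.ESSENTIAL_SPLICE, "essential_splice"),
                (cq.SPLICE_REGION, "splice_region"),
            )
        }
        carriers = popstats.carriers_from_calls(calls)
        row = {
            "version": name,
            "n_variants": len(calls),
            **counts,
            "carriers": carriers,
            "prevalence_pct": round(
                popstats.prevalence(carriers, cohort_sizes[name]), 3
            ),
        }
        if prev_name is not None:
            shared, only_prev, only_curr = compare_callsets(callsets[prev_name], calls)
            row.update(
                shared_with_prev=len(shared),
                only_prev=len(only_prev),
                only_curr=len(only_curr),
            )
        else:
            row.update(shared_with_prev=0, only_prev=0, only_curr=0)
        rows.append(row)
        prev_name = name
    return pd.DataFrame(rows)


# -- run manifest ------------------------------------------------------------


@dataclass
class RunManifest:
    command: str
    config: dict
    seed: int | None = None
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stage_traces: list[dict] = field(default_factory=list)
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path) -> None:
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def write(self, path) -> None:
        data = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "inputs": self.inputs,
            "stage_traces": self.stage_traces,
            "version": self.version,
            "timestamp": self.timestamp
            or datetime.now(timezone.utc).isoformat(timespec="seconds"),
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")
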