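"""Splice-distance allele-frequency-spectrum analysis.

Splice variants are binned by absolute intron distance (1-2 bp = essential
splice sites, 3-4 bp and 5-6 bp = splice region) and each variant is placed in
an allele-frequency class:

* ``private`` - a dataset-wide singleton (AC equal to the configured maximum,
  1 by default);
* ``low_frequency`` - not private, allele frequency below the configured
  bound (0.5% by default, the conventional low-frequency boundary);
* ``common`` - everything else.

Compositions between distance bins are compared with two-sided Fisher's exact
tests, which remain exact at the small counts typical of a single gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from scipy import stats

from ttnpop.consequence import ConsequenceCall

PRIVATE = "private"
LOW_FREQUENCY = "low_frequency"
COMMON = "common"
AFS_CLASSES = (PRIVATE, LOW_FREQUENCY, COMMON)

BIN_ESSENTIAL = "1-2"
BIN_NEAR = "3-4"
BIN_FAR = "5-6"
BIN_ORDER = (BIN_ESSENTIAL, BIN_NEAR, BIN_FAR)


@dataclass(frozen=True)
class AfsConfig:
    private_max_ac: int = 1
    low_freq_max_af: float = 0.005


@dataclass(frozen=True)
class AfsClass:
    label: str
    private_max_ac: int
    low_freq_max_af: float


def afs_class(AC: int, AN: int, config: AfsConfig = AfsConfig()) -> AfsClass:
    """Allele-frequency class of an observed allele; AC must be positive."""
    if AC <= 0:
        raise ValueError(f"AC must be positive for an observed allele, got {AC}")
    if AC > AN:
        raise ValueError(f"AC {AC} exceeds AN {AN}")
    if AC <= config.private_max_ac:
        label = PRIVATE
    elif AC / AN < config.low_freq_max_af:
        label = LOW_FREQUENCY
    else:
        label = COMMON
    return AfsClass(label, config.private_max_ac, config.low_freq_max_af)


def distance_bin(splice_dist: int) -> str | None:
    d = abs(splice_dist)
    if 1 <= d <= 2:
        return BIN_ESSENTIAL
    if 3 <= d <= 4:
        return BIN_NEAR
    if 5 <= d <= 6:
        return BIN_FAR
    return None


@dataclass
class SpliceBinTable:
    """Counts of AFS classes per splice-distance bin."""

    counts: dict[str, Counter]

    def bin_total(self, bin_label: str) -> int:
        return sum(self.counts[bin_label].values())

    def class_count(self, bin_label: str, class_label: str) -> int:
        return self.counts[bin_label].get(class_label, 0)

    def pooled(self, bins: tuple[str, ...]) -> Counter:
        pooled: Counter = Counter()
        for b in bins:
            pooled.update(self.counts[b])
        return pooled


def splice_bin_table(
    calls: list[ConsequenceCall], config: AfsConfig = AfsConfig()
) -> SpliceBinTable:
    """Bin splice-annotated calls by |distance| and AFS class.

    Calls without a splice distance or deeper than 6 bp are excluded.
    """
    counts = {b: Counter() for b in BIN_ORDER}
    for call in calls:
        if call.splice_distance is None:
            continue
        b = distance_bin(call.splice_distance)
        if b is None:
            continue
        cls = afs_class(call.record.AC, call.record.AN, config)
        counts[b][cls.label] += 1
    return SpliceBinTable(counts)


def afs_composition_test(
    table: SpliceBinTable,
    bin_a: str | tuple[str, ...],
    bin_b: str | tuple[str, ...],
    class_label: str,
) -> float:
    """Two-sided Fisher's exact p for [class vs not-class] x [bin_a vs bin_b].

    Each bin argument may be a single bin label or a tuple of labels to pool
    (e.g. ``("3-4", "5-6")`` for all non-essential splice variants).
    """
    def pool(spec) -> Counter:
        bins = (spec,) if isinstance(spec, str) else tuple(spec)
        return table.pooled(bins)

    ca, cb = pool(bin_a), pool(bin_b)
    na, nb = sum(ca.values()), sum(cb.values())
    if na == 0 or nb == 0:
        raise ValueError("empty bin in composition test")
    a_in, b_in = ca.get(class_label, 0), cb.get(class_label, 0)
    contingency = [[a_in, na - a_in], [b_in, nb - b_in]]
    _, p = stats.fisher_exact(contingency, alternative="two-sided")
    return float(p)


def splice_report_frame(
    table: SpliceBinTable, essential_bin: str = BIN_ESSENTIAL
):
    """Per-bin report: n, class fractions and Fisher p vs the essential bin."""
    import pandas as pd

    rows = []
    for b in BIN_ORDER:
        n = table.bin_total(b)
        row = {"bin": b, "n": n}
        for cls in AFS_CLASSES:
            row[f"{cls}_frac"] = table.class_count(b, cls) / n if n else 0.0
        if b != essential_bin and n and table.bin_total(essential_bin):
            row["p_vs_essential"] = afs_composition_test(
                table, b, essential_bin, PRIVATE
            )
        else:
            row["p_vs_essential"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
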