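"""Read, normalise and key site-level variants and per-position coverage.

Input is a VCF v4.2 subset carrying ExAC-style summary counts in INFO
(``AC``, ``AN``, optional ``Hom`` and per-population ``AC_<POP>``/``AN_<POP>``
fields).  No genotype columns are required; allele counts drive every
downstream statistic.  Multi-allelic sites are decomposed into one record per
alternate allele on read.

Allele normalisation follows the standard minimal-representation rule: trim
shared suffix bases (extending left when an allele would empty), trim shared
prefix bases, which left-aligns indels as far as the flanking sequence allows.
The operation is idempotent and preserves the edited haplotype sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import pysam

logger = logging.getLogger(__name__)


class VariantIOError(ValueError):
    """Malformed variant or coverage input."""


@dataclass(frozen=True)
class VariantRecord:
    """One normalised site-level variant with summary allele counts."""

    chrom: str
    pos: int  # 1-based position of the first REF base
    ref: str
    alt: str
    AC: int
    AN: int
    hom_count: int = 0
    qual: float | None = None
    filter_status: str = "PASS"
    pop_counts: tuple[tuple[str, tuple[int, int]], ...] = ()
    dataset: str = "SIM"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise VariantIOError(f"{self.chrom}:{self.pos} ref equals alt ({self.ref})")
        if self.AC > self.AN:
            raise VariantIOError(f"{self.chrom}:{self.pos} AC {self.AC} > AN {self.AN}")
        if 2 * self.hom_count > self.AC:
            raise VariantIOError(
                f"{self.chrom}:{self.pos} hom_count {self.hom_count} inconsistent "
                f"with AC {self.AC}"
            )
        pop_ac = sum(ac for _, (ac, _) in self.pop_counts)
        if self.pop_counts and pop_ac > self.AC:
            raise VariantIOError(
                f"{self.chrom}:{self.pos} per-population AC sum {pop_ac} > AC {self.AC}"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def af(self) -> float:
        return self.AC / self.AN

    def pop_count_map(self) -> dict[str, tuple[int, int]]:
        return dict(self.pop_counts)


@dataclass(frozen=True)
class CoverageRecord:
    chrom: str
    pos: int
    mean_depth: float
    frac_ge: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        fracs = [f for _, f in sorted(self.frac_ge)]
        if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise VariantIOError(
                f"{self.chrom}:{self.pos} frac_ge not non-increasing in threshold"
            )


class CoverageTable:
    """Per-position coverage lookup keyed by (chrom, pos)."""

    def __init__(self, records: list[CoverageRecord]):
        self.records = list(records)
        self._by_pos = {(r.chrom, r.pos): r for r in self.records}

    def get(self, chrom: str, pos: int) -> CoverageRecord | None:
        return self._by_pos.get((chrom, pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def variant_key(rec: VariantRecord) -> tuple[str, int, str, str]:
    """Normalised identity key used for all cross-dataset set operations."""
    return (rec.chrom, rec.pos, rec.ref, rec.alt)


# -- VCF reading -------------------------------------------------------------


def _scalar(value, index: int):
    """Pick the per-allele element from a Number=A INFO value."""
    if isinstance(value, (tuple, list)):
        return value[index]
    return value


def read_vcf(
    path: str | Path,
    region: str | None = None,
    dataset: str | None = None,
) -> list[VariantRecord]:
    """Read a VCF into decomposed, per-alternate-allele site records.

    Multi-allelic records become one :class:`VariantRecord` per ALT with the
    matching per-allele AC/Hom values.  ``region`` is a ``chrom:start-end``
    string filtered in memory (no index required).  ``dataset`` overrides the
    dataset tag (defaults to the file stem).
    """
    path = Path(path)
    if dataset is None:
        dataset = path.stem
    reg_chrom, reg_lo, reg_hi = None, None, None
    if region:
        reg_chrom, span = region.split(":")
        lo, hi = span.split("-")
        reg_lo, reg_hi = int(lo), int(hi)
    records: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise VariantIOError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        pop_labels = sorted(
            key[3:]
            for key in vcf.header.info
            if key.startswith("AC_") and f"AN_{key[3:]}" in vcf.header.info
        )
        for rec in vcf:
            if reg_chrom is not None and (
                rec.chrom != reg_chrom or not (reg_lo <= rec.pos <= reg_hi)
            ):
                continue
            if "AC" not in rec.info or "AN" not in rec.info:
                raise VariantIOError(
                    f"{path.name} {rec.chrom}:{rec.pos}: missing AC/AN INFO field"
                )
            if "Hom" not in rec.info:
                logger.warning(
                    "%s %s:%s: no Hom field, homozygote count defaults to 0",
                    path.name, rec.chrom, rec.pos,
                )
            filters = list(rec.filter.keys())
            filter_status = "PASS" if filters in ([], ["PASS"]) else ";".join(filters)
            for i, alt in enumerate(rec.alts or ()):
                pop_counts = []
                for label in pop_labels:
                    ac_key, an_key = f"AC_{label}", f"AN_{label}"
                    if ac_key in rec.info and an_key in rec.info:
                        pop_counts.append(
                            (
                                label,
                                (
                                    int(_scalar(rec.info[ac_key], i)),
                                    int(_scalar(rec.info[an_key], i)),
                                ),
                            )
                        )
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        AC=int(_scalar(rec.info["AC"], i)),
                        AN=int(rec.info["AN"]),
                        hom_count=int(_scalar(rec.info.get("Hom", 0), i)),
                        qual=rec.qual,
                        filter_status=filter_status,
                        pop_counts=tuple(pop_counts),
                        dataset=dataset,
                    )
                )
    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return records


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">
##INFO=<ID=Hom,Number=A,Type=Integer,Description="Homozygous-alternate individual count">
{pop_lines}##FILTER=<ID=LowQual,Description="Failed quality filters">
##contig=<ID={chrom},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    records: list[VariantRecord],
    path: str | Path,
    chrom: str,
    contig_length: int,
) -> Path:
    """Write site records as an uncompressed VCF v4.2 text file.

    Plain-text emission keeps the output byte-deterministic; files are read
    back through :func:`read_vcf` (pysam), so round-trips are exercised.
    """
    path = Path(path)
    pop_labels = sorted({label for r in records for label, _ in r.pop_counts})
    pop_lines = "".join(
        f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Allele count in {p}">\n'
        f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Allele number in {p}">\n'
        for p in pop_labels
    )
    lines = [
        VCF_HEADER_TEMPLATE.format(
            pop_lines=pop_lines, chrom=chrom, length=contig_length
        )
    ]
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.ref, r.alt)):
        info = [f"AC={rec.AC}", f"AN={rec.AN}", f"Hom={rec.hom_count}"]
        for label, (ac, an) in rec.pop_counts:
            info.append(f"AC_{label}={ac}")
            info.append(f"AN_{label}={an}")
        qual = "." if rec.qual is None else f"{rec.qual:g}"
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t{qual}\t"
            f"{rec.filter_status}\t{';'.join(info)}\n"
        )
    path.write_text("".join(lines))
    return path


# -- normalisation -----------------------------------------------------------


def normalize_variant(model, rec: VariantRecord) -> VariantRecord:
    """Left-aligned minimal representation of a variant against the locus.

    ``model`` is a :class:`~ttnpop.gene_model.GeneModel` (anything exposing
    ``base_at``/``subsequence``/``locus_offset``).  Raises on reference
    mismatch and when REF equals ALT after trimming.
    """
    expected = model.subsequence(rec.pos, rec.pos + len(rec.ref) - 1)
    if expected != rec.ref:
        raise VariantIOError(
            f"reference mismatch at {rec.chrom}:{rec.pos}: "
            f"expected {expected!r}, record has {rec.ref!r}"
        )
    pos, ref, alt = rec.pos, rec.ref, rec.alt
    if ref == alt:
        raise VariantIOError(f"{rec.chrom}:{rec.pos} ref equals alt after trimming")
    changed = True
    while changed:
        changed = False
        if ref and alt and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        if not ref or not alt:
            if pos <= model.locus_offset:
                raise VariantIOError(
                    f"{rec.chrom}:{rec.pos}: cannot left-align past locus start"
                )
            pos -= 1
            base = model.base_at(pos)
            ref, alt = base + ref, base + alt
            changed = True
        if len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
    if ref == alt:
        raise VariantIOError(f"{rec.chrom}:{rec.pos} ref equals alt after trimming")
    if (pos, ref, alt) == (rec.pos, rec.ref, rec.alt):
        return rec
    return replace(rec, pos=pos, ref=ref, alt=alt)


# -- coverage ----------------------------------------------------------------


def read_coverage(path: str | Path) -> CoverageTable:
    """Read a coverage TSV with columns chrom, pos, mean_depth, ge_<threshold>...

    A leading ``#`` on the header line is tolerated.  frac_ge monotonicity is
    validated per row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    required = {"chrom", "pos", "mean_depth"}
    if not required <= set(df.columns):
        raise VariantIOError(
            f"coverage file {path} missing columns {sorted(required - set(df.columns))}"
        )
    thresholds = [
        (int(c[3:]), c) for c in df.columns if c.startswith("ge_")
    ]
    thresholds.sort()
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            CoverageRecord(
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                mean_depth=float(d["mean_depth"]),
                frac_ge=tuple((t, float(d[c])) for t, c in thresholds),
            )
        )
    return CoverageTable(records)


def write_coverage(table: CoverageTable, path: str | Path) -> Path:
    path = Path(path)
    thresholds = sorted({t for rec in table for t, _ in rec.frac_ge})
    header = ["#chrom", "pos", "mean_depth"] + [f"ge_{t}" for t in thresholds]
    lines = ["\t".join(header) + "\n"]
    for rec in sorted(table, key=lambda r: (r.chrom, r.pos)):
        frac = dict(rec.frac_ge)
        cells = [rec.chrom, str(rec.pos), f"{rec.mean_depth:.1f}"] + [
            f"{frac[t]:.3f}" for t in thresholds
        ]
        lines.append("\t".join(cells) + "\n")
    path.write_text("".join(lines))
    return path
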