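"""Nonsense-mutation spectrum: codon-to-stop enumeration and CpG hotspots.

Under the standard genetic code there are exactly 23 single-nucleotide
substitutions that convert a sense codon into a stop codon: nine at the first
codon position, seven at the second and seven at the third.  Patterns are
labelled in the conventional style with the mutated base uppercased, e.g.
``Cga/Tga`` for CGA->TGA (arginine to stop, R/*), which is also a CpG
deamination hotspot because the mutated C is followed by G.

CpG context is evaluated on the spliced coding sequence by default, so a
codon's neighbour across an exon-exon junction is the spliced neighbour; a
``genomic`` mode uses the unspliced locus instead.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

from Bio.Seq import Seq
from scipy import stats

from ttnpop.consequence import NONSENSE, ConsequenceCall
from ttnpop.gene_model import STOP_CODONS, GeneModel

BASES = "ACGT"
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
)


@dataclass(frozen=True)
class StopGainPattern:
    ref_codon: str
    codon_pos: int  # 1..3
    alt_codon: str

    def __post_init__(self) -> None:
        diffs = [i for i in range(3) if self.ref_codon[i] != self.alt_codon[i]]
        if diffs != [self.codon_pos - 1]:
            raise ValueError(
                f"{self.ref_codon}->{self.alt_codon} does not differ exactly at "
                f"position {self.codon_pos}"
            )
        if self.ref_codon in STOP_CODONS or self.alt_codon not in STOP_CODONS:
            raise ValueError(f"{self.ref_codon}->{self.alt_codon} is not a stop gain")

    @property
    def ref_aa(self) -> str:
        return str(Seq(self.ref_codon).translate())

    @property
    def label(self) -> str:
        """Mutated base uppercase, remaining bases lowercase: e.g. Cga/Tga."""
        def fmt(codon: str) -> str:
            i = self.codon_pos - 1
            return codon[:i].lower() + codon[i] + codon[i + 1 :].lower()

        return f"{fmt(self.ref_codon)}/{fmt(self.alt_codon)}"


def enumerate_stop_gain_patterns() -> list[StopGainPattern]:
    """All 23 single-substitution codon->stop patterns, ordered by
    (codon position, reference codon)."""
    patterns = []
    for codon_pos in (1, 2, 3):
        for ref in SENSE_CODONS:
            for alt_base in BASES:
                if alt_base == ref[codon_pos - 1]:
                    continue
                alt = ref[: codon_pos - 1] + alt_base + ref[codon_pos:]
                if alt in STOP_CODONS:
                    patterns.append(StopGainPattern(ref, codon_pos, alt))
    return patterns


def is_cpg_transition(local_context: str, ref_base: str, alt_base: str) -> bool:
    """Deamination-type CpG transition test on a 3-mer centred on the variant.

    True iff C->T with the next base G, or G->A with the previous base C
    (the opposite-strand deamination of the same CpG dinucleotide).
    """
    if len(local_context) != 3 or local_context[1] != ref_base:
        raise ValueError(
            f"context {local_context!r} does not centre on ref base {ref_base!r}"
        )
    if ref_base == "C" and alt_base == "T":
        return local_context[2] == "G"
    if ref_base == "G" and alt_base == "A":
        return local_context[0] == "C"
    return False


def nonsense_pattern(
    call: ConsequenceCall, model: GeneModel, cpg_context: str = "spliced"
) -> tuple[StopGainPattern, bool]:
    """Stop-gain pattern and CpG-hotspot flag for a nonsense call.

    The CpG flag looks at the coding-strand neighbourhood of the mutated base.
    In ``spliced`` mode (default) neighbours come from the spliced CDS, so a
    cross-codon neighbour over an exon junction is the biological coding
    neighbour; ``genomic`` mode uses the unspliced locus sequence.
    """
    if call.consequence_class != NONSENSE:
        raise ValueError(f"call {call.key} is not a nonsense variant")
    ctx = call.coding
    pattern = StopGainPattern(ctx.ref_codon, ctx.codon_pos, call.alt_codon)
    ref_base = ctx.ref_codon[ctx.codon_pos - 1]
    alt_base = call.alt_codon[ctx.codon_pos - 1]
    if cpg_context == "spliced":
        cds = model.spliced_cds(ctx.transcript_id)
        i = ctx.cds_pos - 1
        prev_b = cds[i - 1] if i > 0 else "N"
        next_b = cds[i + 1] if i + 1 < len(cds) else "N"
    elif cpg_context == "genomic":
        chrom, pos, _, _ = call.key
        lo = model.subsequence(pos - 1, pos + 1)
        if model.strand == "+":
            prev_b, next_b = lo[0], lo[2]
        else:
            rc = str(Seq(lo).reverse_complement())
            prev_b, next_b = rc[0], rc[2]
    else:
        raise ValueError(f"unknown cpg_context {cpg_context!r}")
    cpg = is_cpg_transition(prev_b + ref_base + next_b, ref_base, alt_base)
    return pattern, cpg


@dataclass
class SpectrumSummary:
    """Tallies of nonsense variants by pattern, codon position, CpG and band."""

    entries: list[tuple[StopGainPattern, bool, str | None]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return len(self.entries)

    @property
    def counts(self) -> Counter:
        return Counter(p for p, _, _ in self.entries)

    @property
    def by_position(self) -> dict[int, int]:
        c = Counter(p.codon_pos for p, _, _ in self.entries)
        return {1: c.get(1, 0), 2: c.get(2, 0), 3: c.get(3, 0)}

    @property
    def cpg_transition_count(self) -> int:
        return sum(1 for _, cpg, _ in self.entries if cpg)

    @property
    def r_star_count(self) -> int:
        return sum(1 for p, _, _ in self.entries if p.ref_aa == "R")

    def band_slice(self, band: str) -> "SpectrumSummary":
        return SpectrumSummary([e for e in self.entries if e[2] == band])

    def cga_tga_over_r_star(self, band: str | None = None) -> float:
        """Fraction of R/* nonsense variants that are the Cga/Tga pattern."""
        scope = self if band is None else self.band_slice(band)
        r_star = scope.r_star_count
        if r_star == 0:
            raise ZeroDivisionError("no R/* nonsense variants in scope")
        cga = sum(
            1 for p, _, _ in scope.entries
            if p.ref_codon == "CGA" and p.alt_codon == "TGA"
        )
        return cga / r_star

    def a_band_over_all_cpg(self, band: str = "A") -> float:
        """Fraction of all CpG-hotspot nonsense variants lying in the given band
        as Cga/Tga changes."""
        if self.cpg_transition_count == 0:
            raise ZeroDivisionError("no CpG-hotspot nonsense variants")
        in_band = sum(
            1 for p, cpg, b in self.entries
            if cpg and b == band and p.ref_codon == "CGA" and p.alt_codon == "TGA"
        )
        return in_band / self.cpg_transition_count


def spectrum_summary(
    calls: list[ConsequenceCall],
    model: GeneModel,
    band_filter: str | None = None,
    cpg_context: str = "spliced",
) -> SpectrumSummary:
    """Summarise the nonsense calls of a cohort; non-nonsense calls are ignored."""
    entries = []
    for call in calls:
        if call.consequence_class != NONSENSE:
            continue
        if band_filter is not None and call.band != band_filter:
            continue
        pattern, cpg = nonsense_pattern(call, model, cpg_context)
        entries.append((pattern, cpg, call.band))
    return SpectrumSummary(entries)


OPPORTUNITY_WEIGHTS = (9 / 23, 7 / 23, 7 / 23)


def codon_position_bias_test(
    summary: SpectrumSummary, null_model: str = "uniform"
) -> tuple[float, float]:
    """Chi-square goodness of fit of codon-position counts.

    ``uniform`` expects (1/3, 1/3, 1/3); ``opportunity`` weights by the number
    of stop-gain patterns available at each position (9, 7, 7 of 23).
    """
    observed = [summary.by_position[i] for i in (1, 2, 3)]
    n = sum(observed)
    if n == 0:
        raise ValueError("no nonsense variants to test")
    if null_model == "uniform":
        expected = [n / 3] * 3
    elif null_model == "opportunity":
        expected = [n * w for w in OPPORTUNITY_WEIGHTS]
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    if any(e == 0 for e in expected):
        raise ValueError("zero expected cell")
    stat, p = stats.chisquare(observed, expected)
    return float(stat), float(p)


def spectrum_report_frame(summary: SpectrumSummary):
    """Spectrum report table: one row per pattern with counts and CpG/band slices."""
    import pandas as pd

    bands = sorted({b for _, _, b in summary.entries if b is not None})
    rows = []
    for pattern in enumerate_stop_gain_patterns():
        matching = [e for e in summary.entries if e[0] == pattern]
        if not matching and summary.entries:
            pass  # keep full enumeration so absent patterns are visible
        row = {
            "label": pattern.label,
            "ref_aa": pattern.ref_aa,
            "codon_pos": pattern.codon_pos,
            "count": len(matching),
            "cpg_count": sum(1 for _, cpg, _ in matching if cpg),
        }
        for band in bands:
            row[f"count_{band}"] = sum(1 for _, _, b in matching if b == band)
        rows.append(row)
    return pd.DataFrame(rows)
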