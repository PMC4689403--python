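"""Molecular consequence calling on the gene model.

A variant is classified on a designated reference transcript (the longest CDS
by default).  When the reference transcript gives no coding or splice context
(e.g. the variant sits in an isoform-specific exon), per-transcript calls are
compared and the most severe one wins, with the precedence

    nonsense > frameshift > essential_splice > splice_region > inframe_indel
    > missense > synonymous > intronic > noncoding

Splice distances are measured in transcription order: +d means d bases into
the intron past a donor site (3' end of an exon), -d means d bases before an
acceptor (5' start of the next exon).  Distances 1-2 are essential splice
sites (the canonical GT/AG dinucleotides), 3-6 the splice region; anything
deeper is plain intronic.

Truncating variants (TTNtv) are the union {nonsense, frameshift,
essential_splice}.  Non-essential splice-region variants are explicitly *not*
truncating.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from ttnpop.gene_model import STOP_CODONS, CodingContext, GeneModel
from ttnpop.variant_io import VariantIOError, VariantRecord, variant_key

NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
ESSENTIAL_SPLICE = "essential_splice"
SPLICE_REGION = "splice_region"
INFRAME_INDEL = "inframe_indel"
MISSENSE = "missense"
SYNONYMOUS = "synonymous"
INTRONIC = "intronic"
NONCODING = "noncoding"

SEVERITY_ORDER = (
    NONSENSE,
    FRAMESHIFT,
    ESSENTIAL_SPLICE,
    SPLICE_REGION,
    INFRAME_INDEL,
    MISSENSE,
    SYNONYMOUS,
    INTRONIC,
    NONCODING,
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

TTNTV_CLASSES = frozenset({NONSENSE, FRAMESHIFT, ESSENTIAL_SPLICE})

MAX_SPLICE_DISTANCE = 6
ESSENTIAL_MAX = 2


@dataclass(frozen=True)
class ConsequenceCall:
    key: tuple[str, int, str, str]
    consequence_class: str
    record: VariantRecord
    band: str | None = None
    transcript_hits: frozenset[str] = frozenset()
    affects_all: bool = False
    coding: CodingContext | None = None
    alt_codon: str | None = None
    aa_change: str | None = None
    splice_distance: int | None = None
    exon_id: str | None = None  # containing exon, or adjacent exon for splice calls
    transcript_id: str | None = None  # transcript the call was made on


def severity_rank(consequence_class: str) -> int:
    return _SEVERITY_RANK[consequence_class]


def is_ttntv(call: ConsequenceCall) -> bool:
    """True for the truncating classes: nonsense, frameshift, essential splice."""
    return call.consequence_class in TTNTV_CLASSES


# -- splice distance ---------------------------------------------------------


def _splice_context(
    model: GeneModel, gpos: int, transcript_id: str
) -> tuple[int, str] | None:
    """(signed splice distance, adjacent exon id) for intronic gpos, else None.

    Only distances 1..MAX_SPLICE_DISTANCE from the nearest intron boundary of
    the transcript qualify.  Signs follow transcription order and the model
    strand.
    """
    tx = model.transcripts[transcript_id]
    exons = [model.exons[e] for e in tx.exon_ids]
    for left, right in zip(exons, exons[1:]):
        if not (left.end < gpos < right.start):
            continue
        dist_left = gpos - left.end  # bases past the genomically-left exon
        dist_right = right.start - gpos  # bases before the genomically-right exon
        if dist_left <= dist_right:
            nearest, adjacent = dist_left, left
            donor_side = model.strand == "+"  # left exon is donor only on plus strand
        else:
            nearest, adjacent = dist_right, right
            donor_side = model.strand == "-"
        if nearest > MAX_SPLICE_DISTANCE:
            return None
        signed = nearest if donor_side else -nearest
        return signed, adjacent.exon_id
    return None


def splice_distance(model: GeneModel, gpos: int, transcript_id: str) -> int | None:
    """Signed distance into the intron (1-6 bp) or None if not a splice position."""
    ctx = _splice_context(model, gpos, transcript_id)
    return None if ctx is None else ctx[0]


# -- per-transcript classification ------------------------------------------


def _mutate_codon(model: GeneModel, ctx: CodingContext, alt_base: str) -> str:
    """Reference codon with the variant base substituted, on the coding strand."""
    base = alt_base if model.strand == "+" else str(Seq(alt_base).complement())
    i = ctx.codon_pos - 1
    return ctx.ref_codon[:i] + base + ctx.ref_codon[i + 1 :]


def _affected_positions(rec: VariantRecord) -> list[int]:
    """Genomic positions whose bases change (deletions) or flank the edit.

    For a normalised indel the anchor base at ``pos`` is unchanged: a deletion
    removes pos+1..pos+len(ref)-1, an insertion falls between pos and pos+1.
    """
    if rec.is_snv:
        return [rec.pos]
    if len(rec.ref) > len(rec.alt):  # deletion
        return list(range(rec.pos + 1, rec.pos + len(rec.ref)))
    # insertion (or MNV-like): use the two flanking anchored positions
    return [rec.pos + 1]


def _classify_on_transcript(
    model: GeneModel, rec: VariantRecord, transcript_id: str
) -> dict | None:
    """Raw classification of one record on one transcript, or None if untouched."""
    span_lo, span_hi = model.transcript_span(transcript_id)

    if rec.is_snv:
        ctx = model.codon_context(transcript_id, rec.pos)
        if ctx is not None:
            alt_codon = _mutate_codon(model, ctx, rec.alt)
            alt_aa = str(Seq(alt_codon).translate())
            if ctx.ref_codon in STOP_CODONS:
                cls = MISSENSE  # stop-loss folded into missense (not analysed)
            elif alt_codon in STOP_CODONS:
                cls = NONSENSE
            elif alt_aa == ctx.ref_aa:
                cls = SYNONYMOUS
            else:
                cls = MISSENSE
            exon = model.exon_of(rec.pos)
            return {
                "class": cls,
                "coding": ctx,
                "alt_codon": alt_codon,
                "aa_change": f"{ctx.ref_aa}/{alt_aa}",
                "splice_distance": None,
                "exon_id": exon.exon_id if exon else None,
            }
        splice = _splice_context(model, rec.pos, transcript_id)
        if splice is not None:
            d, exon_id = splice
            cls = ESSENTIAL_SPLICE if abs(d) <= ESSENTIAL_MAX else SPLICE_REGION
            return {
                "class": cls,
                "coding": None,
                "alt_codon": None,
                "aa_change": None,
                "splice_distance": d,
                "exon_id": exon_id,
            }
        if span_lo <= rec.pos <= span_hi:
            tx = model.transcripts[transcript_id]
            exonic = any(
                model.exons[e].contains(rec.pos) for e in tx.exon_ids
            )
            cls = NONCODING if exonic else INTRONIC  # exonic UTR-like position
            return {"class": cls, "coding": None, "alt_codon": None,
                    "aa_change": None, "splice_distance": None, "exon_id": None}
        return None

    # indel: exonic portion wins if any changed base is coding
    positions = _affected_positions(rec)
    coding_positions = [
        p for p in positions if model.genomic_to_cds(transcript_id, p) is not None
    ]
    length_change = abs(len(rec.ref) - len(rec.alt))
    if coding_positions:
        p = coding_positions[0]
        ctx = model.codon_context(transcript_id, p)
        cls = FRAMESHIFT if length_change % 3 != 0 else INFRAME_INDEL
        exon = model.exon_of(p)
        return {
            "class": cls,
            "coding": ctx,
            "alt_codon": None,
            "aa_change": None,
            "splice_distance": None,
            "exon_id": exon.exon_id if exon else None,
        }
    splice = _splice_context(model, positions[0], transcript_id)
    if splice is not None:
        d, exon_id = splice
        cls = ESSENTIAL_SPLICE if abs(d) <= ESSENTIAL_MAX else SPLICE_REGION
        return {"class": cls, "coding": None, "alt_codon": None,
                "aa_change": None, "splice_distance": d, "exon_id": exon_id}
    if span_lo <= positions[0] <= span_hi:
        return {"class": INTRONIC, "coding": None, "alt_codon": None,
                "aa_change": None, "splice_distance": None, "exon_id": None}
    return None


def classify_variant(
    model: GeneModel,
    rec: VariantRecord,
    psi_threshold: float = 0.15,
    reference_transcript: str | None = None,
) -> ConsequenceCall:
    """Classify a normalised variant's molecular consequence on the gene model.

    The call is made on the reference transcript when it yields a coding or
    splice classification; otherwise the most severe per-transcript call wins.
    ``transcript_hits`` records which transcripts contain the variant position
    (the adjacent exon's membership for splice calls), and ``affects_all``
    whether that is every transcript in the model.
    """
    expected = model.subsequence(rec.pos, rec.pos + len(rec.ref) - 1)
    if expected != rec.ref:
        raise VariantIOError(
            f"reference mismatch at {rec.chrom}:{rec.pos}: "
            f"expected {expected!r}, record has {rec.ref!r}"
        )
    if reference_transcript is None:
        reference_transcript = model.reference_transcript_id()

    raw = _classify_on_transcript(model, rec, reference_transcript)
    chosen_tx = reference_transcript
    if raw is None or raw["class"] in (INTRONIC, NONCODING):
        for tid in sorted(model.transcripts):
            if tid == reference_transcript:
                continue
            other = _classify_on_transcript(model, rec, tid)
            if other is None:
                continue
            if raw is None or severity_rank(other["class"]) < severity_rank(raw["class"]):
                raw, chosen_tx = other, tid
    if raw is None:
        raw = {"class": NONCODING, "coding": None, "alt_codon": None,
               "aa_change": None, "splice_distance": None, "exon_id": None}

    if raw["exon_id"] is not None and raw["splice_distance"] is not None:
        # splice call: transcript membership via the adjacent exon
        exon = model.exons[raw["exon_id"]]
        probe = exon.start
    else:
        probe = rec.pos if rec.is_snv else _affected_positions(rec)[0]
    hits = model.transcripts_containing(probe)
    return ConsequenceCall(
        key=variant_key(rec),
        consequence_class=raw["class"],
        record=rec,
        band=model.band_of(rec.pos),
        transcript_hits=frozenset(hits),
        affects_all=hits == set(model.transcripts),
        coding=raw["coding"],
        alt_codon=raw["alt_codon"],
        aa_change=raw["aa_change"],
        splice_distance=raw["splice_distance"],
        exon_id=raw["exon_id"],
        transcript_id=chosen_tx,
    )


def annotate_records(
    model: GeneModel,
    records: list[VariantRecord],
    psi_threshold: float = 0.15,
    reference_transcript: str | None = None,
) -> list[ConsequenceCall]:
    """Normalise is assumed done; classify a batch of records in order."""
    return [
        classify_variant(model, r, psi_threshold, reference_transcript)
        for r in records
    ]


# -- annotated TSV round-trip ------------------------------------------------

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "consequence_class", "band", "affects_all",
    "transcript_hits", "aa_change", "ref_codon", "alt_codon", "codon_pos",
    "splice_distance", "exon_id", "AC", "AN", "hom_count", "dataset",
]


def calls_to_frame(calls: list[ConsequenceCall]):
    """Annotated calls as a pandas DataFrame in the external TSV layout."""
    import pandas as pd

    rows = []
    for c in calls:
        chrom, pos, ref, alt = c.key
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "consequence_class": c.consequence_class,
                "band": c.band or ".",
                "affects_all": int(c.affects_all),
                "transcript_hits": ",".join(sorted(c.transcript_hits)) or ".",
                "aa_change": c.aa_change or ".",
                "ref_codon": c.coding.ref_codon if c.coding else ".",
                "alt_codon": c.alt_codon or ".",
                "codon_pos": c.coding.codon_pos if c.coding else ".",
                "splice_distance": c.splice_distance if c.splice_distance is not None else ".",
                "exon_id": c.exon_id or ".",
                "AC": c.record.AC,
                "AN": c.record.AN,
                "hom_count": c.record.hom_count,
                "dataset": c.record.dataset,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotated(calls: list[ConsequenceCall], path) -> None:
    df = calls_to_frame(calls)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(ANNOTATION_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
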