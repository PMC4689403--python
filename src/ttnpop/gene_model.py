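"""Multi-transcript gene model with band annotations, PSI values and sequence.

The container is deliberately gene-centric: a single locus sequence, a set of
exons shared between transcripts, per-transcript CDS bounds, genomic band
intervals (Z/I/A/M sarcomere regions for titin), and a proportion-spliced-in
(PSI) value per exon.  All file coordinates are 1-based inclusive; the same
convention is used internally throughout.

Bands are *genomic* intervals rather than residue ranges, so intronic variants
(splice-site changes) inherit the band of their genomic location without extra
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BANDS = ("Z", "I", "A", "M")

ALL_TRANSCRIPTS = "all_transcripts"
ISOFORM_SPECIFIC = "isoform_specific"
LOW_PSI = "low_psi"

DEFAULT_PSI_THRESHOLD = 0.15


class ModelValidationError(ValueError):
    """A gene-model invariant failed; the message names the invariant."""


@dataclass(frozen=True)
class Exon:
    exon_id: str
    start: int  # genomic, 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelValidationError(
                f"exon {self.exon_id}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, gpos: int) -> bool:
        return self.start <= gpos <= self.end


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    name: str
    exon_ids: tuple[str, ...]
    cds_start: int  # genomic
    cds_end: int


@dataclass(frozen=True)
class BandInterval:
    band: str
    start: int
    end: int


@dataclass(frozen=True)
class CodingContext:
    """Translation-frame context of one genomic position on one transcript."""

    transcript_id: str
    cds_pos: int  # 1-based within the spliced CDS, translation order
    codon_index: int  # 1-based
    codon_pos: int  # 1, 2 or 3
    ref_codon: str  # coding-strand 3-mer
    ref_aa: str  # one-letter amino acid; "*" for stop


@dataclass
class GeneModel:
    gene_name: str
    chrom: str
    strand: str  # "+" or "-"
    locus_offset: int  # genomic position of sequence[0]
    sequence: str
    exons: dict[str, Exon]
    transcripts: dict[str, Transcript]
    bands: list[BandInterval]
    psi: dict[str, float]

    _cds_maps: dict = field(default_factory=dict, repr=False, compare=False)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        locus_end = self.locus_offset + len(self.sequence) - 1
        for exon in self.exons.values():
            if exon.start < self.locus_offset or exon.end > locus_end:
                raise ModelValidationError(
                    f"exon {exon.exon_id} outside locus bounds "
                    f"[{self.locus_offset}, {locus_end}]"
                )
        for tx in self.transcripts.values():
            exons = []
            for eid in tx.exon_ids:
                if eid not in self.exons:
                    raise ModelValidationError(
                        f"transcript {tx.transcript_id} references unknown exon {eid}"
                    )
                exons.append(self.exons[eid])
            for a, b in zip(exons, exons[1:]):
                if a.end >= b.start:
                    raise ModelValidationError(
                        f"transcript {tx.transcript_id}: exons {a.exon_id},{b.exon_id} "
                        "overlap or are out of genomic order"
                    )
            if not any(e.contains(tx.cds_start) for e in exons) or not any(
                e.contains(tx.cds_end) for e in exons
            ):
                raise ModelValidationError(
                    f"transcript {tx.transcript_id}: CDS bounds outside exon union"
                )
            if self.cds_length(tx.transcript_id) % 3 != 0:
                raise ModelValidationError(
                    f"transcript {tx.transcript_id}: CDS length not multiple of 3"
                )
        for eid in self.exons:
            if eid not in self.psi:
                raise ModelValidationError(f"psi missing for exon {eid}")
        for eid, value in self.psi.items():
            if not 0.0 <= value <= 1.0:
                raise ModelValidationError(f"psi for exon {eid} out of [0, 1]: {value}")
        # bands: disjoint and jointly covering the CDS span of the longest tx
        ordered = sorted(self.bands, key=lambda b: b.start)
        for a, b in zip(ordered, ordered[1:]):
            if a.end >= b.start:
                raise ModelValidationError(f"bands {a.band},{b.band} overlap")
        if self.bands:
            ref = self.transcripts[self.reference_transcript_id()]
            lo, hi = min(ref.cds_start, ref.cds_end), max(ref.cds_start, ref.cds_end)
            if ordered[0].start > lo or ordered[-1].end < hi:
                raise ModelValidationError(
                    "band intervals do not cover the CDS span of the longest transcript"
                )
            for a, b in zip(ordered, ordered[1:]):
                if a.end + 1 != b.start:
                    raise ModelValidationError(
                        f"gap between bands {a.band} and {b.band}"
                    )

    # -- sequence access ----------------------------------------------------

    def base_at(self, gpos: int) -> str:
        """Plus-strand reference base at a genomic position."""
        idx = gpos - self.locus_offset
        if idx < 0 or idx >= len(self.sequence):
            raise ValueError(f"position {gpos} outside locus")
        return self.sequence[idx]

    def subsequence(self, start: int, end: int) -> str:
        """Plus-strand reference bases for the inclusive genomic interval."""
        return self.sequence[start - self.locus_offset : end - self.locus_offset + 1]

    # -- coordinate mapping -------------------------------------------------

    def _cds_map(self, transcript_id: str):
        """(gpos -> cds_pos dict, genomic positions in translation order, CDS string)."""
        cached = self._cds_maps.get(transcript_id)
        if cached is not None:
            return cached
        if transcript_id not in self.transcripts:
            raise KeyError(f"unknown transcript {transcript_id!r}")
        tx = self.transcripts[transcript_id]
        lo, hi = min(tx.cds_start, tx.cds_end), max(tx.cds_start, tx.cds_end)
        positions: list[int] = []
        for eid in tx.exon_ids:
            exon = self.exons[eid]
            positions.extend(
                p for p in range(exon.start, exon.end + 1) if lo <= p <= hi
            )
        if self.strand == "-":
            positions.reverse()
        mapping = {g: i + 1 for i, g in enumerate(positions)}
        bases = [self.base_at(g) for g in positions]
        cds_seq = "".join(bases)
        if self.strand == "-":
            cds_seq = str(Seq(cds_seq).complement())
        result = (mapping, positions, cds_seq)
        self._cds_maps[transcript_id] = result
        return result

    def cds_length(self, transcript_id: str) -> int:
        return len(self._cds_map(transcript_id)[1])

    def spliced_cds(self, transcript_id: str) -> str:
        """Coding-strand spliced CDS sequence in translation order."""
        return self._cds_map(transcript_id)[2]

    def reference_transcript_id(self) -> str:
        """The longest-CDS transcript (ties broken by transcript id)."""
        return min(
            self.transcripts, key=lambda t: (-self.cds_length(t), t)
        )

    def transcript_span(self, transcript_id: str) -> tuple[int, int]:
        tx = self.transcripts[transcript_id]
        exons = [self.exons[e] for e in tx.exon_ids]
        return exons[0].start, exons[-1].end

    # -- queries ------------------------------------------------------------

    def genomic_to_cds(self, transcript_id: str, gpos: int) -> int | None:
        """1-based spliced-CDS position of a genomic coordinate, or None.

        Returns None for intronic, non-coding or out-of-transcript positions.
        Translation order: ascending genomic for '+', descending for '-'.
        """
        mapping, _, _ = self._cds_map(transcript_id)
        return mapping.get(gpos)

    def cds_to_genomic(self, transcript_id: str, cds_pos: int) -> int:
        _, positions, _ = self._cds_map(transcript_id)
        return positions[cds_pos - 1]

    def codon_context(self, transcript_id: str, gpos: int) -> CodingContext | None:
        cds_pos = self.genomic_to_cds(transcript_id, gpos)
        if cds_pos is None:
            return None
        cds_seq = self.spliced_cds(transcript_id)
        codon_index = (cds_pos - 1) // 3 + 1
        codon_pos = (cds_pos - 1) % 3 + 1
        ref_codon = cds_seq[3 * (codon_index - 1) : 3 * codon_index]
        ref_aa = str(Seq(ref_codon).translate())
        return CodingContext(
            transcript_id=transcript_id,
            cds_pos=cds_pos,
            codon_index=codon_index,
            codon_pos=codon_pos,
            ref_codon=ref_codon,
            ref_aa=ref_aa,
        )

    def transcripts_containing(self, gpos: int) -> set[str]:
        """Transcript ids whose exon union covers the genomic position."""
        hits = set()
        for tid, tx in self.transcripts.items():
            if any(self.exons[e].contains(gpos) for e in tx.exon_ids):
                hits.add(tid)
        return hits

    def affects_all(self, gpos: int) -> bool:
        return self.transcripts_containing(gpos) == set(self.transcripts)

    def band_of(self, gpos: int) -> str | None:
        for band in self.bands:
            if band.start <= gpos <= band.end:
                return band.band
        return None

    def exon_of(self, gpos: int) -> Exon | None:
        for exon in self.exons.values():
            if exon.contains(gpos):
                return exon
        return None

    def exon_class(
        self, exon_id: str, psi_threshold: float = DEFAULT_PSI_THRESHOLD
    ) -> str:
        """Classify an exon as low_psi, isoform_specific or all_transcripts.

        low_psi (PSI below the threshold) takes precedence over
        isoform_specific (absent from at least one transcript).
        """
        if exon_id not in self.exons:
            raise KeyError(f"unknown exon {exon_id!r}")
        if self.psi[exon_id] < psi_threshold:
            return LOW_PSI
        if any(exon_id not in tx.exon_ids for tx in self.transcripts.values()):
            return ISOFORM_SPECIFIC
        return ALL_TRANSCRIPTS


# -- module-level operation wrappers ----------------------------------------


def genomic_to_cds(model: GeneModel, transcript_id: str, gpos: int) -> int | None:
    return model.genomic_to_cds(transcript_id, gpos)


def codon_context(model: GeneModel, transcript_id: str, gpos: int) -> CodingContext | None:
    return model.codon_context(transcript_id, gpos)


def transcripts_containing(model: GeneModel, gpos: int) -> set[str]:
    return model.transcripts_containing(gpos)


def band_of(model: GeneModel, gpos: int) -> str | None:
    return model.band_of(gpos)


def exon_class(
    model: GeneModel, exon_id: str, psi_threshold: float = DEFAULT_PSI_THRESHOLD
) -> str:
    return model.exon_class(exon_id, psi_threshold)


# -- serialisation -----------------------------------------------------------


def load_gene_model(path: str | Path) -> GeneModel:
    """Load a gene-model JSON bundle (sequence in a sidecar FASTA) and validate it.

    Schema keys: gene, chrom, strand, locus_offset, sequence_fasta, exons,
    transcripts, bands, psi.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelValidationError(f"invalid JSON in {path}: {exc}") from exc
    required = {
        "gene", "chrom", "strand", "locus_offset", "sequence_fasta",
        "exons", "transcripts", "bands", "psi",
    }
    missing = required - set(data)
    if missing:
        raise ModelValidationError(f"missing keys in gene model: {sorted(missing)}")
    fasta = path.parent / data["sequence_fasta"]
    records = list(SeqIO.parse(str(fasta), "fasta"))
    if len(records) != 1:
        raise ModelValidationError(f"expected exactly one FASTA record in {fasta}")
    exons = {e["id"]: Exon(e["id"], int(e["start"]), int(e["end"])) for e in data["exons"]}
    if len(exons) != len(data["exons"]):
        raise ModelValidationError("exon ids are not unique")
    transcripts = {
        t["id"]: Transcript(
            transcript_id=t["id"],
            name=t.get("name", t["id"]),
            exon_ids=tuple(t["exons"]),
            cds_start=int(t["cds_start"]),
            cds_end=int(t["cds_end"]),
        )
        for t in data["transcripts"]
    }
    bands = [
        BandInterval(b["band"], int(b["start"]), int(b["end"])) for b in data["bands"]
    ]
    model = GeneModel(
        gene_name=data["gene"],
        chrom=data["chrom"],
        strand=data["strand"],
        locus_offset=int(data["locus_offset"]),
        sequence=str(records[0].seq).upper(),
        exons=exons,
        transcripts=transcripts,
        bands=bands,
        psi={k: float(v) for k, v in data["psi"].items()},
    )
    model.validate()
    return model


def save_gene_model(model: GeneModel, directory: str | Path, stem: str = "model") -> Path:
    """Write the JSON + FASTA bundle; byte-deterministic for a given model."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fasta_name = "locus.fa"
    data = {
        "gene": model.gene_name,
        "chrom": model.chrom,
        "strand": model.strand,
        "locus_offset": model.locus_offset,
        "sequence_fasta": fasta_name,
        "exons": [
            {"id": e.exon_id, "start": e.start, "end": e.end}
            for e in sorted(model.exons.values(), key=lambda e: (e.start, e.exon_id))
        ],
        "transcripts": [
            {
                "id": t.transcript_id,
                "name": t.name,
                "exons": list(t.exon_ids),
                "cds_start": t.cds_start,
                "cds_end": t.cds_end,
            }
            for t in sorted(model.transcripts.values(), key=lambda t: t.transcript_id)
        ],
        "bands": [
            {"band": b.band, "start": b.start, "end": b.end}
            for b in sorted(model.bands, key=lambda b: b.start)
        ],
        "psi": {k: model.psi[k] for k in sorted(model.psi)},
    }
    json_path = directory / f"{stem}.json"
    with open(json_path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
    record = SeqRecord(Seq(model.sequence), id=f"{model.chrom}", description="")
    with open(directory / fasta_name, "w") as fh:
        SeqIO.write([record], fh, "fasta")
    return json_path
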