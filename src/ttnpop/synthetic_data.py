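"""Synthetic gene models and variant cohorts with exact ground truth.

Everything downstream of this module is testable without external downloads:
the generator builds a titin-like multi-transcript gene (one full transcript,
one "short" transcript skipping designated exons, one novex-like transcript
with a unique terminal exon), plants variants of requested consequence classes
at positions that guarantee the class, draws allele counts from a
singleton-heavy frequency spectrum, splits them over population groups, and
emits VCF / coverage / truth-table files that are byte-identical for identical
configurations.

Variants are *planted*, not mutated at random: each candidate position is
chosen so the intended consequence is unambiguous (stop-gain codons for
nonsense, interior exonic 1-2 bp indels for frameshifts, exact intron
distances for splice variants), so truth labels are exact by construction and
independent of the classifier under test.

The module also provides deterministic worked-example fixtures whose aggregate
margins match the published reference-population summaries (cohort totals,
filtered counts, band splits, nonsense-spectrum and splice-spectrum ratios),
for end-to-end report tests.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from ttnpop import consequence as cq
from ttnpop.gene_model import (
    BandInterval,
    Exon,
    GeneModel,
    STOP_CODONS,
    Transcript,
    save_gene_model,
)
from ttnpop.variant_io import (
    CoverageRecord,
    CoverageTable,
    VariantRecord,
    normalize_variant,
    variant_key,
    write_coverage,
    write_vcf,
)

BASES = "ACGT"
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are desk-scale: a 40-exon gene, three transcripts, four
    populations of 5000 individuals each, a singleton-heavy allele-frequency
    spectrum, and ExAC-like superset/subset dataset roles.
    """

    seed: int = 0
    # gene geometry
    n_exons: int = 40
    exon_codons_min: int = 20
    exon_codons_max: int = 60
    intron_min: int = 30
    intron_max: int = 80
    novex_exon_codons: int = 20
    iso_exon_period: int = 3  # every k-th internal exon absent from the short tx
    low_psi_period: int = 10  # every k-th exon assigned a sub-threshold PSI
    low_psi_min: float = 0.01
    low_psi_max: float = 0.12
    band_fractions: tuple[float, float, float, float] = (0.05, 0.45, 0.40, 0.10)
    strand: str = "+"
    chrom: str = "chrS"
    locus_offset: int = 100001
    flank: int = 200
    cga_weight: float = 1.0  # enrichment of CGA/AGA codons (CpG hotspot supply)
    # variant classes to plant
    class_counts: tuple[tuple[str, int], ...] = (
        (cq.NONSENSE, 30),
        (cq.FRAMESHIFT, 20),
        (cq.ESSENTIAL_SPLICE, 12),
        (cq.SPLICE_REGION, 12),
        (cq.INFRAME_INDEL, 6),
        (cq.MISSENSE, 30),
        (cq.SYNONYMOUS, 30),
    )
    # allele-frequency spectrum
    singleton_fraction: float = 0.6
    common_fraction: float = 0.05
    low_freq_max_af: float = 0.005
    common_max_af: float = 0.02
    hom_rate: float = 0.0
    # populations: (label, diploid individuals, carrier-rate multiplier)
    populations: tuple[tuple[str, int, float], ...] = (
        ("AFR", 5000, 1.3),
        ("EUR", 5000, 0.8),
        ("EAS", 5000, 1.0),
        ("SAS", 5000, 1.5),
    )
    # dataset roles
    superset: str = "SIM_EXAC"
    subsets: tuple[tuple[str, float, float], ...] = (
        # (name, cohort fraction, per-variant membership probability)
        ("SIM_1KG", 0.3, 0.5),
        ("SIM_ESP", 0.3, 0.5),
    )
    n_false_positives: int = 4  # planted per subset, absent from the superset
    # quality and coverage
    pass_fraction: float = 0.95
    depth_mean: float = 60.0
    depth_sd: float = 15.0
    low_depth_fraction: float = 0.1
    min_depth: float = 15.0

    def cohort_size(self) -> int:
        return sum(n for _, n, _ in self.populations)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_counts"] = [list(x) for x in self.class_counts]
        d["populations"] = [list(x) for x in self.populations]
        d["subsets"] = [list(x) for x in self.subsets]
        d["band_fractions"] = list(self.band_fractions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("class_counts", "populations", "subsets"):
            if key in d:
                d[key] = tuple(tuple(x) for x in d[key])
        if "band_fractions" in d:
            d["band_fractions"] = tuple(d["band_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


class SimulationError(ValueError):
    """Infeasible simulation configuration (e.g. not enough eligible sites)."""


# ---------------------------------------------------------------------------
# gene model simulation
# ---------------------------------------------------------------------------


def planned_exon_classes(config: SimConfig) -> dict[str, str]:
    """Exon-class truth table implied by the deterministic construction rules.

    Internal exon i (1-based) is absent from the short transcript when
    ``i % iso_exon_period == 1`` (never the first or last exon); exon i gets a
    sub-threshold PSI when ``i % low_psi_period == 5``; low PSI takes
    precedence.  The novex exon is isoform-specific by construction.
    """
    classes = {}
    for i in range(1, config.n_exons + 1):
        eid = f"E{i:03d}"
        if i % config.low_psi_period == 5 % config.low_psi_period:
            classes[eid] = "low_psi"
        elif 1 < i < config.n_exons and i % config.iso_exon_period == 1:
            classes[eid] = "isoform_specific"
        else:
            classes[eid] = "all_transcripts"
    classes["EN"] = "isoform_specific"
    return classes


def _skipped_exon_ids(config: SimConfig) -> list[str]:
    return [
        f"E{i:03d}"
        for i in range(2, config.n_exons)
        if i % config.iso_exon_period == 1
    ]


def _low_psi_exon_ids(config: SimConfig) -> list[str]:
    return [
        f"E{i:03d}"
        for i in range(1, config.n_exons + 1)
        if i % config.low_psi_period == 5 % config.low_psi_period
    ]


def _random_seq(rng, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _random_codons(rng, n: int, cga_weight: float) -> str:
    weights = np.array(
        [cga_weight if c in ("CGA", "AGA") else 1.0 for c in SENSE_CODONS]
    )
    weights /= weights.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n, p=weights)
    return "".join(SENSE_CODONS[i] for i in idx)


def simulate_gene_model(config: SimConfig) -> GeneModel:
    """Build a validated titin-like gene model from the configuration.

    Every exon length is a multiple of three and every transcript's CDS starts
    at an exon boundary, so each exon contributes whole codons in every
    transcript and exon sequences built from sense codons contain no internal
    stop in any splicing.  The novex-like transcript carries all main exons
    plus a unique terminal exon outside its coding span.
    """
    if config.n_exons < 8:
        raise SimulationError("need at least 8 exons")
    rng = np.random.default_rng(config.seed)
    exon_lengths = 3 * rng.integers(
        config.exon_codons_min, config.exon_codons_max + 1, size=config.n_exons
    )
    intron_lengths = rng.integers(
        max(13, config.intron_min), config.intron_max + 1, size=config.n_exons
    )  # one intron after each exon; the last hosts the novex exon

    pieces: list[str] = []
    cursor = config.locus_offset
    pieces.append(_random_seq(rng, config.flank))
    cursor += config.flank

    exons: dict[str, Exon] = {}
    main_ids: list[str] = []
    for i in range(1, config.n_exons + 1):
        eid = f"E{i:03d}"
        length = int(exon_lengths[i - 1])
        seq = _random_codons(rng, length // 3, config.cga_weight)
        if config.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        exons[eid] = Exon(eid, cursor, cursor + length - 1)
        main_ids.append(eid)
        pieces.append(seq)
        cursor += length
        if i < config.n_exons:
            ilen = int(intron_lengths[i - 1])
            intron = _random_seq(rng, ilen)
            if config.strand == "+":
                intron = "GT" + intron[2:-2] + "AG"
            else:
                intron = "CT" + intron[2:-2] + "AC"
            pieces.append(intron)
            cursor += ilen

    # unique terminal exon of the novex-like transcript, past the last main exon
    gap = max(20, int(intron_lengths[-1]))
    pieces.append(_random_seq(rng, gap))
    cursor += gap
    novex_len = 3 * config.novex_exon_codons
    novex_seq = _random_codons(rng, config.novex_exon_codons, 1.0)
    exons["EN"] = Exon("EN", cursor, cursor + novex_len - 1)
    pieces.append(novex_seq)
    cursor += novex_len
    pieces.append(_random_seq(rng, config.flank))

    skipped = set(_skipped_exon_ids(config))
    short_ids = [e for e in main_ids if e not in skipped]
    cds_start = exons[main_ids[0]].start
    cds_end = exons[main_ids[-1]].end
    transcripts = {
        "T1": Transcript("T1", "full", tuple(main_ids), cds_start, cds_end),
        "T2": Transcript("T2", "short", tuple(short_ids), cds_start, cds_end),
        "T3": Transcript(
            "T3", "novex3-like", tuple(main_ids + ["EN"]), cds_start, cds_end
        ),
    }

    # band intervals partition the CDS span of the full transcript
    span = cds_end - cds_start + 1
    fractions = np.asarray(config.band_fractions, dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9 or (fractions <= 0).any():
        raise SimulationError("band fractions must be positive and sum to 1")
    edges = cds_start + np.round(np.cumsum(fractions) * span).astype(int)
    edges[-1] = cds_end + 1
    bands, lo = [], cds_start
    for name, hi in zip(("Z", "I", "A", "M"), edges):
        if hi <= lo:
            raise SimulationError(f"band {name} would be empty")
        bands.append(BandInterval(name, lo, int(hi) - 1))
        lo = int(hi)

    low_psi = set(_low_psi_exon_ids(config))
    psi = {}
    for eid in exons:
        if eid in low_psi:
            psi[eid] = round(float(rng.uniform(config.low_psi_min, config.low_psi_max)), 4)
        else:
            psi[eid] = 1.0

    model = GeneModel(
        gene_name="TTN_SIM",
        chrom=config.chrom,
        strand=config.strand,
        locus_offset=config.locus_offset,
        sequence="".join(pieces),
        exons=exons,
        transcripts=transcripts,
        bands=bands,
        psi=psi,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# candidate sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Candidate:
    """One eligible variant site with its guaranteed consequence class."""

    vclass: str
    pos: int
    ref: str
    alt: str
    exon_id: str | None
    band: str | None
    exon_class: str
    splice_distance: int | None = None
    ref_codon: str | None = None
    codon_pos: int | None = None
    alt_codon: str | None = None


class VariantPlanter:
    """Deterministic pools of class-guaranteed variant sites on a model."""

    def __init__(self, model: GeneModel, psi_threshold: float = 0.15):
        self.model = model
        self.psi_threshold = psi_threshold
        self.tx = model.reference_transcript_id()
        self._pools: dict[str, list[Candidate]] = {}

    def pool(self, vclass: str) -> list[Candidate]:
        if vclass not in self._pools:
            builder = {
                cq.NONSENSE: self._substitution_pool,
                cq.MISSENSE: self._substitution_pool,
                cq.SYNONYMOUS: self._substitution_pool,
                cq.FRAMESHIFT: self._indel_pool,
                cq.INFRAME_INDEL: self._indel_pool,
                cq.ESSENTIAL_SPLICE: self._splice_pool,
                cq.SPLICE_REGION: self._splice_pool,
            }.get(vclass)
            if builder is None:
                raise SimulationError(f"no planting rule for class {vclass!r}")
            builder()
        return self._pools[vclass]

    # substitutions: scan every codon of the reference transcript
    def _substitution_pool(self) -> None:
        model, tx = self.model, self.tx
        cds = model.spliced_cds(tx)
        pools = {cq.NONSENSE: [], cq.MISSENSE: [], cq.SYNONYMOUS: []}
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci : 3 * ci + 3]
            if codon in STOP_CODONS:
                continue
            ref_aa = str(Seq(codon).translate())
            for cp in range(3):
                cds_pos = 3 * ci + cp + 1
                gpos = model.cds_to_genomic(tx, cds_pos)
                exon = model.exon_of(gpos)
                exon_cls = model.exon_class(exon.exon_id, self.psi_threshold)
                genomic_ref = model.base_at(gpos)
                for alt_base in BASES:
                    if alt_base == codon[cp]:
                        continue
                    alt_codon = codon[:cp] + alt_base + codon[cp + 1 :]
                    alt_aa = str(Seq(alt_codon).translate())
                    if alt_codon in STOP_CODONS:
                        vclass = cq.NONSENSE
                    elif alt_aa == ref_aa:
                        vclass = cq.SYNONYMOUS
                    else:
                        vclass = cq.MISSENSE
                    genomic_alt = (
                        alt_base
                        if model.strand == "+"
                        else str(Seq(alt_base).complement())
                    )
                    pools[vclass].append(
                        Candidate(
                            vclass=vclass,
                            pos=gpos,
                            ref=genomic_ref,
                            alt=genomic_alt,
                            exon_id=exon.exon_id,
                            band=model.band_of(gpos),
                            exon_class=exon_cls,
                            ref_codon=codon,
                            codon_pos=cp + 1,
                            alt_codon=alt_codon,
                        )
                    )
        self._pools.update(pools)

    # indels: short deletions strictly interior to an exon, pre-normalised
    def _indel_pool(self) -> None:
        model, tx = self.model, self.tx
        fs, inframe = [], []
        for eid in model.transcripts[tx].exon_ids:
            exon = model.exons[eid]
            exon_cls = model.exon_class(eid, self.psi_threshold)
            for anchor in range(exon.start + 3, exon.end - 6, 2):
                for del_len, bucket in ((1, fs), (2, fs), (3, inframe)):
                    ref = model.subsequence(anchor, anchor + del_len)
                    rec = VariantRecord(
                        chrom=model.chrom, pos=anchor, ref=ref, alt=ref[0],
                        AC=1, AN=2,
                    )
                    norm = normalize_variant(model, rec)
                    # reject candidates whose left-aligned form escapes the
                    # exon interior (homopolymer runs across the boundary)
                    del_lo, del_hi = norm.pos + 1, norm.pos + len(norm.ref) - 1
                    if del_lo <= exon.start + 1 or del_hi >= exon.end - 1:
                        continue
                    bucket.append(
                        Candidate(
                            vclass=cq.FRAMESHIFT if del_len != 3 else cq.INFRAME_INDEL,
                            pos=norm.pos,
                            ref=norm.ref,
                            alt=norm.alt,
                            exon_id=eid,
                            band=model.band_of(norm.pos),
                            exon_class=exon_cls,
                        )
                    )
        self._pools[cq.FRAMESHIFT] = fs
        self._pools[cq.INFRAME_INDEL] = inframe

    # intronic substitutions at exact distances from the splice boundaries
    def _splice_pool(self) -> None:
        model, tx = self.model, self.tx
        essential, region = [], []
        exon_list = [model.exons[e] for e in model.transcripts[tx].exon_ids]
        for left, right in zip(exon_list, exon_list[1:]):
            intron_len = right.start - left.end - 1
            if intron_len < 13:
                continue  # distances would be ambiguous between boundaries
            for d in range(1, 7):
                for gpos, adjacent in (
                    (left.end + d, left),
                    (right.start - d, right),
                ):
                    donor_side = (
                        (adjacent is left) if model.strand == "+" else (adjacent is right)
                    )
                    signed = d if donor_side else -d
                    ref = model.base_at(gpos)
                    exon_cls = model.exon_class(adjacent.exon_id, self.psi_threshold)
                    bucket = essential if d <= 2 else region
                    for alt in BASES:
                        if alt == ref:
                            continue
                        bucket.append(
                            Candidate(
                                vclass=cq.ESSENTIAL_SPLICE if d <= 2 else cq.SPLICE_REGION,
                                pos=gpos,
                                ref=ref,
                                alt=alt,
                                exon_id=adjacent.exon_id,
                                band=model.band_of(gpos),
                                exon_class=exon_cls,
                                splice_distance=signed,
                            )
                        )
        self._pools[cq.ESSENTIAL_SPLICE] = essential
        self._pools[cq.SPLICE_REGION] = region

    def draw(
        self,
        vclass: str,
        n: int,
        rng: np.random.Generator,
        used: set,
        predicate=None,
    ) -> list[Candidate]:
        """Draw n unused candidates of a class, optionally filtered."""
        pool = [c for c in self.pool(vclass) if predicate is None or predicate(c)]
        order = rng.permutation(len(pool))
        out: list[Candidate] = []
        for i in order:
            c = pool[i]
            key = (self.model.chrom, c.pos, c.ref, c.alt)
            if key in used:
                continue
            used.add(key)
            out.append(c)
            if len(out) == n:
                return out
        raise SimulationError(
            f"not enough eligible positions for class {vclass!r}: "
            f"wanted {n}, found {len(out)}"
        )

    def take(self, vclass: str, n: int, used: set, predicate=None) -> list[Candidate]:
        """Like draw, but in deterministic pool order (for worked-example fixtures)."""
        out: list[Candidate] = []
        for c in self.pool(vclass):
            if predicate is not None and not predicate(c):
                continue
            key = (self.model.chrom, c.pos, c.ref, c.alt)
            if key in used:
                continue
            used.add(key)
            out.append(c)
            if len(out) == n:
                return out
        raise SimulationError(
            f"not enough eligible positions for class {vclass!r}: "
            f"wanted {n}, found {len(out)}"
        )


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    true_class: str
    band: str | None
    exon_class: str
    afs_class: str
    false_positive: bool
    low_depth: bool
    passes: bool
    datasets: tuple[str, ...]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulatedCohort:
    config: SimConfig
    records_by_dataset: dict[str, list[VariantRecord]]
    coverage: CoverageTable
    truth: list[TruthRecord]

    def truth_by_key(self) -> dict:
        return {t.key: t for t in self.truth}


def _draw_afs(rng, config: SimConfig, an_total: int) -> tuple[str, int]:
    """(afs label, AC) drawn from the configured spectrum; label is truth."""
    u = rng.random()
    if u < config.singleton_fraction:
        return "private", 1
    if u < config.singleton_fraction + config.common_fraction:
        af = rng.uniform(config.low_freq_max_af, config.common_max_af)
        return "common", max(int(round(af * an_total)), int(config.low_freq_max_af * an_total) + 1)
    hi = max(3, int(config.low_freq_max_af * an_total) - 1)
    return "low_frequency", int(rng.integers(2, hi + 1))


def simulate_variants(config: SimConfig, model: GeneModel) -> SimulatedCohort:
    """Plant the configured variant classes and build per-dataset call sets."""
    rng = np.random.default_rng(config.seed + 1_000_003)
    planter = VariantPlanter(model)
    used: set = set()
    n_total = config.cohort_size()
    an_total = 2 * n_total
    pop_labels = [p for p, _, _ in config.populations]
    pop_an = {p: 2 * n for p, n, _ in config.populations}
    weights = np.array([n * m for _, n, m in config.populations], dtype=float)
    weights /= weights.sum()

    planted: list[tuple[Candidate, str, int]] = []  # candidate, afs label, AC
    for vclass, count in config.class_counts:
        for cand in planter.draw(vclass, count, rng, used):
            label, ac = _draw_afs(rng, config, an_total)
            planted.append((cand, label, ac))

    records_by_dataset: dict[str, list[VariantRecord]] = defaultdict(list)
    truth: list[TruthRecord] = []
    depth_by_pos: dict[int, float] = {}

    def assign_depth(pos: int) -> float:
        if pos not in depth_by_pos:
            if rng.random() < config.low_depth_fraction:
                depth_by_pos[pos] = float(rng.uniform(3.0, config.min_depth - 3.0))
            else:
                d = rng.normal(config.depth_mean, config.depth_sd)
                depth_by_pos[pos] = float(max(config.min_depth + 5.0, d))
        return depth_by_pos[pos]

    for cand, afs_label, ac in planted:
        hom = int(rng.binomial(ac // 2, config.hom_rate)) if config.hom_rate else 0
        split = rng.multinomial(ac, weights)
        pop_counts = tuple(
            sorted(
                (label, (int(split[i]), pop_an[label]))
                for i, label in enumerate(pop_labels)
            )
        )
        passes = bool(rng.random() < config.pass_fraction)
        status = "PASS" if passes else "LowQual"
        depth = assign_depth(cand.pos)
        rec = VariantRecord(
            chrom=model.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
            AC=ac, AN=an_total, hom_count=hom, qual=99.0,
            filter_status=status, pop_counts=pop_counts, dataset=config.superset,
        )
        records_by_dataset[config.superset].append(rec)
        datasets = [config.superset]
        for name, fraction, membership in config.subsets:
            if rng.random() >= membership:
                continue
            an_sub = int(round(an_total * fraction))
            ac_sub = min(an_sub, max(1, int(rng.binomial(ac, fraction))))
            records_by_dataset[name].append(
                VariantRecord(
                    chrom=model.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
                    AC=ac_sub, AN=an_sub, hom_count=0, qual=99.0,
                    filter_status=status, dataset=name,
                )
            )
            datasets.append(name)
        truth.append(
            TruthRecord(
                chrom=model.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
                true_class=cand.vclass, band=cand.band, exon_class=cand.exon_class,
                afs_class=afs_label, false_positive=False,
                low_depth=depth < config.min_depth, passes=passes,
                datasets=tuple(datasets),
            )
        )

    # planted false positives: truncating-class sites unique to one subset
    fp_classes = itertools.cycle([cq.FRAMESHIFT, cq.NONSENSE])
    for name, fraction, _ in config.subsets:
        an_sub = int(round(an_total * fraction))
        for vclass in itertools.islice(fp_classes, config.n_false_positives):
            cand = planter.draw(
                vclass, 1, rng, used,
                predicate=lambda c: c.exon_class == "all_transcripts",
            )[0]
            depth = assign_depth(cand.pos)
            records_by_dataset[name].append(
                VariantRecord(
                    chrom=model.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
                    AC=1, AN=an_sub, hom_count=0, qual=80.0,
                    filter_status="PASS", dataset=name,
                )
            )
            truth.append(
                TruthRecord(
                    chrom=model.chrom, pos=cand.pos, ref=cand.ref, alt=cand.alt,
                    true_class=cand.vclass, band=cand.band,
                    exon_class=cand.exon_class, afs_class="private",
                    false_positive=True, low_depth=depth < config.min_depth,
                    passes=True, datasets=(name,),
                )
            )

    coverage = CoverageTable(
        [
            CoverageRecord(
                chrom=model.chrom, pos=pos, mean_depth=round(depth, 1),
                frac_ge=tuple(
                    (t, round(min(1.0, 1.0 - np.exp(-depth / t)), 3))
                    for t in (10, 50)
                ),
            )
            for pos, depth in sorted(depth_by_pos.items())
        ]
    )
    truth.sort(key=lambda t: t.key)
    for name in records_by_dataset:
        records_by_dataset[name].sort(key=variant_key)
    return SimulatedCohort(
        config=config,
        records_by_dataset=dict(records_by_dataset),
        coverage=coverage,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "chrom", "pos", "ref", "alt", "true_class", "band", "exon_class",
    "afs_class", "false_positive", "low_depth", "passes", "datasets",
]


def write_truth(truth: list[TruthRecord], path) -> None:
    lines = ["#" + "\t".join(TRUTH_COLUMNS) + "\n"]
    for t in truth:
        lines.append(
            "\t".join(
                [
                    t.chrom, str(t.pos), t.ref, t.alt, t.true_class,
                    t.band or ".", t.exon_class, t.afs_class,
                    str(int(t.false_positive)), str(int(t.low_depth)),
                    str(int(t.passes)), ",".join(t.datasets),
                ]
            )
            + "\n"
        )
    Path(path).write_text("".join(lines))


def read_truth(path) -> list[TruthRecord]:
    truth = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        truth.append(
            TruthRecord(
                chrom=f[0], pos=int(f[1]), ref=f[2], alt=f[3], true_class=f[4],
                band=None if f[5] == "." else f[5], exon_class=f[6],
                afs_class=f[7], false_positive=bool(int(f[8])),
                low_depth=bool(int(f[9])), passes=bool(int(f[10])),
                datasets=tuple(f[11].split(",")),
            )
        )
    return truth


def write_bundle(config: SimConfig, model: GeneModel, cohort: SimulatedCohort, outdir) -> Path:
    """Write model.json, locus.fa, cohort_<ds>.vcf, coverage.tsv, truth.tsv,
    simconfig.yaml.  Byte-identical output for identical configurations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_gene_model(model, outdir)
    contig_len = model.locus_offset + len(model.sequence)
    for name in sorted(cohort.records_by_dataset):
        write_vcf(
            cohort.records_by_dataset[name],
            outdir / f"cohort_{name}.vcf",
            chrom=model.chrom,
            contig_length=contig_len,
        )
    write_coverage(cohort.coverage, outdir / "coverage.tsv")
    write_truth(cohort.truth, outdir / "truth.tsv")
    with open(outdir / "simconfig.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return outdir


def simulate_bundle(config: SimConfig, outdir) -> tuple[GeneModel, SimulatedCohort]:
    model = simulate_gene_model(config)
    cohort = simulate_variants(config, model)
    write_bundle(config, model, cohort, outdir)
    return model, cohort


# ---------------------------------------------------------------------------
# worked-example fixtures with published aggregate margins
# ---------------------------------------------------------------------------

# Shared geometry for the worked-example fixtures: an 80-exon gene with fixed
# exon/intron sizes so candidate pools are ample in every band, and CGA/AGA
# codons enriched so the CpG-hotspot nonsense supply matches a titin-like gene.
_FIXTURE_GEOMETRY = dict(
    n_exons=80,
    exon_codons_min=50,
    exon_codons_max=50,
    intron_min=40,
    intron_max=40,
    novex_exon_codons=20,
    band_fractions=(0.05, 0.45, 0.40, 0.10),
    cga_weight=3.0,
)

_FS, _NS, _SP = cq.FRAMESHIFT, cq.NONSENSE, cq.ESSENTIAL_SPLICE

# Reference-population cohort sizes (ExAC / 1000 Genomes phase 3 / ESP).
TABLE1_COHORTS = {"ExAC": 60706, "1KG": 2504, "ESP": 6504}
_TABLE1_AN = {"ExAC": 121412, "1KG": 5008, "ESP": 13008}

# ExAC variants surviving every filter, per (band, class): (variants, carriers).
_EXAC_KEEP = {
    ("Z", _FS): (8, 8), ("Z", _NS): (4, 4), ("Z", _SP): (7, 11),
    ("I", _FS): (10, 12), ("I", _NS): (19, 20), ("I", _SP): (10, 12),
    ("A", _FS): (35, 35), ("A", _NS): (37, 55), ("A", _SP): (18, 29),
    ("M", _FS): (10, 12), ("M", _NS): (12, 18), ("M", _SP): (3, 3),
}
# ExAC variants in isoform-specific / low-PSI exons (transcript-filter stage).
_EXAC_NOTALL = {
    ("Z", _FS): 2, ("Z", _NS): 4, ("Z", _SP): 3,
    ("I", _FS): 69, ("I", _NS): 69, ("I", _SP): 62,
    ("A", _FS): 15, ("A", _NS): 12, ("A", _SP): 5,
    ("M", _NS): 5, ("M", _SP): 1,
}
# ExAC variants in constitutive exons but at low-coverage positions.
_EXAC_LOWDEPTH = {("I", _FS): 30, ("I", _NS): 15, ("I", _SP): 5}
# Allele copies carried by the removed ExAC variants, per band.
_EXAC_REMOVED_CARRIERS = {"Z": 15, "I": 537, "A": 34, "M": 8}

# Subset call sets reuse ExAC keys by (band, class, slice); conc = fresh keys
# unique to the subset (removed by the concordance filter).
_1KG_KEEP = [("I", _NS, 0, 1, 1), ("A", _FS, 0, 1, 2), ("A", _NS, 0, 6, 6),
             ("M", _SP, 0, 1, 1)]  # (band, class, start, n, carriers)
_ESP_KEEP = [("Z", _NS, 0, 1, 1), ("I", _NS, 1, 5, 5), ("I", _SP, 0, 2, 2),
             ("A", _FS, 1, 1, 1), ("A", _NS, 6, 3, 3), ("M", _FS, 0, 2, 5),
             ("M", _NS, 0, 2, 2)]
_1KG_NOTALL = [("Z", _SP, 0, 1), ("I", _SP, 0, 10), ("A", _SP, 0, 1),
               ("I", _NS, 0, 3), ("A", _NS, 0, 2)]
# ESP's I-band splice slice [7:16] overlaps 1KG's [0:10] in exactly 3 keys,
# the three splice variants shared between the two subset call sets.
_ESP_NOTALL = [("I", _FS, 0, 15), ("I", _NS, 3, 12), ("I", _SP, 7, 9)]
_1KG_CONC = [("I", _NS, 4), ("A", _NS, 3)]
_ESP_CONC = [("I", _FS, 7), ("I", _NS, 5), ("I", _SP, 2)]
_1KG_REMOVED_CARRIERS = 36
_ESP_REMOVED_CARRIERS = {_FS: 160, _NS: 22, _SP: 411}

# Per-population carriers/sizes of the filtered ExAC truncation set.
TABLE1_GROUP_COUNTS = {
    "AFR": (24, 5203), "AMR": (29, 5789), "FIN": (4, 3307), "NFE": (95, 33370),
    "EAS": (16, 4327), "SAS": (51, 8256), "OTH": (0, 454),
}


def _assign_acs(n: int, carriers: int) -> list[int]:
    """Split `carriers` allele copies over n variants, singletons first."""
    acs = [1] * n
    extra = carriers - n
    if extra < 0:
        raise SimulationError(f"carriers {carriers} below variant count {n}")
    i = 0
    while extra > 0:
        acs[i % n] += 1
        extra -= 1
        i += 1
    return acs


@dataclass
class Table1Fixture:
    """Deterministic three-dataset cohort whose aggregate margins reproduce the
    published reference-population truncation summary."""

    model: GeneModel
    records_by_dataset: dict[str, list[VariantRecord]]
    coverage: CoverageTable
    cohort_sizes: dict[str, int]
    group_counts: dict[str, tuple[int, int]]
    superset: str = "ExAC"


def make_table1_fixture() -> Table1Fixture:
    config = SimConfig(seed=97, **_FIXTURE_GEOMETRY)
    model = simulate_gene_model(config)
    planter = VariantPlanter(model)
    used: set = set()

    def keep_pred(band):
        return lambda c: c.band == band and c.exon_class == "all_transcripts"

    def notall_pred(band):
        return lambda c: c.band == band and c.exon_class != "all_transcripts"

    exac_keep: dict[tuple[str, str], list[Candidate]] = {}
    exac_notall: dict[tuple[str, str], list[Candidate]] = {}
    ok_positions: set[int] = set()

    for (band, vclass), (n, _) in _EXAC_KEEP.items():
        cands = planter.take(vclass, n, used, keep_pred(band))
        exac_keep[(band, vclass)] = cands
        ok_positions.update(c.pos for c in cands)
    for (band, vclass), n in _EXAC_NOTALL.items():
        cands = planter.take(vclass, n, used, notall_pred(band))
        exac_notall[(band, vclass)] = cands
        ok_positions.update(c.pos for c in cands)

    kg_conc: list[Candidate] = []
    for band, vclass, n in _1KG_CONC:
        kg_conc.extend(planter.take(vclass, n, used, keep_pred(band)))
    esp_conc: list[Candidate] = []
    for band, vclass, n in _ESP_CONC:
        esp_conc.extend(planter.take(vclass, n, used, keep_pred(band)))
    ok_positions.update(c.pos for c in kg_conc + esp_conc)

    exac_lowdepth: dict[tuple[str, str], list[Candidate]] = {}
    low_positions: set[int] = set()
    for (band, vclass), n in _EXAC_LOWDEPTH.items():
        pred = keep_pred(band)
        cands = planter.take(
            vclass, n, used,
            lambda c, p=pred: p(c) and c.pos not in ok_positions,
        )
        exac_lowdepth[(band, vclass)] = cands
        low_positions.update(c.pos for c in cands)

    def make_records(cands, acs, dataset, an):
        return [
            VariantRecord(
                chrom=model.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                AC=ac, AN=an, hom_count=0, qual=99.0,
                filter_status="PASS", dataset=dataset,
            )
            for c, ac in zip(cands, acs)
        ]

    # --- ExAC -------------------------------------------------------------
    an = _TABLE1_AN["ExAC"]
    exac_records: list[VariantRecord] = []
    for (band, vclass), (n, carriers) in _EXAC_KEEP.items():
        exac_records.extend(
            make_records(exac_keep[(band, vclass)], _assign_acs(n, carriers), "ExAC", an)
        )
    for band in ("Z", "I", "A", "M"):
        removed = [
            c
            for (b, v), cands in list(exac_notall.items()) + list(exac_lowdepth.items())
            if b == band
            for c in cands
        ]
        acs = _assign_acs(len(removed), _EXAC_REMOVED_CARRIERS[band])
        exac_records.extend(make_records(removed, acs, "ExAC", an))

    # --- 1000 Genomes role --------------------------------------------------
    an = _TABLE1_AN["1KG"]
    kg_records: list[VariantRecord] = []
    for band, vclass, start, n, carriers in _1KG_KEEP:
        cands = exac_keep[(band, vclass)][start : start + n]
        kg_records.extend(make_records(cands, _assign_acs(n, carriers), "1KG", an))
    kg_removed = [
        c
        for band, vclass, start, n in _1KG_NOTALL
        for c in exac_notall[(band, vclass)][start : start + n]
    ] + kg_conc
    kg_records.extend(
        make_records(
            kg_removed, _assign_acs(len(kg_removed), _1KG_REMOVED_CARRIERS), "1KG", an
        )
    )

    # --- ESP role -----------------------------------------------------------
    an = _TABLE1_AN["ESP"]
    esp_records: list[VariantRecord] = []
    for band, vclass, start, n, carriers in _ESP_KEEP:
        cands = exac_keep[(band, vclass)][start : start + n]
        esp_records.extend(make_records(cands, _assign_acs(n, carriers), "ESP", an))
    for vclass in (_FS, _NS, _SP):
        removed = [
            c
            for band, v, start, n in _ESP_NOTALL
            if v == vclass
            for c in exac_notall[(band, v)][start : start + n]
        ] + [c for c in esp_conc if c.vclass == vclass]
        acs = _assign_acs(len(removed), _ESP_REMOVED_CARRIERS[vclass])
        esp_records.extend(make_records(removed, acs, "ESP", an))

    positions = sorted(
        {r.pos for recs in (exac_records, kg_records, esp_records) for r in recs}
    )
    coverage = CoverageTable(
        [
            CoverageRecord(
                chrom=model.chrom, pos=pos,
                mean_depth=8.0 if pos in low_positions else 60.0,
                frac_ge=((10, 0.4), (50, 0.1)) if pos in low_positions
                else ((10, 1.0), (50, 0.8)),
            )
            for pos in positions
        ]
    )
    for records in (exac_records, kg_records, esp_records):
        records.sort(key=variant_key)
    return Table1Fixture(
        model=model,
        records_by_dataset={"ExAC": exac_records, "1KG": kg_records, "ESP": esp_records},
        coverage=coverage,
        cohort_sizes=dict(TABLE1_COHORTS),
        group_counts=dict(TABLE1_GROUP_COUNTS),
        superset="ExAC",
    )


# --- nonsense-spectrum fixture ---------------------------------------------

# (ref codon, alt codon, band predicate, count): 21 A-band Cga/Tga CpG
# hotspots, 2 A-band Aga/Tga (the other reachable R/* pattern), 13 Cga/Tga
# outside the A band, and non-CpG fillers whose context is class-guaranteed.
_SPECTRUM_PLAN = [
    ("CGA", "TGA", lambda b: b == "A", 21),
    ("AGA", "TGA", lambda b: b == "A", 2),
    ("CGA", "TGA", lambda b: b in ("I", "M"), 13),
    ("CAA", "TAA", lambda b: b is not None, 6),
    ("TAC", "TAA", lambda b: b is not None, 6),
]


def make_spectrum_fixture():
    """Nonsense calls whose pattern/CpG margins match the published spectrum:
    21/23 A-band R/* are Cga/Tga, and those 21 are 21/34 of all CpG-hotspot
    nonsense variants.  Returns (calls, model)."""
    config = SimConfig(seed=98, **_FIXTURE_GEOMETRY)
    model = simulate_gene_model(config)
    planter = VariantPlanter(model)
    used: set = set()
    an = _TABLE1_AN["ExAC"]
    calls = []
    for ref_codon, alt_codon, band_pred, n in _SPECTRUM_PLAN:
        cands = planter.take(
            cq.NONSENSE, n, used,
            lambda c, rc=ref_codon, ac=alt_codon, bp=band_pred: (
                c.ref_codon == rc and c.alt_codon == ac and bp(c.band)
            ),
        )
        for c in cands:
            rec = VariantRecord(
                chrom=model.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                AC=1, AN=an, dataset="ExAC",
            )
            calls.append(cq.classify_variant(model, rec))
    return calls, model


# --- splice allele-frequency-spectrum fixture -------------------------------

# (band predicate, |distance| choices, afs label, AC, count)
_SPLICE_PLAN = [
    ("A", (1, 2), "private", 1, 18),
    ("A", (1, 2), "low_frequency", 10, 4),
    ("other", (1, 2), "private", 1, 23),
    ("other", (1, 2), "low_frequency", 10, 4),
    ("A", (3, 4), "private", 1, 48),
    ("A", (3, 4), "low_frequency", 10, 35),
    ("A", (3, 4), "common", 1000, 5),
    ("A", (5, 6), "private", 1, 48),
    ("A", (5, 6), "low_frequency", 10, 35),
    ("A", (5, 6), "common", 1000, 4),
    ("other", (3, 4), "private", 1, 41),
    ("other", (3, 4), "low_frequency", 10, 30),
    ("other", (3, 4), "common", 1000, 4),
    ("other", (5, 6), "private", 1, 41),
    ("other", (5, 6), "low_frequency", 10, 30),
    ("other", (5, 6), "common", 1000, 3),
]


def make_splice_fixture():
    """373 splice calls matching the published splice-spectrum margins:
    49 essential (41 private), 324 non-essential, 197 in the A band of which
    175 are non-essential.  Returns (calls, model)."""
    config = SimConfig(seed=99, **_FIXTURE_GEOMETRY)
    model = simulate_gene_model(config)
    planter = VariantPlanter(model)
    used: set = set()
    an = _TABLE1_AN["ExAC"]
    calls = []
    for band, dists, _, ac, n in _SPLICE_PLAN:
        vclass = cq.ESSENTIAL_SPLICE if max(dists) <= 2 else cq.SPLICE_REGION
        cands = planter.take(
            vclass, n, used,
            lambda c, b=band, ds=dists: (
                (c.band == "A" if b == "A" else c.band != "A")
                and abs(c.splice_distance) in ds
            ),
        )
        for c in cands:
            rec = VariantRecord(
                chrom=model.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                AC=ac, AN=an, dataset="ExAC",
            )
            calls.append(cq.classify_variant(model, rec))
    return calls, model
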