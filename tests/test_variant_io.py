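"""VCF/coverage I/O, allele normalisation and variant keying."""

import numpy as np
import pytest

from ttnpop.synthetic_data import write_bundle
from ttnpop.variant_io import (
    CoverageRecord,
    VariantIOError,
    VariantRecord,
    normalize_variant,
    read_coverage,
    read_vcf,
    variant_key,
    write_coverage,
    write_vcf,
)

from conftest import build_two_exon_model

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="x">
##INFO=<ID=AN,Number=1,Type=Integer,Description="x">
##INFO=<ID=Hom,Number=A,Type=Integer,Description="x">
##contig=<ID=chrT,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
chrT\t150\t.\tG\tA,T\t50\tPASS\tAC=5,2;AN=100;Hom=1,0
"""


class TestReadVcf:
    def test_multiallelic_decomposition(self, tmp_path):
        path = tmp_path / "multi.vcf"
        path.write_text(MULTIALLELIC_VCF)
        records = read_vcf(path, dataset="X")
        assert [(r.alt, r.AC, r.hom_count) for r in records] == [("A", 5, 1), ("T", 2, 0)]
        assert all(r.AN == 100 for r in records)

    def test_empty_body(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(MULTIALLELIC_VCF.rsplit("chrT", 1)[0])
        assert read_vcf(path) == []

    def test_missing_ac_an_is_an_error(self, tmp_path):
        text = MULTIALLELIC_VCF.replace("AC=5,2;AN=100;Hom=1,0", "Hom=1,0")
        path = tmp_path / "bad.vcf"
        path.write_text(text)
        with pytest.raises(VariantIOError, match="AC/AN"):
            read_vcf(path)

    def test_simulator_round_trip_matches_truth(self, sim_config, sim_model, sim_cohort, tmp_path):
        write_bundle(sim_config, sim_model, sim_cohort, tmp_path)
        for name, expected in sim_cohort.records_by_dataset.items():
            reread = read_vcf(tmp_path / f"cohort_{name}.vcf", dataset=name)
            assert reread == expected

    def test_region_filter(self, sim_config, sim_model, sim_cohort, tmp_path):
        write_bundle(sim_config, sim_model, sim_cohort, tmp_path)
        name = sim_config.superset
        full = sim_cohort.records_by_dataset[name]
        lo, hi = full[10].pos, full[30].pos
        region = read_vcf(
            tmp_path / f"cohort_{name}.vcf", region=f"{sim_model.chrom}:{lo}-{hi}",
            dataset=name,
        )
        assert region == [r for r in full if lo <= r.pos <= hi]


class TestRecordInvariants:
    def test_ac_above_an_rejected(self):
        with pytest.raises(VariantIOError):
            VariantRecord(chrom="c", pos=1, ref="A", alt="T", AC=5, AN=4)

    def test_hom_inconsistent_with_ac_rejected(self):
        with pytest.raises(VariantIOError):
            VariantRecord(chrom="c", pos=1, ref="A", alt="T", AC=3, AN=10, hom_count=2)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(VariantIOError):
            VariantRecord(chrom="c", pos=1, ref="AT", alt="AT", AC=1, AN=10)


def _apply_edit(sequence: str, offset: int, rec: VariantRecord) -> str:
    i = rec.pos - offset
    assert sequence[i : i + len(rec.ref)] == rec.ref
    return sequence[:i] + rec.alt + sequence[i + len(rec.ref) :]


def _leftmost_deletion_start(sequence: str, haplotype: str) -> int:
    """Enumeration oracle: smallest 0-based start of a deletion producing the
    haplotype from the reference sequence."""
    d = len(sequence) - len(haplotype)
    starts = [
        q
        for q in range(len(sequence) - d + 1)
        if sequence[:q] + sequence[q + d :] == haplotype
    ]
    return min(starts)


def _leftmost_insertion_start(sequence: str, haplotype: str) -> int:
    d = len(haplotype) - len(sequence)
    starts = [
        q
        for q in range(len(sequence) + 1)
        if haplotype[:q] + haplotype[q + d :] == sequence
    ]
    return min(starts)


class TestNormalize:
    def test_snv_unchanged(self, two_exon_model):
        rec = VariantRecord(
            chrom="chrT", pos=150, ref=two_exon_model.base_at(150),
            alt="T" if two_exon_model.base_at(150) != "T" else "G", AC=1, AN=10,
        )
        assert normalize_variant(two_exon_model, rec) == rec

    def test_reference_mismatch_raises(self, two_exon_model):
        wrong = "A" if two_exon_model.base_at(150) != "A" else "C"
        rec = VariantRecord(chrom="chrT", pos=150, ref=wrong, alt="T" if wrong != "T" else "G", AC=1, AN=10)
        with pytest.raises(VariantIOError, match="mismatch"):
            normalize_variant(two_exon_model, rec)

    def test_repeat_deletion_left_aligned(self):
        """A deletion inside a CACA repeat shifts to the leftmost equivalent."""
        from ttnpop.gene_model import BandInterval, Exon, GeneModel, Transcript

        seq = "GGGGGGGCACACATTTTTTTTT" + "A" * 80
        model = GeneModel(
            gene_name="R", chrom="chrR", strand="+", locus_offset=1,
            sequence=seq,
            exons={"E1": Exon("E1", 2, 100)},
            transcripts={"T1": Transcript("T1", "t", ("E1",), 2, 100)},
            bands=[BandInterval("A", 2, 100)], psi={"E1": 1.0},
        )
        # written representation: pos 10 ref "CACA" alt "CA" (delete one CA)
        rec = VariantRecord(chrom="chrR", pos=10, ref="CACA", alt="CA", AC=1, AN=10)
        norm = normalize_variant(model, rec)
        hap = _apply_edit(seq, 1, rec)
        assert _apply_edit(seq, 1, norm) == hap
        start = _leftmost_deletion_start(seq, hap)  # 0-based
        assert norm.pos == start  # VCF anchors one base left of the deletion
        assert normalize_variant(model, norm) == norm

    def test_degenerate_identical_alleles_rejected(self, two_exon_model):
        base = two_exon_model.base_at(150)
        nxt = two_exon_model.base_at(151)
        with pytest.raises(VariantIOError, match="ref equals alt"):
            VariantRecord(chrom="chrT", pos=150, ref=base + nxt, alt=base + nxt, AC=1, AN=10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_indels_match_enumeration_oracle(self, two_exon_model, seed):
        """Normalisation is idempotent, haplotype-preserving and leftmost."""
        model = two_exon_model
        seq = model.sequence
        rng = np.random.default_rng(seed)
        for _ in range(150):
            pos = int(rng.integers(20, 450))
            if rng.random() < 0.5:  # deletion of 1-3 bases
                d = int(rng.integers(1, 4))
                ref = model.subsequence(pos, pos + d)
                alt = ref[0]
            else:  # insertion of 1-3 bases
                ref = model.base_at(pos)
                ins = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(1, 4))))
                alt = ref + ins
            rec = VariantRecord(chrom="chrT", pos=pos, ref=ref, alt=alt, AC=1, AN=10)
            norm = normalize_variant(model, rec)
            hap = _apply_edit(seq, 1, rec)
            assert _apply_edit(seq, 1, norm) == hap
            assert normalize_variant(model, norm) == norm  # idempotent
            if len(ref) > len(alt):
                assert norm.pos == _leftmost_deletion_start(seq, hap)
            else:
                assert norm.pos == _leftmost_insertion_start(seq, hap)


class TestVariantKey:
    def test_equal_across_datasets(self):
        a = VariantRecord(chrom="c", pos=5, ref="A", alt="T", AC=1, AN=10, dataset="X")
        b = VariantRecord(chrom="c", pos=5, ref="A", alt="T", AC=9, AN=20, dataset="Y")
        assert variant_key(a) == variant_key(b)

    def test_snv_and_insertion_differ(self):
        a = VariantRecord(chrom="c", pos=5, ref="A", alt="T", AC=1, AN=10)
        b = VariantRecord(chrom="c", pos=5, ref="A", alt="AT", AC=1, AN=10)
        assert variant_key(a) != variant_key(b)

    def test_equivalent_representations_share_key(self):
        """The two CACA-repeat spellings normalise to the same key."""
        from conftest import build_two_exon_model  # local import for clarity

        model_seq = "GGGGGGGCACACATTTTTTTTT" + "A" * 80
        from ttnpop.gene_model import BandInterval, Exon, GeneModel, Transcript

        model = GeneModel(
            gene_name="R", chrom="chrR", strand="+", locus_offset=1,
            sequence=model_seq,
            exons={"E1": Exon("E1", 2, 100)},
            transcripts={"T1": Transcript("T1", "t", ("E1",), 2, 100)},
            bands=[BandInterval("A", 2, 100)], psi={"E1": 1.0},
        )
        r1 = VariantRecord(chrom="chrR", pos=10, ref="CACA", alt="CA", AC=1, AN=10)
        r2 = VariantRecord(chrom="chrR", pos=8, ref="CAC", alt="C", AC=1, AN=10)
        k1 = variant_key(normalize_variant(model, r1))
        k2 = variant_key(normalize_variant(model, r2))
        assert k1 == k2


class TestCoverage:
    def test_row_parsing(self, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text("#chrom\tpos\tmean_depth\tge_10\tge_50\nchr2\t100\t62.1\t1.0\t0.93\n")
        table = read_coverage(path)
        rec = table.get("chr2", 100)
        assert rec.mean_depth == 62.1
        assert dict(rec.frac_ge) == {10: 1.0, 50: 0.93}

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text("#chrom\tpos\tmean_depth\tge_10\n")
        assert len(read_coverage(path)) == 0

    def test_non_monotone_fractions_rejected(self, tmp_path):
        path = tmp_path / "cov.tsv"
        path.write_text("#chrom\tpos\tmean_depth\tge_10\tge_50\nchr2\t100\t62.1\t0.5\t0.93\n")
        with pytest.raises(VariantIOError, match="non-increasing"):
            read_coverage(path)

    def test_simulator_round_trip(self, sim_cohort, tmp_path):
        path = tmp_path / "cov.tsv"
        write_coverage(sim_cohort.coverage, path)
        reread = read_coverage(path)
        assert len(reread) == len(sim_cohort.coverage)
        for rec in sim_cohort.coverage:
            got = reread.get(rec.chrom, rec.pos)
            assert got.mean_depth == pytest.approx(rec.mean_depth, abs=0.05)
            assert dict(got.frac_ge) == pytest.approx(dict(rec.frac_ge), abs=5e-4)


class TestWriteVcfRoundTrip:
    def test_fields_survive_write_read(self, tmp_path):
        records = [
            VariantRecord(
                chrom="chrT", pos=10, ref="A", alt="T", AC=4, AN=100, hom_count=1,
                qual=77.0, filter_status="PASS",
                pop_counts=(("AFR", (3, 40)), ("EUR", (1, 60))), dataset="D",
            ),
            VariantRecord(
                chrom="chrT", pos=20, ref="C", alt="G", AC=1, AN=100,
                filter_status="LowQual", dataset="D",
            ),
        ]
        path = write_vcf(records, tmp_path / "out.vcf", chrom="chrT", contig_length=1000)
        reread = read_vcf(path, dataset="D")
        assert reread == records
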