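"""Variant table I/O, review filtering, and fixture integrity."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secondhit import variant_io
from secondhit.variant_io import (
    Origin,
    SnpObservation,
    VariantCall,
    VariantTableError,
    VariantType,
    filter_variant_calls,
    read_snp_track,
    read_variant_table,
    write_snp_track,
    write_variant_table,
)


def _call(mutant=10, ref=90, bidirectional=True, **kw):
    defaults = dict(
        patient_id="P1", sample_id="S1", gene="GENE001",
        variant_type=VariantType.missense, cdna_change="c.100A>G",
        mutant_reads=mutant, ref_reads=ref, bidirectional=bidirectional,
        origin=Origin.somatic,
    )
    defaults.update(kw)
    return VariantCall(**defaults)


class TestReadWrite:
    def test_af_recomputed_from_read_counts(self, bundle):
        ins = next(
            c for c in bundle.tsc_calls
            if c.sample_id == "S26" and c.variant_type is VariantType.frameshift_ins
        )
        assert ins.mutant_reads == 155 and ins.ref_reads == 345
        assert ins.af == pytest.approx(0.31)
        assert ins.gene == "TSC2"

    def test_zero_depth_row_flagged_uncovered(self, bundle):
        maz = next(
            c for c in bundle.other_calls
            if c.sample_id == "S2" and c.gene == "MAZ"
        )
        assert not maz.covered
        assert maz.af is None

    @pytest.mark.parametrize(
        "fixture_file",
        [variant_io.TABLE1_FILE, variant_io.TABLE2_FILE],
    )
    def test_round_trip_is_byte_identical(self, fixture_file, tmp_path):
        src = variant_io._data_path(fixture_file)
        calls = read_variant_table(src)
        out = tmp_path / "copy.tsv"
        write_variant_table(calls, out)
        assert out.read_bytes() == src.read_bytes()

    def test_unknown_variant_type_token_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        header = "\t".join(variant_io.VARIANT_COLUMNS)
        row = "P1\tS1\t\tG\tweird_type\tc.1A>G\t\t5\t5\t\tsomatic\t\t\t\t\t"
        p.write_text(header + "\n" + row + "\n")
        with pytest.raises(VariantTableError, match="variant_type"):
            read_variant_table(p)

    def test_malformed_hgvs_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        header = "\t".join(variant_io.VARIANT_COLUMNS)
        row = "P1\tS1\t\tG\tmissense\tnot-hgvs\t\t5\t5\t\tsomatic\t\t\t\t\t"
        p.write_text(header + "\n" + row + "\n")
        with pytest.raises(VariantTableError, match="line 2"):
            read_variant_table(p)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\tc\n1\t2\t3\n")
        with pytest.raises(VariantTableError, match="header"):
            read_variant_table(p)

    def test_snp_track_round_trip_and_order_check(self, tmp_path):
        snps = [SnpObservation("16", p, 20, 21, 30, 9) for p in (100, 200, 300)]
        path = tmp_path / "snps.tsv"
        write_snp_track(snps, path)
        assert read_snp_track(path) == snps
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "chrom\tpos\tnormal_ref\tnormal_alt\ttumor_ref\ttumor_alt\n"
            "16\t200\t1\t1\t1\t1\n16\t100\t1\t1\t1\t1\n"
        )
        with pytest.raises(VariantTableError, match="increasing"):
            read_snp_track(bad)

    def test_negative_read_counts_rejected(self):
        with pytest.raises(ValueError):
            SnpObservation("16", 1, normal_ref=-1)


class TestReviewFilter:
    @pytest.mark.parametrize(
        "mutant,ref,bidir,kept,reason_part",
        [
            (2, 98, True, False, "variant reads"),
            (3, 57, True, True, None),  # AF exactly 0.05: boundary kept
            (10, 90, False, False, "one direction"),
            (4, 96, True, False, "allele fraction"),
            (0, 0, True, False, "no coverage"),
            (50, 50, True, True, None),
        ],
    )
    def test_boundary_semantics(self, mutant, ref, bidir, kept, reason_part):
        call = _call(mutant, ref, bidir)
        if mutant == 0 and ref == 0:
            call = _call(None, None)
        kept_list, rejected = filter_variant_calls([call])
        assert bool(kept_list) is kept
        if reason_part:
            assert reason_part in rejected[0].reason

    def test_empty_input(self):
        assert filter_variant_calls([]) == ([], [])

    def test_genomic_deletions_pass_through(self):
        call = _call(None, None, variant_type=VariantType.genomic_del, cdna_change="NA")
        kept, rejected = filter_variant_calls([call])
        assert kept == [call] and not rejected

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(st.integers(0, 100), st.booleans()), min_size=0, max_size=100
        )
    )
    def test_partition_property_and_refilter_oracle(self, rows):
        """kept ∪ rejected = input, disjoint; kept = brute-force re-filter."""
        calls = [
            _call(alt, 100 - alt, bidir, cdna_change=f"c.{i+1}A>G")
            for i, (alt, bidir) in enumerate(rows)
        ]
        kept, rejected = filter_variant_calls(calls)
        assert len(kept) + len(rejected) == len(calls)
        assert {id(c) for c in kept}.isdisjoint({id(r.call) for r in rejected})
        oracle = [
            c for c in calls
            if c.mutant_reads >= 3 and c.bidirectional and c.af >= 0.05
        ]
        assert kept == oracle


class TestFixtures:
    def test_cohort_shape(self, bundle):
        assert len(bundle.samples) == 32
        assert len(bundle.patients) == 15
        p13 = sorted(
            {c.sample_id for c in bundle.tsc_calls if c.patient_id == "P13"},
            key=lambda s: int(s[1:]),
        )
        assert p13 == [f"S{i}" for i in range(14, 30)]
        assert len(bundle.paired_samples) == 23

    def test_germline_tsc1_nonsense_in_both_p14_samples(self, bundle):
        hits = [
            c for c in bundle.tsc_calls
            if c.gene == "TSC1" and c.protein_change == "p.R692*"
        ]
        assert sorted(c.sample_id for c in hits) == ["S30", "S31"]
        assert all(c.origin is Origin.germline for c in hits)

    def test_s7_genomic_deletion_with_region_sizes(self, bundle):
        row = next(
            c for c in bundle.tsc_calls
            if c.variant_type is VariantType.genomic_del
        )
        assert row.sample_id == "S7"
        assert "homozygous_del_kb=50" in row.notes
        assert "single_copy_loss_kb=150" in row.notes

    def test_duplicated_row_flagged(self, bundle):
        thbs3 = [c for c in bundle.other_calls if c.gene == "THBS3"]
        assert len(thbs3) == 2
        assert [c.duplicate for c in thbs3] == [False, True]

    def test_recomputed_afs_match_printed_column(self, bundle):
        """Printed AFs were rounded to 2 decimals; recomputation must agree
        to within the rounding resolution."""
        checked = 0
        for c in bundle.tsc_calls + bundle.other_calls:
            if not c.covered or not c.printed_af:
                continue
            assert abs(c.af - float(c.printed_af)) <= 0.006, c.key()
            checked += 1
        assert checked > 100

    def test_checksum_mismatch_detected(self, tmp_path, monkeypatch):
        import shutil

        data_dir = tmp_path / "data"
        shutil.copytree(variant_io._data_path("."), data_dir, dirs_exist_ok=True)
        target = data_dir / variant_io.TABLE1_FILE
        target.write_bytes(target.read_bytes() + b"#tampered\n")
        monkeypatch.setattr(variant_io, "_data_path", lambda name: data_dir / name)
        with pytest.raises(variant_io.FixtureIntegrityError):
            variant_io.load_fixtures()


class TestVcfImport:
    def test_ad_fields_mapped(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="gene">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\n"
            "16\t2100000\t.\tA\tT\t.\tPASS\tGENE=TSC2\tAD\t90,10\n"
        )
        calls = variant_io.variants_from_vcf(vcf, sample="TUMOR")
        assert len(calls) == 1
        assert calls[0].mutant_reads == 10 and calls[0].ref_reads == 90
        assert calls[0].gene == "TSC2"
        assert calls[0].af == pytest.approx(0.1)
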