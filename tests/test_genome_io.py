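import numpy as np
import pytest

from spex import (
    ContactMatrix,
    Gene,
    cache_tensor,
    load_cached_tensor,
    load_contacts,
    load_expression,
    load_genes,
    write_cool,
    write_pixel_list,
)


# ---------------------------------------------------------------------------
# gene annotations


class TestLoadGenes:
    def test_bed6_tss_by_strand(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr8\t1000\t2000\tG1\t0\t+\nchr8\t1000\t2000\tG2\t0\t-\n")
        genes = load_genes(str(p))
        assert genes == [Gene("G1", "chr8", 1000, "+"), Gene("G2", "chr8", 1999, "-")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("")
        assert load_genes(str(p)) == []

    def test_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "A";\n'
            'chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tgene_id "B";\n'
        )
        genes = load_genes(str(p))
        # GTF is 1-based closed: + TSS at 0-based 1000, − TSS at 0-based 1999
        assert genes[0] == Gene("A", "chr1", 1000, "+")
        assert genes[1] == Gene("B", "chr1", 1999, "-")

    def test_bed_and_gtf_agree_on_the_same_interval(self, tmp_path):
        """Converting the equivalent BED/GTF record yields the same TSS."""
        bed = tmp_path / "g.bed"
        gtf = tmp_path / "g.gtf"
        bed.write_text("chr2\t500\t800\tX\t0\t-\n")
        gtf.write_text('chr2\tsrc\tgene\t501\t800\t.\t-\t.\tgene_id "X";\n')
        assert load_genes(str(bed))[0].tss == load_genes(str(gtf))[0].tss == 799

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t10\t20\tA\t0\t+\nchr1\tnotanumber\t20\tB\t0\t+\n")
        with pytest.raises(ValueError, match=":2"):
            load_genes(str(p))

    def test_unknown_strand_skipped_with_warning(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t10\t20\tA\t0\t.\nchr1\t10\t20\tB\t0\t+\n")
        with pytest.warns(UserWarning, match="strand"):
            genes = load_genes(str(p))
        assert [g.gene_id for g in genes] == ["B"]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t10\t20\tA\t0\t+\nchr1\t30\t40\tA\t0\t+\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_genes(str(p))


# ---------------------------------------------------------------------------
# expression


class TestLoadExpression:
    def test_basic(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("G1\t3.5\nG2\t0.0\n")
        table = load_expression(str(p))
        assert table.entries == {"G1": 3.5, "G2": 0.0}

    @pytest.mark.parametrize(
        "content,msg",
        [
            ("G1\t1.0\nG1\t2.0\n", "duplicate"),
            ("G1\t-1\n", "negative"),
            ("G1\tabc\n", "unparsable"),
        ],
    )
    def test_rejects_bad_rows(self, tmp_path, content, msg):
        p = tmp_path / "e.tsv"
        p.write_text(content)
        with pytest.raises(ValueError, match=msg):
            load_expression(str(p))


# ---------------------------------------------------------------------------
# contact matrices


class TestContactMatrix:
    def test_pixel_list_parse_and_symmetry(self, tmp_path):
        p = tmp_path / "px.tsv"
        p.write_text("chr8 40000 45000 chr8 90000 95000 1.2\n".replace(" ", "\t"))
        cm = load_contacts(str(p), resolution=5000)
        assert cm.n_pixels() == 1
        assert cm.count("chr8", 8, 18) == pytest.approx(1.2)
        assert cm.count("chr8", 18, 8) == pytest.approx(1.2)  # symmetric access

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "px.tsv"
        p.write_text("chr1\t0\t5000\tchr1\t10000\t15000\t-2\n")
        with pytest.raises(ValueError, match="negative"):
            load_contacts(str(p), resolution=5000)

    def test_bin_arithmetic_roundtrip(self):
        cm = ContactMatrix(5000, {"chr1": 23000})
        for pos in [0, 1, 4999, 5000, 22999]:
            b = cm.bin_of(pos)
            start, end = cm.bin_interval("chr1", b)
            assert start <= pos < end
        assert cm.bin_interval("chr1", 4) == (20000, 23000)  # truncated at chrom end

    def test_missing_chromosome_lists_available(self):
        cm = ContactMatrix(5000, {"chr1": 10000})
        with pytest.raises(KeyError, match="chr1"):
            list(cm.pixels("chrX"))


class TestCoolerSchema:
    def _matrix(self):
        cm = ContactMatrix(5000, {"chr1": 20000, "chr2": 15000})
        cm.add_pixel("chr1", 0, 2, 1.5)
        cm.add_pixel("chr1", 1, 1, 4.0)
        cm.add_pixel("chr2", 0, 2, 0.75)
        return cm

    def test_cool_roundtrip(self, tmp_path):
        cm = self._matrix()
        path = str(tmp_path / "m.cool")
        write_cool(cm, path)
        back = load_contacts(path, resolution=5000)
        assert back.chrom_sizes == cm.chrom_sizes
        assert not back.balanced
        for chrom in ("chr1", "chr2"):
            assert list(back.pixels(chrom)) == list(cm.pixels(chrom))

    def test_mcool_requires_matching_resolution(self, tmp_path):
        cm = self._matrix()
        path = str(tmp_path / "m.mcool")
        write_cool(cm, path, mcool=True)
        assert load_contacts(path, resolution=5000).n_pixels() == cm.n_pixels()
        with pytest.raises(ValueError, match="available.*5000"):
            load_contacts(path, resolution=10000)

    def test_balancing_weights_applied(self, tmp_path):
        cm = self._matrix()
        path = str(tmp_path / "m.cool")
        weights = {"chr1": np.array([0.5, 2.0, 1.0, 1.0]), "chr2": np.array([4.0, 1.0, 0.25])}
        write_cool(cm, path, weights=weights)
        back = load_contacts(path, resolution=5000)
        assert back.balanced
        # raw 1.5 at (chr1, 0, 2): balanced = 1.5 × w0 × w2 = 1.5 × 0.5 × 1.0
        assert back.count("chr1", 0, 2) == pytest.approx(1.5 * 0.5 * 1.0)
        # raw 0.75 at (chr2, 0, 2): 0.75 × 4.0 × 0.25
        assert back.count("chr2", 0, 2) == pytest.approx(0.75)

    def test_raw_counts_override(self, tmp_path):
        cm = self._matrix()
        path = str(tmp_path / "m.cool")
        write_cool(cm, path, weights={"chr1": np.array([0.5, 2.0, 1.0, 1.0])})
        back = load_contacts(path, resolution=5000, raw_counts=True)
        assert not back.balanced
        assert back.count("chr1", 0, 2) == pytest.approx(1.5)

    def test_nan_weight_bins_dropped(self, tmp_path):
        cm = self._matrix()
        path = str(tmp_path / "m.cool")
        write_cool(cm, path, weights={"chr1": np.array([np.nan, 1.0, 1.0, 1.0]),
                                      "chr2": np.array([1.0, 1.0, 1.0])})
        back = load_contacts(path, resolution=5000)
        assert back.count("chr1", 0, 2) == 0.0
        assert back.count("chr1", 1, 1) == pytest.approx(4.0)

    def test_pixel_list_roundtrip_random(self, tmp_path, rng):
        cm = ContactMatrix(2000, {"chrA": 50000})
        for _ in range(30):
            i, j = sorted(rng.integers(0, 25, size=2))
            cm.add_pixel("chrA", int(i), int(j), float(rng.uniform(0, 5)))
        path = str(tmp_path / "px.tsv")
        write_pixel_list(cm, path)
        back = load_contacts(str(path), resolution=2000)
        for i, j, c in cm.pixels("chrA"):
            assert back.count("chrA", i, j) == pytest.approx(c, rel=1e-6)


# ---------------------------------------------------------------------------
# tensor cache


class TestTensorCache:
    def test_roundtrip_bit_exact(self, tmp_path, rng):
        t = rng.normal(size=(4, 11))
        path = str(tmp_path / "G1.tensor")
        cache_tensor("G1", t, path, build_params={"window_bp": 20000})
        gid, back, meta = load_cached_tensor(path)
        assert gid == "G1"
        assert np.array_equal(back, t)  # bit-exact
        assert meta["spatial"] is True and meta["F"] == 4

    def test_baseline_metadata_flags_no_spatial(self, tmp_path, rng):
        path = str(tmp_path / "G2.tensor")
        cache_tensor("G2", rng.normal(size=(4, 10)), path)
        _, _, meta = load_cached_tensor(path)
        assert meta["spatial"] is False and meta["columns"] == 10

    def test_shape_mismatch_detected(self, tmp_path, rng):
        import json

        path = str(tmp_path / "G3.tensor")
        cache_tensor("G3", rng.normal(size=(4, 10)), path)
        meta = json.load(open(path + ".json"))
        meta["F"] = 5
        json.dump(meta, open(path + ".json", "w"))
        with pytest.raises(ValueError, match="sidecar"):
            load_cached_tensor(path)

    def test_non_finite_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="finite"):
            cache_tensor("G4", np.array([[np.inf, 1.0]] * 2), str(tmp_path / "t"))
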