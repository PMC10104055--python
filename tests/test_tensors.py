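import numpy as np
import pytest
from oracles import brute_force_select, random_contact_matrix

from spex import (
    ContactMatrix,
    Gene,
    SignalTrackSet,
    TrackPredictor,
    assemble_tensor,
    build_all_tensors,
    build_linear_tensor,
    build_spatial_column,
    select_spatial_contacts,
    strip_spatial,
)
from spex.tensors import DEFAULT_DECAY_RATES, DistalRegion, SpatialColumn

CHROM_LEN = 200_000


def predictor_from(intervals, n_features=2, chrom="chr1", length=CHROM_LEN):
    tracks = SignalTrackSet.from_intervals(n_features, {chrom: length}, intervals)
    return TrackPredictor(tracks)


class TestLinearTensor:
    def test_zero_signal_gives_zero_tensor(self):
        pred = predictor_from([])
        t = build_linear_tensor(Gene("G", "chr1", 100_000, "+"), pred)
        assert t.values.shape == (2, 10)
        assert np.all(t.values == 0)

    def test_symmetric_signal_equates_upstream_downstream(self):
        tss = 100_000
        intervals = [("chr1", tss - 5000, tss - 4000, 0, 2.0),
                     ("chr1", tss + 4000, tss + 5000, 0, 2.0)]
        t = build_linear_tensor(Gene("G", "chr1", tss, "+"), predictor_from(intervals))
        assert np.allclose(t.values[:, :5], t.values[:, 5:])

    def test_single_downstream_bin_closed_form(self):
        """Signal 1.0 filling the bin at distance 3 downstream → exp(−rate·3)."""
        tss = 100_000
        # + strand downstream bins: [tss, tss+200), [tss+200, ...); distance 3 = [tss+600, tss+800)
        pred = predictor_from([("chr1", tss + 600, tss + 800, 0, 1.0)], n_features=1)
        t = build_linear_tensor(Gene("G", "chr1", tss, "+"), pred)
        assert np.all(t.values[:, :5] == 0)  # upstream empty
        for k, rate in enumerate(DEFAULT_DECAY_RATES):
            assert t.values[0, 5 + k] == pytest.approx(np.exp(-rate * 3), rel=1e-12)
        assert t.values[0, 8] == pytest.approx(np.exp(-0.1 * 3), rel=1e-12)  # ≈ 0.7408

    def test_minus_strand_equals_mirrored_plus_strand(self, rng):
        """Brute-force reflection oracle: mirror the signal through the TSS."""
        tss = 100_000
        offsets = rng.integers(-19_000, 18_800, size=12)
        amps = rng.uniform(0.5, 3.0, size=12)
        fwd = [("chr1", tss + int(o), tss + int(o) + 200, 0, float(a))
               for o, a in zip(offsets, amps)]
        # reflect interval [tss+o, tss+o+200) through tss → [tss-o-200, tss-o)
        mir = [("chr1", tss - int(o) - 200, tss - int(o), 0, float(a))
               for o, a in zip(offsets, amps)]
        t_minus = build_linear_tensor(Gene("G", "chr1", tss, "-"), predictor_from(fwd, 1))
        t_plus = build_linear_tensor(Gene("G", "chr1", tss, "+"), predictor_from(mir, 1))
        assert np.allclose(t_minus.values, t_plus.values, rtol=1e-10)

    def test_chromosome_edge_zero_padded(self):
        pred = predictor_from([("chr1", 0, CHROM_LEN, 0, 1.0)], n_features=1)
        t = build_linear_tensor(Gene("G", "chr1", 5000, "+"), pred)
        full = build_linear_tensor(Gene("G", "chr1", 100_000, "+"), pred)
        # upstream summaries shrink (75 of 100 upstream bins fall off the chromosome)
        assert np.all(t.values[0, :5] < full.values[0, :5])
        assert np.allclose(t.values[0, 5:], full.values[0, 5:])

    def test_parameter_validation(self):
        pred = predictor_from([])
        gene = Gene("G", "chr1", 100_000, "+")
        with pytest.raises(ValueError):
            build_linear_tensor(gene, pred, window_bp=0)
        with pytest.raises(ValueError, match="divide"):
            build_linear_tensor(gene, pred, window_bp=20000, bin_bp=333)


class TestSelectSpatialContacts:
    def _gene_and_matrix(self):
        cm = ContactMatrix(5000, {"chr1": 500_000})
        gene = Gene("G", "chr1", 102_500, "+")  # TSS bin 20
        return gene, cm

    def test_qualifying_distal_pixel_included(self):
        gene, cm = self._gene_and_matrix()
        cm.add_pixel("chr1", 20, 30, 1.2)  # partner 50 kb downstream
        regions = select_spatial_contacts(gene, cm)
        assert [(r.start, r.end, r.count) for r in regions] == [(150_000, 155_000, 1.2)]

    def test_subthreshold_count_excluded(self):
        gene, cm = self._gene_and_matrix()
        cm.add_pixel("chr1", 20, 30, 0.4)
        assert select_spatial_contacts(gene, cm) == []

    def test_partner_inside_linear_scope_excluded(self):
        gene, cm = self._gene_and_matrix()
        cm.add_pixel("chr1", 20, 21, 2.0)  # ~5 kb away: inside ±20 kb
        assert select_spatial_contacts(gene, cm) == []

    def test_pixel_not_anchored_at_tss_excluded(self):
        gene, cm = self._gene_and_matrix()
        cm.add_pixel("chr1", 40, 50, 3.0)
        assert select_spatial_contacts(gene, cm) == []

    def test_tss_self_pixel_never_returned(self):
        gene, cm = self._gene_and_matrix()
        cm.add_pixel("chr1", 20, 20, 9.0)
        assert select_spatial_contacts(gene, cm) == []

    def test_empty_matrix(self):
        gene, cm = self._gene_and_matrix()
        assert select_spatial_contacts(gene, cm) == []

    def test_missing_chromosome_errors(self):
        gene, cm = self._gene_and_matrix()
        with pytest.raises(KeyError):
            select_spatial_contacts(Gene("G2", "chrX", 1000, "+"), cm)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(25):
            cm = random_contact_matrix(rng)
            tss = int(rng.integers(0, 60_000))
            gene = Gene("G", "chrT", tss, "+")
            got = [(r.start, r.end, r.count) for r in select_spatial_contacts(gene, cm)]
            assert got == brute_force_select(gene, cm)

    def test_monotone_in_count_and_scope(self, rng):
        cm = random_contact_matrix(rng, n_pixels=200)
        gene = Gene("G", "chrT", 30_000, "+")
        n = [len(select_spatial_contacts(gene, cm, min_count=mc)) for mc in (0.0, 0.5, 1.0, 2.0)]
        assert n == sorted(n, reverse=True)
        n = [len(select_spatial_contacts(gene, cm, linear_scope_bp=s)) for s in (1000, 10_000, 25_000)]
        assert n == sorted(n, reverse=True)


class TestSpatialColumn:
    def test_no_regions_zero_column(self):
        col = build_spatial_column(Gene("G", "chr1", 0, "+"), [], predictor_from([]))
        assert col.n_regions == 0
        assert np.all(col.values == 0)

    def test_constant_region_sums_over_windows(self):
        # constant 3.0, one 1000-bp region tiled at 200 → 5 windows × 3.0 = 15.0
        pred = predictor_from([("chr1", 0, CHROM_LEN, 0, 3.0)], n_features=1)
        region = DistalRegion("chr1", 50_000, 51_000, 1.0)
        col = build_spatial_column(Gene("G", "chr1", 0, "+"), [region], pred)
        assert col.values[0] == pytest.approx(15.0)
        assert col.n_regions == 1

    def test_two_identical_regions_double_the_column(self):
        pred = predictor_from([("chr1", 0, CHROM_LEN, 0, 1.7)], n_features=1)
        r = DistalRegion("chr1", 50_000, 55_000, 1.0)
        one = build_spatial_column(Gene("G", "chr1", 0, "+"), [r], pred)
        two = build_spatial_column(Gene("G", "chr1", 0, "+"), [r, r], pred)
        assert np.allclose(two.values, 2 * one.values)


class TestAssembleTensor:
    def test_linear_plus_spatial_is_11_columns(self, rng):
        from spex.tensors import LinearTensor

        lin = LinearTensor(rng.normal(size=(4, 10)), "G")
        spa = SpatialColumn(rng.uniform(size=4), 2, "G")
        t = assemble_tensor(lin, spa)
        assert t.values.shape == (4, 11) and t.spatial
        assert np.array_equal(t.values[:, :10], lin.values)
        assert np.array_equal(t.values[:, 10], spa.values)

    def test_linear_alone_is_baseline(self, rng):
        from spex.tensors import LinearTensor

        t = assemble_tensor(LinearTensor(rng.normal(size=(4, 10)), "G"))
        assert t.values.shape == (4, 10) and not t.spatial

    def test_gene_or_f_mismatch_errors(self, rng):
        from spex.tensors import LinearTensor

        lin = LinearTensor(rng.normal(size=(4, 10)), "G")
        with pytest.raises(ValueError, match="gene_id"):
            assemble_tensor(lin, SpatialColumn(np.zeros(4), 0, "H"))
        with pytest.raises(ValueError, match="F mismatch"):
            assemble_tensor(lin, SpatialColumn(np.zeros(5), 0, "G"))


class TestBuildAllTensors:
    def test_spatial_and_baseline_modes(self, distal_sim):
        genes = distal_sim.genes[:5]
        pred = distal_sim.predictor()
        with_contacts = build_all_tensors(genes, pred, distal_sim.contacts)
        without = build_all_tensors(genes, pred, None)
        assert all(t.values.shape[1] == 11 for t in with_contacts.values())
        assert all(t.values.shape[1] == 10 for t in without.values())
        for gid in without:
            assert np.array_equal(with_contacts[gid].values[:, :10], without[gid].values)

    def test_missing_chromosome_gets_zero_column(self, distal_sim, caplog):
        import logging

        gene = distal_sim.genes[0]
        cm = ContactMatrix(5000, {"chrZZ": 10_000})
        with caplog.at_level(logging.WARNING):
            out = build_all_tensors([gene], distal_sim.predictor(), cm)
        assert np.all(out[gene.gene_id].values[:, 10] == 0)
        assert any("absent" in r.message for r in caplog.records)

    def test_strip_spatial_is_bit_identical_baseline(self, distal_sim):
        gene = distal_sim.genes[0]
        t = build_all_tensors([gene], distal_sim.predictor(), distal_sim.contacts)[gene.gene_id]
        b = strip_spatial(t)
        assert not b.spatial and np.array_equal(b.values, t.values[:, :10])

    def test_empty_gene_list_errors(self, distal_sim):
        with pytest.raises(ValueError):
            build_all_tensors([], distal_sim.predictor(), None)
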