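import numpy as np
import pytest

from chipnorm import (
    MatrixLayout,
    SignalTrack,
    ValidationError,
    compute_matrix,
    compute_tss_matrix,
    mean_profile,
    write_bigwig_from_array,
)
from chipnorm.matrix import _resample_to_bins

from conftest import make_gene
from oracles import resample_oracle

SMALL = MatrixLayout(body_length=200, flank=100, bin_size=10)


@pytest.fixture
def make_track(tmp_path):
    """Write per-base arrays to a bigWig and open it."""
    tracks = []

    def _make(arrays, chrom_sizes=None, name="t.bw"):
        sizes = chrom_sizes or {c: len(a) for c, a in arrays.items()}
        path = tmp_path / name
        write_bigwig_from_array(sizes, arrays, path)
        t = SignalTrack(path)
        tracks.append(t)
        return t

    yield _make
    for t in tracks:
        t.close()


class TestLayout:
    def test_default_bin_count(self):
        assert MatrixLayout().n_bins == 4800  # 40000/10 + 2*4000/10

    def test_divisibility_enforced(self):
        with pytest.raises(ValidationError):
            MatrixLayout(body_length=105, flank=100, bin_size=10)

    @pytest.mark.parametrize(
        "layout", [SMALL, MatrixLayout(300, 50, 5), MatrixLayout(1000, 200, 20)]
    )
    def test_column_count_conserved(self, layout, make_track):
        track = make_track({"chr1": np.full(2000, 1.0)})
        genes = [make_gene("g", start=500, end=800)]
        m = compute_matrix(track, genes, layout)
        assert m.values.shape == (1, layout.n_bins)


class TestComputeMatrix:
    def test_constant_track_fills_every_cell(self, make_track):
        track = make_track({"chr1": np.full(3000, 2.5)})
        genes = [make_gene("g1", start=700, end=1500, strand="+"),
                 make_gene("g2", start=1900, end=2400, strand="-")]
        m = compute_matrix(track, genes, SMALL)
        np.testing.assert_allclose(m.values, 2.5, rtol=1e-12)

    def test_strand_mirror_symmetry(self, make_track):
        rng = np.random.default_rng(0)
        signal = rng.uniform(0, 10, 600)
        # plus gene over the signal; minus gene over its genomic mirror
        arr = np.zeros(3000)
        arr[200:800] = signal
        arr[2000:2600] = signal[::-1]
        track = make_track({"chr1": arr})
        plus = make_gene("p", start=300, end=700, strand="+")
        minus = make_gene("m", start=2100, end=2500, strand="-")
        m = compute_matrix(track, [plus, minus], SMALL)
        np.testing.assert_allclose(m.values[0], m.values[1], rtol=1e-9)

    def test_linearity_in_track_values(self, make_track):
        rng = np.random.default_rng(1)
        base = np.round(rng.uniform(0, 50, 4000) * 256) / 256
        t1 = make_track({"chr1": base}, name="a.bw")
        t2 = make_track({"chr1": 2.0 * base + 0.5}, name="b.bw")
        genes = [make_gene("g1", start=500, end=1100, strand="+"),
                 make_gene("g2", start=2000, end=2230, strand="-")]
        m1 = compute_matrix(t1, genes, SMALL)
        m2 = compute_matrix(t2, genes, SMALL)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values + 0.5, atol=1e-9)

    def test_flank_truncated_at_chromosome_edge_reads_zero(self, make_track):
        track = make_track({"chr1": np.full(400, 3.0)})
        gene = make_gene("g", start=50, end=250)  # upstream flank exceeds edge
        m = compute_matrix(track, [gene], SMALL)
        left = m.values[0, : SMALL.n_flank_bins]
        # first 50 bp of the 100 bp flank fall before base 0 -> zeros
        np.testing.assert_allclose(left[:5], 0.0)
        np.testing.assert_allclose(left[5:], 3.0)

    def test_uncovered_intervals_read_as_zero(self, make_track):
        arr = np.zeros(2000)
        arr[600:900] = 4.0
        track = make_track({"chr1": arr})
        gene = make_gene("g", start=600, end=900)
        m = compute_matrix(track, [gene], SMALL)
        assert not np.isnan(m.values).any()
        body = m.values[0, SMALL.n_flank_bins:-SMALL.n_flank_bins]
        np.testing.assert_allclose(body, 4.0, rtol=1e-12)

    def test_genes_on_unknown_chromosomes_dropped(self, make_track, caplog):
        track = make_track({"chr1": np.full(2000, 1.0)})
        genes = [make_gene("ok", start=500, end=700),
                 make_gene("bad", chrom="chrUn", start=500, end=700)]
        with caplog.at_level("WARNING"):
            m = compute_matrix(track, genes, SMALL)
        assert m.gene_ids == ["ok"]
        assert "dropped 1" in caplog.text

    def test_empty_gene_list_rejected(self, make_track):
        track = make_track({"chr1": np.full(100, 1.0)})
        with pytest.raises(ValidationError):
            compute_matrix(track, [], SMALL)


class TestBodyResampling:
    @pytest.mark.parametrize("length,n_bins", [(7, 3), (100, 40), (33, 10)])
    def test_matches_micro_unit_oracle(self, length, n_bins):
        rng = np.random.default_rng(length * n_bins)
        values = rng.uniform(0, 5, length)
        got = _resample_to_bins(values, n_bins)
        np.testing.assert_allclose(got, resample_oracle(values, n_bins), rtol=1e-10)

    def test_mean_is_conserved(self):
        rng = np.random.default_rng(7)
        values = rng.uniform(0, 5, 57)
        assert _resample_to_bins(values, 13).mean() == pytest.approx(
            values.mean(), rel=1e-12
        )


class TestTssMatrix:
    def test_window_binning_and_orientation(self, make_track):
        arr = np.zeros(10000)
        arr[4000:4010] = 7.0  # 10 bp spike just downstream of a + TSS at 4000
        track = make_track({"chr1": arr})
        plus = make_gene("p", start=4000, end=5000, strand="+")
        ids, rows = compute_tss_matrix(track, [plus], half_window=400, bin_size=10)
        assert rows.shape == (1, 80)
        assert rows[0, 40] == pytest.approx(7.0)
        # a minus gene with TSS at its end sees the spike upstream -> bin 39
        minus = make_gene("m", start=3000, end=4000, strand="-")
        _, rows_m = compute_tss_matrix(track, [minus], half_window=400, bin_size=10)
        assert rows_m[0, 39] == pytest.approx(7.0)


class TestMeanProfile:
    def test_single_row_is_identity(self, make_track):
        track = make_track({"chr1": np.arange(2000, dtype=float)})
        m = compute_matrix(track, [make_gene("g", start=500, end=900)], SMALL)
        np.testing.assert_array_equal(mean_profile(m), m.values[0])

    def test_two_rows_average(self, make_track):
        t2 = make_track({"chr1": np.full(3000, 2.0)}, name="c2.bw")
        genes = [make_gene("a", start=500, end=700),
                 make_gene("b", start=1500, end=1800)]
        m = compute_matrix(t2, genes, SMALL)
        m.values[0, :] = 2.0
        m.values[1, :] = 4.0
        np.testing.assert_allclose(mean_profile(m), 3.0)

    def test_matches_per_column_mean(self, make_track):
        rng = np.random.default_rng(3)
        track = make_track({"chr1": rng.uniform(0, 9, 5000)})
        genes = [make_gene(f"g{i}", start=300 + 900 * i, end=700 + 900 * i)
                 for i in range(5)]
        m = compute_matrix(track, genes, SMALL)
        expected = np.array(
            [np.mean([m.values[i, j] for i in range(5)])
             for j in range(SMALL.n_bins)]
        )
        np.testing.assert_allclose(mean_profile(m), expected, atol=1e-12)
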