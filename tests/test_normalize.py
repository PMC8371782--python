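import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chipnorm import (
    DensityMatrix,
    MatrixLayout,
    QuantileMap,
    SignalTrack,
    ValidationError,
    apply_affine,
    apply_quantile_map,
    build_gene_groups,
    choose_reference,
    compute_matrix,
    fit_affine,
    fit_quantile_map,
    group_means,
    mean_profile,
    select_constant_genes,
    write_bigwig_from_array,
)
from chipnorm.normalize import AffineModel

from oracles import ols_oracle, quantile_normalize_oracle

TINY = MatrixLayout(body_length=10, flank=10, bin_size=10)  # 3 bins


def flat_matrix(sample_id, gene_values, layout=TINY):
    """One matrix whose gene rows are constant at the given values."""
    vals = np.tile(np.asarray(gene_values, float)[:, None], (1, layout.n_bins))
    ids = [f"g{i}" for i in range(len(gene_values))]
    return DensityMatrix(sample_id=sample_id, gene_ids=ids, layout=layout, values=vals)


class TestChooseReference:
    def test_median_of_three(self):
        ms = [flat_matrix("a", [2.0]), flat_matrix("b", [5.0]), flat_matrix("c", [9.0])]
        assert choose_reference(ms) == "b"

    def test_two_samples_lower_median(self):
        ms = [flat_matrix("hi", [8.0]), flat_matrix("lo", [1.0])]
        assert choose_reference(ms) == "lo"

    def test_matches_brute_force_on_five_samples(self, multi_world):
        sel = select_constant_genes(multi_world.table)
        models = multi_world.constant_models(sel.gene_ids)
        matrices = []
        for sid in multi_world.paths.bigwigs:
            with multi_world.open_track(sid) as t:
                matrices.append(compute_matrix(t, models, sample_id=sid))
        got = choose_reference(matrices)
        means = sorted((m.values.mean(), m.sample_id) for m in matrices)
        assert got == means[(len(means) - 1) // 2][1]

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            choose_reference([flat_matrix("only", [1.0])])


class TestFitAffine:
    def test_identity(self):
        x = np.linspace(0, 10, 200)
        m = fit_affine(x, x)
        assert m.alpha == pytest.approx(1.0, abs=1e-10)
        assert m.beta == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine(self):
        x = np.linspace(1, 9, 100)
        m = fit_affine(2.0 * x + 5.0, x)
        assert m.alpha == pytest.approx(2.0, abs=1e-12)
        assert m.beta == pytest.approx(5.0, abs=1e-12)

    def test_noisy_fit_matches_closed_form_ols(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 30, 4800)
        y = 1.7 * x + 3.0 + rng.normal(0, 0.1, x.size)
        m = fit_affine(y, x)
        assert m.alpha == pytest.approx(1.7, abs=0.01)
        assert m.beta == pytest.approx(3.0, abs=0.05)
        slope, intercept = ols_oracle(x, y)
        assert m.alpha == pytest.approx(slope, rel=1e-9)
        assert m.beta == pytest.approx(intercept, rel=1e-9)

    def test_constant_reference_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            fit_affine(np.arange(10.0), np.full(10, 3.0))

    def test_negative_slope_advises_quantile_mode(self):
        x = np.linspace(0, 10, 50)
        with pytest.raises(ValidationError, match="quantile"):
            fit_affine(-2.0 * x + 30.0, x)


class TestApplyAffine:
    @pytest.mark.parametrize("v,expected", [(5.0, 0.0), (25.0, 10.0), (3.0, 0.0)])
    def test_correction_formula_with_clamp(self, v, expected):
        m = AffineModel("s", "r", alpha=2.0, beta=5.0)
        assert m.correct(np.array([v]))[0] == pytest.approx(expected)

    def test_round_trip_recovers_reference_values(self, tmp_path):
        rng = np.random.default_rng(2)
        ref = np.round(rng.uniform(0, 40, 500) * 256) / 256
        distorted = 1.5 * ref + 2.0
        write_bigwig_from_array({"chr1": 500}, {"chr1": distorted}, tmp_path / "d.bw")
        with SignalTrack(tmp_path / "d.bw") as t:
            apply_affine(t, AffineModel("s", "r", 1.5, 2.0), tmp_path / "n.bw")
        with SignalTrack(tmp_path / "n.bw") as t:
            got = t.values("chr1", 0, 500)
        np.testing.assert_allclose(got, ref, atol=1e-6)

    def test_no_negative_output_values(self, tmp_path):
        arr = np.array([0.0, 1.0, 2.0, 10.0])
        write_bigwig_from_array({"chr1": 4}, {"chr1": arr}, tmp_path / "a.bw")
        with SignalTrack(tmp_path / "a.bw") as t:
            apply_affine(t, AffineModel("s", "r", 1.0, 5.0), tmp_path / "o.bw")
        with SignalTrack(tmp_path / "o.bw") as t:
            assert (t.values("chr1", 0, 4) >= 0).all()


class TestGeneGroups:
    def test_forty_genes_twenty_pairs(self):
        rng = np.random.default_rng(0)
        m = flat_matrix("s", rng.uniform(0, 9, 40))
        groups = build_gene_groups([m], k=20)
        assert groups.k == 20
        assert all(len(g) == 2 for g in groups.groups)

    def test_groups_follow_sorted_overall_intensity(self):
        rng = np.random.default_rng(1)
        tiers = np.repeat([1.0, 5.0, 20.0, 80.0], 10) + rng.uniform(0, 0.5, 40)
        m1 = flat_matrix("s1", tiers)
        m2 = flat_matrix("s2", tiers * 2)
        groups = build_gene_groups([m1, m2], k=4)
        overall = (tiers + tiers * 2) / 2
        order = np.argsort(overall, kind="stable")
        expected = [tuple(f"g{i}" for i in order[j * 10:(j + 1) * 10])
                    for j in range(4)]
        got = [tuple(sorted(g, key=lambda x: int(x[1:]))) for g in groups.groups]
        want = [tuple(sorted(e, key=lambda x: int(x[1:]))) for e in expected]
        assert got == want

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValidationError):
            build_gene_groups([flat_matrix("s", [1.0, 2.0])], k=20)


class TestQuantileMap:
    def test_hand_example_targets_and_mapping(self):
        m1 = flat_matrix("s1", [1.0, 2.0, 3.0])
        m2 = flat_matrix("s2", [3.0, 6.0, 9.0])
        groups = build_gene_groups([m1, m2], k=3)
        q1, q2 = fit_quantile_map([m1, m2], groups)
        np.testing.assert_allclose(q1.knots_out, [2.0, 4.0, 6.0])
        np.testing.assert_allclose(q2.knots_out, [2.0, 4.0, 6.0])
        # 3 knots -> piecewise-linear fallback; sample-1 value 2 -> 4
        assert q1.method == "linear"
        assert q1(np.array([2.0]))[0] == pytest.approx(4.0)

    def test_matches_quantile_normalization_oracle(self):
        rng = np.random.default_rng(6)
        G = rng.uniform(0, 50, (8, 3))
        ms = [flat_matrix(f"s{j}", G[:, j]) for j in range(3)]
        groups = build_gene_groups(ms, k=8)
        # flat_matrix group means equal the gene values, in sorted overall order
        order = np.argsort(G.mean(axis=1), kind="stable")
        maps = fit_quantile_map(ms, groups)
        T = quantile_normalize_oracle(G[order])
        for j, qm in enumerate(maps):
            order_in = np.argsort(qm.knots_in)
            np.testing.assert_allclose(
                qm.knots_out[order_in], np.sort(T[:, j]), rtol=1e-12
            )

    def test_identical_samples_give_identity_map(self):
        vals = np.linspace(1, 30, 10)
        ms = [flat_matrix(s, vals) for s in ("a", "b", "c")]
        groups = build_gene_groups(ms, k=10)
        for qm in fit_quantile_map(ms, groups):
            np.testing.assert_allclose(qm.knots_out, qm.knots_in, rtol=1e-12)
            probe = np.linspace(0, 40, 100)
            np.testing.assert_allclose(qm(probe), np.maximum(probe, 0), atol=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_monotone_and_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        knots_in = np.sort(rng.uniform(0, 100, 20))
        knots_out = rng.uniform(0, 100, 20)  # unordered on purpose
        qm = QuantileMap("s", knots_in, knots_out)
        v = np.sort(rng.uniform(-10, 200, 1000))
        out = qm(v)
        assert (np.diff(out) >= -1e-9).all()
        assert (out >= 0).all()

    def test_extrapolation_uses_terminal_slope(self):
        qm = QuantileMap("s", np.array([0.0, 1.0, 2.0, 3.0]),
                         np.array([0.0, 2.0, 4.0, 6.0]))
        assert qm(np.array([10.0]))[0] == pytest.approx(20.0)

    def test_duplicate_knots_collapsed(self, caplog):
        with caplog.at_level("WARNING"):
            qm = QuantileMap("s", np.array([1.0, 1.0, 2.0, 3.0]),
                            np.array([1.0, 3.0, 4.0, 5.0]))
        assert qm.knots_in.size == 3
        assert qm.knots_out[0] == pytest.approx(2.0)  # averaged targets
        assert "collapsed" in caplog.text

    def test_apply_identity_map_preserves_track(self, tmp_path):
        rng = np.random.default_rng(9)
        arr = np.round(rng.uniform(0, 20, 300) * 256) / 256
        write_bigwig_from_array({"chr1": 300}, {"chr1": arr}, tmp_path / "i.bw")
        knots = np.linspace(0.0, 25.0, 8)
        qm = QuantileMap("s", knots, knots)
        with SignalTrack(tmp_path / "i.bw") as t:
            apply_quantile_map(t, qm, tmp_path / "o.bw")
        with SignalTrack(tmp_path / "o.bw") as t:
            np.testing.assert_allclose(t.values("chr1", 0, 300), arr, rtol=1e-6)


class TestQuantileConsistencyOnFixtures:
    def test_group_means_agree_after_normalization(self, noisy_world, tmp_path):
        """After quantile normalization of affine-distorted tracks, group
        means recomputed from the normalized tracks agree across samples."""
        sel = select_constant_genes(noisy_world.table)
        models = noisy_world.constant_models(sel.gene_ids)
        sample_ids = sorted(noisy_world.paths.bigwigs)
        tracks = {sid: noisy_world.open_track(sid) for sid in sample_ids}
        try:
            matrices = [compute_matrix(tracks[sid], models, sample_id=sid)
                        for sid in sample_ids]
            groups = build_gene_groups(matrices, k=20)
            qmaps = fit_quantile_map(matrices, groups)
            renorm = []
            for sid, qm in zip(sample_ids, qmaps):
                out = tmp_path / f"{sid}.qn.bw"
                apply_quantile_map(tracks[sid], qm, out)
                with SignalTrack(out) as nt:
                    renorm.append(
                        group_means(compute_matrix(nt, models, sample_id=sid),
                                    groups)
                    )
        finally:
            for t in tracks.values():
                t.close()
        a, b = renorm
        assert np.max(np.abs(a - b) / ((a + b) / 2)) < 0.01
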