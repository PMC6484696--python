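"""Acquisition simulator: motion statistics, geometry, forward-model accuracy."""

import numpy as np
import pytest

import svrecon as sv
from svrecon.acquisition import (
    MotionModel,
    MotionTrace,
    ProtocolConfig,
    coverage_slices,
    load_motion_trace,
    sample_motion_trace,
    save_motion_traces,
    simulate_protocol,
    simulate_stack,
    stack_geometry_for_box,
)
from svrecon.psf import PointSpreadFunction


def test_zero_motion_model_gives_identity():
    trace = sample_motion_trace(MotionModel.still(), 10, seed=3)
    assert all(np.allclose(t.params, 0.0) for t in trace.transforms)


def test_same_seed_bit_identical():
    m = MotionModel()
    a = sample_motion_trace(m, 25, seed=11)
    b = sample_motion_trace(m, 25, seed=11)
    c = sample_motion_trace(m, 25, seed=12)
    assert all(np.array_equal(x.params, y.params) for x, y in zip(a.transforms, b.transforms))
    assert any(not np.array_equal(x.params, y.params) for x, y in zip(a.transforms, c.transforms))


def test_negative_amplitudes_rejected():
    with pytest.raises(ValueError):
        MotionModel(drift_sigma_translation=-0.1)


def test_random_walk_matches_closed_form():
    """RMS of the final translation over seeds must match sigma*sqrt(n)."""
    sigma, n, n_seeds = 0.5, 60, 500
    m = MotionModel(sigma, 0.0, 0.0, 0.0, 0.0)
    finals = np.array(
        [sample_motion_trace(m, n, seed=s).transforms[-1].translation for s in range(n_seeds)]
    )
    expect = sigma * np.sqrt(n)
    # sd of a sample-sd estimate: expect / sqrt(2 (n_seeds - 1))
    se = expect / np.sqrt(2 * (n_seeds - 1))
    for axis in range(3):
        assert abs(finals[:, axis].std() - expect) < 3 * se


def test_trace_log_roundtrip(tmp_path):
    m = MotionModel()
    traces = {
        f"stack{k:02d}": sample_motion_trace(m, 12, seed=k, center=(1, 2, 3)).transforms
        for k in range(9)
    }
    path = str(tmp_path / "trace.txt")
    save_motion_traces(traces, path, pivot=(1, 2, 3))
    back = load_motion_trace(path)
    assert set(back) == set(traces)
    assert all(len(back[k]) == 12 for k in back)
    for k in traces:
        for t_in, t_out in zip(traces[k], back[k].transforms):
            assert np.allclose(t_in.params, t_out.params, atol=1e-6)


def test_malformed_trace_line_errors_with_line_number(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("s 0 0 0 0 0 0 0\nnot-enough-fields\n")
    with pytest.raises(ValueError, match=":2"):
        load_motion_trace(str(path))


def test_constant_truth_preserved():
    truth = sv.Volume(np.full((40, 40, 40), 7.0), sv.axis_aligned_affine((40, 40, 40), 1.0))
    cfg = ProtocolConfig(n_stacks=1, noise_sigma=0, scale_jitter=0, motion=MotionModel.still(), margin=0)
    stacks, _ = simulate_protocol(truth, cfg)
    mid = stacks[0].slices[len(stacks[0]) // 2]
    inner = mid.pixels[8:-8, 8:-8]  # pixels whose PSF support stays inside
    assert np.abs(inner - 7.0).max() < 1e-6


def test_default_geometry_oversamples_through_plane():
    cfg = ProtocolConfig()
    geom, shape, n = stack_geometry_for_box("axial", np.zeros(3), np.full(3, 40.0), cfg)
    assert geom.slice_step == pytest.approx(1.25)
    assert geom.thickness == pytest.approx(2.5)
    assert geom.thickness / geom.slice_step == pytest.approx(2.0)  # 2x oversampling
    assert geom.overlap == pytest.approx(1.25)


def test_coverage_about_100_slices_for_clinical_box():
    """A 128 mm craniocaudal field at 1.25 mm steps needs ~100 slices."""
    assert 100 <= coverage_slices(128.0, 1.25, margin=1.25) <= 107


def test_interleaved_acquisition_order():
    order = sv.interleaved_order(7)
    assert order.tolist() == [0, 2, 4, 6, 1, 3, 5]


def test_simulated_pixels_match_dense_quadrature():
    """Forward model vs 0.05 mm dense PSF quadrature: < 1% relative error.

    A smooth random field isolates the quadrature rule itself: on piecewise
    structure (sharp edges) no practical rule can chase a 0.05 mm reference.
    """
    from scipy import ndimage

    r = np.random.default_rng(0)
    data = ndimage.gaussian_filter(r.normal(size=(48, 48, 48)), 2.0) * 50 + 100
    truth = sv.Volume(data, sv.axis_aligned_affine((48, 48, 48), 1.0))
    cfg = ProtocolConfig(margin=0)
    geom, shape, n = stack_geometry_for_box(
        "axial", np.full(3, -20.0), np.full(3, 20.0), cfg
    )
    trace = sample_motion_trace(MotionModel(0.2, 0.2, 0.1, 2, 2), n, seed=4)
    stack, truth_by_slice = simulate_stack(truth, geom, n, shape, trace, seed=1)
    psf = PointSpreadFunction.for_geometry(geom)

    rng = np.random.default_rng(0)
    axes = [np.arange(-psf.support_cutoff * s, psf.support_cutoff * s + 1e-9, 0.05) for s in psf.sigmas]
    U, V, N = np.meshgrid(*axes, indexing="ij")
    off = np.stack([U.ravel(), V.ravel(), N.ravel()], axis=-1)
    w = psf.weight(off)
    w = w / w.sum()
    world_off = off @ geom.orientation.T
    for _ in range(20):
        k = int(rng.integers(n))
        u = int(rng.integers(shape[0]))
        v = int(rng.integers(shape[1]))
        p = geom.shifted(k).pixel_world(shape)[u, v]
        T = truth_by_slice[k]
        oracle = float(w @ truth.sample(T.apply(p[None, :] + world_off)))
        got = stack.slices[k].pixels[u, v]
        assert got == pytest.approx(oracle, rel=0.01)


def test_forward_model_linearity(small_phantom):
    truth, _, _ = small_phantom
    scaled = sv.Volume(3.0 * truth.data, truth.affine)
    cfg = ProtocolConfig(n_stacks=1, noise_sigma=0, scale_jitter=0, seed=5)
    s1, _ = simulate_protocol(truth, cfg)
    s3, _ = simulate_protocol(scaled, cfg)
    a = s1[0].as_volume().data
    b = s3[0].as_volume().data
    assert np.allclose(3.0 * a, b, atol=1e-9)


def test_protocol_nine_stacks_nine_traces(small_phantom, tmp_path):
    truth, _, _ = small_phantom
    cfg = ProtocolConfig(n_stacks=9, seed=3)
    stacks, traces = simulate_protocol(truth, cfg)
    assert len(stacks) == 9 and len(traces) == 9
    orientations = [st.id.split("_")[1] for st in stacks]
    assert orientations[:3] == ["axial", "coronal", "sagittal"]
    path = str(tmp_path / "log.txt")
    save_motion_traces(traces, path)
    assert len(load_motion_trace(path)) == 9


def test_zero_motion_protocol_blank_flags_only_at_margins(clean_single_stack):
    """Coverage margin pushes only the outermost slices off the truth grid."""
    stacks, traces = clean_single_stack
    st = stacks[0]
    blank = [s.index_in_stack for s in st.slices if s.excluded]
    n = len(st)
    assert all(i < 3 or i > n - 4 for i in blank)
    assert all(np.allclose(t.params, 0) for t in traces[st.id])


def test_motion_replay_reproduces_trace(small_phantom, tmp_path):
    """Simulating with a loaded trace and re-saving is bit-exact."""
    truth, _, _ = small_phantom
    cfg = ProtocolConfig(n_stacks=2, seed=9)
    stacks, traces = simulate_protocol(truth, cfg)
    path = str(tmp_path / "log.txt")
    save_motion_traces(traces, path)
    loaded = load_motion_trace(path)
    path2 = str(tmp_path / "log2.txt")
    save_motion_traces({k: v.transforms for k, v in loaded.items()}, path2)
    assert open(path).read() == open(path2).read()
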