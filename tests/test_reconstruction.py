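"""Forward-model coefficients, EM robust statistics, and SR update properties."""

import numpy as np
import pytest
from scipy import ndimage

import svrecon as sv
from svrecon.acquisition import MotionModel, ProtocolConfig, simulate_protocol
from svrecon.reconstruction import (
    EMState,
    ReconConfig,
    ReconstructionError,
    build_coefficients,
    em_robust_update,
    estimate_slice_scales,
    initialize_volume,
    make_output_grid,
    reconstruct,
    superresolution_step,
)


@pytest.fixture(scope="module")
def smooth_problem():
    """Small smooth truth + one clean stack + coefficient map on a 0.75 grid."""
    r = np.random.default_rng(3)
    data = ndimage.gaussian_filter(r.normal(size=(40, 40, 40)), 2.5) * 40 + 120
    truth = sv.Volume(data, sv.axis_aligned_affine((40, 40, 40), 1.0))
    cfg = ProtocolConfig(
        n_stacks=3, noise_sigma=0, scale_jitter=0, motion=MotionModel.still(), margin=0, seed=3
    )
    stacks, _ = simulate_protocol(truth, cfg)
    mask = sv.Mask(np.ones((40, 40, 40), bool), truth.affine)
    grid = make_output_grid(mask, 0.75, pad_mm=0.0)
    cmap = build_coefficients(stacks, grid, mask=mask)
    return truth, stacks, mask, grid, cmap


def test_interior_rows_sum_to_one(smooth_problem):
    _, _, _, _, cmap = smooth_problem
    rows = np.asarray(cmap.matrix.sum(axis=1)).ravel()
    valid = cmap.valid
    assert valid.sum() > 1000
    assert np.abs(rows[valid] - 1.0).max() < 1e-6
    assert np.all(cmap.matrix.data >= 0)


def test_forward_model_matches_simulated_pixels(smooth_problem):
    """M @ x on the resampled truth reproduces PSF-simulated pixels within 1%."""
    truth, _, _, grid, cmap = smooth_problem
    x = truth.sample(grid.grid_world().reshape(-1, 3)).reshape(grid.shape)
    yhat = cmap.simulate(x)
    v = cmap.valid & (np.abs(cmap.y) > 20)
    rel = np.abs(yhat[v] - cmap.y[v]) / np.abs(cmap.y[v])
    assert np.percentile(rel, 99) < 0.01


def test_translation_by_one_voxel_shifts_row_support(smooth_problem):
    truth, stacks, mask, grid, _ = smooth_problem
    st = stacks[0].shallow_copy()  # axial, axis-aligned
    spacing = grid.spacing[0]
    cmap0 = build_coefficients([st], grid, mask=mask)
    for s in st.slices:
        s.transform = sv.RigidTransform(translation=(spacing, 0.0, 0.0))
    cmap1 = build_coefficients([st], grid, mask=mask)
    row = np.where(cmap0.valid & cmap1.valid)[0][50]
    c0 = sorted(cmap0.matrix[row].indices)
    c1 = sorted(cmap1.matrix[row].indices)
    stride = grid.shape[1] * grid.shape[2]  # +1 along first index axis
    assert c1 == [c + stride for c in c0]


def test_initialize_constant_and_masked(smooth_problem):
    truth, stacks, mask, grid, cmap = smooth_problem
    const = sv.Volume(np.full(truth.shape, 5.0), truth.affine)
    cfg = ProtocolConfig(
        n_stacks=1, noise_sigma=0, scale_jitter=0, motion=MotionModel.still(), margin=0, seed=1
    )
    cstacks, _ = simulate_protocol(const, cfg)
    ball = np.zeros(truth.shape, bool)
    ball[10:30, 10:30, 10:30] = True
    bmask = sv.Mask(ball, truth.affine)
    bgrid = make_output_grid(bmask, 0.75, pad_mm=2.0)
    bc = build_coefficients(cstacks, bgrid, mask=bmask)
    mask_grid = bmask.sample(bgrid.grid_world().reshape(-1, 3)).reshape(bgrid.shape) >= 0.5
    x0 = initialize_volume(bc, mask_grid)
    covered = mask_grid & (x0 != 0)
    assert covered.sum() > 100
    assert np.abs(x0[covered] - 5.0).max() < 1e-3
    assert np.all(x0[~mask_grid] == 0.0)


def test_slice_scale_recovery(smooth_problem):
    truth, _, _, grid, cmap = smooth_problem
    x = truth.sample(grid.grid_world().reshape(-1, 3)).reshape(grid.shape)
    yhat = cmap.simulate(x)

    import dataclasses

    # slices with no usable pixels keep scale 1 by contract; check the rest
    counts = np.bincount(cmap.slice_ids[cmap.valid], minlength=cmap.n_slices)
    has_data = counts > 50

    gained = dataclasses.replace(cmap, y=1.3 * yhat)
    s = estimate_slice_scales(gained, x)
    assert np.allclose(s[has_data], 1.3, atol=1e-3)

    exact = dataclasses.replace(cmap, y=yhat.copy())
    assert np.allclose(estimate_slice_scales(exact, x)[has_data], 1.0, atol=1e-9)

    extreme = dataclasses.replace(cmap, y=10.0 * yhat)
    assert np.allclose(estimate_slice_scales(extreme, x)[has_data], 5.0)  # clamp


def test_em_pure_inlier_limit():
    e = np.zeros(500)
    state = em_robust_update(e, np.zeros(500, dtype=int), 1, intensity_range=100.0)
    assert np.all(state.p > 0.99)


def test_em_recovers_planted_mixture():
    """80/20 Gaussian/uniform mixture: c and the posterior labelling recover."""
    r = np.random.default_rng(42)
    n = 10_000
    labels = r.random(n) < 0.8
    e = np.where(labels, r.standard_normal(n), r.uniform(-10, 10, n))
    slice_ids = np.repeat(np.arange(20), n // 20)
    state = em_robust_update(e, slice_ids, 20, intensity_range=20.0)
    assert 0.75 <= state.c <= 0.85
    # rank-based AUC of posteriors for the known labels
    order = np.argsort(np.argsort(state.p))
    auc = (order[labels].mean() - order[~labels].mean()) / n + 0.5
    assert auc > 0.9
    assert 0.8 <= state.sigma <= 1.2


def test_sr_fixed_point(smooth_problem):
    """Data simulated from the current volume, lambda=0: the update is zero."""
    truth, _, _, grid, cmap = smooth_problem
    x = truth.sample(grid.grid_world().reshape(-1, 3)).reshape(grid.shape)
    import dataclasses

    fixed = dataclasses.replace(cmap, y=cmap.simulate(x))
    em = EMState(
        p=np.ones(int(fixed.valid.sum())),
        sigma=1.0,
        c=0.9,
        slice_weights=np.ones(fixed.n_slices),
        excluded=np.zeros(fixed.n_slices, bool),
    )
    mask_grid = np.ones(grid.shape, bool)
    x2, misfit = superresolution_step(
        x, fixed, np.ones(fixed.n_slices), em, mask_grid, alpha=1.0, lambda_reg=0.0
    )
    assert np.abs(x2 - x).max() < 1e-6
    assert misfit < 1e-12


def test_sr_misfit_monotone_on_clean_data(smooth_problem):
    truth, _, _, grid, cmap = smooth_problem
    em = EMState(
        p=np.ones(int(cmap.valid.sum())),
        sigma=1.0,
        c=0.9,
        slice_weights=np.ones(cmap.n_slices),
        excluded=np.zeros(cmap.n_slices, bool),
    )
    mask_grid = np.ones(grid.shape, bool)
    x = initialize_volume(cmap, mask_grid)
    prev = np.inf
    for _ in range(25):
        x, misfit = superresolution_step(
            x, cmap, np.ones(cmap.n_slices), em, mask_grid, alpha=1.0, lambda_reg=0.0
        )
        assert misfit <= prev * (1 + 1e-12)
        prev = misfit


def test_regularization_smooths_flat_regions_but_keeps_edges():
    """lambda > 0 lowers flat-region noise variance; a step edge stays sharp."""
    r = np.random.default_rng(5)
    shape = (24, 24, 24)
    truth_data = np.where(np.arange(shape[0])[:, None, None] < 12, 50.0, 150.0)
    truth_data = np.broadcast_to(truth_data, shape).astype(float)
    truth = sv.Volume(truth_data, sv.axis_aligned_affine(shape, 1.0))
    cfg = ProtocolConfig(
        n_stacks=3, noise_sigma=4.0, scale_jitter=0, motion=MotionModel.still(), margin=0, seed=6
    )
    stacks, _ = simulate_protocol(truth, cfg)
    mask = sv.Mask(np.ones(shape, bool), truth.affine)
    grid = make_output_grid(mask, 0.75, pad_mm=0.0)
    cmap = build_coefficients(stacks, grid, mask=mask)
    em = EMState(
        p=np.ones(int(cmap.valid.sum())),
        sigma=4.0,
        c=0.9,
        slice_weights=np.ones(cmap.n_slices),
        excluded=np.zeros(cmap.n_slices, bool),
    )
    mask_grid = np.ones(grid.shape, bool)
    results = {}
    for lam in (0.0, 0.05):
        x = initialize_volume(cmap, mask_grid)
        for _ in range(40):
            x, _ = superresolution_step(
                x, cmap, np.ones(cmap.n_slices), em, mask_grid,
                alpha=1.0, lambda_reg=lam, delta=5.0,
            )
        results[lam] = x
    # flat-region variance strictly lower with regularisation
    flat = np.s_[20:28, 8:24, 8:24]
    assert results[0.05][flat].var() < results[0.0][flat].var()
    # 10-90% rise width of the edge grows by less than one voxel
    def edge_width(x):
        prof = x[:, 8:24, 8:24].mean(axis=(1, 2))
        lo, hi = 50 + 0.1 * 100, 50 + 0.9 * 100
        i10 = np.argmax(prof > lo)
        i90 = np.argmax(prof > hi)
        return i90 - i10
    assert edge_width(results[0.05]) - edge_width(results[0.0]) < 1.0 / 0.75


def test_recon_config_validation():
    with pytest.raises(ValueError, match="spacing"):
        ReconConfig(spacing=0.4)
    with pytest.raises(ValueError, match="spacing"):
        ReconConfig(spacing=1.0)
    with pytest.raises(ValueError):
        ReconConfig(lambda_reg=-1.0)


def test_all_slices_excluded_raises(smooth_problem):
    truth, stacks, mask, _, _ = smooth_problem
    st = stacks[0].shallow_copy()
    for s in st.slices:
        s.excluded = True
    with pytest.raises(ReconstructionError):
        reconstruct([st], mask, ReconConfig(n_outer=1, n_sr=1))
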