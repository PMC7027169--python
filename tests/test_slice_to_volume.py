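import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from emlddmm.grids import Image, ImageGrid, interpolate
from emlddmm.slice_to_volume import (
    SliceStack,
    TransformChain,
    VolumeSliceRegistration,
    map_detections_to_atlas,
    rot2,
    tabulate_tau,
)
from emlddmm.registration import AffineMap


def make_volume(seed=0, shape=(12, 40, 40), spacing=(2.0, 1.0, 1.0)):
    rng = np.random.default_rng(seed)
    vol = gaussian_filter(rng.normal(size=shape), (1.5, 2.5, 2.5))
    vol = (vol - vol.mean()) / vol.std()
    return Image(ImageGrid(shape, spacing, (0.0, 0.0, 0.0)), vol)


def extract_slices(volume, zs, angles=None, shifts=None, noise=0.0, seed=0):
    """Slices sampled from the volume after known per-slice 2D rigids."""
    rng = np.random.default_rng(seed)
    ny, nx = volume.grid.shape[1:]
    sgrid = ImageGrid((ny, nx), volume.grid.spacing[1:],
                      volume.grid.origin[1:])
    pts = sgrid.coordinate_array().reshape(-1, 2)
    c = np.array([(ny - 1) / 2.0 * sgrid.spacing[0],
                  (nx - 1) / 2.0 * sgrid.spacing[1]])
    images = []
    for k, z in enumerate(zs):
        p = pts
        if angles is not None:
            p = (pts - c) @ rot2(angles[k]).T + c + shifts[k]
        q = np.concatenate([np.full((len(p), 1), z), p], axis=1)
        vals = interpolate(volume, q).reshape(ny, nx)
        if noise:
            vals = vals + rng.normal(0, noise, (ny, nx))
        images.append(Image(sgrid, vals))
    return SliceStack(images, zs)


class TestSliceStack:
    def test_nonincreasing_z_rejected(self):
        g = ImageGrid((4, 4), (1, 1), (0, 0))
        imgs = [Image(g, np.zeros((4, 4)))] * 2
        with pytest.raises(ValueError):
            SliceStack(imgs, [2.0, 1.0])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            SliceStack([], [])


class TestTransformChain:
    def test_chain_pullback_equals_sequential_components(self):
        # the composed map must agree with applying each component in turn
        rng = np.random.default_rng(3)
        chain = TransformChain([0.0, 4.0], [[10.0, 10.0], [10.0, 10.0]])
        chain.angles = np.array([0.1, -0.2])
        chain.shifts = rng.normal(size=(2, 2))
        chain.scale_xy = 1.3
        R = AffineMap(project_linear := np.eye(3), rng.normal(size=3),
                      np.zeros(3))
        chain.rigid3d = R
        pts = rng.uniform(0, 20, (30, 2))
        for i in range(2):
            got = chain.slice_to_volume_affine(i, pts)
            c = chain.slice_centers[i]
            step1 = (pts - c) @ rot2(chain.angles[i]).T + c + chain.shifts[i]
            step2 = c + chain.scale_xy * (step1 - c)
            step3 = np.concatenate(
                [np.full((30, 1), chain.z[i]), step2], axis=1
            )
            step4 = R(step3)
            assert np.allclose(got, step4, atol=1e-12)

    def test_inverse_chain_round_trips(self):
        rng = np.random.default_rng(4)
        chain = TransformChain([0.0, 5.0], [[8.0, 8.0], [8.0, 8.0]])
        chain.angles = np.array([0.15, -0.1])
        chain.shifts = rng.normal(size=(2, 2))
        chain.rigid3d = AffineMap(np.eye(3), rng.normal(size=3), np.zeros(3))
        pts = rng.uniform(0, 16, (20, 2))
        for i in range(2):
            vol_pts = chain.map_slice_points(i, pts)
            back = chain.volume_to_slice(i, vol_pts)
            assert np.allclose(back, pts, atol=1e-10)


class TestRegisterVolumeToStack:
    def test_exact_extraction_stays_at_identity(self):
        volume = make_volume(seed=1)
        stack = extract_slices(volume, [4.0, 12.0])
        est = VolumeSliceRegistration(order=1, classes=("matching",),
                                      n_em=1, n_iter=5).fit(volume, stack)
        assert np.abs(est.chain_.angles).max() < 0.01
        assert np.abs(est.chain_.shifts).max() < 0.2
        assert np.abs(est.chain_.rigid3d.translation).max() < 0.2

    def test_recovers_known_per_slice_rigid_motions(self):
        volume = make_volume(seed=0)
        true_ang = np.array([0.03, -0.05, 0.02])
        true_shift = np.array([[1.2, -0.8], [0.5, 1.5], [-1.0, 0.6]])
        stack = extract_slices(volume, [4.0, 10.0, 16.0], true_ang,
                               true_shift, noise=0.01, seed=7)
        est = VolumeSliceRegistration(
            order=2, contrast_mode="separable", classes=("matching",),
            sigma_m=0.1, n_em=3, n_iter=60,
        ).fit(volume, stack)
        chain = est.chain_
        # rotations within 1 degree
        assert np.abs(chain.angles - true_ang).max() < np.deg2rad(1.0)
        # total in-plane offset (per-slice shift + shared 3D translation is
        # a gauge split) within 1 pixel
        for k in range(3):
            eff = chain.shifts[k] + chain.rigid3d.translation[1:]
            assert np.linalg.norm(eff - true_shift[k]) < 1.0

    def test_torn_wedge_is_classified_background(self):
        volume = make_volume(seed=2)
        volume = Image(volume.grid, volume.values - volume.values.min())
        stack = extract_slices(volume, [6.0, 14.0])
        vals = stack.images[0].values.copy()
        ny, nx = vals.shape[:2]
        yy, xx = np.mgrid[0:ny, 0:nx]
        wedge = (xx > yy) & (xx > nx - yy)  # wedge from the bottom edge
        vals[wedge] = 0.0
        imgs = [Image(stack.images[0].grid, vals), stack.images[1]]
        stack2 = SliceStack(imgs, stack.z)
        est = VolumeSliceRegistration(
            order=1, classes=("matching", "background"), sigma_m=0.2,
            n_em=3, n_iter=10,
        ).fit(volume, stack2)
        post = est.posteriors_[0]
        labels = post.argmax_labels()  # 0 matching, 1 background
        frac_bg = np.mean(labels[wedge] == 1)
        assert frac_bg > 0.8

    def test_per_slice_contrasts_are_independent(self):
        volume = make_volume(seed=3)
        stack = extract_slices(volume, [4.0, 12.0], noise=0.01, seed=1)
        est = VolumeSliceRegistration(order=1, classes=("matching",),
                                      n_em=1, n_iter=3).fit(volume, stack)
        theta_before = [F.theta_.copy() for F in est.contrasts_]
        # corrupt slice 1's intensities only
        imgs = [stack.images[0],
                Image(stack.images[1].grid, 2.0 * stack.images[1].values + 1)]
        est2 = VolumeSliceRegistration(order=1, classes=("matching",),
                                       n_em=1, n_iter=3).fit(
            volume, SliceStack(imgs, stack.z)
        )
        assert np.allclose(est2.contrasts_[0].theta_, theta_before[0],
                           atol=0.05)
        assert not np.allclose(est2.contrasts_[1].theta_, theta_before[1],
                               atol=0.05)


class TestDetectionMapping:
    def _fitted_chain(self, volume, zs):
        stack = extract_slices(volume, zs)
        est = VolumeSliceRegistration(order=1, classes=("matching",),
                                      n_em=1, n_iter=1).fit(volume, stack)
        return est.chain_, stack

    def test_identity_chain_stamps_density_at_slice_planes(self):
        volume = make_volume(seed=4, shape=(10, 24, 24))
        chain, stack = self._fitted_chain(volume, [4.0, 12.0])
        dens = [Image(im.grid, np.full(im.grid.shape, 0.7))
                for im in stack.images]
        mapped = map_detections_to_atlas(dens, chain, volume.grid)
        vals = mapped.scalar()
        supported = np.isfinite(vals)
        assert supported.any()
        assert np.allclose(vals[supported], 0.7, atol=1e-6)
        # planes far from any slice are unsupported
        assert np.all(~supported[-1])

    def test_unfitted_chain_rejected(self):
        chain = TransformChain([0.0], [[0.0, 0.0]])
        g = ImageGrid((4, 4, 4), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="not fitted"):
            map_detections_to_atlas([], chain, g)

    def test_known_translation_moves_density_centroid(self):
        volume = make_volume(seed=5, shape=(10, 24, 24))
        chain, stack = self._fitted_chain(volume, [4.0])
        offset = np.array([0.0, 3.0, -2.0])
        chain.rigid3d = AffineMap(np.eye(3), offset, np.zeros(3))
        im = stack.images[0]
        blob = np.zeros(im.grid.shape)
        blob[10:14, 8:12] = 1.0
        mapped = map_detections_to_atlas([Image(im.grid, blob)], chain,
                                         volume.grid)
        vals = np.nan_to_num(mapped.scalar(), nan=0.0)
        com = np.array([
            float(np.sum(w * vals.sum(axis=tuple(a for a in range(3)
                                                 if a != d))))
            for d, w in enumerate(volume.grid.axis_coordinates())
        ]) / vals.sum()
        # in-plane centroid moved by exactly the in-plane offset
        expected_rc = np.array([11.5, 9.5]) + offset[1:]
        assert np.allclose(com[1:], expected_rc, atol=0.6)


class TestTabulateTau:
    def _grid(self):
        return ImageGrid((4, 6, 6), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    def test_zero_density_gives_zero_areas_and_fractions(self):
        g = self._grid()
        dens = Image(g, np.zeros(g.shape))
        labels = Image(g, np.ones(g.shape))
        tab = tabulate_tau(dens, labels, pixel_area=0.01)
        assert (tab["tangle_area"] == 0).all()
        assert (tab["fraction"] == 0).all()

    def test_hand_counted_partial_coverage(self):
        # 10 fully-positive pixels of 0.01 area inside a 100-pixel structure
        g = ImageGrid((1, 10, 10), (1, 1, 1), (0, 0, 0))
        dens = np.zeros(g.shape)
        dens[0, 0, :] = 1.0
        labels = Image(g, np.ones(g.shape))
        tab = tabulate_tau(Image(g, dens), labels, pixel_area=0.01)
        assert tab.loc[0, "tangle_area"] == pytest.approx(0.1)
        assert tab.loc[0, "structure_area"] == pytest.approx(1.0)
        assert tab.loc[0, "fraction"] == pytest.approx(0.1)

    def test_saturated_density_gives_fraction_one(self):
        g = self._grid()
        tab = tabulate_tau(Image(g, np.ones(g.shape)),
                           Image(g, np.ones(g.shape)), pixel_area=1.0)
        assert np.allclose(tab["fraction"], 1.0)

    def test_page_partition_preserves_total_area(self):
        rng = np.random.default_rng(6)
        g = self._grid()
        dens = Image(g, rng.uniform(size=g.shape))
        labels = Image(g, rng.integers(0, 3, g.shape).astype(float))
        by_page = tabulate_tau(dens, labels, 1.0, pages=[0.0, 1.0, 2.0, 3.0])
        whole = tabulate_tau(dens, labels, 1.0, pages=[0.0])
        for s in whole["structure"]:
            total = by_page[by_page["structure"] == s]["tangle_area"].sum()
            ref = whole[whole["structure"] == s]["tangle_area"].sum()
            assert total == pytest.approx(ref)

    def test_unit_mismatch_rejected(self):
        g = self._grid()
        with pytest.raises(ValueError):
            tabulate_tau(Image(g, np.zeros(g.shape)),
                         Image(g, np.zeros(g.shape)), pixel_area=0.0)
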