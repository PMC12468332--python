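import numpy as np
import pytest

from mwbreast.forward import synthesize_scan, frequency_grid
from mwbreast.geometry import (LesionSpec, PhantomSpec, build_probe_array,
                               lattice_centers, make_phantom)
from mwbreast.imaging import (PCFIB_RANGES, ImagingConfigError, SectorImage,
                              SliceGeometry, VolumeImage, composite_images,
                              focus_quality, form_subarray, high_ranges,
                              low_ranges, music_pseudospectrum,
                              pcfib_candidates, sector_taper,
                              select_pcfib, stack_slices, stitch_sectors,
                              trmusic_sector)
from mwbreast.preprocess import Mode, preprocess_sector


class TestSubarray:
    def test_center_zero_wraps(self, probe_ring):
        assert form_subarray(probe_ring, 0).tolist() == [18, 19, 20, 0, 1, 2, 3, 4]

    def test_union_covers_all_probes(self, probe_ring):
        probes = set()
        for c in range(21):
            probes.update(form_subarray(probe_ring, c).tolist())
        assert probes == set(range(21))

    def test_adjacent_centers_share_seven(self, probe_ring):
        for c in range(21):
            a = set(form_subarray(probe_ring, c).tolist())
            b = set(form_subarray(probe_ring, (c + 1) % 21).tolist())
            assert len(a & b) == 7


class TestRanges:
    def test_eleven_printed_ranges(self):
        assert len(PCFIB_RANGES) == 11
        assert all(lo < hi for lo, hi in PCFIB_RANGES)

    def test_low_high_membership(self):
        assert set(low_ranges()) == {(10, 30), (20, 40), (30, 50), (20, 50)}
        assert set(high_ranges()) == {(50, 70), (60, 80), (70, 90), (50, 80)}

    def test_candidate_grid(self):
        assert pcfib_candidates((20, 50)).tolist() == [20, 25, 30, 35, 40, 45, 50]


def _clean_sectors(phantom, scan, geom, pc_fib, freqs, centers=range(21)):
    cache = {}
    out = []
    for c in centers:
        pre = preprocess_sector(scan.data[0], freqs, c, Mode.DEFAULT,
                                phantom.envelope, scan.array.probe_xy(),
                                geom.z, phantom.media, emd=False, pca=False)
        out.append(trmusic_sector(pre.cleaned, freqs, geom, c, pre.probes,
                                  pc_fib, phantom.media,
                                  steering_cache=cache))
    return out


class TestTRMusic:
    def test_point_scatterer_localized_to_one_voxel(self, point_phantom,
                                                    probe_ring, freqs):
        scan = synthesize_scan(point_phantom, probe_ring, freqs,
                               slices=np.array([-41.0]))
        geom = SliceGeometry.build(point_phantom.envelope, scan.array, -41.0, 64)
        img = stitch_sectors(_clean_sectors(point_phantom, scan, geom, 0.35,
                                            freqs), geom.mask)
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert abs(geom.grid_x[ix] - 15.0) <= 2.0
        assert abs(geom.grid_y[iy] - 9.0) <= 2.0

    def test_noise_subspace_orthogonal_at_truth(self, point_phantom, freqs,
                                                probe_ring):
        """Steering at the true location is annihilated by the noise
        subspace of the (full-diagonal) rank-one data matrix."""
        geom = SliceGeometry.build(point_phantom.envelope, probe_ring, -41.0, 64)
        A = geom.steering(0.35, freqs, point_phantom.media)
        probes = form_subarray(probe_ring, 0)
        vox = point_phantom.lesions[0].voxels[0]
        pix = np.nonzero((geom.grid_x[geom.pix_index % 64] == vox[0])
                         & (geom.grid_y[geom.pix_index // 64] == vox[1]))[0][0]
        for fi in (0, len(freqs) // 2, len(freqs) - 1):
            g = A[fi][probes][:, pix]
            M = np.outer(g, g)
            u, s, _ = np.linalg.svd(M)
            noise_proj = np.linalg.norm(u[:, 1:].conj().T @ (g / np.linalg.norm(g)))
            assert noise_proj <= 1e-6

    def test_two_scatterers_resolved(self, freqs):
        spec = PhantomSpec(pc_fib=0.35, lesions=(
            LesionSpec(center=(15.0, 9.0, -41.0), axes=(1.5,) * 3),
            LesionSpec(center=(15.0, 21.0, -41.0), axes=(1.5,) * 3)))
        ph = make_phantom(spec, 2)
        arr = build_probe_array(100.0, ph.envelope.z_grid[0], -24.0)
        scan = synthesize_scan(ph, arr, freqs, slices=np.array([-41.0]))
        geom = SliceGeometry.build(ph.envelope, scan.array, -41.0, 64)
        # the sector whose wedge faces both scatterers resolves them
        [sector] = _clean_sectors(ph, scan, geom, 0.35, freqs, centers=[1])
        img = sector.values
        from scipy.ndimage import maximum_filter
        peaks = (img == maximum_filter(img, size=3)) & (img > 0.3 * img.max())
        pys, pxs = np.nonzero(peaks)
        pts = np.column_stack([geom.grid_x[pxs], geom.grid_y[pys]])
        for truth in ((15.0, 9.0), (15.0, 21.0)):
            d = np.linalg.norm(pts - np.array(truth), axis=1)
            assert d.min() <= 2.0 * np.sqrt(2)

    def test_scale_invariance(self, rng):
        M = rng.standard_normal((4, 6, 6)) + 1j * rng.standard_normal((4, 6, 6))
        A = rng.standard_normal((4, 6, 50)) + 1j * rng.standard_normal((4, 6, 50))
        p1 = music_pseudospectrum(M, A)
        p2 = music_pseudospectrum(1e3 * M, A)
        assert np.allclose(p1, p2, rtol=1e-9)

    def test_all_zero_matrix_uniform_with_warning(self, rng):
        A = rng.standard_normal((2, 6, 10)) + 0j
        with pytest.warns(UserWarning):
            p = music_pseudospectrum(np.zeros((2, 6, 6), complex), A)
        assert np.all(p == p[0])


class TestFocusQuality:
    def _sector(self, values):
        return SectorImage(values=values, weight=(values >= 0).astype(float),
                           pc_fib=0.3)

    def test_impulse_beats_spread(self):
        base = np.zeros((16, 16))
        imp = base.copy()
        imp[8, 8] = 1.0
        spread = np.full((16, 16), 1.0 / 256)
        assert focus_quality(self._sector(imp)) > focus_quality(self._sector(spread))

    def test_uniform_scores_one(self):
        assert focus_quality(self._sector(np.ones((8, 8)))) == pytest.approx(1.0)

    def test_all_zero_scores_zero(self):
        s = SectorImage(values=np.zeros((8, 8)), weight=np.zeros((8, 8)),
                        pc_fib=0.3)
        assert focus_quality(s) == 0.0

    def test_tight_gaussian_beats_wide(self):
        y, x = np.mgrid[:32, :32]
        tight = np.exp(-((x - 16) ** 2 + (y - 16) ** 2) / (2 * 2.0 ** 2))
        wide = np.exp(-((x - 16) ** 2 + (y - 16) ** 2) / (2 * 6.0 ** 2))
        assert focus_quality(self._sector(tight)) > focus_quality(self._sector(wide))

    def test_scaling_invariant(self, rng):
        v = rng.random((16, 16))
        assert focus_quality(self._sector(v)) == pytest.approx(
            focus_quality(self._sector(7.3 * v)))


class TestSelectPcfib:
    def _cand(self, pc, score):
        s = SectorImage(values=np.ones((4, 4)), weight=np.ones((4, 4)), pc_fib=pc)
        s.score = score
        return s

    def test_max_score_wins(self):
        cands = [self._cand(0.2, 1.0), self._cand(0.3, 5.0), self._cand(0.4, 2.0)]
        assert select_pcfib(cands, (20, 40)).pc_fib == 0.3

    def test_tie_breaks_toward_midpoint(self):
        cands = [self._cand(0.2, 1.0), self._cand(0.3, 1.0), self._cand(0.5, 1.0)]
        assert select_pcfib(cands, (20, 50)).pc_fib == 0.3

    def test_empty_candidates_rejected(self):
        with pytest.raises(ImagingConfigError):
            select_pcfib([], (20, 50))


class TestStitching:
    def _sectors_const(self, n=64):
        gx = lattice_centers(n)
        out = []
        for c in range(21):
            w = sector_taper(gx, gx, c)
            out.append(SectorImage(values=(w > 0).astype(float), weight=w,
                                   pc_fib=0.3))
        return out

    def test_partition_of_unity(self):
        img = stitch_sectors(self._sectors_const())
        covered = sum(s.weight for s in self._sectors_const()) > 0
        assert np.allclose(img[covered], 1.0)

    def test_zero_sector_stays_finite(self):
        sectors = self._sectors_const()
        sectors[3].values[:] = 0.0
        img = stitch_sectors(sectors)
        assert np.all(np.isfinite(img))

    def test_coverage_gap_raises(self):
        sectors = self._sectors_const()[:3]
        mask = np.ones_like(sectors[0].values, bool)
        with pytest.raises(ImagingConfigError):
            stitch_sectors(sectors, mask)


class TestStackAndComposites:
    def _slices(self, value=1.0):
        gx = lattice_centers(16)
        imgs, masks = {}, {}
        for z in (-40.0, -42.0, -44.0):
            imgs[z] = np.full((16, 16), value)
            masks[z] = np.ones((16, 16), bool)
        return imgs, masks, gx

    def test_identical_slices_identical_planes(self):
        imgs, masks, gx = self._slices()
        vol = stack_slices(imgs, masks, gx, gx)
        filled = vol.data[:, :, ~vol.excluded_z]
        assert np.allclose(filled, 1.0)

    def test_single_slab_peak_at_its_height(self):
        imgs, masks, gx = self._slices(0.0)
        imgs[-42.0][8, 8] = 5.0
        vol = stack_slices(imgs, masks, gx, gx)
        k = np.argmax(vol.data.max(axis=(0, 1)))
        assert abs(vol.z_planes[k] - (-42.0)) <= 2.0

    def test_cutout_zeroes_flagged_planes(self):
        imgs, masks, gx = self._slices()
        vol = stack_slices(imgs, masks, gx, gx, cutout_index=1)
        assert vol.excluded_z.any()
        assert np.all(vol.data[:, :, vol.excluded_z] == 0)
        assert np.all(vol.data[:, :, ~vol.excluded_z] > 0)

    def _volumes(self, rng=None):
        gx = lattice_centers(8)
        z = np.arange(-45.0, -38.0, 2.0)
        vols = {}
        for i, r in enumerate(PCFIB_RANGES):
            data = np.full((8, 8, len(z)), float(i + 1))
            vols[r] = VolumeImage(data=data, grid_x=gx, grid_y=gx, z_planes=z,
                                  mask=np.ones(data.shape, bool))
        return vols

    def test_global_is_voxelwise_mean(self):
        vols = self._volumes()
        comps = composite_images(vols)
        expected = np.mean([v.data for v in vols.values()], axis=0)
        assert np.array_equal(comps["GLOBAL"].data, expected)

    def test_low_high_average_four_ranges_each(self):
        comps = composite_images(self._volumes())
        assert len(comps["LOW"].provenance["members"]) == 4
        assert len(comps["HIGH"].provenance["members"]) == 4

    def test_identical_volumes_identical_composites(self):
        vols = self._volumes()
        for v in vols.values():
            v.data[:] = 3.14
        comps = composite_images(vols)
        for c in comps.values():
            assert np.allclose(c.data, 3.14)

    def test_composite_within_input_bounds(self, rng):
        vols = self._volumes()
        for v in vols.values():
            v.data[:] = rng.random(v.data.shape)
        comps = composite_images(vols)
        lo = np.min([v.data for v in vols.values()], axis=0)
        hi = np.max([v.data for v in vols.values()], axis=0)
        for c in comps.values():
            assert np.all(c.data >= lo - 1e-12)
            assert np.all(c.data <= hi + 1e-12)

    def test_wrong_count_rejected(self):
        vols = self._volumes()
        vols.pop((10, 30))
        with pytest.raises(ImagingConfigError):
            composite_images(vols)


class TestPcfibRecovery:
    def test_selected_assumption_recovers_truth(self):
        """Two opposite point scatterers, noiseless, range 20:50, truth 35%:
        the per-sector selection lands within one 5-point step of truth in
        at least 70% of the 21 sectors."""
        spec = PhantomSpec(pc_fib=0.35, lesions=(
            LesionSpec(center=(23.0, 7.0, -41.0), axes=(1.5,) * 3, contrast=3.0),
            LesionSpec(center=(-23.0, -7.0, -41.0), axes=(1.5,) * 3, contrast=3.0)))
        ph = make_phantom(spec, 1)
        arr = build_probe_array(100.0, ph.envelope.z_grid[0], -24.0)
        freqs = frequency_grid(n_freq=24)
        scan = synthesize_scan(ph, arr, freqs, slices=np.array([-41.0]))
        geom = SliceGeometry.build(ph.envelope, scan.array, -41.0, 64)
        cache = {}
        hits = 0
        for c in range(21):
            pre = preprocess_sector(scan.data[0], freqs, c, Mode.DEFAULT,
                                    ph.envelope, scan.array.probe_xy(), -41.0,
                                    ph.media, emd=False, pca=False)
            cands = [trmusic_sector(pre.cleaned, freqs, geom, c, pre.probes,
                                    p / 100.0, ph.media, steering_cache=cache)
                     for p in pcfib_candidates((20, 50))]
            best = select_pcfib(cands, (20, 50))
            hits += abs(best.pc_fib - 0.35) <= 0.0501
        assert hits >= 15


class TestVolumeIO:
    def test_nifti_round_trip(self, tmp_path):
        gx = lattice_centers(16)
        z = np.arange(-45.0, -38.0, 2.0)
        data = np.random.default_rng(0).random((16, 16, len(z)))
        vol = VolumeImage(data=data, grid_x=gx, grid_y=gx, z_planes=z,
                          mask=np.ones(data.shape, bool))
        vol.save(tmp_path / "v.nii")
        back = VolumeImage.load(tmp_path / "v.nii")
        assert np.allclose(back.data, data, atol=1e-6)
        assert np.allclose(back.grid_x, gx)
        assert np.allclose(back.z_planes, z)
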