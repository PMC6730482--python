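"""Coordinate-frame reconciliation and streamline/volume I/O."""

import numpy as np
import pytest

import tractmargin as tm
from tractmargin.spaces import FormatError, ReconcileError, points_to_voxels


def make_grid(dims=(4, 5, 6), vs=(1.0, 1.0, 1.0), codes="RAS", values=None):
    A = np.diag(list(vs) + [1.0])
    A[:3, 3] = 0.5 * np.asarray(vs)
    if values is None:
        values = np.zeros(dims)
    return tm.VolumeGrid(values, vs, A, codes)


def make_set(polylines, dims=(4, 5, 6), vs=(1.0, 1.0, 1.0), order="RAS"):
    hdr = tm.StreamlineHeader(dims, vs, order)
    return tm.StreamlineSet([np.asarray(p, dtype=np.float32) for p in polylines], hdr)


class TestTrkRoundTrip:
    def test_write_read_reproduces_coordinates_exactly(self, tmp_path):
        rng = np.random.default_rng(3)
        polys = [rng.uniform(0, 4, size=(n, 3)).astype(np.float32)
                 for n in (2, 7, 30)]
        s = make_set(polys)
        f = tmp_path / "b.trk"
        tm.write_streamlines(s, f)
        s2 = tm.read_streamlines(f)
        assert len(s2) == 3
        for a, b in zip(s, s2):
            assert np.array_equal(a, b)
        assert s2.header.voxel_order == "RAS"
        assert s2.header.dims == (4, 5, 6)

    def test_empty_set_round_trips(self, tmp_path):
        hdr = tm.StreamlineHeader((4, 5, 6), (1, 1, 1), "LPS")
        s = tm.StreamlineSet([], hdr)
        f = tmp_path / "e.trk"
        tm.write_streamlines(s, f)
        s2 = tm.read_streamlines(f)
        assert len(s2) == 0
        assert s2.header.voxel_order == "LPS"  # preserved verbatim

    def test_truncated_file_is_a_format_error(self, tmp_path):
        s = make_set([[[0, 0, 0], [1, 1, 1]]])
        f = tmp_path / "t.trk"
        tm.write_streamlines(s, f)
        data = f.read_bytes()
        f.write_bytes(data[:-5])
        with pytest.raises(FormatError, match="truncated"):
            tm.read_streamlines(f)

    def test_bad_magic_names_the_field(self, tmp_path):
        f = tmp_path / "bad.trk"
        f.write_bytes(b"NOPE!" + bytes(1200))
        with pytest.raises(FormatError, match="id_string|magic"):
            tm.read_streamlines(f)

    def test_agrees_with_nibabel_reader(self, tmp_path):
        """Independent cross-check: nibabel's TRK reader returns the same
        geometry after its voxmm->rasmm transform."""
        import nibabel as nib
        from nibabel.streamlines.trk import TrkFile, get_affine_trackvis_to_rasmm

        rng = np.random.default_rng(11)
        polys = [rng.uniform(0, 4, size=(5, 3)).astype(np.float32) for _ in range(4)]
        s = make_set(polys, vs=(1.1, 1.0, 2.0))
        f = tmp_path / "x.trk"
        tm.write_streamlines(s, f)
        trk = TrkFile.load(str(f), lazy_load=False)
        A = get_affine_trackvis_to_rasmm(trk.header)
        inv = np.linalg.inv(A)
        for mine, theirs in zip(s, trk.tractogram.streamlines):
            voxmm = theirs @ inv[:3, :3].T + inv[:3, 3]
            assert np.allclose(voxmm, mine, atol=1e-4)

    def test_consecutive_duplicates_removed_on_load(self):
        s = make_set([[[0, 0, 0], [0, 0, 0], [1, 0, 0]]])
        assert len(s.polylines[0]) == 2


class TestNiftiVolumes:
    def test_binary_mask_unchanged(self, tmp_path):
        g = make_grid(values=np.eye(4)[:, :, None] * np.ones((1, 1, 6)),
                      dims=(4, 4, 6))
        f = tmp_path / "m.nii.gz"
        tm.write_volume(g, f, dtype=np.uint8)
        g2 = tm.read_volume(f, binarize=True)
        assert np.array_equal(g2.values, g.values)

    def test_nonbinary_mask_binarized_preserving_count(self, tmp_path):
        vals = np.zeros((4, 5, 6))
        vals[1:3, 2, 2] = 255.0
        g = make_grid(values=vals)
        f = tmp_path / "m255.nii.gz"
        tm.write_volume(g, f)
        g2 = tm.read_volume(f, binarize=True)
        assert set(np.unique(g2.values)) <= {0, 1}
        assert g2.values.sum() == 2

    def test_4d_multivolume_rejected(self, tmp_path):
        import nibabel as nib
        f = tmp_path / "fourd.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3, 2)), np.eye(4)), str(f))
        with pytest.raises(ValueError, match="4-D"):
            tm.read_volume(f)

    def test_non_invertible_affine_rejected(self):
        A = np.diag([1.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            tm.VolumeGrid(np.zeros((3, 3, 3)), (1, 1, 1), A, "RAS")


class TestReconcileAffine:
    def test_identity_ordering_is_scale_plus_center_shift(self):
        g = make_grid(vs=(2.0, 2.0, 2.0))
        hdr = tm.StreamlineHeader((4, 5, 6), (2, 2, 2), "RAS")
        a = tm.reconcile_affine(hdr, g)
        expected = np.diag([2.0, 2.0, 2.0, 1.0])
        expected[:3, 3] = 1.0  # half-voxel center shift
        assert np.allclose(a.matrix, expected)

    def test_lps_grid_ras_streamlines_brute_force_corners(self):
        """All 8 corner voxels of an LPS grid map to the flipped RAS trk voxels."""
        dims, vs = (4, 6, 8), (2.0, 2.0, 2.0)
        g = make_grid(dims=dims, vs=vs, codes="LPS")
        hdr = tm.StreamlineHeader(dims, vs, "RAS")
        a = tm.reconcile_affine(hdr, g)
        for i in (0, dims[0] - 1):
            for j in (0, dims[1] - 1):
                for k in (0, dims[2] - 1):
                    got = a.apply([i, j, k])[0]
                    # L vs R and P vs A flip, S matches: trk index is
                    # (dims-1-i, dims-1-j, k); point = (idx + .5) * vs
                    want = (np.array([dims[0] - 1 - i, dims[1] - 1 - j, k]) + 0.5) \
                        * np.asarray(vs)
                    assert np.allclose(got, want)

    def test_output_is_4x4(self):
        g = make_grid()
        a = tm.reconcile_affine(tm.StreamlineHeader((4, 5, 6), (1, 1, 1), "RAS"), g)
        assert a.matrix.shape == (4, 4)
        assert np.allclose(a.matrix[3], [0, 0, 0, 1])

    def test_permuted_axes_on_a_cubic_grid(self):
        """Label-driven reconciliation: equal dims still permute correctly."""
        dims, vs = (6, 6, 6), (1.0, 1.0, 1.0)
        g = make_grid(dims=dims, vs=vs, codes="ASR")
        hdr = tm.StreamlineHeader(dims, vs, "RAS")
        a = tm.reconcile_affine(hdr, g)
        # grid axis 0 is A -> trk axis 1; axis 1 is S -> trk 2; axis 2 is R -> trk 0
        got = a.apply([1, 2, 3])[0]
        assert np.allclose(got, (np.array([3, 1, 2]) + 0.5) * 1.0)

    def test_irreconcilable_dims_raise_listing_both(self):
        g = make_grid(dims=(4, 5, 6))
        hdr = tm.StreamlineHeader((4, 5, 7), (1, 1, 1), "RAS")
        with pytest.raises(ReconcileError, match=r"4, 5, 6.*4, 5, 7"):
            tm.reconcile_affine(hdr, g)

    def test_voxel_size_mismatch_raises(self):
        g = make_grid(vs=(1.0, 1.0, 1.0))
        hdr = tm.StreamlineHeader((4, 5, 6), (1.0, 1.0, 1.01), "RAS")
        with pytest.raises(ReconcileError, match="voxel sizes"):
            tm.reconcile_affine(hdr, g)

    def test_swapped_orientations_give_mutually_inverse_maps(self):
        dims, vs = (4, 6, 8), (1.0, 1.3, 2.0)
        g_lps = make_grid(dims=dims, vs=vs, codes="LPS")
        a = tm.reconcile_affine(tm.StreamlineHeader(dims, vs, "RAS"), g_lps)
        # swap roles: a grid in RAS against a header declaring LPS
        g_ras = make_grid(dims=dims, vs=vs, codes="RAS")
        b = tm.reconcile_affine(tm.StreamlineHeader(dims, vs, "LPS"), g_ras)
        # voxel index -> trk index parts must be mutually inverse permutations
        P_a = a.matrix[:3, :3] / np.asarray(vs)[:, None]
        P_b = b.matrix[:3, :3] / np.asarray(vs)[:, None]
        assert np.allclose(P_a @ P_b, np.eye(3))


class TestPointToVoxel:
    def setup_method(self):
        self.g = make_grid(dims=(5, 5, 5))
        self.a = tm.reconcile_affine(tm.StreamlineHeader((5, 5, 5), (1, 1, 1), "RAS"),
                                     self.g)

    def test_center_point(self):
        assert tm.point_to_voxel(np.array([0.5, 0.5, 0.5]), self.a) == (0, 0, 0)

    def test_boundary_goes_to_higher_voxel(self):
        assert tm.point_to_voxel(np.array([2.0, 0.5, 0.5]), self.a) == (2, 0, 0)

    def test_out_of_bounds_sentinel(self):
        assert tm.point_to_voxel(np.array([-0.5, 0.5, 0.5]), self.a,
                                 dims=(5, 5, 5)) is None

    def test_against_box_membership_oracle(self):
        """1000 random points agree with brute-force search over voxel boxes."""
        dims, vs = (6, 5, 4), (1.1, 0.9, 2.0)
        g = make_grid(dims=dims, vs=vs, codes="LAS")
        a = tm.reconcile_affine(tm.StreamlineHeader(dims, vs, "RAS"), g)
        rng = np.random.default_rng(5)
        # trk-space boxes: trk voxel t spans [t*vs, (t+1)*vs); grid voxel from flip
        pts = rng.uniform(0.05, 0.95, size=(1000, 3)) * (np.array(dims) * np.array(vs))
        idx, inb = points_to_voxels(pts, a, dims)
        assert inb.all()
        for p, got in zip(pts, idx):
            trk = tuple(int(np.floor(p[ax] / vs[ax])) for ax in range(3))
            # brute force: find the grid voxel whose mapped box contains p
            want = None
            for gi in range(dims[0]):
                if (dims[0] - 1 - gi) == trk[0]:  # L vs R flip on axis 0
                    want = (gi, trk[1], trk[2])
            assert want is not None and tuple(got) == want

    def test_round_trip_center_of_every_voxel(self):
        dims, vs = (4, 3, 5), (1.0, 1.25, 2.0)
        for codes in ("RAS", "LPS", "PIR"):
            a = _reconcile(codes, dims, vs)
            for i in range(dims[0]):
                for j in range(dims[1]):
                    for k in range(dims[2]):
                        p = a.apply([i, j, k])[0]
                        assert tm.point_to_voxel(p, a, dims=dims) == (i, j, k)


def _reconcile(codes, dims, vs):
    """Header voxel sizes/dims expressed on the trk (RAS) axes for a grid in `codes`."""
    from tractmargin.spaces import _axis_map
    perm, _ = _axis_map(codes, "RAS")
    tvs = np.empty(3)
    tdims = [0, 0, 0]
    for gax in range(3):
        tvs[perm[gax]] = vs[gax]
        tdims[perm[gax]] = dims[gax]
    A = np.zeros((4, 4))
    A[3, 3] = 1
    for gax in range(3):
        A[gax, gax] = vs[gax]
        A[gax, 3] = 0.5 * vs[gax]
    g = tm.VolumeGrid(np.zeros(dims), vs, A, codes)
    return tm.reconcile_affine(tm.StreamlineHeader(tuple(tdims), tvs, "RAS"), g)


class TestFrameConsistency:
    def test_phantom_world_equals_streamline_space(self, straight_phantom):
        """On phantoms both frames are built from the same world geometry, so
        (grid affine) and (reconciled affine) agree on every voxel center."""
        p = straight_phantom
        a = tm.reconcile_affine(p.streamlines.header, p.fa)
        for idx in [(0, 0, 0), (3, 4, 5), (27, 19, 19)]:
            world = p.fa.affine[:3, :3] @ np.array(idx) + p.fa.affine[:3, 3]
            assert np.allclose(a.apply(list(idx))[0], world, atol=1e-6)
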