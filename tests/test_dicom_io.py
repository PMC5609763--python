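"""DICOM layer: CSA codec (cross-checked against nibabel), tree scanning
with its persistent cache, spectroscopy round trips, voxel geometry, and
the plain-text fixture format."""

import json

import numpy as np
import pytest

from amaresfit import (CsaParseError, FidSeries, NotSpectroscopyError,
                       SchemaError, ValidationError)
from amaresfit.csa import build_csa1, build_csa2, parse_csa
from amaresfit.dicom_io import (CsiGeometry, CsiGrid, read_fixture,
                                read_spectroscopy, scan_dicom_tree,
                                voxel_to_patient, write_fixture,
                                write_synthetic_dicom,
                                write_synthetic_localizer, _cache_path)


def random_fid(rng, n=256, **kw):
    samples = rng.normal(size=n) + 1j * rng.normal(size=n)
    defaults = dict(dwell_time=2.5e-4, transmitter_freq=120.3,
                    dead_time=2e-4, reference_shift=0.0, nucleus="31P")
    defaults.update(kw)
    return FidSeries(samples=samples, **defaults)


def random_grid(rng, dims=(4, 3, 2), n=64):
    nx, ny, nz = dims
    fids = [random_fid(rng, n=n) for _ in range(nx * ny * nz)]
    geometry = CsiGeometry(position=[12.5, -40.0, 3.0],
                           row_dir=[1, 0, 0], col_dir=[0, 0, -1],
                           slice_dir=[0, 1, 0], voxel_size=[8.0, 8.0, 10.0])
    return CsiGrid(dims=dims, fids=fids, geometry=geometry)


class TestCsaCodec:
    TAGS = {
        "EchoLinePosition": ("IS", []),
        "ImagingFrequency": ("DS", [120.3]),
        "DataPointColumns": ("IS", [1024]),
        "ImagedNucleus": ("SH", ["31P"]),
        "RealDwellTime": ("DS", [250000.0]),
    }

    @pytest.mark.parametrize("builder", [build_csa2, build_csa1],
                             ids=["csa2", "csa1"])
    def test_roundtrip_and_nibabel_oracle(self, builder):
        blob = builder(self.TAGS)
        mine = parse_csa(blob)
        assert mine["ImagingFrequency"] == [120.3]
        assert mine["DataPointColumns"] == [1024]
        assert mine["ImagedNucleus"] == ["31P"]
        # independent decoder oracle for both binary dialects
        csareader = pytest.importorskip("nibabel.nicom.csareader")
        nib = csareader.read(blob)
        assert {k: t["items"] for k, t in nib["tags"].items()} == mine

    def test_truncated_block_reports_offset(self):
        blob = build_csa2(self.TAGS)
        with pytest.raises(CsaParseError) as exc:
            parse_csa(blob[:100])
        assert exc.value.offset is not None

    def test_garbage_rejected(self):
        with pytest.raises(CsaParseError):
            parse_csa(b"\xff" * 64)


class TestFixtureFormat:
    def test_fid_roundtrip_bit_exact(self, tmp_path, rng):
        fid = random_fid(rng, n=1024, dead_time=1.3e-4, reference_shift=4.7,
                         nucleus="1H")
        path = tmp_path / "fid.json"
        write_fixture(path, fid)
        back, truth = read_fixture(path)
        assert truth is None
        assert np.array_equal(back.samples, fid.samples)
        for name in ("dwell_time", "dead_time", "transmitter_freq",
                     "reference_shift", "nucleus"):
            assert getattr(back, name) == getattr(fid, name)

    def test_grid_roundtrip_preserves_geometry(self, tmp_path, rng):
        grid = random_grid(rng)
        path = tmp_path / "grid.json"
        write_fixture(path, grid, truth={"note": "synthetic"})
        back, truth = read_fixture(path)
        assert truth == {"note": "synthetic"}
        assert back.dims == grid.dims
        for a, b in zip(back.fids, grid.fids):
            assert np.array_equal(a.samples, b.samples)
        for name in ("position", "row_dir", "col_dir", "slice_dir",
                     "voxel_size"):
            np.testing.assert_array_equal(getattr(back.geometry, name),
                                          getattr(grid.geometry, name))

    def test_missing_field_named(self, tmp_path, rng):
        path = tmp_path / "fid.json"
        write_fixture(path, random_fid(rng))
        doc = json.loads(path.read_text())
        del doc["fid"]["dwell_time"]
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="dwell_time"):
            read_fixture(path)

    def test_schema_version_mismatch(self, tmp_path, rng):
        path = tmp_path / "fid.json"
        write_fixture(path, random_fid(rng))
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="schema_version"):
            read_fixture(path)


class TestSpectroscopyDicom:
    def test_single_voxel_roundtrip(self, tmp_path, rng):
        fid = random_fid(rng, dead_time=1e-4, reference_shift=4.7)
        path = tmp_path / "svs.dcm"
        write_synthetic_dicom(path, fid)
        back = read_spectroscopy(path)
        assert isinstance(back, FidSeries)
        # the file encodes float32 pairs; inversion is exact at that width
        assert np.array_equal(
            back.samples, fid.samples.astype(np.complex64).astype(np.complex128))
        assert back.dwell_time == pytest.approx(fid.dwell_time, rel=1e-12)
        assert back.transmitter_freq == pytest.approx(fid.transmitter_freq,
                                                      rel=1e-12)
        assert back.dead_time == pytest.approx(fid.dead_time, rel=1e-12)
        assert back.reference_shift == pytest.approx(fid.reference_shift,
                                                     rel=1e-12)
        assert back.nucleus == fid.nucleus

    def test_csi_grid_roundtrip(self, tmp_path, rng):
        grid = random_grid(rng, dims=(8, 8, 1))
        path = tmp_path / "csi.dcm"
        write_synthetic_dicom(path, grid)
        back = read_spectroscopy(path)
        assert isinstance(back, CsiGrid)
        assert back.dims == (8, 8, 1)
        assert len(back.fids) == 64
        for a, b in zip(back.fids, grid.fids):
            assert np.array_equal(
                a.samples, b.samples.astype(np.complex64).astype(np.complex128))
        np.testing.assert_allclose(back.geometry.position,
                                   grid.geometry.position)
        np.testing.assert_allclose(back.geometry.voxel_size,
                                   grid.geometry.voxel_size)

    def test_localizer_rejected_with_sop_class(self, tmp_path):
        path = tmp_path / "loc.dcm"
        write_synthetic_localizer(path)
        with pytest.raises(NotSpectroscopyError) as exc:
            read_spectroscopy(path)
        assert "1.2.840.10008.5.1.4.1.1.4" in str(exc.value)


class TestTreeScan:
    def _build_tree(self, root, rng, n_studies=2, n_series=3, n_instances=4):
        from pydicom.uid import generate_uid
        for s in range(n_studies):
            study_uid = generate_uid()
            for se in range(n_series):
                series_uid = generate_uid()
                sub = root / f"study{s}" / f"series{se}"
                sub.mkdir(parents=True)
                for i in range(n_instances):
                    write_synthetic_dicom(
                        sub / f"inst{i}.dcm", random_fid(rng, n=16),
                        study_uid=study_uid, series_uid=series_uid,
                        series_desc=f"fid_{s}_{se}", instance_number=i + 1)

    def test_empty_directory(self, tmp_path):
        tree = scan_dicom_tree(tmp_path)
        assert tree.studies == [] and tree.n_instances == 0

    def test_counts_match_construction(self, tmp_path, rng):
        self._build_tree(tmp_path, rng)
        tree = scan_dicom_tree(tmp_path, use_cache=False)
        assert len(tree.studies) == 2
        assert all(len(st.series) == 3 for st in tree.studies)
        assert tree.n_instances == 2 * 3 * 4
        hits = tree.find_series(description_contains="fid_1_2")
        assert len(hits) == 1 and len(hits[0].instances) == 4
        # instances ordered by instance number
        nums = [i.instance_number for i in hits[0].instances]
        assert nums == sorted(nums)

    def test_warm_rescan_identical(self, tmp_path, rng):
        self._build_tree(tmp_path, rng, n_studies=1, n_series=2, n_instances=3)
        cold = scan_dicom_tree(tmp_path, use_cache=True)
        warm = scan_dicom_tree(tmp_path, use_cache=True)
        assert warm == cold

    def test_corrupt_cache_rebuilt(self, tmp_path, rng):
        self._build_tree(tmp_path, rng, n_studies=1, n_series=1, n_instances=2)
        cold = scan_dicom_tree(tmp_path, use_cache=True)
        _cache_path(str(tmp_path)).write_text("{ not json")
        again = scan_dicom_tree(tmp_path, use_cache=True)
        assert again == cold

    def test_non_dicom_files_skipped(self, tmp_path, rng):
        (tmp_path / "notes.txt").write_text("not dicom")
        write_synthetic_dicom(tmp_path / "a.dcm", random_fid(rng, n=16))
        tree = scan_dicom_tree(tmp_path, use_cache=False)
        assert tree.n_instances == 1

    def test_dicomdir_references_followed(self, tmp_path, rng):
        from pydicom.fileset import FileSet
        import pydicom
        src = tmp_path / "src"
        src.mkdir()
        write_synthetic_localizer(src / "im1.dcm", instance_number=1)
        write_synthetic_localizer(src / "im2.dcm", instance_number=2)
        fs = FileSet()
        for p in sorted(src.glob("*.dcm")):
            fs.add(pydicom.dcmread(p))
        out = tmp_path / "fileset"
        fs.write(out)
        tree = scan_dicom_tree(out, use_cache=False)
        assert tree.n_instances == 2


class TestGeometry:
    def test_origin_voxel(self, rng):
        grid = random_grid(rng, dims=(2, 2, 1))
        np.testing.assert_array_equal(voxel_to_patient(grid, (0, 0, 0)),
                                      grid.geometry.position)

    def test_unit_steps_follow_axes(self, rng):
        grid = random_grid(rng, dims=(3, 3, 2))
        g = grid.geometry
        step_i = voxel_to_patient(grid, (1, 0, 0)) - voxel_to_patient(grid, (0, 0, 0))
        np.testing.assert_allclose(step_i, g.voxel_size[0] * g.row_dir,
                                   atol=1e-12)

    def test_matches_homogeneous_matrix_oracle(self, rng):
        # random orthonormal frame via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        geometry = CsiGeometry(position=rng.normal(size=3) * 50,
                               row_dir=q[:, 0], col_dir=q[:, 1],
                               slice_dir=q[:, 2],
                               voxel_size=rng.uniform(2, 15, 3))
        fids = [random_fid(rng, n=8) for _ in range(2 * 3 * 4)]
        grid = CsiGrid(dims=(2, 3, 4), fids=fids, geometry=geometry)
        m = geometry.affine
        for index in grid.indices():
            oracle = (m @ np.array([*index, 1.0]))[:3]
            np.testing.assert_allclose(voxel_to_patient(grid, index), oracle,
                                       atol=1e-9)

    def test_lattice_spacing_constant(self, rng):
        grid = random_grid(rng, dims=(4, 4, 1))
        pts = np.array([voxel_to_patient(grid, idx) for idx in grid.indices()])
        pts = pts.reshape(1, 4, 4, 3)  # (k, j, i, xyz) in flat order
        di = np.diff(pts, axis=2).reshape(-1, 3)
        assert np.ptp(np.linalg.norm(di, axis=1)) < 1e-9

    def test_out_of_range_index(self, rng):
        grid = random_grid(rng, dims=(2, 2, 1))
        with pytest.raises(ValidationError):
            voxel_to_patient(grid, (2, 0, 0))

    def test_non_orthonormal_rejected(self):
        with pytest.raises(ValidationError):
            CsiGeometry(position=[0, 0, 0], row_dir=[1, 0, 0],
                        col_dir=[1, 0, 0], slice_dir=[0, 0, 1],
                        voxel_size=[1, 1, 1])
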