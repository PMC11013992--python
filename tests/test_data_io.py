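import numpy as np
import pytest

from dfsnet.data_io import (
    ClassMap,
    ParseError,
    PointCloud,
    ValidationError,
    normalize_scene,
    read_manifest,
    read_ply,
    read_xyzl,
    split_scenes,
    subsample,
    write_manifest,
    write_xyzl,
)


class TestReadWrite:
    def test_labeled_parse(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 0 0 1\n1 2 3 4\n")
        cloud = read_xyzl(p)
        assert cloud.n_points == 2
        assert cloud.labels.tolist() == [1, 4]

    def test_unlabeled_parse(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0.5 0.5 0.5\n")
        cloud = read_xyzl(p, has_labels=False)
        assert cloud.n_points == 1 and not cloud.has_labels

    def test_comma_delimited(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("1.0,2.0,3.0,2\n")
        assert read_xyzl(p).labels.tolist() == [2]

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 0 0 1\n0 0\n")
        with pytest.raises(ParseError, match=":2"):
            read_xyzl(p)

    def test_non_integer_label_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("0 0 0 1.5\n")
        with pytest.raises(ValidationError):
            read_xyzl(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "s.txt"
        p.write_text("\n\n")
        with pytest.raises(ValidationError):
            read_xyzl(p)

    def test_single_point_formatting(self, tmp_path):
        cloud = PointCloud(coords=[[0, 0, 0]], labels=[0])
        path = write_xyzl(cloud, tmp_path / "one.txt")
        assert path.read_text() == "0.000000 0.000000 0.000000 0\n"

    def test_unlabeled_writes_three_columns(self, tmp_path):
        cloud = PointCloud(coords=[[1, 2, 3]])
        path = write_xyzl(cloud, tmp_path / "u.txt")
        assert len(path.read_text().split()) == 3

    def test_round_trip_many_random_clouds(self, tmp_path, rng):
        for i in range(100):
            n = int(rng.integers(1, 30))
            cloud = PointCloud(
                coords=rng.uniform(-50, 50, (n, 3)),
                labels=rng.integers(0, 8, n),
            )
            back = read_xyzl(write_xyzl(cloud, tmp_path / f"{i}.txt"))
            assert np.allclose(back.coords, cloud.coords, atol=5e-7)
            assert np.array_equal(back.labels, cloud.labels)


class TestPointCloudInvariants:
    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            PointCloud(coords=np.zeros((0, 3)))

    def test_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            PointCloud(coords=[[0, 0, np.nan]])

    def test_rejects_label_length_mismatch(self):
        with pytest.raises(ValidationError):
            PointCloud(coords=[[0, 0, 0]], labels=[1, 2])

    def test_label_range_checked_against_class_map(self):
        cloud = PointCloud(coords=[[0, 0, 0]], labels=[7])
        cloud.validate_labels(ClassMap.complex())
        with pytest.raises(ValidationError):
            cloud.validate_labels(ClassMap.simple())


class TestClassMap:
    @pytest.mark.parametrize(
        "name,C", [("complex", 8), ("simple", 5), ("minimal", 3)]
    )
    def test_taxonomy_sizes(self, name, C):
        cm = ClassMap.from_name(name)
        assert cm.n_classes == C
        assert sorted(cm.mapping) == list(range(C))

    def test_bidirectional(self):
        cm = ClassMap.complex()
        assert cm.name_of(4) == "grounds"
        assert cm.value_of("grounds") == 4

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValidationError):
            ClassMap({0: "a", 2: "b"})


class TestNormalize:
    def test_min_corner_to_origin(self):
        out = normalize_scene(PointCloud(coords=[[1, 2, 3], [4, 5, 6]]))
        assert np.allclose(out.coords, [[0, 0, 0], [3, 3, 3]])

    def test_idempotent(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(20, 3)))
        once = normalize_scene(cloud)
        twice = normalize_scene(once)
        assert np.array_equal(once.coords, twice.coords)

    def test_isometry_on_random_clouds(self, rng):
        for _ in range(50):
            coords = rng.normal(0, 10, (int(rng.integers(2, 40)), 3))
            out = normalize_scene(PointCloud(coords=coords))
            assert np.allclose(out.coords.min(axis=0), 0, atol=1e-12)
            d_in = np.linalg.norm(coords[:, None] - coords[None], axis=2)
            d_out = np.linalg.norm(
                out.coords[:, None] - out.coords[None], axis=2
            )
            assert np.allclose(d_in, d_out, atol=1e-12)


class TestSubsample:
    def test_full_sample_is_permutation(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(10, 3)),
                           labels=rng.integers(0, 3, 10))
        out = subsample(cloud, 10, seed=3)
        order = np.lexsort(cloud.coords.T)
        order_out = np.lexsort(out.coords.T)
        assert np.allclose(cloud.coords[order], out.coords[order_out])

    def test_deterministic_per_seed(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(100, 3)))
        a = subsample(cloud, 30, seed=9)
        b = subsample(cloud, 30, seed=9)
        assert np.array_equal(a.coords, b.coords)

    def test_pads_with_replacement_when_small(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(5, 3)))
        assert subsample(cloud, 12, seed=0).n_points == 12

    def test_rejects_nonpositive(self, rng):
        cloud = PointCloud(coords=rng.normal(size=(5, 3)))
        with pytest.raises(ValidationError):
            subsample(cloud, 0, seed=0)

    def test_label_proportions_preserved(self):
        labels = np.repeat([0, 1, 2], [50_000, 30_000, 20_000])
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100_000, 3))
        cloud = PointCloud(coords=coords, labels=labels)
        for seed in range(20):
            out = subsample(cloud, 4096, seed=seed)
            frac = np.bincount(out.labels, minlength=3) / 4096
            assert np.all(np.abs(frac - [0.5, 0.3, 0.2]) < 0.05)


class TestSplitAndManifest:
    def test_split_disjoint_and_covering(self):
        scenes = [f"s{i}" for i in range(9)]
        split = split_scenes(scenes, seed=1)
        assert not set(split.train) & set(split.test)
        assert sorted(split.train + split.test) == sorted(scenes)
        assert len(split.train) == 6

    def test_manifest_round_trip(self, tmp_path):
        split = split_scenes([f"s{i}" for i in range(5)], seed=2)
        path = write_manifest(split, tmp_path / "split.txt")
        back = read_manifest(path)
        assert back.train == split.train and back.test == split.test


class TestPly:
    def _header(self, fmt, n, with_label):
        lines = [
            "ply",
            f"format {fmt} 1.0",
            f"element vertex {n}",
            "property float x",
            "property float y",
            "property float z",
        ]
        if with_label:
            lines.append("property int label")
        lines.append("end_header")
        return "\n".join(lines) + "\n"

    def test_ascii(self, tmp_path):
        p = tmp_path / "a.ply"
        p.write_text(self._header("ascii", 2, True) + "0 0 0 1\n1 2 3 4\n")
        cloud = read_ply(p)
        assert cloud.labels.tolist() == [1, 4]
        assert np.allclose(cloud.coords, [[0, 0, 0], [1, 2, 3]])

    def test_binary_little_endian(self, tmp_path, rng):
        coords = rng.uniform(-5, 5, (7, 3)).astype("<f4")
        labels = rng.integers(0, 5, 7).astype("<i4")
        rows = np.zeros(
            7, dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"), ("label", "<i4")]
        )
        rows["x"], rows["y"], rows["z"] = coords.T
        rows["label"] = labels
        p = tmp_path / "b.ply"
        with open(p, "wb") as fh:
            fh.write(self._header("binary_little_endian", 7, True).encode())
            fh.write(rows.tobytes())
        cloud = read_ply(p)
        assert np.allclose(cloud.coords, coords, atol=1e-6)
        assert np.array_equal(cloud.labels, labels)
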