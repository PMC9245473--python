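import hashlib
import zipfile

import pytest

from q2arc import archive
from q2arc.errors import (
    ChecksumManifestMissingError,
    FormatError,
    IntegrityError,
    MalformedArchiveError,
    MetadataParseError,
    ValidationError,
    VersionParseError,
)
from q2arc.fixtures import FixtureSpec, NodeSpec, generate

UUID_A = "5e2d1c3a-0000-4000-8000-0000000000aa"
UUID_B = "5e2d1c3a-0000-4000-8000-0000000000bb"


def _zip_with(path, members):
    with zipfile.ZipFile(path, "w") as zf:
        for name, payload in members:
            zf.writestr(name, payload)
    return path


class TestDetectRoot:
    def test_single_uuid_root(self, tmp_path):
        path = _zip_with(tmp_path / "a.qza", [(f"{UUID_A}/VERSION", b"x")])
        assert archive.detect_root(path) == UUID_A

    def test_two_roots_is_malformed(self, tmp_path):
        path = _zip_with(
            tmp_path / "a.qza",
            [(f"{UUID_A}/VERSION", b"x"), (f"{UUID_B}/VERSION", b"x")],
        )
        with pytest.raises(MalformedArchiveError):
            archive.detect_root(path)

    def test_non_uuid_root_is_malformed(self, tmp_path):
        path = _zip_with(tmp_path / "a.qza", [("stuff/VERSION", b"x")])
        with pytest.raises(MalformedArchiveError):
            archive.detect_root(path)

    def test_plain_text_file_is_format_error(self, tmp_path):
        path = tmp_path / "notzip.qza"
        path.write_text("hello\n")
        with pytest.raises(FormatError):
            archive.detect_root(path)

    def test_missing_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            archive.detect_root(tmp_path / "absent.qza")

    def test_parent_relative_member_rejected(self, tmp_path):
        path = _zip_with(
            tmp_path / "a.qza",
            [(f"{UUID_A}/VERSION", b"x"), (f"{UUID_A}/../escape", b"x")],
        )
        with pytest.raises(MalformedArchiveError):
            archive.detect_root(path)


class TestReadVersion:
    def test_archive_5(self):
        info = archive.read_version("QIIME 2\narchive: 5\nframework: 2020.8.0\n")
        assert info == archive.VersionInfo("QIIME 2", 5, "2020.8.0")

    def test_archive_4(self):
        info = archive.read_version("QIIME 2\narchive: 4\nframework: 2019.10.0\n")
        assert info.archive_version == 4

    def test_non_integer_archive(self):
        with pytest.raises(VersionParseError) as excinfo:
            archive.read_version("QIIME 2\narchive: five\nframework: x\n")
        assert "five" in str(excinfo.value.line)

    def test_too_few_lines(self):
        with pytest.raises(VersionParseError):
            archive.read_version("QIIME 2\n")

    def test_version_below_one_rejected(self):
        with pytest.raises(ValidationError):
            archive.VersionInfo("QIIME 2", 0, "x")


class TestReadMetadata:
    def test_regular(self):
        meta = archive.read_metadata(
            f"uuid: {UUID_A}\ntype: FeatureData[Sequence]\n"
            "format: DNASequencesDirectoryFormat\n"
        )
        assert meta.uuid == UUID_A
        assert meta.semantic_type == "FeatureData[Sequence]"
        assert meta.data_format == "DNASequencesDirectoryFormat"

    def test_null_format_maps_to_none(self):
        meta = archive.read_metadata(
            f"uuid: {UUID_A}\ntype: Visualization\nformat: null\n"
        )
        assert meta.data_format is None

    @pytest.mark.parametrize("missing", ["uuid", "type", "format"])
    def test_missing_key_named_in_error(self, missing):
        doc = {"uuid": UUID_A, "type": "X", "format": "Y"}
        del doc[missing]
        text = "\n".join(f"{k}: {v}" for k, v in doc.items())
        with pytest.raises(MetadataParseError) as excinfo:
            archive.read_metadata(text)
        assert excinfo.value.key == missing

    def test_bad_uuid_is_validation_error(self):
        with pytest.raises(ValidationError):
            archive.read_metadata("uuid: not-a-uuid\ntype: X\nformat: Y\n")


class TestLoadArtifact:
    def test_single_file_fixture(self, suite):
        record = suite["rep-seqs.qza"]
        info = archive.load_artifact(record.artifact_path)
        assert info.kind == "regular"
        assert info.data_entries == ["dna-sequences.fasta"]
        assert info.uuid == record.focal_uuid
        assert info.has_provenance

    def test_visualization_fixture(self, suite):
        info = archive.load_artifact(suite["table-summary.qzv"].artifact_path)
        assert info.kind == "visualization"
        assert info.metadata.data_format is None
        assert info.data_entries == ["css/style.css", "index.html"]

    def test_data_entries_lexicographic(self, suite):
        info = archive.load_artifact(suite["demux.qza"].artifact_path)
        assert info.data_entries == sorted(info.data_entries)
        assert len(info.data_entries) == 4

    def test_uuid_mismatch_is_integrity_error(self, suite):
        with pytest.raises(IntegrityError):
            archive.load_artifact(suite["corrupt-uuidmismatch.qza"].artifact_path)

    def test_truncated_version(self, suite):
        with pytest.raises(VersionParseError):
            archive.load_artifact(suite["corrupt-version.qza"].artifact_path)

    def test_missing_metadata_is_malformed(self, tmp_path):
        path = _zip_with(
            tmp_path / "a.qza",
            [
                (f"{UUID_A}/VERSION", b"QIIME 2\narchive: 4\nframework: x\n"),
                (f"{UUID_A}/data/f.txt", b"x"),
            ],
        )
        with pytest.raises(MalformedArchiveError):
            archive.load_artifact(path)

    def test_idempotent_loading(self, suite):
        path = suite["rep-seqs.qza"].artifact_path
        first, second = archive.load_artifact(path), archive.load_artifact(path)
        assert first == second

    def test_visualization_type_wins_over_extension(self, tmp_path):
        spec = FixtureSpec(
            seed=7,
            chain=[
                NodeSpec(
                    semantic_type="Visualization",
                    data_format=None,
                    payloads=[("index.html", b"<html></html>")],
                )
            ],
        )
        record = generate(spec, tmp_path / "mislabeled.qza")
        info = archive.load_artifact(record.artifact_path)
        assert info.kind == "visualization"
        assert info.warnings

    def test_manifest_required_at_version_5(self, tmp_path):
        path = _zip_with(
            tmp_path / "a.qza",
            [
                (f"{UUID_A}/VERSION", b"QIIME 2\narchive: 5\nframework: x\n"),
                (
                    f"{UUID_A}/metadata.yaml",
                    f"uuid: {UUID_A}\ntype: X\nformat: Y\n".encode(),
                ),
                (f"{UUID_A}/data/f.txt", b"x"),
            ],
        )
        with pytest.raises(MalformedArchiveError):
            archive.load_artifact(path)

    def test_manifest_optional_below_version_5(self, tmp_path):
        path = _zip_with(
            tmp_path / "a.qza",
            [
                (f"{UUID_A}/VERSION", b"QIIME 2\narchive: 4\nframework: x\n"),
                (
                    f"{UUID_A}/metadata.yaml",
                    f"uuid: {UUID_A}\ntype: X\nformat: Y\n".encode(),
                ),
                (f"{UUID_A}/data/f.txt", b"x"),
            ],
        )
        info = archive.load_artifact(path)
        assert info.checksum_manifest is None


class TestVerifyChecksums:
    def test_untampered_fixture_is_clean(self, suite):
        info = archive.load_artifact(suite["rep-seqs.qza"].artifact_path)
        assert archive.verify_checksums(info) == []

    def test_flipped_byte_yields_one_mismatch(self, suite):
        info = archive.load_artifact(suite["corrupt-flipped.qza"].artifact_path)
        mismatches = archive.verify_checksums(info)
        assert len(mismatches) == 1
        rel, expected, observed = mismatches[0]
        assert rel == "data/dna-sequences.fasta"
        # independent digest oracle: recompute md5 of the tampered member
        with zipfile.ZipFile(info.source_path) as zf:
            raw = zf.read(f"{info.uuid}/{rel}")
        assert observed == hashlib.md5(raw).hexdigest()
        assert expected != observed

    def test_empty_payload_digest(self, tmp_path):
        record = generate(
            FixtureSpec(
                seed=3,
                chain=[
                    NodeSpec(
                        semantic_type="X[Y]",
                        data_format="F",
                        payloads=[("empty.txt", b"")],
                    )
                ],
            ),
            tmp_path / "empty.qza",
        )
        info = archive.load_artifact(record.artifact_path)
        # md5 of zero bytes, the classic constant
        assert (
            info.checksum_manifest["data/empty.txt"]
            == "d41d8cd98f00b204e9800998ecf8427e"
        )
        assert archive.verify_checksums(info) == []

    def test_absent_manifest_is_distinct_error(self, tmp_path):
        record = generate(
            FixtureSpec(
                seed=4,
                archive_version=4,
                chain=[
                    NodeSpec(
                        semantic_type="X[Y]",
                        data_format="F",
                        payloads=[("f.txt", b"x")],
                    )
                ],
            ),
            tmp_path / "v4.qza",
        )
        info = archive.load_artifact(record.artifact_path)
        with pytest.raises(ChecksumManifestMissingError):
            archive.verify_checksums(info)


def test_round_trip_all_good_fixtures(good_records):
    for record in good_records:
        info = archive.load_artifact(record.artifact_path)
        assert info.uuid == record.focal_uuid
        assert info.metadata.semantic_type == record.semantic_type
        assert info.metadata.data_format == record.data_format
        assert info.version.archive_version == record.archive_version
        assert info.kind == record.kind
        assert archive.verify_checksums(info) == []


def test_payload_digests_match_record(good_records):
    for record in good_records:
        info = archive.load_artifact(record.artifact_path)
        for rel, digest in record.payload_md5.items():
            assert info.checksum_manifest[f"data/{rel}"] == digest


def test_list_ancestor_uuids(suite):
    record = suite["taxonomy.qza"]
    assert archive.list_ancestor_uuids(record.artifact_path) == sorted(
        record.ancestor_uuids
    )
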