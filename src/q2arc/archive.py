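"""Core reader for Qiime2 artifact archives (.qza / .qzv).

An artifact is a ZIP archive with a single top-level directory named by the
artifact's UUID. Under that root live ``VERSION``, ``metadata.yaml``, a
``data/`` payload tree, optionally a ``provenance/`` tree, and (for archive
version >= 5) a ``checksums.md5`` manifest in ``md5sum`` line format.

This module validates the layout and exposes the metadata without touching
payload bytes: listing N artifacts reads only the ZIP central directory and
the small metadata members, which is what makes batch listing fast.
"""

from __future__ import annotations

import hashlib
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .errors import (
    ChecksumManifestMissingError,
    FormatError,
    IntegrityError,
    MalformedArchiveError,
    MetadataParseError,
    ValidationError,
    VersionParseError,
)

UUID_RE = re.compile(
    r"^[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
)

#: archive versions this reader accepts; the manifest became part of the
#: layout at version 5 and is required from there on.
MIN_ARCHIVE_VERSION = 2
MANIFEST_REQUIRED_FROM = 5


def is_valid_uuid(text: str) -> bool:
    """Syntactic 8-4-4-4-12 lowercase-hex check; the version nibble is not
    enforced so that archives from any producer are accepted."""
    return bool(UUID_RE.match(text))


@dataclass(frozen=True)
class VersionInfo:
    """Parsed content of the VERSION member."""

    framework_name: str
    archive_version: int
    framework_version: str

    def __post_init__(self) -> None:
        if self.archive_version < 1:
            raise ValidationError(
                f"archive version must be >= 1, got {self.archive_version}"
            )
        if not self.framework_version:
            raise ValidationError("framework version must be non-empty")


@dataclass(frozen=True)
class ArtifactMetadata:
    """The identity triple from metadata.yaml.

    ``data_format`` is ``None`` exactly when the file records a null
    format, which is the convention for visualization artifacts.
    """

    uuid: str
    semantic_type: str
    data_format: Optional[str] = None

    def __post_init__(self) -> None:
        if not is_valid_uuid(self.uuid):
            raise ValidationError(f"not a valid UUID: {self.uuid!r}")
        if not self.semantic_type:
            raise ValidationError("semantic type must be non-empty")


@dataclass
class ArtifactInfo:
    """Everything load_artifact learns about one archive."""

    source_path: Path
    kind: str  # "regular" | "visualization"
    metadata: ArtifactMetadata
    version: VersionInfo
    data_entries: list[str]
    has_provenance: bool
    checksum_manifest: Optional[dict[str, str]] = None
    warnings: list[str] = field(default_factory=list)

    @property
    def uuid(self) -> str:
        return self.metadata.uuid


def _open_zip(archive_path: Path | str) -> zipfile.ZipFile:
    path = Path(archive_path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    if not zipfile.is_zipfile(path):
        raise FormatError(f"not a ZIP archive: {path}")
    return zipfile.ZipFile(path)


def _check_member_paths(names: list[str]) -> None:
    # hardening: absolute members or parent-dir escapes are rejected outright
    for name in names:
        if name.startswith("/") or name.startswith("\\"):
            raise MalformedArchiveError(f"absolute member path: {name!r}")
        if ".." in name.split("/"):
            raise MalformedArchiveError(f"parent-relative member path: {name!r}")


def _root_of(names: list[str], archive_path: Path | str) -> str:
    _check_member_paths(names)
    roots = {name.split("/", 1)[0] for name in names if name.strip("/")}
    if len(roots) == 0:
        raise MalformedArchiveError(f"empty archive: {archive_path}")
    if len(roots) > 1:
        raise MalformedArchiveError(
            f"multiple top-level entries {sorted(roots)} in {archive_path}"
        )
    (root,) = roots
    if not is_valid_uuid(root):
        raise MalformedArchiveError(
            f"top-level directory {root!r} is not a UUID in {archive_path}"
        )
    return root


def detect_root(archive_path: Path | str) -> str:
    """Return the single UUID-named top-level directory of the archive.

    Raises FormatError if the file is not a ZIP, MalformedArchiveError if
    there is not exactly one top-level directory or its name is not a UUID.
    """
    with _open_zip(archive_path) as zf:
        return _root_of(zf.namelist(), archive_path)


def read_version(version_text: str) -> VersionInfo:
    """Parse the 3-line VERSION member: banner, ``archive: N``,
    ``framework: V``."""
    lines = [ln for ln in version_text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise VersionParseError(
            f"VERSION needs 3 non-empty lines, got {len(lines)}",
            line=version_text,
        )
    banner = lines[0].strip()
    archive_line, framework_line = lines[1], lines[2]

    m = re.match(r"^archive:\s*(\S+)\s*$", archive_line)
    if not m:
        raise VersionParseError(
            f"bad archive line: {archive_line!r}", line=archive_line
        )
    try:
        archive_version = int(m.group(1))
    except ValueError:
        raise VersionParseError(
            f"archive version is not an integer: {archive_line!r}",
            line=archive_line,
        ) from None

    m = re.match(r"^framework:\s*(\S.*?)\s*$", framework_line)
    if not m:
        raise VersionParseError(
            f"bad framework line: {framework_line!r}", line=framework_line
        )
    return VersionInfo(
        framework_name=banner,
        archive_version=archive_version,
        framework_version=m.group(1),
    )


def read_metadata(metadata_text: str) -> ArtifactMetadata:
    """Parse metadata.yaml (flat mapping with uuid / type / format keys)."""
    try:
        doc = yaml.safe_load(metadata_text)
    except yaml.YAMLError as exc:
        raise MetadataParseError(f"metadata.yaml is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise MetadataParseError("metadata.yaml is not a mapping")
    for key in ("uuid", "type", "format"):
        if key not in doc:
            raise MetadataParseError(f"metadata.yaml missing key {key!r}", key=key)
    fmt = doc["format"]
    return ArtifactMetadata(
        uuid=str(doc["uuid"]),
        semantic_type=str(doc["type"]),
        data_format=None if fmt is None else str(fmt),
    )


def parse_checksum_manifest(text: str) -> dict[str, str]:
    """Parse md5sum-style lines ``<32 hex><two spaces><path>`` into a
    root-relative path -> digest mapping (file order preserved)."""
    manifest: dict[str, str] = {}
    for raw in text.splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        m = re.match(r"^([0-9a-fA-F]{32})[ \t][ \t*](.+)$", line)
        if not m:
            raise MalformedArchiveError(f"bad checksum line: {line!r}")
        manifest[m.group(2)] = m.group(1).lower()
    return manifest


def load_artifact(archive_path: Path | str) -> ArtifactInfo:
    """Open, validate and describe one artifact archive.

    Reads only the central directory plus VERSION, metadata.yaml and (when
    present) checksums.md5 — never the payloads.
    """
    path = Path(archive_path)
    with _open_zip(path) as zf:
        names = zf.namelist()
        root = _root_of(names, path)

        try:
            version_text = zf.read(f"{root}/VERSION").decode("utf-8")
        except KeyError:
            raise MalformedArchiveError(f"missing VERSION in {path}") from None
        version = read_version(version_text)
        if version.archive_version < MIN_ARCHIVE_VERSION:
            raise MalformedArchiveError(
                f"archive version {version.archive_version} predates the "
                f"supported floor ({MIN_ARCHIVE_VERSION}) in {path}"
            )

        try:
            metadata_text = zf.read(f"{root}/metadata.yaml").decode("utf-8")
        except KeyError:
            raise MalformedArchiveError(f"missing metadata.yaml in {path}") from None
        metadata = read_metadata(metadata_text)

        if metadata.uuid != root:
            raise IntegrityError(
                f"root directory {root} does not match metadata uuid "
                f"{metadata.uuid} in {path}"
            )

        data_prefix = f"{root}/data/"
        data_entries = sorted(
            name[len(data_prefix):]
            for name in names
            if name.startswith(data_prefix) and not name.endswith("/")
        )
        if not data_entries:
            raise MalformedArchiveError(f"no data/ payload in {path}")

        has_provenance = any(
            name.startswith(f"{root}/provenance/") for name in names
        )

        manifest: Optional[dict[str, str]] = None
        manifest_name = f"{root}/checksums.md5"
        if manifest_name in names:
            manifest = parse_checksum_manifest(
                zf.read(manifest_name).decode("utf-8")
            )
        elif version.archive_version >= MANIFEST_REQUIRED_FROM:
            raise MalformedArchiveError(
                f"archive version {version.archive_version} requires a "
                f"checksums.md5 manifest, none found in {path}"
            )

    warnings: list[str] = []
    is_viz_type = metadata.semantic_type == "Visualization"
    is_viz_ext = path.suffix.lower() == ".qzv"
    # metadata wins over the filename extension when they disagree
    kind = "visualization" if is_viz_type else "regular"
    if is_viz_type != is_viz_ext:
        warnings.append(
            f"extension {path.suffix!r} disagrees with semantic type "
            f"{metadata.semantic_type!r}; trusting the metadata"
        )

    return ArtifactInfo(
        source_path=path,
        kind=kind,
        metadata=metadata,
        version=version,
        data_entries=data_entries,
        has_provenance=has_provenance,
        checksum_manifest=manifest,
        warnings=warnings,
    )


def verify_checksums(
    artifact: ArtifactInfo,
) -> list[tuple[str, str, Optional[str]]]:
    """Recompute every manifested member's md5 and report mismatches.

    Returns a list of ``(root-relative path, expected, observed)`` tuples;
    ``observed`` is None for members missing from the archive. An empty
    list means full integrity. The manifest itself is never verified.
    """
    if artifact.checksum_manifest is None:
        raise ChecksumManifestMissingError(
            f"{artifact.source_path} carries no checksums.md5 manifest"
        )
    root = artifact.uuid
    mismatches: list[tuple[str, str, Optional[str]]] = []
    with zipfile.ZipFile(artifact.source_path) as zf:
        names = set(zf.namelist())
        for rel_path, expected in artifact.checksum_manifest.items():
            if rel_path == "checksums.md5":
                continue
            member = f"{root}/{rel_path}"
            if member not in names:
                mismatches.append((rel_path, expected, None))
                continue
            digest = hashlib.md5()
            with zf.open(member) as fh:
                for chunk in iter(lambda: fh.read(1 << 16), b""):
                    digest.update(chunk)
            observed = digest.hexdigest()
            if observed != expected:
                mismatches.append((rel_path, expected, observed))
    return mismatches


def list_ancestor_uuids(archive_path: Path | str) -> list[str]:
    """UUIDs of the directories under <root>/provenance/artifacts/,
    sorted; empty when the artifact has no recorded ancestors."""
    with _open_zip(archive_path) as zf:
        names = zf.namelist()
    root = _root_of(names, archive_path)
    prefix = f"{root}/provenance/artifacts/"
    found = {
        name[len(prefix):].split("/", 1)[0]
        for name in names
        if name.startswith(prefix) and len(name) > len(prefix)
    }
    return sorted(u for u in found if u)
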