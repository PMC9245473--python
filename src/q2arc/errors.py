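"""Exception hierarchy for archive handling.

Every failure mode has its own class so callers (and the CLI) can react to
the *kind* of problem: a file that is not a ZIP is different from a ZIP
whose layout is wrong, which is different from one whose content lies about
itself.
"""

from __future__ import annotations


class ArchiveError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ArchiveError):
    """The input is not a ZIP archive at all."""


class MalformedArchiveError(ArchiveError):
    """The ZIP does not follow the artifact layout (single UUID root,
    VERSION, metadata.yaml...)."""


class IntegrityError(ArchiveError):
    """The archive is self-contradictory (e.g. root dir != metadata uuid)."""


class VersionParseError(ArchiveError):
    """The VERSION member cannot be parsed; carries the offending line."""

    def __init__(self, message: str, line: str | None = None):
        super().__init__(message)
        self.line = line


class MetadataParseError(ArchiveError):
    """metadata.yaml is missing a required key or is not valid YAML."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class ValidationError(ArchiveError):
    """A parsed value violates its invariant (e.g. malformed UUID)."""


class ChecksumManifestMissingError(ArchiveError):
    """verify_checksums requested on an artifact without checksums.md5.

    Deliberately distinct from a verification *failure* (which is reported
    as a non-empty mismatch list, not an exception).
    """


class NoProvenanceError(ArchiveError):
    """The artifact carries no provenance/ tree."""


class ProvenanceParseError(ArchiveError):
    """An action.yaml inside the provenance tree cannot be parsed."""


class BibtexParseError(ArchiveError):
    """Unbalanced braces or truncated record; carries the byte offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class ExtractionError(ArchiveError):
    """Destination collision or refusal to overwrite during extract."""


class FixtureError(ArchiveError):
    """A fixture specification violates its own invariants."""


class CitationCollisionWarning(UserWarning):
    """Two entries share a citation key but differ in body; first kept."""
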