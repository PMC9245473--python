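"""BibTeX aggregation across artifacts.

The parser is a deliberately small brace-counting tokenizer: it splits a
``citations.bib`` stream into ``@kind{...}`` records without interpreting
fields, so arbitrary nesting (``{DADA2}`` inside a title) and exotic field
content survive a round trip byte-for-byte.
"""

from __future__ import annotations

import re
import warnings as _warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path

from .archive import load_artifact
from .errors import ArchiveError, BibtexParseError, CitationCollisionWarning

_WS_RUN = re.compile(r"\s+")


@dataclass(frozen=True)
class CitationEntry:
    """One BibTeX record.

    ``body`` is the verbatim text between the record's outer braces
    (including the key and trailing fields); ``normalized_body`` collapses
    whitespace runs so equality survives re-wrapping.
    """

    entry_kind: str
    citation_key: str
    body: str

    @property
    def normalized_body(self) -> str:
        return _WS_RUN.sub(" ", self.body).strip()

    @property
    def normalized_fields(self) -> str:
        """The body with the leading citation key stripped, whitespace
        collapsed — what dedup compares, so one reference hiding under two
        different keys is still recognized as the same entry."""
        _, _, rest = self.body.partition(",")
        return _WS_RUN.sub(" ", rest).strip()

    def serialize(self) -> str:
        return f"@{self.entry_kind}{{{self.body}}}"


def parse_bibtex(text: str) -> list[CitationEntry]:
    """Tokenize concatenated ``@kind{key, ...}`` records, in file order.

    Text outside records (comments, blank lines) is ignored. Unbalanced
    braces raise BibtexParseError carrying the byte offset of the record
    that never closed.
    """
    entries: list[CitationEntry] = []
    i = 0
    n = len(text)
    while i < n:
        at = text.find("@", i)
        if at == -1:
            break
        m = re.match(r"@\s*([A-Za-z]+)\s*\{", text[at:])
        if not m:
            i = at + 1
            continue
        kind = m.group(1).lower()
        body_start = at + m.end()  # just past the opening brace
        depth = 1
        j = body_start
        while j < n and depth > 0:
            ch = text[j]
            if ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
            j += 1
        if depth != 0:
            raise BibtexParseError(
                f"unbalanced braces in record starting at byte {at}", offset=at
            )
        body = text[body_start : j - 1]
        key = body.split(",", 1)[0].strip()
        if not key:
            raise BibtexParseError(
                f"empty citation key in record at byte {at}", offset=at
            )
        entries.append(CitationEntry(entry_kind=kind, citation_key=key, body=body))
        i = j
    return entries


def serialize(entries: list[CitationEntry]) -> str:
    """Concatenate records with a blank line between them; bodies are
    emitted untouched, never re-wrapped."""
    return "\n\n".join(entry.serialize() for entry in entries) + (
        "\n" if entries else ""
    )


def dedup(entries: list[CitationEntry]) -> list[CitationEntry]:
    """Drop later duplicates, keeping first-occurrence order.

    Two entries are duplicates when they share a citation key OR an equal
    normalized body (the same reference can hide under different keys).
    A key collision with a *different* body keeps the first entry and
    emits a CitationCollisionWarning. Idempotent by construction.
    """
    kept: list[CitationEntry] = []
    seen_keys: dict[str, CitationEntry] = {}
    seen_bodies: set[str] = set()
    for entry in entries:
        norm = entry.normalized_fields
        if entry.citation_key in seen_keys:
            if seen_keys[entry.citation_key].normalized_fields != norm:
                _warnings.warn(
                    f"citation key {entry.citation_key!r} maps to two "
                    f"different bodies; keeping the first",
                    CitationCollisionWarning,
                    stacklevel=2,
                )
            continue
        if norm in seen_bodies:
            continue
        kept.append(entry)
        seen_keys[entry.citation_key] = entry
        seen_bodies.add(norm)
    return kept


def collect_citations(archive_path: Path | str) -> list[CitationEntry]:
    """All BibTeX entries carried by one artifact: the focal
    ``provenance/citations.bib`` plus every ancestor's copy, in member
    name order."""
    artifact = load_artifact(archive_path)
    root = artifact.uuid
    entries: list[CitationEntry] = []
    with zipfile.ZipFile(artifact.source_path) as zf:
        members = [
            name
            for name in sorted(zf.namelist())
            if name == f"{root}/provenance/citations.bib"
            or (
                name.startswith(f"{root}/provenance/artifacts/")
                and name.endswith("/citations.bib")
            )
        ]
        # focal citations first so first-occurrence order starts at the
        # artifact the user actually named
        members.sort(key=lambda n: (n != f"{root}/provenance/citations.bib", n))
        for member in members:
            entries.extend(parse_bibtex(zf.read(member).decode("utf-8")))
    return entries


@dataclass
class MergeResult:
    entries: list[CitationEntry]
    notices: list[str]
    failures: list[tuple[str, str]]  # (path, message)

    @property
    def text(self) -> str:
        return serialize(self.entries)

    @property
    def ok(self) -> bool:
        return not self.failures


def merge_citations(artifact_paths: list[Path | str]) -> MergeResult:
    """Gather and deduplicate citations across many artifacts.

    Unreadable artifacts are reported in ``failures`` and processing
    continues; an artifact with no citations anywhere yields a notice, not
    an error.
    """
    collected: list[CitationEntry] = []
    notices: list[str] = []
    failures: list[tuple[str, str]] = []
    for path in artifact_paths:
        try:
            found = collect_citations(path)
        except ArchiveError as exc:
            failures.append((str(path), str(exc)))
            continue
        if not found:
            notices.append(f"{path}: no citations recorded")
        collected.extend(found)
    return MergeResult(entries=dedup(collected), notices=notices, failures=failures)
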