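"""Copy payloads out of artifacts and stream text payloads to a console.

The renaming convention: an artifact holding a single data file is written
as ``<outdir>/<artifact stem><payload extension>`` (compound extensions
like ``.fastq.gz`` preserved whole); artifacts with several payloads — and
every visualization — get their own ``<outdir>/<artifact stem>/``
directory mirroring the ``data/`` subtree.
"""

from __future__ import annotations

import gzip
import hashlib
import shutil
import sys
import zipfile
from pathlib import Path
from typing import BinaryIO, Optional

from .archive import ArtifactInfo, load_artifact
from .errors import ExtractionError

#: bytes sniffed for NUL when deciding whether a payload is text
_SNIFF_LEN = 4096


def _artifact_stem(path: Path) -> str:
    """Artifact basename without its (single) archive extension."""
    return path.name[: -len(path.suffix)] if path.suffix else path.name


def _payload_extension(rel_path: str) -> str:
    """Everything from the first dot of the payload basename, so compound
    suffixes (.fastq.gz, .tsv) are kept intact; empty if no dot."""
    base = rel_path.rsplit("/", 1)[-1]
    dot = base.find(".")
    return base[dot:] if dot != -1 else ""


def plan_destinations(
    artifact: ArtifactInfo, output_dir: Path
) -> dict[str, Path]:
    """Deterministic mapping data-relative member -> destination path.

    Visualizations always take the directory branch; a lone data file
    (even when nested in a subdirectory) is flattened to a single renamed
    file.
    """
    stem = _artifact_stem(artifact.source_path)
    if artifact.kind != "visualization" and len(artifact.data_entries) == 1:
        entry = artifact.data_entries[0]
        return {entry: output_dir / (stem + _payload_extension(entry))}
    return {
        entry: output_dir / stem / Path(entry)
        for entry in artifact.data_entries
    }


def extract(
    artifact_paths: list[Path | str],
    output_dir: Path | str,
    force: bool = False,
) -> list[Path]:
    """Extract every artifact's payload into ``output_dir``.

    Collisions between the planned destinations of different inputs abort
    before anything is written; existing destinations are refused unless
    ``force`` is set. Returns all written paths.
    """
    out = Path(output_dir)
    artifacts = [load_artifact(p) for p in artifact_paths]

    stems = [_artifact_stem(a.source_path) for a in artifacts]
    dupes = {s for s in stems if stems.count(s) > 1}
    if dupes:
        raise ExtractionError(
            f"multiple input artifacts share the basename(s) {sorted(dupes)}"
        )

    plans = [plan_destinations(a, out) for a in artifacts]
    targets = {a.source_path: plan for a, plan in zip(artifacts, plans)}

    if not force:
        for plan in plans:
            for dest in plan.values():
                if dest.exists():
                    raise ExtractionError(
                        f"destination exists: {dest} (use force to overwrite)"
                    )
        # directory-branch artifacts also refuse an existing top directory
        for artifact, plan in zip(artifacts, plans):
            if len(plan) > 1 or artifact.kind == "visualization":
                top = out / _artifact_stem(artifact.source_path)
                if top.exists():
                    raise ExtractionError(
                        f"destination exists: {top} (use force to overwrite)"
                    )

    written: list[Path] = []
    out.mkdir(parents=True, exist_ok=True)
    for artifact, plan in zip(artifacts, plans):
        root = artifact.uuid
        with zipfile.ZipFile(artifact.source_path) as zf:
            for entry, dest in sorted(plan.items()):
                dest.parent.mkdir(parents=True, exist_ok=True)
                with zf.open(f"{root}/data/{entry}") as src, open(dest, "wb") as fh:
                    shutil.copyfileobj(src, fh)
                if artifact.checksum_manifest is not None:
                    expected = artifact.checksum_manifest.get(f"data/{entry}")
                    if expected is not None:
                        observed = hashlib.md5(dest.read_bytes()).hexdigest()
                        if observed != expected:
                            raise ExtractionError(
                                f"md5 mismatch for {dest}: wrote {observed}, "
                                f"manifest says {expected}"
                            )
                written.append(dest)
    return written


def read_member(
    artifact_path: Path | str,
    member_name: str,
    raw: bool = False,
) -> bytes:
    """Payload bytes of one data entry; ``.gz`` members are transparently
    decompressed unless ``raw``."""
    artifact = load_artifact(artifact_path)
    if member_name not in artifact.data_entries:
        raise ExtractionError(
            f"no data entry {member_name!r} in {artifact_path}; "
            f"available: {', '.join(artifact.data_entries)}"
        )
    with zipfile.ZipFile(artifact.source_path) as zf:
        payload = zf.read(f"{artifact.uuid}/data/{member_name}")
    if not raw and member_name.endswith(".gz"):
        payload = gzip.decompress(payload)
    return payload


def view(
    artifact_path: Path | str,
    member_name: Optional[str] = None,
    raw: bool = False,
    out: Optional[BinaryIO] = None,
    err=None,
) -> int:
    """Stream a text payload to ``out`` (stdout by default).

    With no member on a multi-payload artifact the entry list is printed
    and exit status 3 returned so scripts can tell "nothing streamed"
    apart from success. Binary payloads (NUL within the first 4 KiB after
    gzip normalization) are refused unless ``raw``.
    """
    out = out if out is not None else sys.stdout.buffer
    err = err if err is not None else sys.stderr
    artifact = load_artifact(artifact_path)

    if member_name is None:
        if len(artifact.data_entries) == 1:
            member_name = artifact.data_entries[0]
        else:
            for entry in artifact.data_entries:
                print(entry, file=err)
            print(
                f"{artifact_path}: {len(artifact.data_entries)} data entries; "
                "name one to stream it",
                file=err,
            )
            return 3

    payload = read_member(artifact_path, member_name, raw=raw)
    if not raw and b"\x00" in payload[:_SNIFF_LEN]:
        print(
            f"{member_name}: looks binary (NUL byte found); use raw mode",
            file=err,
        )
        return 1
    out.write(payload)
    out.flush()
    return 0
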