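"""Package a static HTML directory as a visualization artifact (.qzv).

The emitted archive follows the version-5 layout: UUID root, VERSION,
metadata.yaml (type Visualization, null format), the directory tree under
``data/``, a minimal import-style provenance record, and a checksums.md5
manifest covering every member except itself.
"""

from __future__ import annotations

import hashlib
import os
import uuid as uuid_module
import zipfile
from pathlib import Path
from typing import Optional

from . import __version__
from .archive import ArtifactInfo, load_artifact
from .bibliography import CitationEntry
from .errors import ArchiveError

ARCHIVE_VERSION = 5
DEFAULT_FRAMEWORK_VERSION = f"q2arc-{__version__}"


def self_citation() -> CitationEntry:
    """The toolkit's own BibTeX record, embedded in generated artifacts so
    the provenance tree always carries a citations.bib."""
    body = (
        "q2arc,\n"
        "  title = {q2arc: standalone toolkit for Qiime2 artifact archives},\n"
        f"  note = {{version {__version__}}},\n"
        "  howpublished = {software}\n"
    )
    return CitationEntry(entry_kind="misc", citation_key="q2arc", body=body)


def version_text(framework_version: str) -> str:
    return f"QIIME 2\narchive: {ARCHIVE_VERSION}\nframework: {framework_version}\n"


def _metadata_text(uuid: str) -> str:
    return f"uuid: {uuid}\ntype: Visualization\nformat: null\n"


def _action_text(source_name: str, note: Optional[str]) -> str:
    lines = [
        "action:",
        "    type: import",
        "    plugin: null",
        "    action: null",
        "    inputs: []",
        "    parameters:",
        f"    -   source_directory: {source_name}",
    ]
    if note:
        lines.append(f"    -   note: {note}")
    lines.append("    output-name: visualization")
    return "\n".join(lines) + "\n"


def _collect_files(html_dir: Path, include_hidden: bool) -> list[str]:
    files: list[str] = []
    for base, dirs, names in os.walk(html_dir):
        rel_base = Path(base).relative_to(html_dir)
        if not include_hidden:
            dirs[:] = [d for d in dirs if not d.startswith(".")]
            names = [n for n in names if not n.startswith(".")]
        for name in names:
            files.append(str(rel_base / name).replace(os.sep, "/"))
    return sorted(files)


def make_visualization(
    html_dir: Path | str,
    output_path: Path | str,
    framework_version: str = DEFAULT_FRAMEWORK_VERSION,
    note: Optional[str] = None,
    include_hidden: bool = False,
) -> ArtifactInfo:
    """Write ``output_path`` as a .qzv wrapping ``html_dir``.

    ``html_dir`` must contain a top-level index.html (the entry point
    viewers open by convention). The archive is written to a temporary
    file and atomically renamed, so a failure never leaves a partial
    archive behind. Returns the loaded ArtifactInfo of the new file.
    """
    src = Path(html_dir)
    dest = Path(output_path)
    if not src.is_dir():
        raise ArchiveError(f"input directory not found: {src}")
    if not (src / "index.html").is_file():
        raise ArchiveError(
            f"{src} has no top-level index.html; a visualization needs one"
        )
    if dest.suffix.lower() != ".qzv":
        import warnings

        warnings.warn(
            f"output {dest.name!r} does not end in .qzv; writing anyway",
            stacklevel=2,
        )

    root = str(uuid_module.uuid4())
    rel_files = _collect_files(src, include_hidden)

    members: list[tuple[str, bytes]] = [
        ("VERSION", version_text(framework_version).encode()),
        ("metadata.yaml", _metadata_text(root).encode()),
    ]
    for rel in rel_files:
        members.append((f"data/{rel}", (src / rel).read_bytes()))
    members.extend(
        [
            ("provenance/metadata.yaml", _metadata_text(root).encode()),
            ("provenance/VERSION", version_text(framework_version).encode()),
            ("provenance/citations.bib", self_citation().serialize().encode() + b"\n"),
            ("provenance/action/action.yaml", _action_text(src.name, note).encode()),
        ]
    )

    manifest_lines = [
        f"{hashlib.md5(payload).hexdigest()}  {rel}" for rel, payload in members
    ]
    members.append(("checksums.md5", ("\n".join(manifest_lines) + "\n").encode()))

    dest.parent.mkdir(parents=True, exist_ok=True)
    tmp = dest.with_name(dest.name + f".tmp{os.getpid()}")
    try:
        with zipfile.ZipFile(tmp, "w", zipfile.ZIP_DEFLATED) as zf:
            for rel, payload in members:
                zf.writestr(f"{root}/{rel}", payload)
        os.replace(tmp, dest)
    finally:
        if tmp.exists():
            tmp.unlink()

    return load_artifact(dest)
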