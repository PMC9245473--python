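"""Synthetic artifact generator — the test oracle for every other module.

``generate`` writes one structurally valid artifact from a declarative
chain of node specs (ancestors first, focal last) and returns a
FixtureRecord stating exactly what went into it: uuids, adjacency,
citation keys, payload digests. Tests compare module output against these
records instead of re-deriving anything from the archive.

All randomness (uuid draws) comes from a seeded generator and ZIP member
timestamps are pinned, so the same spec + seed produces byte-identical
archives.
"""

from __future__ import annotations

import gzip
import hashlib
import random
import uuid as uuid_module
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .bibliography import parse_bibtex
from .errors import FixtureError

_ZIP_DATE = (2020, 1, 1, 0, 0, 0)


@dataclass
class NodeSpec:
    """One link of an ancestry chain."""

    semantic_type: str
    data_format: Optional[str]
    action_kind: str = "import"
    plugin: Optional[str] = None
    action_name: Optional[str] = None
    #: (parameter name, index of an EARLIER chain element)
    inputs: list[tuple[str, int]] = field(default_factory=list)
    parameters: list[tuple[str, str]] = field(default_factory=list)
    #: payload files; only the focal (last) node's payloads are written
    payloads: list[tuple[str, bytes]] = field(default_factory=list)
    #: raw BibTeX text for this node's citations.bib
    citations: str = ""


@dataclass
class FixtureSpec:
    seed: int
    chain: list[NodeSpec]
    archive_version: int = 5
    framework_version: str = "2020.8.0"


@dataclass
class FixtureRecord:
    """Ground truth for one generated artifact."""

    artifact_path: Path
    focal_uuid: str
    ancestor_uuids: list[str]
    adjacency: list[tuple[str, str, str]]  # (input uuid, consumer uuid, param)
    citation_keys: dict[str, list[str]]  # uuid -> keys in that node's bib
    payload_md5: dict[str, str]  # data-relative path -> md5
    semantic_type: str = ""
    data_format: Optional[str] = None
    archive_version: int = 5
    kind: str = "regular"
    corruption: Optional[str] = None  # None for well-formed fixtures


def _seeded_uuid(rng: random.Random) -> str:
    return str(uuid_module.UUID(int=rng.getrandbits(128), version=4))


def _version_text(spec: FixtureSpec) -> str:
    return (
        f"QIIME 2\narchive: {spec.archive_version}\n"
        f"framework: {spec.framework_version}\n"
    )


def _metadata_text(uuid: str, node: NodeSpec) -> str:
    fmt = "null" if node.data_format is None else node.data_format
    return f"uuid: {uuid}\ntype: {node.semantic_type}\nformat: {fmt}\n"


def _action_text(node: NodeSpec, uuids: list[str]) -> str:
    lines = ["action:", f"    type: {node.action_kind}"]
    lines.append(f"    plugin: {node.plugin if node.plugin else 'null'}")
    lines.append(f"    action: {node.action_name if node.action_name else 'null'}")
    if node.inputs:
        lines.append("    inputs:")
        for param, idx in node.inputs:
            lines.append(f"    -   {param}: {uuids[idx]}")
    else:
        lines.append("    inputs: []")
    if node.parameters:
        lines.append("    parameters:")
        for key, value in node.parameters:
            lines.append(f"    -   {key}: {value}")
    else:
        lines.append("    parameters: []")
    return "\n".join(lines) + "\n"


def _validate(spec: FixtureSpec) -> None:
    if not spec.chain:
        raise FixtureError("chain must contain at least one node")
    for i, node in enumerate(spec.chain):
        if node.action_kind == "import" and node.inputs:
            raise FixtureError(f"node {i}: import actions take no inputs")
        for param, idx in node.inputs:
            if not (0 <= idx < i):
                raise FixtureError(
                    f"node {i}: input {param!r} references position {idx}, "
                    "which is not an earlier chain element"
                )
    if not spec.chain[-1].payloads:
        raise FixtureError("focal node must carry at least one payload")


def generate(spec: FixtureSpec, out_path: Path | str) -> FixtureRecord:
    """Write the focal artifact described by ``spec`` to ``out_path``."""
    _validate(spec)
    rng = random.Random(spec.seed)
    uuids = [_seeded_uuid(rng) for _ in spec.chain]
    focal = spec.chain[-1]
    focal_uuid = uuids[-1]
    root = focal_uuid

    members: list[tuple[str, bytes]] = [
        (f"{root}/VERSION", _version_text(spec).encode()),
        (f"{root}/metadata.yaml", _metadata_text(focal_uuid, focal).encode()),
    ]
    for rel, payload in sorted(focal.payloads):
        members.append((f"{root}/data/{rel}", payload))

    members.extend(
        [
            (f"{root}/provenance/VERSION", _version_text(spec).encode()),
            (
                f"{root}/provenance/metadata.yaml",
                _metadata_text(focal_uuid, focal).encode(),
            ),
            (
                f"{root}/provenance/action/action.yaml",
                _action_text(focal, uuids).encode(),
            ),
            (f"{root}/provenance/citations.bib", focal.citations.encode()),
        ]
    )
    for node, uuid in zip(spec.chain[:-1], uuids[:-1]):
        base = f"{root}/provenance/artifacts/{uuid}"
        members.extend(
            [
                (f"{base}/VERSION", _version_text(spec).encode()),
                (f"{base}/metadata.yaml", _metadata_text(uuid, node).encode()),
                (f"{base}/action/action.yaml", _action_text(node, uuids).encode()),
                (f"{base}/citations.bib", node.citations.encode()),
            ]
        )

    if spec.archive_version >= 5:
        lines = [
            f"{hashlib.md5(payload).hexdigest()}  {name[len(root) + 1:]}"
            for name, payload in members
        ]
        members.append(
            (f"{root}/checksums.md5", ("\n".join(lines) + "\n").encode())
        )

    _write_zip(out_path, members)

    adjacency = [
        (uuids[idx], uuids[i], param)
        for i, node in enumerate(spec.chain)
        for param, idx in node.inputs
    ]
    citation_keys = {
        uuid: [e.citation_key for e in parse_bibtex(node.citations)]
        for uuid, node in zip(uuids, spec.chain)
    }
    payload_md5 = {
        rel: hashlib.md5(payload).hexdigest() for rel, payload in focal.payloads
    }
    return FixtureRecord(
        artifact_path=Path(out_path),
        focal_uuid=focal_uuid,
        ancestor_uuids=uuids[:-1],
        adjacency=adjacency,
        citation_keys=citation_keys,
        payload_md5=payload_md5,
        semantic_type=focal.semantic_type,
        data_format=focal.data_format,
        archive_version=spec.archive_version,
        kind="visualization" if focal.semantic_type == "Visualization" else "regular",
    )


def _write_zip(out_path: Path | str, members: list[tuple[str, bytes]]) -> None:
    Path(out_path).parent.mkdir(parents=True, exist_ok=True)
    with zipfile.ZipFile(out_path, "w") as zf:
        for name, payload in members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, payload)


# ---------------------------------------------------------------------------
# canonical fixture set
# ---------------------------------------------------------------------------

_FRAMEWORK_BIB = (
    "@article{framework|q2cli,\n"
    "  title = {Reproducible, interactive, scalable and extensible "
    "microbiome data science},\n"
    "  journal = {Nature Biotechnology},\n"
    "  year = {2019}\n"
    "}\n"
)


def _plugin_bib(name: str) -> str:
    return (
        f"@article{{plugin|{name},\n"
        f"  title = {{The {{{name.upper()}}} plugin}},\n"
        "  year = {2020}\n"
        "}\n"
    )


_FASTA = b">seq1\nACGTACGTAGCTAGCTAG\n>seq2\nTTGCAGGCATCGATCGAT\n"
_TSV = b"Feature ID\tTaxon\nseq1\tk__Bacteria; p__Firmicutes\n"
_FASTQ = b"@read1\nACGTACGT\n+\nIIIIIIII\n@read2\nTTGCAGGC\n+\nIIIIIIII\n"
_HTML = b"<!doctype html>\n<html><head><title>report</title></head>\n<body><h1>Summary</h1></body></html>\n"
_CSS = b"body { font-family: sans-serif; }\n"


def _import_node(semantic_type: str, fmt: str, bib: str = "") -> NodeSpec:
    return NodeSpec(
        semantic_type=semantic_type,
        data_format=fmt,
        action_kind="import",
        citations=bib or _FRAMEWORK_BIB,
    )


def _flip_payload_byte(src: Path, dest: Path, member_suffix: str) -> str:
    """Copy ``src`` flipping one byte of the first data member matching
    ``member_suffix``; the manifest is left stale on purpose. Returns the
    data-relative path of the tampered member."""
    with zipfile.ZipFile(src) as zf:
        members = [(n, zf.read(n)) for n in zf.namelist()]
    tampered = None
    rewritten = []
    for name, payload in members:
        if tampered is None and "/data/" in name and name.endswith(member_suffix):
            payload = bytes([payload[0] ^ 0xFF]) + payload[1:]
            tampered = name.split("/data/", 1)[1]
        rewritten.append((name, payload))
    if tampered is None:
        raise FixtureError(f"no data member matching {member_suffix!r} in {src}")
    _write_zip(dest, rewritten)
    return f"data/{tampered}"


def standard_suite(out_dir: Path | str, seed: int = 2021) -> list[FixtureRecord]:
    """Emit the canonical 10-fixture test set into ``out_dir``.

    Six well-formed artifacts (import-only, single-file FASTA, multi-file
    gzip FASTQ, 3-node chain, diamond ancestry, visualization) and four
    corrupt variants (dual root, uuid mismatch, flipped payload byte,
    truncated VERSION).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[FixtureRecord] = []

    # 1. import-only regular artifact
    records.append(
        generate(
            FixtureSpec(
                seed=seed,
                chain=[
                    NodeSpec(
                        semantic_type="FeatureData[Taxonomy]",
                        data_format="TSVTaxonomyDirectoryFormat",
                        action_kind="import",
                        payloads=[("taxonomy.tsv", _TSV)],
                        citations=_FRAMEWORK_BIB,
                    )
                ],
            ),
            out / "import-only.qza",
        )
    )

    # 2. single-file artifact with one ancestor
    records.append(
        generate(
            FixtureSpec(
                seed=seed + 1,
                chain=[
                    _import_node(
                        "SampleData[SequencesWithQuality]",
                        "SingleLanePerSampleSingleEndFastqDirFmt",
                    ),
                    NodeSpec(
                        semantic_type="FeatureData[Sequence]",
                        data_format="DNASequencesDirectoryFormat",
                        action_kind="method",
                        plugin="dada2",
                        action_name="denoise_single",
                        inputs=[("demultiplexed_seqs", 0)],
                        parameters=[("trunc_len", "120")],
                        payloads=[("dna-sequences.fasta", _FASTA)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("dada2"),
                    ),
                ],
            ),
            out / "rep-seqs.qza",
        )
    )

    # 3. multi-file artifact: four gzip FASTQ payloads
    fastqs = [
        (f"sample{i}_R{r}.fastq.gz", gzip.compress(_FASTQ, mtime=0))
        for i in (1, 2)
        for r in (1, 2)
    ]
    records.append(
        generate(
            FixtureSpec(
                seed=seed + 2,
                chain=[
                    NodeSpec(
                        semantic_type="SampleData[PairedEndSequencesWithQuality]",
                        data_format="CasavaOneEightSingleLanePerSampleDirFmt",
                        action_kind="import",
                        payloads=fastqs,
                        citations=_FRAMEWORK_BIB,
                    )
                ],
            ),
            out / "demux.qza",
        )
    )

    # 4. three-node chain: import -> denoise -> classify (focal taxonomy)
    records.append(
        generate(
            FixtureSpec(
                seed=seed + 3,
                chain=[
                    _import_node(
                        "SampleData[SequencesWithQuality]",
                        "SingleLanePerSampleSingleEndFastqDirFmt",
                    ),
                    NodeSpec(
                        semantic_type="FeatureData[Sequence]",
                        data_format="DNASequencesDirectoryFormat",
                        action_kind="method",
                        plugin="dada2",
                        action_name="denoise_single",
                        inputs=[("demultiplexed_seqs", 0)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("dada2"),
                    ),
                    NodeSpec(
                        semantic_type="FeatureData[Taxonomy]",
                        data_format="TSVTaxonomyDirectoryFormat",
                        action_kind="method",
                        plugin="feature-classifier",
                        action_name="classify_sklearn",
                        inputs=[("reads", 1)],
                        payloads=[("taxonomy.tsv", _TSV)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("classifier"),
                    ),
                ],
            ),
            out / "taxonomy.qza",
        )
    )

    # 5. diamond ancestry: two branches from one import, merged into focal
    records.append(
        generate(
            FixtureSpec(
                seed=seed + 4,
                chain=[
                    _import_node(
                        "SampleData[SequencesWithQuality]",
                        "SingleLanePerSampleSingleEndFastqDirFmt",
                    ),
                    NodeSpec(
                        semantic_type="FeatureTable[Frequency]",
                        data_format="BIOMV210DirFmt",
                        action_kind="method",
                        plugin="dada2",
                        action_name="denoise_single",
                        inputs=[("demultiplexed_seqs", 0)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("dada2"),
                    ),
                    NodeSpec(
                        semantic_type="FeatureData[Sequence]",
                        data_format="DNASequencesDirectoryFormat",
                        action_kind="method",
                        plugin="deblur",
                        action_name="denoise_16S",
                        inputs=[("demultiplexed_seqs", 0)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("deblur"),
                    ),
                    NodeSpec(
                        semantic_type="FeatureTable[Frequency]",
                        data_format="BIOMV210DirFmt",
                        action_kind="method",
                        plugin="feature-table",
                        action_name="filter_seqs",
                        inputs=[("table", 1), ("data", 2)],
                        payloads=[("feature-table.biom", _TSV)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("feature-table"),
                    ),
                ],
            ),
            out / "filtered-table.qza",
        )
    )

    # 6. visualization artifact
    records.append(
        generate(
            FixtureSpec(
                seed=seed + 5,
                chain=[
                    NodeSpec(
                        semantic_type="FeatureTable[Frequency]",
                        data_format="BIOMV210DirFmt",
                        action_kind="import",
                        citations=_FRAMEWORK_BIB,
                    ),
                    NodeSpec(
                        semantic_type="Visualization",
                        data_format=None,
                        action_kind="visualizer",
                        plugin="feature-table",
                        action_name="summarize",
                        inputs=[("table", 0)],
                        payloads=[("index.html", _HTML), ("css/style.css", _CSS)],
                        citations=_FRAMEWORK_BIB + _plugin_bib("feature-table"),
                    ),
                ],
            ),
            out / "table-summary.qzv",
        )
    )

    # 7. corrupt: two top-level roots
    rng = random.Random(seed + 6)
    root_a, root_b = _seeded_uuid(rng), _seeded_uuid(rng)
    _write_zip(
        out / "corrupt-dualroot.qza",
        [
            (f"{root_a}/VERSION", b"QIIME 2\narchive: 5\nframework: x\n"),
            (f"{root_b}/VERSION", b"QIIME 2\narchive: 5\nframework: x\n"),
        ],
    )
    records.append(
        FixtureRecord(
            artifact_path=out / "corrupt-dualroot.qza",
            focal_uuid=root_a,
            ancestor_uuids=[],
            adjacency=[],
            citation_keys={},
            payload_md5={},
            corruption="dual-root",
        )
    )

    # 8. corrupt: root directory disagrees with metadata uuid
    rng = random.Random(seed + 7)
    root_c, other = _seeded_uuid(rng), _seeded_uuid(rng)
    _write_zip(
        out / "corrupt-uuidmismatch.qza",
        [
            (f"{root_c}/VERSION", b"QIIME 2\narchive: 4\nframework: 2019.10.0\n"),
            (
                f"{root_c}/metadata.yaml",
                f"uuid: {other}\ntype: FeatureData[Sequence]\n"
                f"format: DNASequencesDirectoryFormat\n".encode(),
            ),
            (f"{root_c}/data/dna-sequences.fasta", _FASTA),
        ],
    )
    records.append(
        FixtureRecord(
            artifact_path=out / "corrupt-uuidmismatch.qza",
            focal_uuid=root_c,
            ancestor_uuids=[],
            adjacency=[],
            citation_keys={},
            payload_md5={},
            corruption="uuid-mismatch",
        )
    )

    # 9. corrupt: one payload byte flipped after manifest generation
    good = generate(
        FixtureSpec(
            seed=seed + 8,
            chain=[
                NodeSpec(
                    semantic_type="FeatureData[Sequence]",
                    data_format="DNASequencesDirectoryFormat",
                    action_kind="import",
                    payloads=[("dna-sequences.fasta", _FASTA)],
                    citations=_FRAMEWORK_BIB,
                )
            ],
        ),
        out / "corrupt-flipped.qza",
    )
    tampered_member = _flip_payload_byte(
        out / "corrupt-flipped.qza", out / "corrupt-flipped.qza", ".fasta"
    )
    records.append(
        FixtureRecord(
            artifact_path=out / "corrupt-flipped.qza",
            focal_uuid=good.focal_uuid,
            ancestor_uuids=[],
            adjacency=[],
            citation_keys=good.citation_keys,
            payload_md5={tampered_member.split("/", 1)[1]: "(stale)"},
            semantic_type=good.semantic_type,
            data_format=good.data_format,
            corruption="flipped-byte",
        )
    )

    # 10. corrupt: truncated VERSION member
    rng = random.Random(seed + 9)
    root_d = _seeded_uuid(rng)
    _write_zip(
        out / "corrupt-version.qza",
        [
            (f"{root_d}/VERSION", b"QIIME 2\n"),
            (
                f"{root_d}/metadata.yaml",
                f"uuid: {root_d}\ntype: FeatureData[Taxonomy]\n"
                f"format: TSVTaxonomyDirectoryFormat\n".encode(),
            ),
            (f"{root_d}/data/taxonomy.tsv", _TSV),
        ],
    )
    records.append(
        FixtureRecord(
            artifact_path=out / "corrupt-version.qza",
            focal_uuid=root_d,
            ancestor_uuids=[],
            adjacency=[],
            citation_keys={},
            payload_md5={},
            corruption="truncated-version",
        )
    )

    return records
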