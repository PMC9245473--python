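"""Reconstruct the ancestry DAG recorded inside an artifact.

Each ancestor directory under ``<root>/provenance/artifacts/<uuid>/``
carries its own ``metadata.yaml`` and ``action/action.yaml``; the focal
artifact's own records live directly under ``<root>/provenance/``. Edges
run ancestor -> consumer (data flows forward) and are labeled with the
input parameter name.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .archive import ArtifactInfo, ArtifactMetadata, is_valid_uuid
from .errors import (
    NoProvenanceError,
    ProvenanceParseError,
    ValidationError,
)

ACTION_KINDS = ("import", "method", "visualizer", "pipeline")


@dataclass
class ActionRecord:
    """One provenance step (the ``action`` mapping of an action.yaml)."""

    action_kind: str
    plugin: Optional[str] = None
    action_name: Optional[str] = None
    inputs: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, str] = field(default_factory=dict)
    output_name: Optional[str] = None
    #: set when the recorded type was unknown and "method" was assumed
    kind_fallback: bool = False

    def __post_init__(self) -> None:
        if self.action_kind == "import" and self.inputs:
            raise ValidationError("an import action cannot have inputs")
        for name, uuid in self.inputs.items():
            if not is_valid_uuid(uuid):
                raise ValidationError(
                    f"input {name!r} carries invalid uuid {uuid!r}"
                )


@dataclass
class ProvenanceNode:
    uuid: str
    metadata: Optional[ArtifactMetadata] = None
    action: Optional[ActionRecord] = None
    is_focal: bool = False

    @property
    def is_stub(self) -> bool:
        """True for nodes synthesized from a dangling input reference."""
        return self.metadata is None


@dataclass
class ProvenanceGraph:
    """DAG keyed by uuid; edges are (source, target, input-name) triples."""

    focal_uuid: str
    nodes: dict[str, ProvenanceNode] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        focal = [n for n in self.nodes.values() if n.is_focal]
        if len(focal) != 1:
            raise ValidationError(
                f"graph must have exactly one focal node, found {len(focal)}"
            )
        for src, dst, _ in self.edges:
            if src not in self.nodes or dst not in self.nodes:
                raise ValidationError(f"edge ({src}, {dst}) references unknown node")
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        """Kahn's algorithm; ties broken by uuid so output is stable."""
        indegree = {u: 0 for u in self.nodes}
        successors: dict[str, list[str]] = {u: [] for u in self.nodes}
        for src, dst, _ in self.edges:
            indegree[dst] += 1
            successors[src].append(dst)
        ready = sorted(u for u, d in indegree.items() if d == 0)
        order: list[str] = []
        while ready:
            node = ready.pop(0)
            order.append(node)
            changed = False
            for nxt in successors[node]:
                indegree[nxt] -= 1
                if indegree[nxt] == 0:
                    ready.append(nxt)
                    changed = True
            if changed:
                ready.sort()
        if len(order) != len(self.nodes):
            raise ValidationError("provenance graph contains a cycle")
        return order


def parse_action(action_text: str) -> ActionRecord:
    """Parse one action.yaml document into an ActionRecord.

    The ``inputs`` and ``parameters`` sections are serialized by Qiime2 as
    lists of single-pair mappings; file order is preserved. Unknown action
    types are tolerated: the record falls back to "method" with
    ``kind_fallback`` set, so truncated or future archives still load.
    """
    try:
        doc = yaml.safe_load(action_text)
    except yaml.YAMLError as exc:
        raise ProvenanceParseError(f"action.yaml is not valid YAML: {exc}") from exc
    if not isinstance(doc, dict) or not isinstance(doc.get("action"), dict):
        raise ProvenanceParseError("action.yaml lacks a top-level 'action' mapping")
    action = doc["action"]

    raw_kind = str(action.get("type", "method"))
    kind_fallback = raw_kind not in ACTION_KINDS
    kind = "method" if kind_fallback else raw_kind

    def _pairs(section: object) -> dict[str, str]:
        out: dict[str, str] = {}
        if section is None:
            return out
        if isinstance(section, dict):
            items = list(section.items())
        elif isinstance(section, list):
            items = []
            for elem in section:
                if not isinstance(elem, dict) or len(elem) != 1:
                    raise ProvenanceParseError(
                        f"expected single-pair mapping, got {elem!r}"
                    )
                items.extend(elem.items())
        else:
            raise ProvenanceParseError(f"unparsable section: {section!r}")
        for key, value in items:
            out[str(key)] = "" if value is None else str(value)
        return out

    return ActionRecord(
        action_kind=kind,
        plugin=None if action.get("plugin") is None else str(action["plugin"]),
        action_name=None if action.get("action") is None else str(action["action"]),
        inputs=_pairs(action.get("inputs")),
        parameters=_pairs(action.get("parameters")),
        output_name=(
            None if action.get("output-name") is None else str(action["output-name"])
        ),
        kind_fallback=kind_fallback,
    )


def _read_node(
    zf: zipfile.ZipFile,
    names: set[str],
    uuid: str,
    base: str,
    is_focal: bool,
) -> ProvenanceNode:
    from .archive import read_metadata  # local import avoids cycle at module load

    metadata = None
    meta_member = f"{base}/metadata.yaml"
    if meta_member in names:
        metadata = read_metadata(zf.read(meta_member).decode("utf-8"))
    action = None
    action_member = f"{base}/action/action.yaml"
    if action_member in names:
        action = parse_action(zf.read(action_member).decode("utf-8"))
    return ProvenanceNode(uuid=uuid, metadata=metadata, action=action, is_focal=is_focal)


def build_graph(artifact: ArtifactInfo, archive_path: Path | str | None = None) -> ProvenanceGraph:
    """Build the full ancestry DAG of ``artifact``.

    Dangling input references (an input uuid with no matching ancestor
    directory) become stub nodes plus a warning rather than a failure, so
    truncated real-world archives still produce a useful listing.
    """
    if not artifact.has_provenance:
        raise NoProvenanceError(
            f"{artifact.source_path} carries no provenance tree"
        )
    path = Path(archive_path) if archive_path is not None else artifact.source_path
    root = artifact.uuid
    graph = ProvenanceGraph(focal_uuid=root)

    with zipfile.ZipFile(path) as zf:
        names = set(zf.namelist())

        focal = _read_node(zf, names, root, f"{root}/provenance", is_focal=True)
        if focal.metadata is None:
            focal.metadata = artifact.metadata
        graph.nodes[root] = focal

        prefix = f"{root}/provenance/artifacts/"
        ancestor_uuids = sorted(
            {
                n[len(prefix):].split("/", 1)[0]
                for n in names
                if n.startswith(prefix) and len(n) > len(prefix)
            }
        )
        for anc in ancestor_uuids:
            graph.nodes[anc] = _read_node(
                zf, names, anc, f"{prefix}{anc}", is_focal=False
            )

    for node in list(graph.nodes.values()):
        if node.action is None:
            continue
        for input_name, input_uuid in node.action.inputs.items():
            if input_uuid not in graph.nodes:
                graph.nodes[input_uuid] = ProvenanceNode(uuid=input_uuid)
                graph.warnings.append(
                    f"input {input_name!r} of {node.uuid} references "
                    f"{input_uuid} which has no ancestor record; stub created"
                )
            graph.edges.add((input_uuid, node.uuid, input_name))

    graph.validate()
    return graph


def _describe(node: ProvenanceNode, verbose: bool) -> list[str]:
    meta = node.metadata
    fields = [
        node.uuid,
        meta.semantic_type if meta else "?",
        (meta.data_format or "-") if meta else "-",
    ]
    if node.action is not None:
        kind = node.action.action_kind
        if node.action.plugin and node.action.action_name:
            kind += f" {node.action.plugin}:{node.action.action_name}"
        elif node.action.action_name:
            kind += f" {node.action.action_name}"
        fields.append(kind)
    else:
        fields.append("-")
    if verbose and node.action is not None and node.action.parameters:
        params = ",".join(f"{k}={v}" for k, v in node.action.parameters.items())
        fields.append(params)
    return fields


def render_listing(graph: ProvenanceGraph, verbose: bool = False) -> str:
    """One tab-separated line per node, ancestors first (topological order,
    uuid tie-break); the focal node is marked with a trailing ``*``."""
    lines = []
    for uuid in graph.topological_order():
        node = graph.nodes[uuid]
        fields = _describe(node, verbose)
        if node.is_focal:
            fields.append("*")
        lines.append("\t".join(fields))
    return "\n".join(lines) + "\n"


def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(graph: ProvenanceGraph) -> str:
    """Emit the graph as deterministic Graphviz DOT text.

    Node labels show the semantic type over the first 8 uuid characters;
    the full uuid travels in the tooltip. The focal node is drawn with a
    double outline and fill so it stands out in the rendered figure.
    """
    order = graph.topological_order()
    lines = ["digraph provenance {", "  rankdir=TB;", '  node [shape=box, fontname="Helvetica"];']
    for uuid in order:
        node = graph.nodes[uuid]
        type_label = node.metadata.semantic_type if node.metadata else "unknown"
        label = f"{type_label}\\n{uuid[:8]}"
        attrs = [f"label={_dot_quote(label)}", f"tooltip={_dot_quote(uuid)}"]
        if node.is_focal:
            attrs.append("peripheries=2")
            attrs.append("style=filled")
            attrs.append('fillcolor="#dceefb"')
        lines.append(f"  {_dot_quote(uuid)} [{', '.join(attrs)}];")
    for src, dst, name in sorted(graph.edges):
        lines.append(
            f"  {_dot_quote(src)} -> {_dot_quote(dst)} [label={_dot_quote(name)}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
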