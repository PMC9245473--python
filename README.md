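# q2arc

Read, summarize, extract and create Qiime2 artifact archives (`.qza` /
`.qzv`) **without a Qiime2 installation**.

Qiime2 artifacts are ZIP archives with a single UUID-named root directory
holding the data payload (`data/`), identity metadata (`metadata.yaml`,
`VERSION`), an embedded provenance tree recording every ancestor artifact
and action, per-step BibTeX citations, and (archive version ≥ 5) an
md5 checksum manifest. `q2arc` parses all of that with nothing but the
Python standard library, PyYAML and click.

## CLI

One command, six subcommands:

```sh
q2arc list [--all|-a] [--basename] [--checksums] FILE...   # TSV summary per artifact
q2arc extract [--outdir DIR] [--force] FILE...             # copy payloads out, renamed
q2arc cite [--output FILE] FILE...                         # merged, deduplicated BibTeX
q2arc provenance [--dot FILE] [--pdf FILE] [-v] FILE       # ancestry listing / DOT graph
q2arc view FILE [MEMBER] [--raw]                           # stream a text payload
q2arc make --input DIR --output FILE.qzv                   # package an HTML dir as a .qzv
```

Notes on behavior:

- `list` emits strict TSV (header + one row per artifact: file, uuid,
  type, format). Unreadable files go to stderr; processing continues and
  the final exit status is non-zero.
- `extract` renames a single-payload artifact to
  `<artifact-stem><payload extension>` (compound suffixes like
  `.fastq.gz` kept whole); multi-payload artifacts and all visualizations
  get a `<artifact-stem>/` directory mirroring `data/`. Existing
  destinations are refused without `--force`.
- `cite` gathers `citations.bib` from the focal artifact *and* every
  recorded ancestor, dropping duplicates (same key, or same fields under
  a different key); first-occurrence order is preserved.
- `provenance` prints ancestors before descendants (topological order,
  uuid tie-break) and can save the DAG as deterministic Graphviz DOT;
  `--pdf` shells out to `dot` when it is installed and degrades with a
  message otherwise.
- `view` streams the single payload directly, transparently gunzipping
  `.gz` members; with several payloads it lists them and exits with
  status 3. Binary content is refused unless `--raw`.
- `make` requires a top-level `index.html`, writes an archive-version-5
  `.qzv` with a fresh uuid4 root, a minimal import-style provenance
  record and a full checksum manifest, atomically.

Supported archive versions: ≥ 2; `checksums.md5` is optional below
version 5 and required from 5 on.

## Library

```python
from q2arc import load_artifact, verify_checksums, build_graph, to_dot

info = load_artifact("rep-seqs.qza")
print(info.uuid, info.metadata.semantic_type, info.data_entries)
assert verify_checksums(info) == []
print(to_dot(build_graph(info)))
```

`q2arc.fixtures` generates structurally valid synthetic artifacts (with a
ground-truth record of uuids, ancestry adjacency, citation keys and
payload digests) and backs the whole test suite; it is also reachable as
the hidden `q2arc fixtures` subcommand for demos.

## Tests

```sh
python -m pytest -q tests/
```

The suite is hermetic: every artifact it reads is generated on the fly,
no network and no Qiime2 required.

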