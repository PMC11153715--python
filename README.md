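# kgradiate

Radiate analysis and tracing over pathway property graphs: a small,
tested toolkit for mining Reactome-style knowledge graphs.

* **Graph core** — a directed multigraph of typed nodes (entities,
  reactions, pathways) and typed edges, read/written as node/edge TSV
  tables or GraphML. Preprocessing prunes bibliographic labels
  (Person/Affiliation/Taxon), keeps a single species, reverses or adds
  selected edge types, and flags currency metabolites (ATP, H+, NAD(P)H,
  …, plus ubiquitin) so traversal views exclude them. Node lookup is
  compartment-aware (default: extracellular region).
* **Radiate analysis** — forward and reverse personalized PageRank over
  a traversal view, teleport uniform over a source set, dangling mass
  redistributed to the teleport vector, scores renormalized to sum to 1.
* **Tracing** — all minimum-hop paths, or highest-influence paths on the
  network weighted by `w(u,v) = 1/max(π(u), π(v))`; trace graphs with
  per-edge traversal counts; Sankey JSON export.
* **Enrichment** — one-sided Fisher exact (hypergeometric tail) GO
  enrichment with Benjamini–Hochberg q-values, dictionary-based entity
  annotation (leftmost-longest, token-bounded), entity clouds and
  iterative semantic expansion over enrichment tables.
* **Fixtures** — a seeded synthetic pathway-graph generator (ligand →
  reaction → ligand:receptor complex → kinase cascade → transcription
  factor, currency hubs, decoy nodes) with a ground-truth manifest, so
  the whole workflow runs without downloads.
* **Workflow** — one command orchestrating preprocess → radiate → rank →
  trace → Sankey → enrichment → entity cloud, emitting a JSON report
  that links every artifact.

## CLI

```bash
# generate a synthetic fixture bundle
kgradiate simulate --seed 42 --out fixture/

# rank nodes by personalized PageRank from a source list
kgradiate radiate --nodes fixture/nodes.tsv --edges fixture/edges.tsv \
    --sources fixture/sources.txt --direction forward --out radiate.tsv

# trace paths and export a Sankey JSON
kgradiate trace --nodes fixture/nodes.tsv --edges fixture/edges.tsv \
    --sources fixture/sources.txt --targets targets.txt \
    --mode influence --sankey sankey.json

# GO enrichment of a gene list
kgradiate enrich --genes genes.txt --annotations fixture/annotations.tsv \
    --term-names fixture/term_names.tsv --alpha 0.05 --out enrich.tsv

# entity cloud over an enrichment table
kgradiate cloud --table fixture/table.tsv --dictionary fixture/dictionary.tsv \
    --type gene --out cloud.json

# full workflow from a YAML config
kgradiate run --config workflow.yaml --out results/
```

A minimal `workflow.yaml` (paths resolved relative to the config file):

```yaml
node_table: fixture/nodes.tsv
edge_table: fixture/edges.tsv
sources_file: fixture/sources.txt
annotations: fixture/annotations.tsv
term_names: fixture/term_names.tsv
dictionary: fixture/dictionary.tsv
table: fixture/table.tsv
top_k: 10
semantic_iterations: 0
```

Exit codes for `kgradiate run`: 0 success, 2 config error, 3 stage
failure (partial outputs are retained).

## File formats

* Node TSV: `id, labels, display_name, compartments, species,
  is_currency` — `;` separates list values.
* Edge TSV: `source, target, type`.
* Annotations: headerless `gene<TAB>GO:ID`; term names: `GO:ID<TAB>name`.
* Dictionary: headerless `term<TAB>concept_id<TAB>entity_type`.
* Sankey JSON: `{"nodes": [{id, name, role}], "links": [{source_index,
  target_index, value, edge_type}]}` with indices into the nodes array.
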