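"""Seeded synthetic pathway-graph and annotation generator.

Builds small property graphs that mimic the motifs the analyses traverse:
extracellular ligand → binding reaction → ligand:receptor complex →
catalysed kinase cascade → transcription factor, plus a high-degree
ATP-like currency hub, a ubiquitin node, and non-human / bibliographic
decoy nodes that preprocessing must remove.  A ground-truth manifest
records every planted source→target chain so recovery is checkable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from kgradiate.enrichment import AnnotationSet, Dictionary, EnrichmentTable
from kgradiate.graph import EdgeRecord, NodeRecord, PropertyGraph, write_graph

HUMAN = "Homo sapiens"
EXTRACELLULAR = "extracellular region"
CYTOSOL = "cytosol"


@dataclass
class FixtureSpec:
    n_cascades: int = 6
    cascade_length: int = 3
    n_metabolites: int = 6
    currency_hub_degree: int = 4
    extra_random_edges: int = 0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "n_cascades",
            "cascade_length",
            "n_metabolites",
            "currency_hub_degree",
            "extra_random_edges",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _protein(nid: str, name: str, compartment: str = CYTOSOL) -> NodeRecord:
    return NodeRecord(
        id=nid,
        labels=frozenset({"Protein", "PhysicalEntity"}),
        display_name=name,
        compartments=(compartment,),
        species=HUMAN,
    )


def _reaction(nid: str, name: str) -> NodeRecord:
    return NodeRecord(
        id=nid,
        labels=frozenset({"Reaction", "Event"}),
        display_name=name,
        compartments=(CYTOSOL,),
        species=HUMAN,
    )


def generate_pathway_graph(spec: FixtureSpec) -> tuple[PropertyGraph, dict]:
    """Generate a synthetic pathway graph and its ground-truth manifest.

    All randomness flows through one PRNG seeded from ``spec.seed``; node
    ids are issued deterministically so repeated runs produce identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    g = PropertyGraph()
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN-HSA-{counter:06d}"

    n_metabolites = max(spec.n_metabolites, spec.n_cascades)
    metabolite_stids = [f"SYN-MET-{i:04d}" for i in range(1, n_metabolites + 1)]
    for i, stid in enumerate(metabolite_stids, start=1):
        for suffix, compartment in (("extra", EXTRACELLULAR), ("cyto", CYTOSOL)):
            g.add_node(
                NodeRecord(
                    id=f"{stid}.{suffix}",
                    labels=frozenset({"SimpleEntity", "PhysicalEntity"}),
                    display_name=f"MET{i}",
                    compartments=(compartment,),
                    species=HUMAN,
                )
            )

    chains: list[list[str]] = []
    reactions: list[str] = []
    kinases_by_cascade: list[list[str]] = []
    for i in range(1, spec.n_cascades + 1):
        ligand = f"{metabolite_stids[i - 1]}.extra"
        receptor = next_id()
        g.add_node(_protein(receptor, f"RCPT{i}", compartment="plasma membrane"))
        binding = next_id()
        g.add_node(_reaction(binding, f"binding of MET{i} to RCPT{i}"))
        complex_id = next_id()
        g.add_node(
            NodeRecord(
                id=complex_id,
                labels=frozenset({"Complex", "PhysicalEntity"}),
                display_name=f"MET{i}:RCPT{i}",
                compartments=("plasma membrane",),
                species=HUMAN,
            )
        )
        g.add_edge(EdgeRecord(ligand, binding, "input"))
        g.add_edge(EdgeRecord(receptor, binding, "input"))
        g.add_edge(EdgeRecord(binding, complex_id, "output"))
        g.add_edge(EdgeRecord(complex_id, receptor, "hasComponent"))
        reactions.append(binding)

        chain = [ligand, binding, complex_id]
        kinases: list[str] = []
        upstream = complex_id
        for j in range(1, spec.cascade_length + 1):
            rxn = next_id()
            g.add_node(_reaction(rxn, f"activation of KIN{i}_{j}"))
            kinase = next_id()
            g.add_node(_protein(kinase, f"KIN{i}_{j}"))
            g.add_edge(EdgeRecord(upstream, rxn, "catalyst"))
            g.add_edge(EdgeRecord(rxn, kinase, "output"))
            chain += [rxn, kinase]
            reactions.append(rxn)
            kinases.append(kinase)
            upstream = kinase
        tf_rxn = next_id()
        g.add_node(_reaction(tf_rxn, f"activation of TF{i}"))
        tf = next_id()
        g.add_node(_protein(tf, f"TF{i}", compartment="nucleoplasm"))
        g.add_edge(EdgeRecord(upstream, tf_rxn, "catalyst"))
        g.add_edge(EdgeRecord(tf_rxn, tf, "output"))
        chain += [tf_rxn, tf]
        reactions.append(tf_rxn)
        chains.append(chain)
        kinases_by_cascade.append(kinases)

    # ATP-like currency hub wired into reactions across cascades
    hub = None
    if spec.currency_hub_degree > 0 and reactions:
        hub = next_id()
        g.add_node(
            NodeRecord(
                id=hub,
                labels=frozenset({"SimpleEntity", "PhysicalEntity"}),
                display_name="ATP",
                compartments=(CYTOSOL,),
                species=HUMAN,
            )
        )
        # spread over cascades so the hub shortcuts otherwise-disjoint ones
        per_cascade_first = reactions[:: spec.cascade_length + 2]
        wired = (per_cascade_first + reactions)[: spec.currency_hub_degree]
        for rxn in dict.fromkeys(wired):
            g.add_edge(EdgeRecord(hub, rxn, "input"))
            g.add_edge(EdgeRecord(rxn, hub, "output"))

    ubiquitin = next_id()
    g.add_node(_protein(ubiquitin, "ubiquitin"))
    if reactions:
        g.add_edge(EdgeRecord(ubiquitin, reactions[0], "regulator"))

    # decoys that preprocessing must remove
    decoys = [
        NodeRecord(id=next_id(), labels=frozenset({"Person"}), display_name="A. Curator"),
        NodeRecord(
            id=next_id(), labels=frozenset({"Affiliation"}), display_name="Some Institute"
        ),
        NodeRecord(
            id=next_id(),
            labels=frozenset({"Taxon"}),
            display_name="Mus musculus",
        ),
        NodeRecord(
            id=next_id(),
            labels=frozenset({"Protein", "PhysicalEntity"}),
            display_name="mouse Kin1",
            compartments=(CYTOSOL,),
            species="Mus musculus",
        ),
    ]
    for node in decoys:
        g.add_node(node)
    if reactions:
        g.add_edge(EdgeRecord(decoys[0].id, reactions[0], "author"))
        g.add_edge(EdgeRecord(decoys[3].id, reactions[0], "input"))

    # optional random cross-wiring (off by default so planted paths stay unique)
    all_proteins = [k for ks in kinases_by_cascade for k in ks]
    added = 0
    attempts = 0
    while added < spec.extra_random_edges and attempts < spec.extra_random_edges * 50:
        attempts += 1
        if len(all_proteins) < 2:
            break
        u, v = rng.choice(all_proteins, size=2, replace=False)
        edge = EdgeRecord(str(u), str(v), "positivelyRegulates")
        if (edge.source, edge.target, edge.type) in g._edge_keys():
            continue
        g.add_edge(edge)
        added += 1

    decoy_ids = {d.id for d in decoys}
    manifest = {
        "spec": asdict(spec),
        "metabolite_stids": metabolite_stids,
        "source_stids": metabolite_stids[: spec.n_cascades],
        "source_nodes": [c[0] for c in chains],
        "target_nodes": [c[-1] for c in chains],
        "chains": chains,
        "kinases_by_cascade": kinases_by_cascade,
        "currency_hub": hub,
        "ubiquitin": ubiquitin,
        "decoy_nodes": sorted(decoy_ids),
        "human_node_count": sum(
            1
            for n in g.nodes.values()
            if n.id not in decoy_ids and (not n.species or n.species == HUMAN)
        ),
        "n_nodes": g.n_nodes,
        "n_edges": g.n_edges,
    }
    g.validate()
    return g, manifest


def gene_symbols(g: PropertyGraph) -> list[str]:
    """Display names of human, non-currency protein nodes (the gene universe)."""
    return sorted(
        {
            n.display_name
            for n in g.nodes.values()
            if "Protein" in n.labels
            and (not n.species or n.species == HUMAN)
            and not n.is_currency
            and n.display_name != "ubiquitin"
        }
    )


def generate_annotations(
    g: PropertyGraph, n_terms: int = 20, seed: int = 0
) -> tuple[AnnotationSet, dict]:
    """Random gene→GO assignments plus one deliberately planted term.

    The last term is concentrated on the first cascade's kinases (or, for
    graphs without cascades, the first three genes); the manifest records
    the planted term and its gene subset.
    """
    genes = gene_symbols(g)
    if not genes:
        raise ValueError("graph has no gene-like nodes")
    if n_terms == 0:
        return AnnotationSet(gene_to_terms={}, background=set(genes)), {
            "planted_term": None,
            "planted_genes": [],
        }

    rng = np.random.default_rng(seed)
    terms = [f"GO:{i:07d}" for i in range(1, n_terms + 1)]
    term_names = {t: f"synthetic process {i}" for i, t in enumerate(terms, start=1)}
    noise_terms = terms[:-1]
    planted_term = terms[-1]
    term_names[planted_term] = "planted signaling cascade"

    gene_to_terms: dict[str, set[str]] = {gene: set() for gene in genes}
    if noise_terms:
        for gene in genes:
            k = int(rng.integers(1, min(4, len(noise_terms) + 1)))
            chosen = rng.choice(noise_terms, size=k, replace=False)
            gene_to_terms[gene].update(str(t) for t in chosen)

    planted_genes = sorted(
        gene for gene in genes if gene.startswith("KIN1_")
    ) or genes[:3]
    for gene in planted_genes:
        gene_to_terms[gene].add(planted_term)

    ann = AnnotationSet(
        gene_to_terms={g_: t for g_, t in gene_to_terms.items() if t},
        background=set(genes),
        term_names=term_names,
    )
    return ann, {"planted_term": planted_term, "planted_genes": planted_genes}


def generate_dictionary(g: PropertyGraph) -> Dictionary:
    """Gene and chemical dictionary derived from the graph's display names."""
    entries: list[tuple[str, str, str]] = []
    for gene in gene_symbols(g):
        entries.append((gene, gene, "gene"))
    chemicals = sorted(
        {
            n.display_name
            for n in g.nodes.values()
            if "SimpleEntity" in n.labels
        }
    )
    for chem in chemicals:
        entries.append((chem, chem, "chemical"))
    return Dictionary(entries=entries)


def generate_enrichment_table(g: PropertyGraph, manifest: dict) -> EnrichmentTable:
    """Deterministic per-gene description texts for semantic analysis.

    Each kinase's text mentions the next molecule in its cascade, so
    iterative semantic expansion walks down the planted chains.
    """
    follower: dict[str, str] = {}
    for kinases in manifest.get("kinases_by_cascade", []):
        names = []
        for nid in kinases:
            names.append(g.nodes[nid].display_name)
        for a, b in zip(names, names[1:]):
            follower[a] = b
    rows: dict[str, dict[str, str]] = {}
    for gene in gene_symbols(g):
        mention = follower.get(gene, "")
        text = f"{gene} is a synthetic signaling component."
        if mention:
            text += f" It phosphorylates {mention} downstream."
        rows[gene] = {
            "ncbi": text,
            "ncbi_url": f"https://example.org/ncbi/{gene}",
            "uniprot": f"{gene} localizes to the cytosol.",
            "uniprot_url": f"https://example.org/uniprot/{gene}",
            "stringdb": "",
            "stringdb_url": "",
            "go": "",
            "go_url": "",
        }
    return EnrichmentTable(rows=rows)


def write_fixture_bundle(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write graph tables, annotations, dictionary, table and manifest.

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, manifest = generate_pathway_graph(spec)
    write_graph(g, out / "nodes.tsv", out / "edges.tsv")

    ann, planted = generate_annotations(g, seed=spec.seed)
    manifest["annotations"] = planted
    with open(out / "annotations.tsv", "w") as fh:
        for gene in sorted(ann.gene_to_terms):
            for term in sorted(ann.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")
    with open(out / "term_names.tsv", "w") as fh:
        for term in sorted(ann.term_names):
            fh.write(f"{term}\t{ann.term_names[term]}\n")
    with open(out / "background.txt", "w") as fh:
        for gene in sorted(ann.background):
            fh.write(gene + "\n")

    dictionary = generate_dictionary(g)
    with open(out / "dictionary.tsv", "w") as fh:
        for term, concept_id, entity_type in dictionary.entries:
            fh.write(f"{term}\t{concept_id}\t{entity_type}\n")

    table = generate_enrichment_table(g, manifest)
    table.to_tsv(out / "table.tsv")

    with open(out / "sources.txt", "w") as fh:
        for stid in manifest["source_stids"]:
            fh.write(stid + "\n")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
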