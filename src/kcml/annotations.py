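"""Gene -> GO-term annotation handling.

Builds the catalog of candidate terms for classification: annotations are
propagated up the ontology graph (a gene annotated to a child term is
implicitly annotated to every ancestor), terms are filtered to a size window
that leaves enough positive examples without becoming uninformatively broad,
and near-duplicate terms (high Jaccard overlap of their gene sets) are merged
so a single phenotypic signature is not learned many times over.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

log = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "CatalogEntry",
    "TermCatalog",
    "propagate_annotations",
    "filter_terms",
    "jaccard",
    "merge_redundant_terms",
    "new_annotation_diff",
    "read_annotation_pairs",
    "read_gaf",
    "write_catalog",
]


class OntologyDAG:
    """Directed acyclic graph of ontology terms with child -> parent edges."""

    def __init__(
        self,
        terms: Mapping[str, dict] | Iterable[str],
        parent_links: Iterable[tuple[str, str]],
    ):
        self.graph = nx.DiGraph()
        if isinstance(terms, Mapping):
            for t, attrs in terms.items():
                self.graph.add_node(t, **attrs)
        else:
            self.graph.add_nodes_from(terms)
        for child, parent in parent_links:
            if child not in self.graph or parent not in self.graph:
                raise ValueError(
                    f"edge ({child!r}, {parent!r}) references an undeclared term"
                )
            self.graph.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(self.graph):
            edge = next(iter(nx.find_cycle(self.graph)))
            raise ValueError(f"ontology graph has a cycle through edge {edge}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable from *term* via parent links (term excluded)."""
        return nx.descendants(self.graph, term)

    @classmethod
    def from_obo(cls, path: str | Path, include_part_of: bool = True) -> "OntologyDAG":
        """Read an OBO 1.2 file ([Term] stanzas; is_a and optionally part_of).

        Obsolete terms are dropped by the reader.
        """
        import obonet

        g = obonet.read_obo(str(path))
        terms = {
            n: {k: v for k, v in d.items() if k in ("name", "namespace")}
            for n, d in g.nodes(data=True)
        }
        links = []
        for child, parent, key in g.edges(keys=True):
            if key == "is_a" or (include_part_of and key == "part_of"):
                links.append((child, parent))
        return cls(terms, links)


@dataclass
class AnnotationSet:
    """Bipartite gene <-> term annotation mapping.

    ``gene_to_terms`` and ``term_to_genes`` are kept as exact inverses; the
    class is constructed from (gene, term) pairs so duplicates collapse.
    """

    gene_to_terms: dict[str, set[str]]
    release_tag: str = ""

    def __post_init__(self):
        self.gene_to_terms = {g: set(ts) for g, ts in self.gene_to_terms.items() if ts}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], release_tag: str = "") -> "AnnotationSet":
        g2t: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(gene, set()).add(term)
        return cls(g2t, release_tag)

    @property
    def term_to_genes(self) -> dict[str, set[str]]:
        t2g: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                t2g.setdefault(t, set()).add(g)
        return t2g

    def pairs(self) -> set[tuple[str, str]]:
        return {(g, t) for g, ts in self.gene_to_terms.items() for t in ts}

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def __len__(self) -> int:
        return sum(len(ts) for ts in self.gene_to_terms.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationSet) and self.gene_to_terms == other.gene_to_terms


@dataclass
class CatalogEntry:
    term_id: str
    genes: frozenset[str]
    merged_from: list[str] = field(default_factory=list)


@dataclass
class TermCatalog:
    """Candidate terms for classification, with the size bounds used."""

    entries: list[CatalogEntry]
    min_genes: int = 100
    max_genes: int = 500

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def term_ids(self) -> list[str]:
        return [e.term_id for e in self.entries]

    def get(self, term_id: str) -> CatalogEntry:
        for e in self.entries:
            if e.term_id == term_id:
                return e
        raise KeyError(term_id)


def propagate_annotations(ann: AnnotationSet, dag: OntologyDAG) -> AnnotationSet:
    """Escalate each gene's annotations to every ancestor term.

    Idempotent; terms absent from the graph pass through unchanged (logged).
    """
    unknown = {t for ts in ann.gene_to_terms.values() for t in ts} - dag.terms
    if unknown:
        log.warning("%d annotated terms absent from ontology; passed through", len(unknown))
    anc_cache: dict[str, set[str]] = {}
    out: dict[str, set[str]] = {}
    for gene, terms in ann.gene_to_terms.items():
        expanded = set(terms)
        for t in terms:
            if t in dag.terms:
                if t not in anc_cache:
                    anc_cache[t] = dag.ancestors(t)
                expanded |= anc_cache[t]
        out[gene] = expanded
    return AnnotationSet(out, ann.release_tag)


def filter_terms(ann: AnnotationSet, min_genes: int = 100, max_genes: int = 500) -> TermCatalog:
    """Keep terms whose positive-gene set size is within [min_genes, max_genes]."""
    t2g = ann.term_to_genes
    if not t2g:
        log.warning("empty annotation set: empty catalog")
    entries = [
        CatalogEntry(t, frozenset(gs))
        for t, gs in sorted(t2g.items())
        if min_genes <= len(gs) <= max_genes
    ]
    return TermCatalog(entries, min_genes, max_genes)


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a n b| / |a u b|; 0 when both sets are empty (by convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        log.debug("jaccard of two empty sets: 0 by convention")
        return 0.0
    return len(a & b) / len(union)


def merge_redundant_terms(cat: TermCatalog, threshold: float = 0.70) -> TermCatalog:
    """Greedily merge term pairs with Jaccard overlap above *threshold*.

    Repeatedly merges the currently most-overlapping pair: gene sets are
    unioned, the id of the larger set is kept (ties: lexicographically smaller
    id) and ``merged_from`` records the absorbed ids. Merged sets may exceed
    the catalog's size ceiling and are kept.
    """
    entries = {e.term_id: CatalogEntry(e.term_id, e.genes, list(e.merged_from)) for e in cat.entries}
    while True:
        best = None  # (jac, id_a, id_b) with id_a < id_b
        ids = sorted(entries)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                j = jaccard(entries[a].genes, entries[b].genes)
                if j > threshold and (best is None or j > best[0]):
                    best = (j, a, b)
        if best is None:
            break
        _, a, b = best
        ea, eb = entries[a], entries[b]
        if len(ea.genes) > len(eb.genes) or (len(ea.genes) == len(eb.genes) and a < b):
            keep, drop = ea, eb
        else:
            keep, drop = eb, ea
        merged = CatalogEntry(
            keep.term_id,
            keep.genes | drop.genes,
            keep.merged_from + [drop.term_id] + drop.merged_from,
        )
        del entries[drop.term_id]
        entries[keep.term_id] = merged
    return TermCatalog(sorted(entries.values(), key=lambda e: e.term_id), cat.min_genes, cat.max_genes)


def new_annotation_diff(old: AnnotationSet, new: AnnotationSet) -> AnnotationSet:
    """(gene, term) pairs present in *new* but absent from *old*.

    Used to validate predictions against annotations accumulated after the
    training release.
    """
    diff = new.pairs() - old.pairs()
    tag = f"{new.release_tag}-{old.release_tag}" if new.release_tag or old.release_tag else ""
    return AnnotationSet.from_pairs(diff, tag)


# ---------------------------------------------------------------------------
# readers / writers

def read_annotation_pairs(path: str | Path, release_tag: str = "") -> AnnotationSet:
    """Two-column TSV: gene_id <TAB> term_id, optional header line."""
    pairs = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {i + 1} has fewer than two columns")
            gene, term = fields[0], fields[1]
            if i == 0 and gene.lower() in ("gene", "gene_id"):
                continue
            pairs.append((gene, term))
    return AnnotationSet.from_pairs(pairs, release_tag)


def read_gaf(path: str | Path, use_symbol: bool = False, release_tag: str = "") -> AnnotationSet:
    """GAF 2.x reader: DB Object ID (col 2) or symbol (col 3) and GO ID (col 5).

    Rows with a NOT qualifier are ignored.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            gene = cols[2] if use_symbol else cols[1]
            pairs.append((gene, cols[4]))
    return AnnotationSet.from_pairs(pairs, release_tag)


def write_catalog(cat: TermCatalog, path: str | Path) -> None:
    """TSV (term_id, n_genes, merged_from) plus a JSON parameter sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("term_id\tn_genes\tmerged_from\n")
        for e in cat.entries:
            fh.write(f"{e.term_id}\t{len(e.genes)}\t{';'.join(e.merged_from)}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"min_genes": cat.min_genes, "max_genes": cat.max_genes,
                   "n_terms": len(cat)}, fh, indent=2)


def read_catalog(path: str | Path, ann: AnnotationSet | None = None,
                 gene_sets: Mapping[str, Iterable[str]] | None = None) -> TermCatalog:
    """Re-hydrate a catalog written by :func:`write_catalog`.

    Gene memberships are not stored in the TSV; supply either the propagated
    annotation set or an explicit term -> genes mapping.
    """
    t2g = dict(gene_sets) if gene_sets is not None else (ann.term_to_genes if ann else {})
    entries = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            term_id, _n, merged = line.rstrip("\n").split("\t")
            genes = frozenset(t2g.get(term_id, ()))
            entries.append(CatalogEntry(term_id, genes, merged.split(";") if merged else []))
    return TermCatalog(entries)
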