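"""Phenotype-driven gene relevance from the Human Phenotype Ontology.

A patient is described by a set of HPO term ids; genes carry HPO
annotations.  Gene relevance is scored with an information-content-weighted
Jaccard index over *ancestor closures*:

    IC(t)  = -log( fraction of mapped genes annotated, via closure, with t )
    score  = sum IC over closure(query) ∩ closure(gene annotations)
           / sum IC over closure(query) ∪ closure(gene annotations)

The root term is annotated to every gene, so IC(root) = 0 and two term sets
sharing only the root score 0.  An unmapped gene scores 0.  Scores are
always in [0, 1] and equal 1 when the two closures coincide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = ["GenePhenotypeMap", "hpo_gene_score", "load_obo", "load_gene_map"]


@dataclass
class GenePhenotypeMap:
    """Gene -> HPO term sets plus the ontology DAG (edges child -> parent)."""

    gene_terms: dict[str, set[str]]
    ontology: nx.DiGraph
    _closure_cache: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _ic: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("ontology is not acyclic")
        unknown = {
            t for terms in self.gene_terms.values() for t in terms if t not in self.ontology
        }
        if unknown:
            raise ValueError(f"gene annotations use term(s) absent from ontology: {sorted(unknown)[:10]}")

    def closure(self, term: str) -> frozenset[str]:
        """The term plus all its ancestors (transitive is-a parents)."""
        cached = self._closure_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.ontology, term)) | {term}
            self._closure_cache[term] = cached
        return cached

    def set_closure(self, terms: set[str]) -> set[str]:
        out: set[str] = set()
        for t in terms:
            out |= self.closure(t)
        return out

    def information_content(self) -> dict[str, float]:
        """IC per term from the gene-annotation corpus (closure counts)."""
        if self._ic is None:
            n_genes = len(self.gene_terms)
            counts: dict[str, int] = {t: 0 for t in self.ontology.nodes}
            for terms in self.gene_terms.values():
                for t in self.set_closure(set(terms)):
                    counts[t] += 1
            # Terms no gene is annotated with are treated as maximally
            # informative (the IC of a singleton annotation).
            max_ic = math.log(n_genes) if n_genes > 0 else 0.0
            ic: dict[str, float] = {}
            for t, c in counts.items():
                ic[t] = -math.log(c / n_genes) if c > 0 else max_ic
            self._ic = ic
        return self._ic


def hpo_gene_score(query: set[str], gene: str, pheno_map: GenePhenotypeMap) -> float:
    """IC-weighted Jaccard similarity between patient terms and a gene.

    Unknown query terms are dropped with a warning; an empty query after
    dropping is an error.  Genes without annotations score 0.
    """
    known = {t for t in query if t in pheno_map.ontology}
    dropped = set(query) - known
    if dropped:
        warnings.warn(f"dropping unknown HPO term(s): {sorted(dropped)}", stacklevel=2)
    if not known:
        raise ValueError("HPO query is empty after dropping unknown terms")
    gene_terms = pheno_map.gene_terms.get(gene)
    if not gene_terms:
        return 0.0
    ic = pheno_map.information_content()
    q_closure = pheno_map.set_closure(known)
    g_closure = pheno_map.set_closure(set(gene_terms))
    inter = sum(ic.get(t, 0.0) for t in q_closure & g_closure)
    union = sum(ic.get(t, 0.0) for t in q_closure | g_closure)
    if union == 0.0:
        return 0.0
    return min(1.0, inter / union)


def load_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology, keeping only is-a edges (child -> parent)."""
    import obonet

    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    g.add_nodes_from(multi.nodes(data=True))
    for u, v, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(u, v)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError(f"{path}: is-a graph is cyclic")
    return g


def load_gene_map(path: str | Path, ontology: nx.DiGraph) -> GenePhenotypeMap:
    """Read a 2-column TSV (gene <tab> HPO term id) into a phenotype map.

    Terms absent from the ontology are dropped with a warning rather than
    failing, since public annotation releases routinely lag the ontology.
    """
    gene_terms: dict[str, set[str]] = {}
    dropped: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            gene, term = parts[0], parts[1]
            if term not in ontology:
                dropped.add(term)
                continue
            gene_terms.setdefault(gene, set()).add(term)
    if dropped:
        warnings.warn(f"{path}: dropped term(s) absent from ontology: {sorted(dropped)[:10]}")
    return GenePhenotypeMap(gene_terms=gene_terms, ontology=ontology)
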