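"""Negative-set construction from Gene Ontology annotation.

Experimentally verified moonlighting proteins exist, but there is no curated
set of proteins known *not* to moonlight, so non-MP negatives are screened
from GO annotation. A term's information content is derived from its
recursive annotation frequency; pairs of terms are compared with the simRel
similarity (an information-content ratio over the best common ancestor,
damped by that ancestor's rarity weight ``1 - p``); terms are clustered on
that similarity; and a protein qualifies as a negative when

1. it carries at least eight GO terms in total,
2. its biological-process (BP) terms form a single cluster whose score lies
   inside the similarity band (0.1, 0.5), and
3. at most one of its molecular-function (MF) clusters scores inside that
   band.

Negatives sharing an exact sequence with any positive are then removed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import FormatError, StructuralError

logger = logging.getLogger(__name__)

NAMESPACES = ("BP", "MF", "CC")

_OBO_NAMESPACE = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

#: Similarity band of the selection principles, read as an open interval.
DEFAULT_BAND = (0.1, 0.5)

#: Merge threshold of the agglomerative clustering (lower band edge).
DEFAULT_CLUSTER_THRESHOLD = 0.1


@dataclass
class GoDag:
    """A directed acyclic ontology with per-term annotation counts.

    ``parents`` maps a term to its ``is_a`` parents (same namespace);
    ``anno`` is the number of gene products directly annotated to the term
    in the reference corpus.
    """

    parents: dict[str, set[str]] = field(default_factory=dict)
    namespace: dict[str, str] = field(default_factory=dict)
    anno: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, set[str]] | None = None
        self._ancestors: dict[str, frozenset[str]] = {}

    @property
    def terms(self) -> set[str]:
        return set(self.namespace)

    def children(self, term: str) -> set[str]:
        if self._children is None:
            ch: dict[str, set[str]] = {t: set() for t in self.namespace}
            for t, ps in self.parents.items():
                for p in ps:
                    ch.setdefault(p, set()).add(t)
            self._children = ch
        return self._children.get(term, set())

    def graph(self) -> nx.DiGraph:
        """child -> parent edge view of the ontology."""
        g = nx.DiGraph()
        g.add_nodes_from(self.namespace)
        for t, ps in self.parents.items():
            for p in ps:
                g.add_edge(t, p)
        return g

    def validate(self) -> None:
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise StructuralError("ontology contains a cycle")
        for ns in set(self.namespace.values()):
            if len(self.roots(ns)) != 1:
                raise StructuralError(f"namespace {ns} must have exactly one root")

    def roots(self, ns: str) -> list[str]:
        return [
            t
            for t, n in self.namespace.items()
            if n == ns and not self.parents.get(t)
        ]

    def root(self, ns: str) -> str:
        roots = self.roots(ns)
        if len(roots) != 1:
            raise StructuralError(f"namespace {ns} has {len(roots)} roots")
        return roots[0]

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of ``term`` including the term itself."""
        cached = self._ancestors.get(term)
        if cached is not None:
            return cached
        seen = {term}
        stack = [term]
        while stack:
            for p in self.parents.get(stack.pop(), ()):
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        result = frozenset(seen)
        self._ancestors[term] = result
        return result


@dataclass(frozen=True)
class ProteinAnnotation:
    """GO terms attached to one protein, partitioned by namespace on demand."""

    protein_id: str
    terms: frozenset[str]

    def by_namespace(self, dag: GoDag, ns: str) -> list[str]:
        return sorted(t for t in self.terms if dag.namespace.get(t) == ns)


@dataclass
class TermStats:
    """Recursive annotation frequency and probability per term."""

    freq: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)


@dataclass
class ClusterResult:
    """A partition of terms with the mean pairwise simRel of each block.

    Singleton clusters have an undefined score, flagged as NaN.
    """

    clusters: list[list[str]]
    scores: list[float]


# ---------------------------------------------------------------------------
# loading


def read_obo(path: str | Path) -> GoDag:
    """Load an ontology from OBO (``id`` / ``is_a`` / ``namespace`` stanzas)."""
    g = obonet.read_obo(str(path))
    dag = GoDag()
    for term, data in g.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise FormatError(f"term {term}: missing namespace")
        dag.namespace[term] = _OBO_NAMESPACE.get(ns, ns)
        dag.parents[term] = set()
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            dag.parents[child].add(parent)
    return dag


def read_edgelist(path: str | Path) -> GoDag:
    """Load an ontology from a 3-column TSV: child, parent, namespace.

    A root is declared with an empty parent field.
    """
    dag = GoDag()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise FormatError(f"{Path(path).name}:{lineno}: expected 3 columns")
            child, parent, ns = (f.strip() for f in row)
            dag.namespace[child] = ns
            dag.parents.setdefault(child, set())
            if parent:
                dag.parents[child].add(parent)
                dag.namespace.setdefault(parent, ns)
                dag.parents.setdefault(parent, set())
    return dag


def read_term_counts(path: str | Path) -> dict[str, int]:
    """Read per-term direct annotation counts (TSV: term, count)."""
    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise FormatError(f"{Path(path).name}:{lineno}: expected 2 columns")
            counts[row[0].strip()] = int(row[1])
    return counts


def read_annotations(path: str | Path) -> list[ProteinAnnotation]:
    """Read protein -> GO term pairs (TSV: protein id, term id)."""
    by_protein: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise FormatError(f"{Path(path).name}:{lineno}: expected 2 columns")
            by_protein.setdefault(row[0].strip(), set()).add(row[1].strip())
    return [
        ProteinAnnotation(pid, frozenset(ts)) for pid, ts in sorted(by_protein.items())
    ]


# ---------------------------------------------------------------------------
# term statistics


def term_freq(dag: GoDag) -> TermStats:
    """Recursive frequency: freq(c) = anno(c) + sum of children frequencies.

    Applied literally on the DAG (a multi-parent descendant is counted once
    per path), matching the stated recursion; ``unique_descendants=True`` on
    :func:`term_freq_unique` gives the de-duplicated alternative.
    """
    g = dag.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError("cycle detected while computing term frequencies")
    stats = TermStats()
    # child->parent edges: topological order yields children before parents
    for term in nx.topological_sort(g):
        stats.freq[term] = float(dag.anno.get(term, 0)) + sum(
            stats.freq[h] for h in dag.children(term)
        )
    return stats


def term_freq_unique(dag: GoDag) -> TermStats:
    """Frequency counting each descendant's annotation once (DAG-safe variant)."""
    g = dag.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise StructuralError("cycle detected while computing term frequencies")
    stats = TermStats()
    desc: dict[str, set[str]] = {}
    for term in nx.topological_sort(g):
        d = {term}
        for h in dag.children(term):
            d |= desc[h]
        desc[term] = d
        stats.freq[term] = float(sum(dag.anno.get(t, 0) for t in d))
    return stats


def term_prob(stats: TermStats, dag: GoDag) -> TermStats:
    """p(c) = freq(c) / freq(root of c's namespace); p(root) = 1."""
    root_freq = {}
    for ns in set(dag.namespace.values()):
        root = dag.root(ns)
        f = stats.freq.get(root, 0.0)
        if f <= 0:
            raise StructuralError(f"namespace {ns}: root frequency is 0 (empty ontology)")
        root_freq[ns] = f
    for term, f in stats.freq.items():
        stats.p[term] = f / root_freq[dag.namespace[term]]
    return stats


# ---------------------------------------------------------------------------
# simRel similarity


def simrel(c1: str, c2: str, stats: TermStats, dag: GoDag) -> float:
    """simRel similarity between two terms of the same namespace.

    max over common ancestors c (each term counting as its own ancestor) of
    ``2 log p(c) / (log p(c1) + log p(c2)) * (1 - p(c))``, clamped to [0,1].
    Terms with zero frequency have undefined information content and are
    excluded upstream.
    """
    if dag.namespace.get(c1) != dag.namespace.get(c2):
        raise StructuralError(f"{c1} and {c2} are in different namespaces")
    for c in (c1, c2):
        if stats.p.get(c, 0.0) <= 0.0:
            raise StructuralError(f"term {c} has zero frequency; simRel undefined")
    common = dag.ancestors(c1) & dag.ancestors(c2)
    if not common:
        raise StructuralError(f"{c1} and {c2} share no ancestor")
    log1, log2 = np.log(stats.p[c1]), np.log(stats.p[c2])
    denom = log1 + log2
    best = 0.0
    for c in common:
        pc = stats.p[c]
        if pc <= 0.0:
            continue
        if denom == 0.0:
            # both query terms are roots: zero information content
            ratio = 0.0
        else:
            ratio = 2.0 * np.log(pc) / denom
        best = max(best, ratio * (1.0 - pc))
    return float(min(max(best, 0.0), 1.0))


def simrel_matrix(terms: list[str], stats: TermStats, dag: GoDag) -> np.ndarray:
    n = len(terms)
    sim = np.zeros((n, n))
    for i in range(n):
        sim[i, i] = simrel(terms[i], terms[i], stats, dag)
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = simrel(terms[i], terms[j], stats, dag)
    return sim


# ---------------------------------------------------------------------------
# clustering and selection


def cluster_terms(
    terms: list[str] | set[str],
    stats: TermStats,
    dag: GoDag,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> ClusterResult:
    """Average-linkage agglomerative clustering on simRel.

    Clusters merge while their average similarity is at least ``threshold``.
    Cluster score is the mean pairwise simRel; singleton scores are NaN.
    """
    terms = sorted(terms)
    if not terms:
        raise ValueError("cluster_terms requires at least one term")
    if len(terms) == 1:
        return ClusterResult(clusters=[list(terms)], scores=[float("nan")])

    sim = simrel_matrix(terms, stats, dag)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=1.0 - threshold, criterion="distance")

    clusters: list[list[str]] = []
    scores: list[float] = []
    for lab in sorted(set(labels)):
        members = [t for t, l in zip(terms, labels) if l == lab]
        clusters.append(members)
        if len(members) == 1:
            scores.append(float("nan"))
        else:
            idx = [terms.index(t) for t in members]
            pair = [sim[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]]
            scores.append(float(np.mean(pair)))
    return ClusterResult(clusters=clusters, scores=scores)


def _in_band(score: float, band: tuple[float, float]) -> bool:
    return bool(np.isfinite(score) and band[0] < score < band[1])


def select_negatives(
    annotations: list[ProteinAnnotation],
    dag: GoDag,
    stats: TermStats,
    band: tuple[float, float] = DEFAULT_BAND,
    threshold: float = DEFAULT_CLUSTER_THRESHOLD,
) -> tuple[set[str], dict[str, str]]:
    """Screen candidate non-moonlighting proteins by the three principles.

    Returns the accepted protein ids and an audit mapping protein id ->
    outcome ("accepted" or the principle that rejected it). Proteins citing
    terms unknown to the DAG (or with zero frequency) are skipped with a
    warning.
    """
    accepted: set[str] = set()
    audit: dict[str, str] = {}
    for ann in annotations:
        unknown = {t for t in ann.terms if t not in dag.namespace}
        if unknown:
            logger.warning(
                "protein %s: cites unknown terms %s; skipped",
                ann.protein_id,
                sorted(unknown),
            )
            audit[ann.protein_id] = "skipped: unknown GO terms"
            continue
        usable = [t for t in sorted(ann.terms) if stats.p.get(t, 0.0) > 0.0]
        if len(usable) < len(ann.terms):
            logger.warning(
                "protein %s: excluding zero-frequency terms %s from similarity",
                ann.protein_id,
                sorted(set(ann.terms) - set(usable)),
            )
        if len(ann.terms) < 8:
            audit[ann.protein_id] = "rejected: fewer than eight GO terms"
            continue
        bp = [t for t in usable if dag.namespace[t] == "BP"]
        mf = [t for t in usable if dag.namespace[t] == "MF"]
        if not bp:
            audit[ann.protein_id] = "rejected: no usable BP terms"
            continue
        bp_clusters = cluster_terms(bp, stats, dag, threshold)
        if len(bp_clusters.clusters) != 1 or not _in_band(bp_clusters.scores[0], band):
            audit[ann.protein_id] = (
                "rejected: BP terms do not form one cluster scoring inside the band"
            )
            continue
        if mf:
            mf_clusters = cluster_terms(mf, stats, dag, threshold)
            qualifying = sum(1 for s in mf_clusters.scores if _in_band(s, band))
            if qualifying > 1:
                audit[ann.protein_id] = (
                    "rejected: more than one MF cluster scores inside the band"
                )
                continue
        accepted.add(ann.protein_id)
        audit[ann.protein_id] = "accepted"
    return accepted, audit


def dedupe_against_positives(
    negatives: set[str],
    negative_seqs: dict[str, str],
    positive_seqs: dict[str, str] | set[str],
) -> set[str]:
    """Drop negatives whose residue string exactly matches any positive.

    Comparison is case-insensitive (sequences are uppercased first).
    """
    if isinstance(positive_seqs, dict):
        pos = {s.upper() for s in positive_seqs.values()}
    else:
        pos = {s.upper() for s in positive_seqs}
    return {
        pid
        for pid in negatives
        if negative_seqs.get(pid, "").upper() not in pos
    }
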