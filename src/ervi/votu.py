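"""Clustering of ERVi elements into viral operational taxonomic units.

Elements are compared all-against-all; a pair is connected when the best
local alignment covers at least 80% of the shorter sequence at >= 95%
nucleotide identity with e-value <= 1e-5 (coverage is symmetrized over the
shorter sequence so edges are direction-independent).  The similarity graph
is then partitioned with a from-scratch Markov clustering (MCL) at
inflation 1.4.  The module also locates orthologous/paralogous copies of an
element's flanked LTRs genome-wide.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

from ._align import KA_NUC, evalue, nuc_local_aligner, summarize
from .ltr_scan import ProvirusCandidate, as_seq_dict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityThresholds:
    min_coverage: float = 80.0  # percent of the shorter sequence aligned
    min_identity: float = 95.0
    e_max: float = 1e-5


@dataclass
class SimilarityEdge:
    element_a: str
    element_b: str
    coverage: float
    identity: float
    e_value: float


@dataclass
class VOTUPartition:
    clusters: list[frozenset[str]]
    inflation: float
    method: str = "mcl"
    converged: bool = True

    def labels(self) -> dict[str, int]:
        out = {}
        for i, cluster in enumerate(self.clusters):
            for node in cluster:
                out[node] = i
        return out


def pairwise_similarity(
    elements, thresholds: SimilarityThresholds | None = None
) -> list[SimilarityEdge]:
    """All-to-all best-local-alignment similarity edges.

    An edge exists iff the best local alignment satisfies all three
    thresholds; self-edges are excluded and each unordered pair is stored
    once.
    """
    thresholds = thresholds or SimilarityThresholds()
    if isinstance(elements, Mapping):
        seqs = {str(k): str(v).upper() for k, v in elements.items()}
        if len(seqs) != len(elements):
            raise ValueError("duplicate element ids")
    else:
        seqs = {}
        for rec in elements:
            rid = str(rec.id)
            if rid in seqs:
                raise ValueError(f"duplicate element id: {rid}")
            seqs[rid] = str(rec.seq).upper()
    ids = sorted(seqs)
    aligner = nuc_local_aligner()
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = seqs[ids[i]], seqs[ids[j]]
            alns = aligner.align(a, b)
            if len(alns) == 0 or alns.score <= 0:
                continue
            stats = summarize(alns[0])
            shorter_aligned = stats.target_aligned if len(a) <= len(b) else stats.query_aligned
            coverage = 100.0 * shorter_aligned / min(len(a), len(b))
            e = evalue(stats.score, len(a), len(b), KA_NUC)
            if (
                coverage >= thresholds.min_coverage
                and stats.identity_pct >= thresholds.min_identity
                and e <= thresholds.e_max
            ):
                edges.append(
                    SimilarityEdge(ids[i], ids[j], coverage, stats.identity_pct, e)
                )
    return edges


def mcl_cluster(
    edges: Sequence[SimilarityEdge],
    node_ids: Sequence[str],
    inflation: float = 1.4,
    weight: str = "similarity",  # or "binary"
    max_iter: int = 200,
    prune: float = 1e-8,
    tol: float = 1e-6,
) -> VOTUPartition:
    """Markov clustering of the similarity graph.

    Weighted adjacency (weight = identity x coverage / 1e4, or 1 for
    ``binary``) plus unit self-loops, column-normalized, then alternating
    expansion (matrix square) and inflation (entrywise power, renormalize)
    with entries below ``prune`` zeroed, until the largest entry change
    drops below ``tol`` or ``max_iter`` iterations.  Clusters are read from
    the attractor structure; singletons form their own cluster.  Node order
    is canonicalized, so the result is invariant to input order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(set(node_ids))
    idx = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return VOTUPartition(clusters=[], inflation=inflation)
    mat = np.zeros((n, n))
    for edge in edges:
        if edge.element_a not in idx or edge.element_b not in idx:
            raise ValueError("edge references unknown node")
        w = 1.0 if weight == "binary" else edge.identity * edge.coverage / 1e4
        i, j = idx[edge.element_a], idx[edge.element_b]
        mat[i, j] = max(mat[i, j], w)
        mat[j, i] = mat[i, j]
    np.fill_diagonal(mat, 1.0)
    mat = mat / mat.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        new = mat @ mat
        new = new ** inflation
        new[new < prune] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        diff = np.abs(new - mat).max()
        mat = new
        if diff < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations; returning current state", max_iter)
    clusters = _interpret(mat, nodes, tol)
    return VOTUPartition(clusters=clusters, inflation=inflation, converged=converged)


def _interpret(mat: np.ndarray, nodes: list[str], tol: float) -> list[frozenset[str]]:
    n = len(nodes)
    linked = (mat > tol) | (mat.T > tol)
    np.fill_diagonal(linked, True)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if linked[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, set[str]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(nodes[i])
    clusters = [frozenset(g) for g in groups.values()]
    clusters.sort(key=lambda c: min(c))
    return clusters


@dataclass
class LocusHit:
    assembly_id: str
    contig_id: str
    span: tuple[int, int]  # 0-based half-open
    label: str  # self / paralog / ortholog
    identity: float
    query: str  # ltr5 / ltr3


def find_ortho_para(
    element: ProvirusCandidate,
    genomes: Mapping[str, Mapping[str, str]],
    source_assembly: str,
    source_genome=None,
    flank: int = 500,
    min_identity: float = 95.0,
) -> list[LocusHit]:
    """Locate orthologous/paralogous copies of an element's flanked LTRs.

    Each LTR extended by ``flank`` bases on both sides is searched against
    every contig of every assembly; a hit requires the full query aligned at
    >= ``min_identity`` identity.  The element's own locus is labeled
    ``self``; other hits in the source assembly ``paralog``; hits in other
    assemblies ``ortholog``.
    """
    if source_genome is None:
        source_genome = genomes[source_assembly]
    source = as_seq_dict(source_genome)
    contig = source[element.contig_id]
    queries = {}
    for name, (qs, qe) in (("ltr5", element.ltr5_span), ("ltr3", element.ltr3_span)):
        if qs - flank < 0 or qe + flank > len(contig):
            raise ValueError(f"flanks unavailable for {name} of {element.locus_id}")
        queries[name] = contig[qs - flank : qe + flank]
    hits: list[LocusHit] = []
    for assembly_id in sorted(genomes):
        contigs = as_seq_dict(genomes[assembly_id])
        for contig_id in sorted(contigs):
            target = contigs[contig_id]
            for qname, qseq in queries.items():
                hits.extend(
                    _search_full_query(
                        qseq, qname, target, assembly_id, contig_id, min_identity
                    )
                )
    # label and merge
    s, e = element.element_span
    out: list[LocusHit] = []
    for hit in hits:
        if (
            hit.assembly_id == source_assembly
            and hit.contig_id == element.contig_id
            and hit.span[0] < e + flank
            and s - flank < hit.span[1]
        ):
            hit.label = "self"
        elif hit.assembly_id == source_assembly:
            hit.label = "paralog"
        else:
            hit.label = "ortholog"
        out.append(hit)
    return _merge_hits(out)


def _search_full_query(
    qseq: str, qname: str, target: str, assembly_id: str, contig_id: str, min_identity: float
) -> list[LocusHit]:
    max_ed = int(math.floor(len(qseq) * (100.0 - min_identity) / 100.0))
    masked = target
    hits = []
    for _ in range(32):  # iterative best-hit masking
        res = edlib.align(qseq, masked, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] < 0:
            break
        start, end = res["locations"][0]
        end += 1
        identity = 100.0 * (len(qseq) - res["editDistance"]) / len(qseq)
        hits.append(
            LocusHit(
                assembly_id=assembly_id,
                contig_id=contig_id,
                span=(start, end),
                label="",
                identity=identity,
                query=qname,
            )
        )
        masked = masked[:start] + "N" * (end - start) + masked[end:]
    return hits


def _merge_hits(hits: list[LocusHit]) -> list[LocusHit]:
    """Merge overlapping/adjacent hits on the same contig into loci."""
    hits = sorted(hits, key=lambda h: (h.assembly_id, h.contig_id, h.span))
    merged: list[LocusHit] = []
    for hit in hits:
        if merged:
            last = merged[-1]
            same = last.assembly_id == hit.assembly_id and last.contig_id == hit.contig_id
            if same and hit.span[0] <= last.span[1] + 5000 and last.label == hit.label:
                last.span = (last.span[0], max(last.span[1], hit.span[1]))
                last.identity = max(last.identity, hit.identity)
                continue
        merged.append(hit)
    return merged


__all__ = [
    "SimilarityThresholds",
    "SimilarityEdge",
    "VOTUPartition",
    "LocusHit",
    "pairwise_similarity",
    "mcl_cluster",
    "find_ortho_para",
]
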