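"""Junction-read genotyping of insertional polymorphism.

For each provirus candidate three queries are built: a *query of initial
state* (the pre-insertion locus: 5' flank joined to the 3' flank with one
TSD copy removed) and 5'/3' *queries of insertion state* (flank joined to
the element boundary).  Population reads are mapped against all three; a
read is *meaningful* only when it is full-length mapped at high identity
and its mapping fully covers the junction window (positions 190-210 of the
query at the default 200-bp flank).  Meaningful reads on the insertion
queries evidence the insertion allele (i); on the initial query, the empty
allele (-).  One meaningful read suffices for presence, and diploid
genotypes i/i, i/-, -/- follow from which alleles have evidence.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from ._align import KA_READ, evalue, read_local_aligner, revcomp, summarize
from .ltr_scan import ProvirusCandidate, as_seq_dict

logger = logging.getLogger(__name__)

JUNCTION_HALF_WIDTH = 10  # junction window = [flank_len - 10, flank_len + 10], 1-based
MIN_READ_LEN = 2 * JUNCTION_HALF_WIDTH + 1  # shorter reads can never be meaningful
SCREEN_KMER = 21
SCREEN_STRIDE = 10


@dataclass
class JunctionQuerySet:
    """The three constructed queries for one locus."""

    locus_id: str
    initial_state: str
    ins5: str
    ins3: str
    junction_window: tuple[int, int]  # 1-based inclusive, identical across queries
    flank_len: int
    tsd_len: int

    def query(self, query_id: str) -> str:
        return {"initial": self.initial_state, "ins5": self.ins5, "ins3": self.ins3}[query_id]


@dataclass
class ReadMapping:
    read_id: str
    query_id: str  # initial/ins5/ins3
    query_span: tuple[int, int]  # 1-based inclusive
    identity: float
    e_value: float
    full_length: bool
    strand: str = "+"


@dataclass
class GenotypeCall:
    sample_id: str
    locus_id: str
    n_ins_reads: int
    n_empty_reads: int
    genotype: str  # ii / i- / -- / nocall
    sample_kind: str = "individual"  # individual / pool_with_size / pool_unsized / unknown
    pool_size: int | None = None


@dataclass
class PopulationFrequencies:
    locus_id: str
    group_id: str
    n_individuals: int
    freq_i: float | None
    freq_empty: float | None
    genotype_freqs: dict[str, float] | None
    reported: bool
    n_samples_total: int = 0  # all evidentiary samples incl. mixed/unsized pools (TD-style)


def build_junction_queries(
    genome, candidate: ProvirusCandidate, flank_len: int = 200
) -> JunctionQuerySet:
    """Construct the initial-state and the two insertion-state queries.

    ``initial_state`` removes one TSD copy so it reconstructs the ancestral
    pre-insertion locus exactly; the junction falls between positions
    ``flank_len`` and ``flank_len + 1`` on every query.
    """
    seqs = as_seq_dict(genome)
    seq = seqs[candidate.contig_id]
    s, e = candidate.element_span
    tsd_len = len(candidate.tsd_seq) if candidate.tsd_seq else 0
    if s - flank_len < 0 or e + flank_len > len(seq):
        raise ValueError(f"insufficient flank on contig for locus {candidate.locus_id}")
    if e - s < flank_len:
        raise ValueError(f"element shorter than flank_len at locus {candidate.locus_id}")
    flank5 = seq[s - flank_len : s]
    flank3 = seq[e : e + flank_len]
    element = seq[s:e]
    window = (flank_len - JUNCTION_HALF_WIDTH, flank_len + JUNCTION_HALF_WIDTH)
    return JunctionQuerySet(
        locus_id=candidate.locus_id,
        initial_state=flank5 + flank3[tsd_len:],
        ins5=flank5 + element[:flank_len],
        ins3=element[-flank_len:] + flank3,
        junction_window=window,
        flank_len=flank_len,
        tsd_len=tsd_len,
    )


def _edlib_mapping(read: str, read_id: str, query_id: str, qseq: str, strand: str,
                   e_max: float, min_identity: float) -> ReadMapping | None:
    max_ed = int(math.floor(len(read) * (100.0 - min_identity) / 100.0)) + 1
    res = edlib.align(read, qseq, mode="HW", task="path", k=max_ed)
    if res["editDistance"] < 0:
        return None
    # edlib emits extended cigar: '=' match, 'X' mismatch, I/D gaps
    eq = xx = i_cols = d_cols = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
        else:
            ln = int(num)
            num = ""
            if ch == "=":
                eq += ln
            elif ch in ("X", "M"):
                xx += ln
            elif ch == "I":
                i_cols += ln
            elif ch == "D":
                d_cols += ln
    columns = eq + xx + i_cols + d_cols
    matches = eq
    identity = 100.0 * matches / columns if columns else 0.0
    if identity < min_identity:
        return None
    score = matches * 1.0 - (res["editDistance"]) * 2.0
    e = evalue(score, len(read), len(qseq), KA_READ)
    if e > e_max:
        return None
    start, end = res["locations"][0]
    return ReadMapping(
        read_id=read_id,
        query_id=query_id,
        query_span=(start + 1, end + 1),
        identity=identity,
        e_value=e,
        full_length=True,
        strand=strand,
    )


def map_read(
    read: str,
    queries: JunctionQuerySet,
    e_max: float = 1e-5,
    min_identity: float = 99.0,
    read_id: str = "read",
    local_fallback: bool = True,
) -> list[ReadMapping]:
    """Best qualifying mapping of one read per query (both orientations).

    A full-length (semi-global) alignment is tried first; if no full-length
    mapping passes the thresholds, the best local alignment is reported
    instead when it does (``full_length=False`` — such mappings can never be
    meaningful but are useful diagnostics).
    """
    read = read.upper()
    if len(read) < MIN_READ_LEN:
        return []
    rc = revcomp(read)
    mappings: list[ReadMapping] = []
    for query_id in ("initial", "ins5", "ins3"):
        qseq = queries.query(query_id)
        best: ReadMapping | None = None
        for strand, r in (("+", read), ("-", rc)):
            m = _edlib_mapping(r, read_id, query_id, qseq, strand, e_max, min_identity)
            if m is not None and (best is None or m.identity > best.identity):
                best = m
        if best is None and local_fallback:
            best = _local_mapping(read, rc, read_id, query_id, qseq, e_max, min_identity)
        if best is not None:
            mappings.append(best)
    return mappings


def _local_mapping(read: str, rc: str, read_id: str, query_id: str, qseq: str,
                   e_max: float, min_identity: float) -> ReadMapping | None:
    aligner = read_local_aligner()
    best = None
    for strand, r in (("+", read), ("-", rc)):
        alns = aligner.align(qseq, r)
        if len(alns) == 0 or alns.score <= 0:
            continue
        stats = summarize(alns[0])
        if best is None or stats.score > best[0].score:
            best = (stats, strand, r)
    if best is None:
        return None
    stats, strand, r = best
    e = evalue(stats.score, len(r), len(qseq), KA_READ)
    if stats.identity_pct < min_identity or e > e_max:
        return None
    full = stats.query_span == (0, len(r))
    return ReadMapping(
        read_id=read_id,
        query_id=query_id,
        query_span=(stats.target_span[0] + 1, stats.target_span[1]),
        identity=stats.identity_pct,
        e_value=e,
        full_length=full,
        strand=strand,
    )


def is_meaningful(mapping: ReadMapping, queries: JunctionQuerySet) -> bool:
    """Full-length mapped and covering the whole junction window."""
    w0, w1 = queries.junction_window
    s, e = mapping.query_span
    return mapping.full_length and s <= w0 and e >= w1


class _ReadScreen:
    """k-mer prescreen: a read can only map full-length at >=99% identity if
    it shares a long exact stretch with a query, hence a sampled k-mer."""

    def __init__(self, queries: JunctionQuerySet):
        self.kmers: set[str] = set()
        for qid in ("initial", "ins5", "ins3"):
            q = queries.query(qid)
            for s in (q, revcomp(q)):
                for i in range(len(s) - SCREEN_KMER + 1):
                    self.kmers.add(s[i : i + SCREEN_KMER])

    def passes(self, read: str) -> bool:
        k = SCREEN_KMER
        n = len(read)
        if n < k:
            return False
        for i in range(0, n - k + 1, SCREEN_STRIDE):
            if read[i : i + k] in self.kmers:
                return True
        return read[n - k :] in self.kmers


def call_presence(
    reads: Iterable, queries: JunctionQuerySet, e_max: float = 1e-5, min_identity: float = 99.0
) -> tuple[int, int]:
    """Count meaningful insertion-supporting and empty-locus-supporting reads.

    A read counts once toward ``n_ins_reads`` if meaningful on ins5 or ins3;
    once toward ``n_empty_reads`` if meaningful on initial.  A read
    meaningful on both sides (possible only under pathological query
    overlap) is discarded with a log entry.
    """
    screen = _ReadScreen(queries)
    n_ins = 0
    n_empty = 0
    for item in reads:
        if isinstance(item, tuple):
            read_id, seq = item
        else:
            read_id, seq = "read", str(item)
        seq = seq.upper()
        if len(seq) < MIN_READ_LEN or not screen.passes(seq):
            continue
        mappings = map_read(seq, queries, e_max, min_identity, read_id=read_id, local_fallback=False)
        ins_hit = any(
            m.query_id in ("ins5", "ins3") and is_meaningful(m, queries) for m in mappings
        )
        empty_hit = any(m.query_id == "initial" and is_meaningful(m, queries) for m in mappings)
        if ins_hit and empty_hit:
            logger.warning("read %s meaningful on both insertion and initial queries; discarded", read_id)
            continue
        if ins_hit:
            n_ins += 1
        elif empty_hit:
            n_empty += 1
    return n_ins, n_empty


def genotype_sample(
    counts: tuple[int, int],
    sample_kind: str = "individual",
    pool_size: int | None = None,
    sample_id: str = "sample",
    locus_id: str = "locus",
) -> GenotypeCall:
    """Infer the diploid genotype (or pool-level state) from read counts.

    Individuals: i/i with only insertion evidence, -/- with only empty
    evidence, i/- with both, nocall with neither.  Pools yield a usable
    (homozygous) call only under single-state evidence; mixed evidence is
    recorded as pool-level heterozygosity and excluded from individual-based
    frequency math.
    """
    n_ins, n_empty = counts
    if sample_kind == "pool_with_size" and pool_size is None:
        raise ValueError("pool_with_size sample requires pool_size")
    if n_ins == 0 and n_empty == 0:
        genotype = "nocall"
    elif n_ins > 0 and n_empty == 0:
        genotype = "ii"
    elif n_ins == 0 and n_empty > 0:
        genotype = "--"
    else:
        genotype = "i-"
    return GenotypeCall(
        sample_id=sample_id,
        locus_id=locus_id,
        n_ins_reads=n_ins,
        n_empty_reads=n_empty,
        genotype=genotype,
        sample_kind=sample_kind,
        pool_size=pool_size,
    )


def population_frequencies(
    calls: Sequence[GenotypeCall], groups: Mapping[str, str]
) -> list[PopulationFrequencies]:
    """Per-group genotype and allele frequencies for one locus.

    Individuals contribute their diploid call; pools with a known size and
    single-state evidence contribute ``pool_size`` homozygous individuals.
    Frequencies are withheld (``reported=False``) when the group has 4 or
    fewer contributing individuals (the IN > 4 rule).
    """
    loci = {c.locus_id for c in calls}
    if len(loci) > 1:
        raise ValueError("population_frequencies expects calls for a single locus")
    locus_id = loci.pop() if loci else "locus"
    by_group: dict[str, list[GenotypeCall]] = {}
    for call in calls:
        group = groups.get(call.sample_id, "all")
        by_group.setdefault(group, []).append(call)
    out = []
    for group in sorted(by_group):
        n = {"ii": 0, "i-": 0, "--": 0}
        n_samples = 0
        for call in by_group[group]:
            if call.genotype == "nocall":
                continue
            n_samples += 1
            if call.sample_kind == "individual" or call.sample_kind == "unknown":
                if call.sample_kind == "individual":
                    n[call.genotype] += 1
            elif call.sample_kind == "pool_with_size":
                if call.genotype in ("ii", "--"):
                    n[call.genotype] += call.pool_size or 0
                # mixed pools: heterozygosity evidence only
            # pool_unsized: presence evidence only, never enters the counts
        n_ind = n["ii"] + n["i-"] + n["--"]
        reported = n_ind > 4
        if n_ind > 0:
            freq_i = (2 * n["ii"] + n["i-"]) / (2 * n_ind)
            gfreqs = {g: n[g] / n_ind for g in ("ii", "i-", "--")}
        else:
            freq_i = None
            gfreqs = None
        out.append(
            PopulationFrequencies(
                locus_id=locus_id,
                group_id=group,
                n_individuals=n_ind,
                freq_i=freq_i if reported else None,
                freq_empty=(1.0 - freq_i) if (reported and freq_i is not None) else None,
                genotype_freqs=gfreqs if reported else None,
                reported=reported,
                n_samples_total=n_samples,
            )
        )
    return out


def genotype_individual(
    reads: Iterable, queries: JunctionQuerySet, sample_id: str = "sample",
    sample_kind: str = "individual", pool_size: int | None = None,
) -> GenotypeCall:
    """Convenience: call_presence + genotype_sample for one sample."""
    counts = call_presence(reads, queries)
    return genotype_sample(
        counts, sample_kind=sample_kind, pool_size=pool_size,
        sample_id=sample_id, locus_id=queries.locus_id,
    )


__all__ = [
    "JunctionQuerySet",
    "ReadMapping",
    "GenotypeCall",
    "PopulationFrequencies",
    "build_junction_queries",
    "map_read",
    "is_meaningful",
    "call_presence",
    "genotype_sample",
    "population_frequencies",
    "genotype_individual",
    "MIN_READ_LEN",
]
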