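"""Detection of proviral elements bounded by identical long terminal repeats.

A provirus integrates with two *identical* LTRs; the pair only diverges
afterwards, so exact LTR identity marks a very recent insertion.  This module
finds such loci with a from-scratch k-mer seed + exact bidirectional
extension scan (a desk-scale replacement for an LTRharvest-style search run
at a 100% similarity threshold) and locates the target-site duplication
(TSD) that integration leaves on both flanks.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from ._align import ltr_global_aligner, revcomp, summarize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    """Bounds for the identical-LTR scan.

    ``ltr_similarity_pct`` is fixed at 100: only exactly identical repeat
    pairs are candidates.  Element-span and LTR-length defaults follow common
    LTR-retroelement mining conventions.
    """

    min_ltr_len: int = 100
    max_ltr_len: int = 2000
    min_element_span: int = 1000
    max_element_span: int = 15000
    ltr_similarity_pct: float = 100.0
    tsd_min: int = 4
    tsd_max: int = 20
    seed_kmer: int = 20

    def __post_init__(self) -> None:
        if self.min_ltr_len < self.seed_kmer:
            raise ValueError("min_ltr_len must be >= seed_kmer")
        if self.min_element_span <= 2 * self.min_ltr_len:
            raise ValueError("min_element_span must exceed twice min_ltr_len")
        if not (0 < self.ltr_similarity_pct <= 100):
            raise ValueError("ltr_similarity_pct must be in (0, 100]")
        if self.tsd_min > self.tsd_max:
            raise ValueError("tsd_min must be <= tsd_max")


@dataclass
class ProvirusCandidate:
    """A locus with paired identical LTR spans; the unit flowing through all filters."""

    contig_id: str
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    element_span: tuple[int, int]
    tsd_seq: str | None = None
    strand: str = "+"
    ltr_identity: float = 100.0
    notes: list[str] = field(default_factory=list)

    @property
    def locus_id(self) -> str:
        return f"{self.contig_id}:{self.element_span[0] + 1}-{self.element_span[1]}"

    @property
    def ltr_len(self) -> int:
        return self.ltr5_span[1] - self.ltr5_span[0]

    @property
    def element_len(self) -> int:
        return self.element_span[1] - self.element_span[0]


def as_seq_dict(genome) -> dict[str, str]:
    """Accept a mapping id->sequence or an iterable of SeqRecord-likes."""
    if isinstance(genome, Mapping):
        return {str(k): str(v).upper() for k, v in genome.items()}
    out = {}
    for rec in genome:
        out[str(rec.id)] = str(rec.seq).upper()
    return out


def find_identical_ltr_pairs(genome, params: ScanParams | None = None) -> list[ProvirusCandidate]:
    """Find maximal identical repeat pairs consistent with a proviral LTR pair.

    Every returned candidate carries two exact-match repeat spans of length
    within ``[min_ltr_len, max_ltr_len]`` whose enclosing span respects the
    element-span bounds, and no returned pair can be extended by one base on
    either side while remaining identical and in-bounds.  Overlapping
    candidates from nested repeats are resolved by keeping the longest
    element (ties: leftmost start).  N bases never match.
    """
    params = params or ScanParams()
    seqs = as_seq_dict(genome)
    candidates: list[ProvirusCandidate] = []
    for contig_id in sorted(seqs):
        seq = seqs[contig_id]
        if len(seq) < params.min_element_span:
            logger.info(
                "skipping contig %s: length %d < min_element_span %d",
                contig_id, len(seq), params.min_element_span,
            )
            continue
        candidates.extend(_scan_contig(contig_id, seq, params))
    candidates.sort(key=lambda c: (c.contig_id, c.element_span[0], c.element_span[1]))
    return candidates


def _scan_contig(contig_id: str, seq: str, params: ScanParams) -> list[ProvirusCandidate]:
    k = params.seed_kmer
    n = len(seq)
    # distance between LTR starts: element span = dist + ltr_len
    min_dist = max(params.min_ltr_len, params.min_element_span - params.max_ltr_len)
    max_dist = params.max_element_span - params.min_ltr_len

    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    # seed pairs grouped by diagonal (distance between repeat copies)
    diagonals: dict[int, set[int]] = {}
    for positions in index.values():
        if len(positions) < 2:
            continue
        for a_idx in range(len(positions)):
            for b_idx in range(a_idx + 1, len(positions)):
                d = positions[b_idx] - positions[a_idx]
                if min_dist <= d <= max_dist:
                    diagonals.setdefault(d, set()).add(positions[a_idx])

    raw: list[ProvirusCandidate] = []
    seen: set[tuple[int, int]] = set()
    for d, starts in diagonals.items():
        for p in sorted(starts):
            left, right = _extend(seq, p, p + k, d)
            key = (left, d)
            if key in seen:
                continue
            seen.add(key)
            ltr_len = right - left
            if not (params.min_ltr_len <= ltr_len <= params.max_ltr_len):
                continue
            if right > left + d:  # repeat copies overlap: not a provirus geometry
                continue
            element = (left, right + d)
            span_len = element[1] - element[0]
            if not (params.min_element_span <= span_len <= params.max_element_span):
                continue
            raw.append(
                ProvirusCandidate(
                    contig_id=contig_id,
                    ltr5_span=(left, right),
                    ltr3_span=(left + d, right + d),
                    element_span=element,
                    ltr_identity=100.0,
                )
            )
    return _resolve_overlaps(raw)


def _extend(seq: str, left: int, right: int, d: int) -> tuple[int, int]:
    """Maximal exact bidirectional extension of the repeat pair on diagonal d."""
    n = len(seq)
    while left > 0 and seq[left - 1] == seq[left - 1 + d] and seq[left - 1] != "N":
        left -= 1
    while right + d < n and seq[right] == seq[right + d] and seq[right] != "N":
        right += 1
    return left, right


def _resolve_overlaps(cands: list[ProvirusCandidate]) -> list[ProvirusCandidate]:
    ordered = sorted(
        cands, key=lambda c: (-(c.element_span[1] - c.element_span[0]), c.element_span[0])
    )
    kept: list[ProvirusCandidate] = []
    for cand in ordered:
        s, e = cand.element_span
        if any(s < k.element_span[1] and k.element_span[0] < e for k in kept):
            continue
        kept.append(cand)
    return kept


def detect_tsd(genome, candidate: ProvirusCandidate, params: ScanParams | None = None) -> ProvirusCandidate:
    """Fill in the target-site duplication for a candidate.

    The TSD is the longest exact match between the bases immediately 5' and
    immediately 3' of the element, with length within ``[tsd_min, tsd_max]``.
    Candidates too close to a contig edge get ``tsd_seq = None`` and a flag.
    """
    params = params or ScanParams()
    seqs = as_seq_dict(genome)
    seq = seqs[candidate.contig_id]
    s, e = candidate.element_span
    if s < params.tsd_max or e + params.tsd_max > len(seq):
        return replace(candidate, tsd_seq=None, notes=candidate.notes + ["tsd_at_contig_edge"])
    for length in range(params.tsd_max, params.tsd_min - 1, -1):
        left = seq[s - length : s]
        right = seq[e : e + length]
        if "N" not in left and left == right:
            return replace(candidate, tsd_seq=left)
    return replace(candidate, tsd_seq=None)


def ltr_identity(ltr_a: str, ltr_b: str) -> float:
    """Percent identity between two LTRs.

    Equal-length inputs are compared position-wise (N never matches);
    unequal lengths go through a global alignment (match +1, mismatch -1,
    gap -2) with identity reported over alignment columns.
    """
    if not ltr_a or not ltr_b:
        raise ValueError("LTR sequences must be non-empty")
    a, b = ltr_a.upper(), ltr_b.upper()
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "N")
        return 100.0 * matches / len(a)
    aligner = ltr_global_aligner()
    stats = summarize(aligner.align(a, b)[0])
    return stats.identity_pct


__all__ = [
    "ScanParams",
    "ProvirusCandidate",
    "find_identical_ltr_pairs",
    "detect_tsd",
    "ltr_identity",
    "as_seq_dict",
    "revcomp",
]
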