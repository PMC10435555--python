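"""Shared pairwise-alignment kernels and Karlin–Altschul e-values.

All similarity searches in the package run through Biopython's
:class:`Bio.Align.PairwiseAligner` (exact dynamic programming) or edlib
(bit-parallel semi-global edit distance) so that results are deterministic
and reproducible without an external search engine.  E-values use the
Karlin–Altschul formula ``E = K * m * n * exp(-lambda * S)`` with standard
published parameter sets for the scoring schemes below.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters (lambda, K) for the scoring schemes used here.
# BLOSUM62 with gap open 11 / extend 1; nucleotide match 2 / mismatch -3 with
# gap open 5 / extend 2; and simple match 1 / mismatch -2 (ungapped-style).
KA_PROTEIN = (0.267, 0.041)
KA_NUC = (0.625, 0.41)
KA_READ = (1.28, 0.46)


def evalue(score: float, m: int, n: int, params: tuple[float, float]) -> float:
    """Karlin-Altschul expected number of chance hits at this score."""
    lam, k = params
    x = k * m * n * math.exp(-lam * score)
    return x


def protein_local_aligner() -> Align.PairwiseAligner:
    """Local protein aligner: BLOSUM62, affine gaps 11/1 (tBLASTn-style)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def nuc_local_aligner() -> Align.PairwiseAligner:
    """Local nucleotide aligner with megablast-like scores (2/-3, gaps 5/2)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nuc_matrix(2.0, -3.0)
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def read_local_aligner() -> Align.PairwiseAligner:
    """Local aligner for short-read mapping fallback (1/-2, gaps 2.5/0.5)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _nuc_matrix(1.0, -2.0)
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def ltr_global_aligner() -> Align.PairwiseAligner:
    """Global aligner for LTR-vs-LTR identity (match 1, mismatch -1, gap -2)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _nuc_matrix(1.0, -1.0)
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _nuc_matrix(match: float, mismatch: float):
    # N never matches anything, itself included: assembly gaps must not
    # manufacture identity.
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                mat[a, b] = match
            else:
                mat[a, b] = mismatch
    return mat


@dataclass(frozen=True)
class AlnStats:
    """Summary of one pairwise alignment."""

    score: float
    identities: int
    mismatches: int
    gaps: int
    columns: int
    target_span: tuple[int, int]  # 0-based half-open on the first sequence
    query_span: tuple[int, int]  # 0-based half-open on the second sequence
    target_aligned: int  # target bases inside aligned blocks (gaps excluded)
    query_aligned: int

    @property
    def identity_pct(self) -> float:
        """Identity over alignment columns; gaps count as mismatches."""
        if self.columns == 0:
            return 0.0
        return 100.0 * self.identities / self.columns


def summarize(alignment) -> AlnStats:
    counts = alignment.counts()
    tblocks, qblocks = alignment.aligned
    t_span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    t_aln = int(sum(b[1] - b[0] for b in tblocks))
    q_aln = int(sum(b[1] - b[0] for b in qblocks))
    cols = counts.gaps + counts.identities + counts.mismatches
    return AlnStats(
        score=float(alignment.score),
        identities=int(counts.identities),
        mismatches=int(counts.mismatches),
        gaps=int(counts.gaps),
        columns=int(cols),
        target_span=t_span,
        query_span=q_span,
        target_aligned=t_aln,
        query_aligned=q_aln,
    )


def best_local(aligner: Align.PairwiseAligner, target: str, query: str) -> AlnStats | None:
    """Best-scoring local alignment of query against target, or None."""
    if not target or not query:
        return None
    alignments = aligner.align(target, query)
    if len(alignments) == 0:
        return None
    best = alignments[0]
    if best.score <= 0:
        return None
    return summarize(best)


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]
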