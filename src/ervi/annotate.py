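"""Retroviral classification and replication-intactness filtering.

An identical-LTR candidate is kept as an ERVi candidate only if it is
retroviral (its reverse transcriptase is closer to retroviral RTs than to
retrotransposon RTs) and replication-intact: gag, pro, pol and env open
reading frames at least 80% of the shortest corresponding ORF in the
reference panel, no premature stop codons, RT-RH-IN domain order in Pol and
a transmembrane stretch in Env.

Domain presence uses configurable ordered motif profiles (regular
expressions matched in order within the peptide) plus a Kyte-Doolittle
hydropathy rule for the transmembrane helix; the profiles ship as editable
defaults and are part of the reference panel.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Seq import Seq

from ._align import KA_PROTEIN, best_local, evalue, protein_local_aligner
from .ltr_scan import ProvirusCandidate

logger = logging.getLogger(__name__)

CORE_GENES = ("gag", "pro", "pol", "env")

#: Ordered motif profiles for the Pol domains.  RT carries the canonical
#: LPQG and Y[MVIL]DD catalytic motifs; the RH and IN profiles are the toy
#: panel's signature motifs and are user-replaceable for real data.
DEFAULT_MOTIFS: dict[str, list[str]] = {
    "RT": ["LPQG", "Y[MVIL]DD"],
    "RH": ["DASQKG"],
    "IN": ["HLHTGE"],
}

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

TM_WINDOW = 19
TM_MEAN_HYDROPATHY = 1.6
MIN_ORF_CODONS = 25


@dataclass
class PanelGenome:
    """One toy reference retrovirus: full proviral sequence plus gene layout."""

    genome_id: str
    seq: str
    ltr_len: int
    gene_spans: dict[str, tuple[int, int]]  # coding span incl. ATG, excl. stop
    gene_aa: dict[str, str]


@dataclass
class ReferencePanel:
    """Reference retrovirus panel driving classification and intactness rules.

    ``orf_min_len`` holds, per core gene, 80% of the shortest ORF length
    among the panel's classified retroviruses — the intactness cutoff.
    """

    rt_queries: dict[str, str]
    decoy_rts: dict[str, str]
    orf_min_len: dict[str, int]
    motif_profiles: dict[str, list[str]] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    gene_proteins: dict[str, dict[str, str]] = field(default_factory=dict)
    genomes: dict[str, PanelGenome] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [g for g in CORE_GENES if g not in self.orf_min_len]
        if missing:
            raise ValueError(f"orf_min_len missing genes: {missing}")
        if not self.rt_queries:
            raise ValueError("rt_queries must be non-empty")


@dataclass
class OrfAnnotation:
    gene: str  # gag/pro/pol/env/other
    span: tuple[int, int]  # half-open, on the element, ATG..before stop
    frame: int  # 0/1/2
    strand: str  # +/-
    aa_len: int
    has_premature_stop: bool = False
    peptide: str = ""
    score: float = 0.0


@dataclass
class RTHit:
    query_id: str
    score: float
    e_value: float
    aa_len: int
    frame: int
    strand: str
    peptide: str


@dataclass
class ERViRecord:
    candidate: ProvirusCandidate
    rt_hit: RTHit | None = None
    classification: str = "unclassified"  # retrovirus/retrotransposon/unclassified
    orfs: list[OrfAnnotation] = field(default_factory=list)
    domain_flags: dict[str, bool] = field(default_factory=dict)
    domain_positions: dict[str, int | None] = field(default_factory=dict)
    verdict: str | None = None  # pass/fail
    fail_reasons: list[str] = field(default_factory=list)


def six_frame_translate(seq: str) -> list[tuple[int, str, str]]:
    """Translate all six frames; returns (frame, strand, peptide) triples.

    Stops are rendered as ``*`` and never dropped; N-containing codons
    translate to ``X``.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if re.search(r"[^ACGTN]", seq):
        raise ValueError("sequence contains non-ACGTN characters")
    frames = []
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for frame in range(3):
            sub = s[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            pep = str(Seq(sub).translate()) if sub else ""
            frames.append((frame, strand, pep))
    return frames


def rt_homology_search(candidate_seq: str, panel: ReferencePanel, e_max: float = 1e-5) -> RTHit | None:
    """Best retroviral-RT homology hit in the six translated frames.

    A hit qualifies only if its e-value is at or below ``e_max``, the
    aligned region exceeds 100 aa and contains no stop codon.
    """
    if not panel.rt_queries:
        raise ValueError("reference panel has no RT queries")
    aligner = protein_local_aligner()
    best: RTHit | None = None
    frames = six_frame_translate(candidate_seq)
    for frame, strand, pep in frames:
        if not pep:
            continue
        for qid, query in panel.rt_queries.items():
            stats = best_local(aligner, pep, query)
            if stats is None:
                continue
            e = evalue(stats.score, len(pep), len(query), KA_PROTEIN)
            if e > e_max or stats.columns <= 100:
                continue
            region = pep[stats.target_span[0] : stats.target_span[1]]
            if "*" in region:
                continue
            if best is None or stats.score > best.score:
                best = RTHit(
                    query_id=qid,
                    score=stats.score,
                    e_value=e,
                    aa_len=stats.columns,
                    frame=frame,
                    strand=strand,
                    peptide=region,
                )
    return best


def classify_rt(hit_peptide: str, panel: ReferencePanel, margin: float = 0.10) -> str:
    """Nearest-reference classification of an RT peptide.

    The peptide is aligned against retroviral RT queries and retrotransposon
    decoy RTs; the winning class labels the peptide unless the two class
    best-scores are within ``margin`` of the top score (then unclassified).
    """
    if len(hit_peptide) <= 100:
        raise ValueError("RT peptide must exceed 100 aa")
    if not panel.decoy_rts:
        logger.warning("no decoy RTs in panel; classification degenerates to retrovirus")
        return "retrovirus"
    aligner = protein_local_aligner()

    def class_score(refs: Mapping[str, str]) -> float:
        scores = [0.0]
        for ref in refs.values():
            stats = best_local(aligner, hit_peptide, ref)
            if stats is not None:
                scores.append(stats.score)
        return max(scores)

    s_retro = class_score(panel.rt_queries)
    s_decoy = class_score(panel.decoy_rts)
    top = max(s_retro, s_decoy)
    if top <= 0 or abs(s_retro - s_decoy) < margin * top:
        return "unclassified"
    return "retrovirus" if s_retro > s_decoy else "retrotransposon"


def _raw_orfs(seq: str) -> list[OrfAnnotation]:
    """ATG..stop ORFs of >= MIN_ORF_CODONS codons in all six frames."""
    n = len(seq)
    orfs = []
    for frame, strand, pep in six_frame_translate(seq):
        pos = 0
        while True:
            start = pep.find("M", pos)
            if start == -1:
                break
            stop = pep.find("*", start)
            end = stop if stop != -1 else len(pep)
            aa_len = end - start
            if aa_len >= MIN_ORF_CODONS:
                nt_start = frame + 3 * start
                nt_end = frame + 3 * end
                if strand == "-":
                    span = (n - nt_end, n - nt_start)
                else:
                    span = (nt_start, nt_end)
                orfs.append(
                    OrfAnnotation(
                        gene="other",
                        span=span,
                        frame=frame,
                        strand=strand,
                        aa_len=aa_len,
                        peptide=pep[start:end],
                    )
                )
            pos = (stop + 1) if stop != -1 else len(pep)
    return orfs


def annotate_orfs(candidate_seq: str, panel: ReferencePanel) -> list[OrfAnnotation]:
    """Predict ORFs and label gag/pro/pol/env by best panel-protein alignment.

    Premature stops are recognized by aligning each gene's reference
    peptides through the frame translation (stops kept): a ``*`` inside the
    aligned region flags the gene, and the reported span is the containing
    ATG->stop ORF (hence truncated).
    """
    seq = candidate_seq.upper()
    if len(seq) < 3:
        return []
    orfs = _raw_orfs(seq)
    if not panel.gene_proteins:
        return sorted(orfs, key=lambda o: o.span)
    aligner = protein_local_aligner()
    frames = six_frame_translate(seq)

    # Per gene, find the best alignment of any reference peptide in any frame.
    for gene in CORE_GENES:
        refs = panel.gene_proteins.get(gene, {})
        best = None  # (score, frame, strand, stats)
        for frame, strand, pep in frames:
            if not pep:
                continue
            for ref in refs.values():
                stats = best_local(aligner, pep, ref)
                if stats is None:
                    continue
                e = evalue(stats.score, len(pep), len(ref), KA_PROTEIN)
                if e > 1e-5:
                    continue
                if best is None or stats.score > best[0]:
                    best = (stats.score, frame, strand, stats, pep)
        if best is None:
            continue
        score, frame, strand, stats, pep = best
        region = pep[stats.target_span[0] : stats.target_span[1]]
        premature = "*" in region
        # the ORF containing the alignment start, same frame and strand
        target = None
        aln_nt_start = frame + 3 * stats.target_span[0]
        n = len(seq)
        if strand == "-":
            aln_span = (n - (frame + 3 * stats.target_span[1]), n - aln_nt_start)
        else:
            aln_span = (aln_nt_start, frame + 3 * stats.target_span[1])
        for orf in orfs:
            if orf.frame == frame and orf.strand == strand and orf.gene == "other":
                if orf.span[0] < aln_span[1] and aln_span[0] < orf.span[1]:
                    if target is None or orf.aa_len > target.aa_len:
                        target = orf
        if target is not None and score > target.score:
            target.gene = gene
            target.score = score
            target.has_premature_stop = premature
    labeled = {o.gene: o for o in orfs if o.gene != "other"}
    # non-overlap among labeled genes: drop the lower-scoring of any clash
    genes = sorted(labeled.values(), key=lambda o: -o.score)
    kept: list[OrfAnnotation] = []
    for orf in genes:
        clash = any(
            orf.span[0] < k.span[1] and k.span[0] < orf.span[1] and k.strand == orf.strand
            and k.frame == orf.frame and k is not orf
            for k in kept
        )
        if clash:
            orf.gene = "other"
        else:
            kept.append(orf)
    return sorted(orfs, key=lambda o: o.span)


def check_domain_architecture(
    pol_peptide: str, env_peptide: str, panel: ReferencePanel
) -> tuple[dict[str, bool], dict[str, int | None]]:
    """RT/RH/IN presence and order in Pol, TM presence in Env.

    Each Pol domain is present when all its ordered motif patterns match in
    order; the three domains must additionally appear in the order
    RT < RH < IN, else the architecture is reported absent.  TM presence is
    a hydrophobic stretch: some window of ``TM_WINDOW`` residues in Env with
    mean Kyte-Doolittle hydropathy >= ``TM_MEAN_HYDROPATHY``.
    """
    if not pol_peptide or not env_peptide:
        raise ValueError("peptides must be non-empty")
    positions: dict[str, int | None] = {}
    for domain in ("RT", "RH", "IN"):
        positions[domain] = _find_ordered_motifs(pol_peptide, panel.motif_profiles.get(domain, []))
    flags = {d: positions[d] is not None for d in ("RT", "RH", "IN")}
    if all(flags.values()):
        ordered = positions["RT"] < positions["RH"] < positions["IN"]  # type: ignore[operator]
        if not ordered:
            flags = {d: False for d in ("RT", "RH", "IN")}
    tm_pos = _find_tm(env_peptide)
    flags["TM"] = tm_pos is not None
    positions["TM"] = tm_pos
    return flags, positions


def _find_ordered_motifs(peptide: str, patterns: Sequence[str]) -> int | None:
    if not patterns:
        return None
    pos = 0
    first = None
    for pat in patterns:
        m = re.search(pat, peptide[pos:])
        if m is None:
            return None
        start = pos + m.start()
        if first is None:
            first = start
        pos = pos + m.end()
    return first


def _find_tm(peptide: str) -> int | None:
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in peptide]
    w = TM_WINDOW
    if len(vals) < w:
        return None
    window_sum = sum(vals[:w])
    best_pos = None
    for i in range(len(vals) - w + 1):
        if i > 0:
            window_sum += vals[i + w - 1] - vals[i - 1]
        if window_sum / w >= TM_MEAN_HYDROPATHY:
            best_pos = i
            break
    return best_pos


def check_intactness(record: ERViRecord, panel: ReferencePanel) -> ERViRecord:
    """Fill the pass/fail verdict from classification, ORFs and domains.

    The verdict is a pure function of its inputs; each violated rule appends
    a reason code: not_retroviral, missing_gene:X, short_orf:X,
    premature_stop:X, order_violation, domain_missing:Y.
    """
    reasons: list[str] = []
    if record.classification != "retrovirus":
        reasons.append("not_retroviral")
    by_gene = {o.gene: o for o in record.orfs if o.gene in CORE_GENES}
    for gene in CORE_GENES:
        orf = by_gene.get(gene)
        if orf is None:
            reasons.append(f"missing_gene:{gene}")
            continue
        if orf.has_premature_stop:
            reasons.append(f"premature_stop:{gene}")
        if orf.aa_len < panel.orf_min_len[gene]:
            reasons.append(f"short_orf:{gene}")
    if all(g in by_gene for g in CORE_GENES):
        starts = [by_gene[g].span[0] for g in CORE_GENES]
        if starts != sorted(starts):
            reasons.append("order_violation")
    for domain in ("RT", "RH", "IN", "TM"):
        if not record.domain_flags.get(domain, False):
            reasons.append(f"domain_missing:{domain}")
    record.fail_reasons = reasons
    record.verdict = "pass" if not reasons else "fail"
    return record


def annotate_element(
    element_seq: str, candidate: ProvirusCandidate, panel: ReferencePanel, ltr_len: int | None = None
) -> ERViRecord:
    """Run the full annotation cascade on one element.

    ``element_seq`` is the element including LTRs; homology and ORF search
    run on the interior (between the LTRs) when ``ltr_len`` is known, else
    on the whole element.
    """
    ltr_len = ltr_len if ltr_len is not None else candidate.ltr_len
    interior = element_seq[ltr_len : len(element_seq) - ltr_len] if ltr_len else element_seq
    record = ERViRecord(candidate=candidate)
    record.rt_hit = rt_homology_search(interior, panel)
    if record.rt_hit is None or len(record.rt_hit.peptide) <= 100:
        # no qualifying hit, or the gap-inflated alignment leaves too short a
        # peptide to place: cannot be confirmed retroviral
        record.classification = "unclassified"
    else:
        record.classification = classify_rt(record.rt_hit.peptide, panel)
    record.orfs = annotate_orfs(interior, panel)
    by_gene = {o.gene: o for o in record.orfs if o.gene in CORE_GENES}
    pol = by_gene.get("pol")
    env = by_gene.get("env")
    if pol is not None and env is not None and pol.peptide and env.peptide:
        record.domain_flags, record.domain_positions = check_domain_architecture(
            pol.peptide, env.peptide, panel
        )
    else:
        record.domain_flags = {d: False for d in ("RT", "RH", "IN", "TM")}
        record.domain_positions = {d: None for d in ("RT", "RH", "IN", "TM")}
    return check_intactness(record, panel)


__all__ = [
    "CORE_GENES",
    "DEFAULT_MOTIFS",
    "KYTE_DOOLITTLE",
    "PanelGenome",
    "ReferencePanel",
    "OrfAnnotation",
    "RTHit",
    "ERViRecord",
    "six_frame_translate",
    "rt_homology_search",
    "classify_rt",
    "annotate_orfs",
    "check_domain_architecture",
    "check_intactness",
    "annotate_element",
]
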