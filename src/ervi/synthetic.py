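"""Fully specified synthetic test worlds with machine-readable truth.

The generator builds, from a seed alone: a toy reference retrovirus panel
(gag-pro-pol-env proviruses with the bundled RT/RH/IN motifs and a
transmembrane stretch in Env), repeat-free background genomes, genomes with
implanted proviruses (including decoys that violate exactly one filter
rule), Hardy-Weinberg populations segregating an insertion, and error-prone
short reads.  Every generator is a pure function of (parameters, seed) and
emits truth records, so each pipeline stage can be tested against known
ground truth without any external data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .annotate import CORE_GENES, DEFAULT_MOTIFS, PanelGenome, ReferencePanel

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(aa, []).append(codon)
for codons in _AA_TO_CODONS.values():
    codons.sort()
_AMINO_ACIDS = sorted(_AA_TO_CODONS)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, tag: int) -> np.random.Generator:
    """Namespaced generator stream: different generators fed the same seed
    must not share a random stream (a panel LTR re-appearing verbatim at the
    start of a background would fabricate repeats)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(tag,)))

#: signature motifs embedded in every panel Pol / Env (see annotate.DEFAULT_MOTIFS)
RT_MOTIF_1 = "LPQG"
RT_MOTIF_2 = "YVDD"
RH_MOTIF = "DASQKG"
IN_MOTIF = "HLHTGE"
TM_SEGMENT = "ILVVLLIVALIIVLFLLIV"  # 19-mer, mean Kyte-Doolittle hydropathy >> 1.6


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AMINO_ACIDS, size=length))


def _embed(seq: str, motif: str, pos: int) -> str:
    return seq[:pos] + motif + seq[pos + len(motif) :]


def _encode(rng: np.random.Generator, peptide: str) -> str:
    """Encode a peptide with random synonymous codons (no internal stops)."""
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in peptide)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def make_reference_panel(seed: int = 0, n_genomes: int = 6, n_decoys: int = 2) -> ReferencePanel:
    """Build the toy reference retrovirus panel.

    Each panel genome is LTR + gag + pro + pol + env + LTR with identical
    LTRs; Pol embeds the RT (LPQG, YVDD), RH and IN signature motifs in
    order and Env a hydrophobic transmembrane 19-mer.  ``orf_min_len`` is
    80% of the shortest panel ORF per gene.  Random panel genomes are far
    below 95% pairwise identity, so they cluster into singleton vOTUs.
    """
    rng = _rng(seed, 1)
    genomes: dict[str, PanelGenome] = {}
    rt_queries: dict[str, str] = {}
    gene_proteins: dict[str, dict[str, str]] = {g: {} for g in CORE_GENES}
    for gi in range(n_genomes):
        gid = f"toyRV{gi + 1}"
        ltr_len = int(rng.integers(250, 351))
        ltr = random_dna(rng, ltr_len)
        gene_aa: dict[str, str] = {}
        gene_aa["gag"] = "M" + _random_protein(rng, int(rng.integers(170, 231)))
        gene_aa["pro"] = "M" + _random_protein(rng, int(rng.integers(90, 131)))
        rt_len = int(rng.integers(175, 201))
        rt = _random_protein(rng, rt_len)
        rt = _embed(rt, RT_MOTIF_1, 25)
        rt = _embed(rt, RT_MOTIF_2, 95)
        rh = _embed(_random_protein(rng, int(rng.integers(55, 71))), RH_MOTIF, 20)
        in_ = _embed(_random_protein(rng, int(rng.integers(70, 91))), IN_MOTIF, 25)
        gene_aa["pol"] = "M" + rt + rh + in_
        env_len = int(rng.integers(170, 221))
        env = _random_protein(rng, env_len)
        env = _embed(env, TM_SEGMENT, env_len - 40)
        gene_aa["env"] = "M" + env
        parts = [ltr]
        gene_spans: dict[str, tuple[int, int]] = {}
        pos = ltr_len
        for gene in CORE_GENES:
            spacer = random_dna(rng, int(rng.integers(20, 61)))
            parts.append(spacer)
            pos += len(spacer)
            coding = _encode(rng, gene_aa[gene])
            gene_spans[gene] = (pos, pos + len(coding))
            parts.append(coding + "TAA")
            pos += len(coding) + 3
        parts.append(random_dna(rng, int(rng.integers(20, 61))))
        parts.append(ltr)
        seq = "".join(parts)
        genomes[gid] = PanelGenome(
            genome_id=gid, seq=seq, ltr_len=ltr_len, gene_spans=gene_spans, gene_aa=gene_aa
        )
        rt_queries[f"{gid}_RT"] = "M" + rt
        for gene in CORE_GENES:
            gene_proteins[gene][gid] = gene_aa[gene]
    decoys = {
        f"retrotransposonRT{i + 1}": _random_protein(rng, 200) for i in range(n_decoys)
    }
    orf_min_len = {
        g: math.floor(0.8 * min(len(p) for p in gene_proteins[g].values()))
        for g in CORE_GENES
    }
    return ReferencePanel(
        rt_queries=rt_queries,
        decoy_rts=decoys,
        orf_min_len=orf_min_len,
        motif_profiles=dict(DEFAULT_MOTIFS),
        gene_proteins=gene_proteins,
        genomes=genomes,
    )


# ---------------------------------------------------------------------------
# backgrounds and implants
# ---------------------------------------------------------------------------

def make_background(
    length: int = 100_000,
    seed: int = 0,
    contig_id: str = "chr1",
    seed_kmer: int = 20,
    max_tries: int = 20,
) -> dict[str, str]:
    """Repeat-free random background: no ``seed_kmer``-mer occurs twice,
    so decoy LTR pairs cannot arise by chance."""
    rng = _rng(seed, 2)
    for _ in range(max_tries):
        seq = random_dna(rng, length)
        seen: set[str] = set()
        dup = False
        for i in range(0, length - seed_kmer + 1):
            kmer = seq[i : i + seed_kmer]
            if kmer in seen:
                dup = True
                break
            seen.add(kmer)
        if not dup:
            return {contig_id: seq}
    raise RuntimeError("could not generate repeat-free background")


@dataclass
class ImplantSpec:
    """Recipe for one provirus implant (or decoy)."""

    element_id: str
    source: str  # panel genome id
    contig: str = "chr1"
    position: int = 50_000
    ltr_len: int | None = None  # override the panel LTR (regenerated at this length)
    ltr_divergence: int = 0  # mismatches between the two LTRs; 0 = identical
    tsd_len: int = 5
    disruptions: list[str] = field(default_factory=list)
    # disruption grammar: "none", "premature_stop:<gene>", "frameshift:<gene>",
    # "delete:<gene>", "swap_rt"


@dataclass
class ImplantTruth:
    element_id: str
    contig: str
    element_span: tuple[int, int]
    ltr5_span: tuple[int, int]
    ltr3_span: tuple[int, int]
    ltr_len: int
    tsd_seq: str
    pre_insertion_pos: int
    ltr_divergence: int
    disruptions: list[str]
    expected_scan_hit: bool
    expected_verdict: str  # pass / fail
    expected_fail_reasons: list[str]


def _expected_reasons(disruptions: Sequence[str]) -> list[str]:
    reasons = []
    for d in disruptions:
        if d == "none":
            continue
        kind, _, gene = d.partition(":")
        if kind == "premature_stop":
            reasons.append(f"premature_stop:{gene}")
        elif kind == "frameshift":
            # a frameshift truncates the original-frame ORF or, when the gene
            # is labeled on the shifted-frame fragment, shows as a premature
            # stop there; either reason code is the expected outcome
            reasons.append(f"short_orf:{gene}|premature_stop:{gene}|missing_gene:{gene}")
        elif kind == "delete":
            reasons.append(f"missing_gene:{gene}")
        elif kind == "swap_rt":
            reasons.append("not_retroviral")
        else:
            raise ValueError(f"unknown disruption {d!r}")
    return reasons


_STOPS = {"TAA", "TAG", "TGA"}


def _orf_len_from_atg(seq: str, start: int) -> int:
    """Codons from the ATG at ``start`` to the first in-frame stop."""
    n = 0
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in _STOPS:
            break
        n += 1
    return n


def _frameshift_is_disruptive(trial: str, gene_span: tuple[int, int], cutoff: int) -> bool:
    """No ORF of >= cutoff codons substantially overlaps the (shifted) gene."""
    from .annotate import _raw_orfs

    s, e = gene_span
    for orf in _raw_orfs(trial):
        if orf.aa_len < cutoff:
            continue
        overlap = min(orf.span[1], e) - max(orf.span[0], s)
        if overlap >= 120:  # >= 40 codons: enough to be labeled as the gene
            return False
    return True


def reasons_satisfied(expected: Sequence[str], actual: Sequence[str]) -> bool:
    """Every expected reason present; '|' separates acceptable alternatives."""
    return all(any(alt in actual for alt in item.split("|")) for item in expected)


def _build_element(spec: ImplantSpec, panel: ReferencePanel, rng: np.random.Generator) -> tuple[str, int]:
    """Element sequence (5'LTR..3'LTR) with disruptions applied; returns (seq, ltr_len)."""
    pg = panel.genomes[spec.source]
    seq = pg.seq
    ltr_len = pg.ltr_len
    spans = dict(pg.gene_spans)
    if spec.ltr_len is not None and spec.ltr_len != ltr_len:
        new_ltr = random_dna(rng, spec.ltr_len)
        interior = seq[ltr_len : len(seq) - ltr_len]
        seq = new_ltr + interior + new_ltr
        shift = spec.ltr_len - ltr_len
        spans = {g: (s + shift, e + shift) for g, (s, e) in spans.items()}
        ltr_len = spec.ltr_len
    # apply gene disruptions right-to-left so earlier spans stay valid
    ops = [d for d in spec.disruptions if d not in ("none",)]

    def gene_of(op: str) -> str:
        return op.partition(":")[2] or "pol"

    for op in sorted(ops, key=lambda o: -(spans[gene_of(o)][0] if gene_of(o) in spans else 0)):
        kind, _, gene = op.partition(":")
        if kind == "swap_rt":
            gene = "pol"
        s, e = spans[gene]
        aa_len = (e - s) // 3
        if kind == "premature_stop":
            cpos = s + 3 * (aa_len // 2)
            seq = seq[:cpos] + "TAA" + seq[cpos + 3 :]
        elif kind == "frameshift":
            # choose the insertion codon so that NO reading frame retains a
            # qualifying ORF over the gene: both the original-frame ORF and
            # the shifted-frame fragment (whose containing ORF can extend
            # into flanking garbage) must stay below the intactness cutoff
            cutoff = panel.orf_min_len.get(gene, aa_len)
            cpos = None
            for c in range(aa_len // 3, (2 * aa_len) // 3):
                trial = seq[:s] + seq[s : s + 3 * c] + "A" + seq[s + 3 * c :]
                if _frameshift_is_disruptive(trial, (s, e + 1), cutoff):
                    cpos = s + 3 * c
                    break
            if cpos is None:
                raise RuntimeError(f"no disruptive frameshift position found in {gene}")
            seq = seq[:cpos] + "A" + seq[cpos:]
            spans = {g: (a + (1 if a >= cpos else 0), b + (1 if b >= cpos else 0))
                     for g, (a, b) in spans.items()}
        elif kind == "delete":
            seq = seq[:s] + seq[e + 3 :]  # drop coding plus its stop codon
            cut = e + 3 - s
            spans = {g: ((a - cut if a >= e else a), (b - cut if b >= e else b))
                     for g, (a, b) in spans.items() if g != gene}
        elif kind == "swap_rt":
            decoy = next(iter(sorted(panel.decoy_rts)))
            decoy_aa = panel.decoy_rts[decoy]
            region_aa = min(len(decoy_aa), 160)
            start = s + 3 * 5  # keep the ATG and a short native prefix
            coding = _encode(rng, decoy_aa[:region_aa])
            seq = seq[:start] + coding + seq[start + 3 * region_aa :]
        else:
            raise ValueError(f"unknown disruption {op!r}")
    # LTR divergence: mutate evenly spaced positions of the 3' LTR
    if spec.ltr_divergence > 0:
        seq_l = list(seq)
        n = len(seq)
        L = ltr_len
        for i in range(spec.ltr_divergence):
            off = round((i + 1) * L / (spec.ltr_divergence + 1))
            pos = n - L + min(off, L - 1)
            old = seq_l[pos]
            seq_l[pos] = "ACGT"[("ACGT".index(old) + 1) % 4]
        seq = "".join(seq_l)
    return seq, ltr_len


def implant_provirus(
    background: Mapping[str, str], spec: ImplantSpec, panel: ReferencePanel, seed: int = 0
) -> tuple[dict[str, str], ImplantTruth]:
    """Insert one element into the background with a duplicated target site.

    ``tsd_len`` bases at the insertion point are copied to both flanks.  The
    two element-internal bases adjacent to the LTRs are nudged if they
    coincide with the flanking base on the same side, so the maximal
    identical-repeat extension recovers the LTR spans exactly.
    """
    rng = _rng(seed, 3)
    bg = dict(background)
    contig = bg[spec.contig]
    pos = spec.position
    t = spec.tsd_len
    if pos < 0 or pos + t > len(contig):
        raise ValueError("implant site outside the contig")
    element, ltr_len = _build_element(spec, panel, rng)
    tsd = contig[pos : pos + t]
    left_neighbor = tsd[-1] if t else (contig[pos - 1] if pos else "")
    right_neighbor = tsd[0] if t else (contig[pos] if pos < len(contig) else "")
    element = _nudge_boundaries(element, ltr_len, left_neighbor, right_neighbor)
    new_contig = contig[: pos + t] + element + contig[pos:]
    bg[spec.contig] = new_contig
    s = pos + t
    e = s + len(element)
    truth = ImplantTruth(
        element_id=spec.element_id,
        contig=spec.contig,
        element_span=(s, e),
        ltr5_span=(s, s + ltr_len),
        ltr3_span=(e - ltr_len, e),
        ltr_len=ltr_len,
        tsd_seq=tsd,
        pre_insertion_pos=pos,
        ltr_divergence=spec.ltr_divergence,
        disruptions=list(spec.disruptions),
        expected_scan_hit=spec.ltr_divergence == 0,
        expected_verdict="pass" if not _expected_reasons(spec.disruptions) else "fail",
        expected_fail_reasons=_expected_reasons(spec.disruptions),
    )
    return bg, truth


def _nudge_boundaries(element: str, ltr_len: int, left_neighbor: str, right_neighbor: str) -> str:
    """Keep the maximal identical-LTR extension from overshooting the LTRs."""
    el = list(element)
    # left extension compares base before 5'LTR (flank) with base before 3'LTR
    # (element interior): make them differ
    i = len(el) - ltr_len - 1
    if left_neighbor and el[i] == left_neighbor:
        el[i] = "ACGT"[("ACGT".index(el[i]) + 1) % 4]
    # right extension compares base after 5'LTR (interior) with base after the
    # element (flank)
    j = ltr_len
    if right_neighbor and el[j] == right_neighbor:
        el[j] = "ACGT"[("ACGT".index(el[j]) + 1) % 4]
    return "".join(el)


def build_world(
    background: Mapping[str, str],
    specs: Sequence[ImplantSpec],
    panel: ReferencePanel,
    seed: int = 0,
) -> tuple[dict[str, str], list[ImplantTruth]]:
    """Apply several implants (ascending positions; overlaps are an error)."""
    ordered = sorted(specs, key=lambda s: (s.contig, s.position))
    for a, b in zip(ordered, ordered[1:]):
        if a.contig == b.contig and b.position < a.position + 1:
            raise ValueError("implant sites overlap")
    genome = dict(background)
    truths: list[ImplantTruth] = []
    offset: dict[str, int] = {}
    for i, spec in enumerate(ordered):
        shift = offset.get(spec.contig, 0)
        shifted = ImplantSpec(**{**spec.__dict__, "position": spec.position + shift})
        before = len(genome[spec.contig])
        genome, truth = implant_provirus(genome, shifted, panel, seed=seed + i)
        truth.element_id = spec.element_id
        offset[spec.contig] = shift + (len(genome[spec.contig]) - before)
        truths.append(truth)
    # overlap check against realized spans
    spans = sorted((t.contig, t.element_span) for t in truths)
    for (c1, s1), (c2, s2) in zip(spans, spans[1:]):
        if c1 == c2 and s2[0] < s1[1]:
            raise ValueError("implants overlap after insertion")
    return genome, truths


# ---------------------------------------------------------------------------
# populations and reads
# ---------------------------------------------------------------------------

@dataclass
class IndividualTruth:
    sample_id: str
    genotype: str  # ii / i- / --
    haplotypes: tuple[str, str] = ("", "")  # keys into PopulationTruth.genomes


@dataclass
class PopulationTruth:
    individuals: list[IndividualTruth]
    allele_freq: float
    genomes: dict[str, dict[str, str]] = field(default_factory=dict)  # with/without
    seed: int = 0


def simulate_population(
    genome_with: Mapping[str, str],
    genome_without: Mapping[str, str],
    allele_freq: float,
    n_individuals: int,
    seed: int = 0,
) -> PopulationTruth:
    """Draw diploid genotypes Hardy-Weinberg at ``allele_freq``."""
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if not (0.0 <= allele_freq <= 1.0):
        raise ValueError("allele_freq must be in [0, 1]")
    rng = _rng(seed, 4)
    n_alleles = rng.binomial(2, allele_freq, size=n_individuals)
    individuals = []
    for i, k in enumerate(n_alleles):
        genotype = {2: "ii", 1: "i-", 0: "--"}[int(k)]
        haps = tuple(["with"] * int(k) + ["without"] * (2 - int(k)))
        individuals.append(IndividualTruth(f"ind{i + 1}", genotype, haps))  # type: ignore[arg-type]
    return PopulationTruth(
        individuals=individuals,
        allele_freq=allele_freq,
        genomes={"with": dict(genome_with), "without": dict(genome_without)},
        seed=seed,
    )


def simulate_reads(
    haplotypes: Sequence[str],
    read_len: int = 150,
    coverage: float = 10.0,
    error_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "read",
) -> list[tuple[str, str]]:
    """Uniform-coverage single-end reads over a set of haplotype sequences.

    ``coverage`` is the total (diploid) depth: the expected read count is
    ``ceil(coverage * mean(haplotype length) / read_len)``; reads pick a
    haplotype proportionally to its length, start uniformly, and suffer
    independent per-base substitution errors at ``error_rate``.  Read names
    encode haplotype and start position for debugging.
    """
    if read_len < 30:
        raise ValueError("read_len must be >= 30")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    lengths = np.array([len(h) for h in haplotypes], float)
    if np.any(lengths < read_len):
        raise ValueError("read_len exceeds a haplotype length")
    rng = _rng(seed, 5)
    n_reads = int(math.ceil(coverage * lengths.mean() / read_len))
    hap_idx = rng.choice(len(haplotypes), size=n_reads, p=lengths / lengths.sum())
    reads = []
    for i in range(n_reads):
        h = int(hap_idx[i])
        start = int(rng.integers(0, len(haplotypes[h]) - read_len + 1))
        seq = haplotypes[h][start : start + read_len]
        if error_rate > 0:
            n_err = rng.binomial(read_len, error_rate)
            if n_err:
                seq_l = list(seq)
                for p in rng.choice(read_len, size=n_err, replace=False):
                    seq_l[p] = "ACGT"[("ACGT".index(seq_l[p]) + int(rng.integers(1, 4))) % 4]
                seq = "".join(seq_l)
        reads.append((f"{name_prefix}_h{h}_p{start}_{i}", seq))
    return reads


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def decoy_specs(sites: Sequence[int], contig: str = "chr1") -> list[ImplantSpec]:
    """The standard decoy battery: one intact element plus the five decoy
    classes (divergent LTRs, premature stop, frameshift, retrotransposon RT,
    missing env)."""
    kinds = [
        ("intact", {}),
        ("divergent_ltr", {"ltr_len": 180, "ltr_divergence": 1}),
        ("stop_pol", {"disruptions": ["premature_stop:pol"]}),
        ("frameshift_gag", {"disruptions": ["frameshift:gag"]}),
        ("retrotransposon_rt", {"disruptions": ["swap_rt"]}),
        ("no_env", {"disruptions": ["delete:env"]}),
    ]
    if len(sites) < len(kinds):
        raise ValueError(f"need {len(kinds)} sites")
    return [
        ImplantSpec(
            element_id=name,
            source=f"toyRV{i + 1}",
            contig=contig,
            position=sites[i],
            **kwargs,
        )
        for i, (name, kwargs) in enumerate(kinds)
    ]


__all__ = [
    "make_reference_panel",
    "make_background",
    "random_dna",
    "ImplantSpec",
    "ImplantTruth",
    "implant_provirus",
    "build_world",
    "decoy_specs",
    "IndividualTruth",
    "PopulationTruth",
    "simulate_population",
    "simulate_reads",
    "RT_MOTIF_1",
    "RT_MOTIF_2",
    "RH_MOTIF",
    "IN_MOTIF",
    "TM_SEGMENT",
]
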