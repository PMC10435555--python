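# Methods

This note documents the models, rules and numerical choices behind `ervi`,
what the synthetic worlds do and do not emulate, and the problem sizes the
test suite runs at.

## The ERVi definition and the filter cascade

An element qualifies as an ERVi candidate when three conditions hold:

1. **Identical LTRs.** At integration a provirus carries two identical
   LTRs; they accumulate mutations independently afterwards, so exact
   identity bounds the insertion age to the very recent past. The scan
   requires 100% identity — a single substitution in either LTR removes the
   pair from consideration.
2. **Replication intactness.** The element must look like a functional
   retrovirus: *gag*, *pro*, *pol*, *env* ORFs each at least 80% of the
   shortest corresponding ORF among the reference panel's replication-
   competent retroviruses; no premature stop codons; RT–RH–IN domain order
   in Pol; a transmembrane stretch in Env; and an RT that classifies with
   retroviruses rather than retrotransposons.
3. **Insertional polymorphism.** The insertion segregates in the host
   population, established from junction-spanning reads.

### Identical-LTR scan (`ltr_scan`)

A from-scratch k-mer seed (default 20-mer) + exact bidirectional extension
scanner. Seed pairs are grouped by diagonal (distance between copies) and
extended maximally; a pair is reported when the repeat length lies in
[100, 2000] bp, the enclosing span in [1000, 15000] bp, and the copies do
not overlap. Maximality guarantees the reported spans cannot be extended by
one base and remain identical. `N` never matches anything (assembly gaps
must not fabricate identity). Overlapping candidates from nested repeats
keep the longest element, ties broken leftmost. Coordinates are 0-based
half-open internally and 1-based inclusive in written reports.

The scanner is strand-agnostic: a pair of identical direct repeats looks
the same on either strand, so all candidates are reported on `+` and strand
is left to annotation evidence (e.g., the RT hit's frame). The
reverse-complement of a genome therefore yields the mirror-image candidate
coordinates.

TSD detection is a brute-force window comparison: the longest L in
[tsd_min, tsd_max] (default 4–20) for which the L bases immediately 5' of
the element equal the L bases immediately 3' of it. Candidates too close to
a contig edge are flagged with `tsd_seq` absent.

LTR identity is position-wise for equal-length inputs and otherwise
computed over the columns of a global alignment (match +1, mismatch −1,
gap −2); gaps count as mismatches.

### Homology, ORFs and domains (`annotate`)

All protein searches use exact local dynamic programming (BLOSUM62, affine
gaps 11/1) over six-frame translations with stops kept as `*`; e-values use
the Karlin–Altschul formula with the standard gapped BLOSUM62 parameters
(λ = 0.267, K = 0.041). An RT hit must reach e ≤ 1e-5 over more than 100
aligned columns with no stop inside the aligned region. Classification is
nearest-reference: the best score against retroviral RT queries versus
retrotransposon decoy RTs, with an ambiguity margin (default 10% of the top
score) yielding `unclassified`. This replaces tree-based placement with a
deterministic, directly testable discriminator; users with real data can
substitute their own panels.

ORFs are ATG→stop, ≥25 codons, in all six frames; gene labels come from the
best panel-protein alignment at e ≤ 1e-5. Premature stops are detected by
letting the reference alignment run through the frame translation: a `*`
inside the aligned region flags the gene, and the reported span is the
containing (hence truncated) ORF. A frameshifted gene therefore fails as a
short ORF or as a premature stop depending on which fragment the reference
alignment lands on; both are correct detections of the disruption.

Domain architecture uses ordered motif profiles — regular expressions that
must match in order within the Pol peptide (RT: `LPQG`, `Y[MVIL]DD`; RH and
IN: the toy panel's signature motifs) — plus the order constraint
RT < RH < IN; the Env transmembrane rule is a 19-residue window with mean
Kyte–Doolittle hydropathy ≥ 1.6. Profiles are data, not code: real-data
users supply their own. The published pipeline's profile-database domain
annotation is out of scope; the order constraint it enforces is preserved.

The verdict is a pure function of (classification, ORFs, domain flags,
panel); each violated rule appends a machine-readable reason code
(`missing_gene:X`, `short_orf:X`, `premature_stop:X`, `order_violation`,
`domain_missing:Y`, `not_retroviral`).

### Junction-read genotyping (`polymorphism`)

For each candidate locus, flanks of 200 bp (configurable) are extracted.
The *initial-state* query joins the 5' flank to the 3' flank with one TSD
copy removed — exactly the ancestral pre-insertion locus. The 5'/3'
*insertion-state* queries join each flank to the adjacent element boundary.
The junction window is [flank_len−10, flank_len+10] 1-based, i.e. 190–210
at defaults, identical across queries.

Reads are mapped semi-globally (edlib, whole read aligned) in both
orientations; identity is matches over alignment columns with gaps counted
as mismatches, thresholded at 99%, with a Karlin–Altschul e-value guard at
1e-5. When no full-length mapping qualifies, the best local alignment is
reported for diagnostics (`full_length=False`; such mappings are never
meaningful). A read is **meaningful** iff full-length mapped and its
mapping covers the entire junction window. Reads shorter than 21 bp are
skipped outright; a k-mer prescreen (21-mers sampled every 10 positions
against the query set) skips reads that cannot share the required long
exact stretch. A read meaningful on both an insertion query and the
initial query — possible only under pathological query overlap — is
discarded and logged.

One meaningful read per allele establishes presence (the published rule);
read counts are always reported so stricter thresholds can be applied
downstream. Individuals: i/i with only insertion evidence, −/− with only
empty evidence, i/− with both, nocall with neither. Pools with a known size
contribute `pool_size` homozygous individuals only under single-state
evidence; mixed-evidence pools are recorded as pool-level heterozygosity
and excluded from individual-based frequency math (both the inclusive and
the individual-based totals are reported). Group frequencies
`freq_i = (2·n_ii + n_i−)/(2·N)` are withheld unless more than 4
individuals contribute (IN > 4).

### vOTU clustering and locus search (`votu`)

Similarity edges require the best local nucleotide alignment (match 2,
mismatch −3, gaps 5/2) to cover ≥80% of the *shorter* sequence at ≥95%
identity with e ≤ 1e-5. Coverage is symmetrized over the shorter sequence
deliberately: a query-relative coverage would make edges depend on
comparison direction.

MCL is implemented from scratch on a dense matrix: weights
identity × coverage / 1e4 (binary optional), unit self-loops, column
normalization, then expansion (matrix square) alternating with inflation
(entrywise power 1.4, renormalize), pruning entries <1e-8, until the
largest entry change <1e-6 or 200 iterations (non-convergence returns the
current interpretation, flagged). Clusters are connected components of the
final matrix's support; singletons stand alone. Node order is
canonicalized, so the partition is invariant to input order. The test
suite pins the implementation to an independently coded dense-matrix
oracle on random two-community graphs.

Ortholog/paralog search extends each LTR by 500 bp on both sides and
requires the full query aligned at ≥95% identity (iterative best-hit
masking with edlib); hits overlapping the element's own locus are `self`,
other hits in the same assembly `paralog`, hits in other assemblies
`ortholog`.

### Statistics (`stats`)

**Richness extrapolation.** The statistic is the mean per-species vOTU
count among surveyed species (zeros included) scaled to the number of
described vertebrate species (default 74,140). Species are bootstrapped
with replacement (default 10,000 replicates) and the 95% interval is BCa:
`z0 = Φ⁻¹(#{θ* < θ̂}/B)` with ties counted half, acceleration from the
jackknife skewness, endpoints at the adjusted quantiles using linear
interpolation. Degenerate inputs (constant or all-zero counts) return a
zero-width interval, flagged where appropriate; θ̂ outside the bootstrap
range is an error. The published corpus point estimate came from a
resampling design over sample-size grids that is not fully specified, so
this package's estimator is validated against closed-form rate scaling and
an exhaustive n=5 enumeration oracle instead of against that number.

**Phylogenetic signal D.** Nodal values are reconstructed by the
contrasts-style weighted-average pruning pass (children weighted by inverse
adjusted branch lengths, branch lengths extended by the pruning
correction), treating the binary states as continuous; `d_obs` is the sum
of |parent − child| over all edges. The random null permutes tip states
(prevalence preserved); the Brownian null simulates unit-rate Brownian
motion along branches and thresholds the tips so the observed prevalence is
reproduced. `D = (d_obs − mean d_Brownian)/(mean d_random − mean
d_Brownian)`; `p(D>0)` is the fraction of Brownian-null d ≥ d_obs and
`p(D<1)` the fraction of permutation-null d ≤ d_obs. The reconstruction is
linear in tip states, so both nulls evaluate as a single matrix product,
making thousand-replicate nulls cheap. Zero or missing branch lengths are
an error (resolve the tree first); fewer than 50 tips warns, since D then
depends on prevalence and tree shape. Fidelity is pinned by calibration —
mean D ≈ 1 on permuted traits and ≈ 0 on Brownian-threshold traits — not by
numeric equality with any external implementation.

**G-test.** `G = 2 Σ O ln(O/E)` over nonzero cells of an r×c table,
df = (r−1)(c−1), p from the upper χ² tail; the Williams correction is
available but off by default. Zero margins and 1×n tables are errors.

## The synthetic worlds

The generator emulates the study's data conditions at toy scale: reference
retroviruses with gag-pro-pol-env architecture (~3.4 kb including 250–350
bp LTRs; gene lengths drawn per genome so the 80% cutoffs are meaningful),
repeat-free backgrounds (rejection-sampled so no 20-mer repeats — decoy LTR
pairs cannot arise by chance), implants with duplicated target sites
(default 5 bp), Hardy–Weinberg diploid populations at a chosen allele
frequency (default 0.5), and uniform-coverage single-end reads (default
150 bp, 10× diploid, error-free unless asked otherwise). Each stream is a
pure function of (parameters, seed); streams for different generators are
namespaced so a panel and a background built from the same seed stay
independent.

Decoy implants each violate exactly one rule: a 1-mismatch LTR pair (built
at 180 bp so that no identical sub-repeat reaches the 100-bp minimum — at
the element's own scale, one substitution removes it from the scan), a
premature stop in *pol*, a 1-bp frameshift placed so that no reading frame
retains a qualifying ORF over the gene, a Pol whose RT region is replaced
by a retrotransposon decoy RT, and a deleted *env*. The two
element-internal bases adjacent to the LTRs are nudged when they coincide
with the flanking base on the same side, so maximal repeat extension stops
exactly at the true LTR boundary and truth recovery can be asserted
*exactly* rather than approximately.

What the worlds do **not** emulate: sequencing indels and quality-score
structure, paired-end geometry, repetitive host genomes (real assemblies
contain LTR families that make scanning and read mapping much harder),
nested or solo-LTR elements, non-reference insertions, and selection or
demography in the populations. Passing tests therefore demonstrate
correctness of the algorithms under clean conditions, not performance on
real vertebrate assemblies.

## Problem sizes and tolerances in the test suite

The suite runs on one CPU in under two minutes. The flagship end-to-end
check uses 20 worlds (seeds fixed in advance) of 200 diploid individuals on
20-kb backgrounds at 10× coverage — 4,000 individual-locus pairs — and
requires ≥99% genotype concordance. That bound is intentionally tight: at
10× diploid coverage each haplotype receives 5×, a heterozygote's expected
number of meaningful empty-locus reads is ≈4.3, so the het→i/i dropout
probability is ≈1.4% and the overall expected error ≈0.7%. The cascade
check runs the full decoy battery in three worlds; MCL is compared with its
oracle on 20 random 30-node graphs; BCa against exhaustive enumeration at
n=5 to 1e-12; D calibration over 100 random 200-tip trees with 200-sample
nulls (within 0.1 of the ideal 1 and 0); bootstrap coverage over 100
simulated surveys of 300 species (counts Bernoulli(0.3) × (1+Poisson(1))),
requiring ≥93/100 coverage of the truth by the nominal-95% interval.
`scripts/acceptance.py` recomputes scaled-down versions of the same
quantities from a single command-line seed.

## Known limitations

* The scan reports only exactly identical LTR pairs; degenerate pairs,
  solo LTRs and nested elements are out of scope by design.
* The bundled motif profiles and the toy panel are stand-ins for curated
  references; real analyses should supply their own panel FASTA, ORF-length
  table and motif profiles.
* E-values are analytic Karlin–Altschul estimates, not empirically
  calibrated per database; they serve as consistent filters, not as
  significance claims.
* Pool genotyping follows the single-state-evidence rule; partial pool
  allele-frequency estimation from read proportions is not attempted.
* The D statistic's nodal reconstruction is one member of a family of
  estimators; its scale is anchored by its own nulls, which is exactly what
  makes D comparable across trees, but individual D values need not match
  other implementations to many decimals.
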