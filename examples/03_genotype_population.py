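"""Genotype a population for an insertion with junction reads.

Simulates 20 diploid individuals segregating the insertion at allele
frequency 0.5, sequences each at 10x with error-free 150-bp reads, and
calls genotypes from meaningful junction-spanning reads.
"""
from ervi import ltr_scan, polymorphism as poly, synthetic

panel = synthetic.make_reference_panel(seed=0)
background = synthetic.make_background(20_000, seed=3)
spec = synthetic.ImplantSpec(element_id="locus", source="toyRV2", position=10_000)
genome, truth = synthetic.implant_provirus(background, spec, panel, seed=3)

candidate = ltr_scan.detect_tsd(genome, ltr_scan.find_identical_ltr_pairs(genome)[0])
queries = poly.build_junction_queries(genome, candidate)
print(f"queries: initial {len(queries.initial_state)} bp, ins5/ins3 {len(queries.ins5)} bp, "
      f"junction window {queries.junction_window[0]}-{queries.junction_window[1]}")

population = synthetic.simulate_population(genome, background, 0.5, 20, seed=3)
calls = []
for k, individual in enumerate(population.individuals):
    haplotypes = [population.genomes[h]["chr1"] for h in individual.haplotypes]
    reads = synthetic.simulate_reads(haplotypes, read_len=150, coverage=10, seed=100 + k)
    call = poly.genotype_individual(reads, queries, sample_id=individual.sample_id)
    calls.append(call)
    mark = "" if call.genotype == individual.genotype else "  <- MISMATCH"
    print(f"{individual.sample_id:6s} truth {individual.genotype:2s}  called {call.genotype:2s} "
          f"(ins reads {call.n_ins_reads}, empty reads {call.n_empty_reads}){mark}")

(freqs,) = poly.population_frequencies(calls, {c.sample_id: "all" for c in calls})
print()
print(f"group frequencies over {freqs.n_individuals} individuals: "
      f"i = {freqs.freq_i:.3f}, - = {freqs.freq_empty:.3f}, genotypes {freqs.genotype_freqs}")
print("One meaningful junction read per allele suffices for presence; both")
print("alleles observed -> heterozygote, one allele -> homozygote.")
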