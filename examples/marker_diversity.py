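"""Per-locus and per-population SSR diversity statistics.

Generates a synthetic survey with the structure of the Chongzuo design
(40 accessions, 7 populations, 14 multi-allelic loci, one divergent
population) and summarises marker diversity the way such surveys tabulate it.
"""

from teadiv import markers
from teadiv.simulate import make_study_like_dataset

bundle = make_study_like_dataset(seed=1)
g, m = bundle.genotypes, bundle.popmap

loci = markers.summarize_loci(g)
print("per-locus diversity (head):")
print(loci.head(5).round(2))
print(f"\npanel totals: Na = {loci.loc['Total', 'Na']:.0f}, "
      f"Ne = {loci.loc['Total', 'Ne']:.2f}; "
      f"panel means: Ho = {loci.loc['Mean', 'Ho']:.2f}, He = {loci.loc['Mean', 'He']:.2f}")

pops = markers.summarize_populations(g, m)
print("\nper-population means across loci:")
print(pops.round(2))
print("\nNa/Ne are observed/effective allele counts, I the Shannon index of the")
print("allele frequencies, Ho/He observed/expected heterozygosity; P1 is the")
print("divergent population and shows the lowest within-population diversity.")
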