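"""Descriptive statistics: codon usage, annotation comparison, tRNA wobble
distribution and tmRNA typing.
"""

from srnascan.genome_stats import (
    classify_tmrna_type,
    codon_fractions_from_percents,
    codon_usage,
    compare_annotations,
    wobble_distribution,
)
from srnascan.synthetic_data import SimulationConfig, generate_genome
from srnascan.io_formats import AnnotationSet, FeatureAnnotation, reverse_complement

# codon usage over the simulated ORFs
cfg = SimulationConfig(genome_length=40_000, n_cds=15, n_ncrna=0,
                       n_antisense_pairs=0, n_trna=0, rng_seed=4)
genome, annotations, truth = generate_genome(cfg)
cds_seqs = []
for f in annotations.of_type("CDS"):
    s = genome.residues[f.start:f.end]
    cds_seqs.append(s if f.strand == "+" else reverse_complement(s))
table = codon_usage(cds_seqs).table
print("codon usage of the simulated ORFs (top 5 by percent):")
print(table.nlargest(5, "percent")[["codon", "aa", "percent", "fraction"]].to_string(index=False))
print("percent = share of all codons; fraction = share within the synonymous family\n")

# within-family fractions can be recovered from a printed percent column alone
fr = codon_fractions_from_percents({"AUU": 1.7, "AUC": 1.0, "AUA": 4.6})
print(f"Ile family from printed percents 1.7/1.0/4.6 -> AUA fraction {fr['AUA']:.2f}")
print("(a strongly skewed family: most isoleucines use the AUA triplet)\n")

# annotation comparison: two gene callers disagreeing on starts
a = AnnotationSet("g", [FeatureAnnotation(f"a{i}", "CDS", 100*i, 100*i+60, "+") for i in range(1, 6)])
b = AnnotationSet("g", [
    FeatureAnnotation("b1", "CDS", 100, 160, "+"),     # equal
    FeatureAnnotation("b2", "CDS", 215, 260, "+"),     # start shifted
    FeatureAnnotation("b3", "CDS", 300, 340, "+"),     # end shifted
    FeatureAnnotation("b4", "CDS", 700, 760, "+"),     # B only
])
cmp = compare_annotations(a, b)
print(f"annotation comparison: equal {cmp.equal}, start shifted {cmp.start_shifted}, "
      f"end shifted {cmp.end_shifted}, A only {cmp.a_only}, B only {cmp.b_only}")
print(f"merged (extended) annotation: {cmp.extended} genes "
      f"= {cmp.n_a} from A + {cmp.b_only} B-only\n")

# tRNA wobble distribution over anticodon families
d = wobble_distribution(["GAA", "UGC", "CAU", "GUU", "UAC", "GAC", "UCC"])
print(f"wobble (anticodon 5') distribution: U {d.U:.2f}  G {d.G:.2f}  C {d.C:.2f}  A {d.A:.2f}")
print("thermophilic genomes show almost no 5'-A anticodons\n")

# tmRNA typing from the pk1 lower stem length
for bp in (5, 4, 3, 2, 7):
    print(f"pk1 lower stem {bp} bp -> type {classify_tmrna_type(bp)}")
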