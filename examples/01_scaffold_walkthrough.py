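"""Walk the transcription scaffold: annealing, labeling, restricted extension.

The 9-nt RNA primer anneals to a unique window of the 64-nt template; one
radiolabeled CMP extends it to the 10-mer; with only ATP and GTP supplied the
polymerase walks nine more positions and stalls where UTP would be required.
RNase A digestion of the released 10-mer shows which fragment carries the
3' label in the protection assay.
"""

from rnapkin import (
    ElongationComplex,
    extend_with_subset,
    next_cognate_nucleotide,
    predict_hybrid_tm,
    rnase_a_protection_products,
    tk_scaffold,
)
from rnapkin.scaffold import NucleicStrand

scaffold = tk_scaffold()
print(f"template ({len(scaffold.template)} nt): {scaffold.template.sequence}")
print(f"primer anneals at template positions {scaffold.anneal_start}-{scaffold.anneal_end}")

ec9 = ElongationComplex.assemble(scaffold)
print(f"next cognate NTP for EC_+9: {next_cognate_nucleotide(ec9)} (the labeling step)")

ec10 = extend_with_subset(ec9, {"CTP"})
ec19 = extend_with_subset(ec10, {"ATP", "GTP"})
print(f"ATP+GTP walk: {ec10.rna.sequence} -> {ec19.rna.sequence} ({ec19.rna_length} nt)")
print(f"stalled because position +{ec19.rna_length + 1} templates {next_cognate_nucleotide(ec19)}")

fragments, labeled = rnase_a_protection_products(ec10.rna)
print(f"RNase A digest of the released 10-mer: {' | '.join(fragments)}")
print(f"3'-labeled fragment: {labeled} ({len(labeled)} nt) — the 'released' band on the gel")

window = NucleicStrand(scaffold.template.sequence[scaffold.anneal_start - 1 : scaffold.anneal_end], "DNA")
tm = predict_hybrid_tm(scaffold.rna, window, monovalent_salt_mM=40.0)
print(f"predicted 9-bp RNA:DNA hybrid Tm at 40 mM monovalent salt: {tm:.1f} C")
print("(complexes remain intact far above this — the polymerase stabilizes the hybrid)")
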