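"""Parent-of-origin sex-linkage scan with double-recombinant masking.

Paternal heterozygous markers are tested for association between the
inherited allele and offspring sex; genotypes that would imply a double
recombination within 10 Mb are treated as errors and masked first.
"""

from trisexscan.linkage_scan import scan
from trisexscan.qc import apply_qc
from trisexscan.simulate import SimConfig, simulate_family

fam = simulate_family(SimConfig(seed=3))
data, _ = apply_qc(fam)
res = scan(data, parent="father", window_bp=10_000_000, apply_fdr=True)

sig = res.table[res.table["q"] < 0.05]
print(f"tested {len(res.table)} paternal-informative sites; "
      f"{res.n_masked} genotypes masked as double-recombinant errors")
print(f"{len(sig)} sites significant after BH-FDR; ten strongest:")
print(sig.nsmallest(10, "p")[["chrom", "pos", "p", "q"]].to_string(index=False))
print()
print("Every strong association is on Chr7: inside the sex-linked region")
print("(< ~10.3 Mb) the father's Y haplotype co-segregates perfectly with")
print("male offspring, and because male recombination is weak the signal")
print("shades well into the neighbouring pseudoautosomal region - the same")
print("shoulder seen in real family data.")
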