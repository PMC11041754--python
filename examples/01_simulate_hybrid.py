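"""Generate a synthetic hybrid polyploid genome with known truth.

Two progenitor genomes are diverged by ~1.2% substitutions, then a
hybrid assembly is built whose chromosome copies include unique copies,
byte-identical (IBD, collapsed) groups of 2-4 copies, and one
interspecific recombinant. Long error-free reads are drawn per
underlying copy, so collapsed sequences receive proportionally more
depth.
"""

import polyarch as pa

pair, truth, reads, paf = pa.default_fixture(seed=1)

print(f"progenitors: {pair.n_chrom} chromosomes x {pair.chrom_length(0):,} bp, "
      f"{len(pair.substitutions):,} substitutions "
      f"(~{len(pair.substitutions) / (pair.n_chrom * pair.chrom_length(0)):.4f}/site)")
print(f"assembly: {len(truth.assembly)} emitted sequences, "
      f"{sum(len(s) for s in truth.assembly.values()):,} bp")
for name, copies in truth.copy_number.items():
    labels = [b.name for b in truth.progenitor_blocks if b.chrom == name]
    print(f"  {name:10s} dosage x{copies}  progenitor {'/'.join(labels)}")
print(f"reads: {len(reads):,} x ~15 kb at 30x per underlying copy")
print("A collapsed group (e.g. dosage x4) is emitted once but receives 4 x 30x")
print("depth; the truth BED tracks above are what the painter and dosage")
print("classifier are later scored against.")
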