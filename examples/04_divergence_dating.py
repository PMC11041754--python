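"""Date the progenitor split from synonymous divergence of orthologs.

Ortholog CDS pairs are simulated with substitutions only at synonymous
sites at a true divergence of 0.012; NG86 Ks is estimated per pair, the
histogram mode located, and the split dated as T = Ks_peak / (2 mu)
with a neutral rate of 0.386e-8 substitutions/site/year.
"""

import polyarch as pa

pairs = pa.simulate_ortholog_pairs(n_pairs=500, n_codons=1000,
                                   ks_true=0.012, seed=1)
ks_values = [pa.kaks_ng86(cds_a, cds_b).ks
             for _, _, cds_a, cds_b in pairs]

dist = pa.ks_peak(ks_values, bin_width=0.002)
print(f"{len(ks_values)} ortholog pairs, Ks peak = {dist.peak:.4f} "
      f"(true synonymous divergence 0.012)")

for mu in (0.383e-8, 0.386e-8):
    est = pa.divergence_time(dist.peak, mu)
    print(f"  mu = {mu:.3e} /site/yr  ->  T = {est.time_years / 1e6:.2f} Myr")
print("The two dates bracket the progenitor split implied by the Ks peak;")
print("a peak of 0.012 corresponds to roughly 1.55-1.57 million years.")

# PID2 on one aligned peptide pair, for flavour
row_a, row_b, pid2 = pa.global_align_pid2("MKVLWAALLVTFLAGCQA", "MKVLWAALRVTFLAGAQA")
print(f"example peptide pair: PID2 = {pid2:.3f} "
      "(exact-match columns over all alignment columns)")
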