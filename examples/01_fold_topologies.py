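"""Fold topologies of SRE sense-strand segments.

Builds the central N-mers of the c-Fos SRE sense strand, enumerates the
two folds a partially palindromic strand can adopt — the unimolecular
hairpin and the antiparallel mismatched homoduplex — and prints their
Watson–Crick pair counts and Oligo Calc masses.
"""

from meltfold import oligo

for n in (12, 14, 16, 18, 20):
    seq = oligo.build_sre_segment(n)
    hairpin = oligo.enumerate_hairpin_fold(seq)
    duplex = oligo.enumerate_homoduplex_fold(seq)
    print(
        f"{seq.name}: {seq.bases}  M_w={oligo.molecular_weight(seq):7.2f} g/mol  "
        f"stem={hairpin.n_wc} WC pairs  duplex={duplex.n_wc}/{len(duplex.pairs)} WC"
    )

seq16 = oligo.build_sre_segment(16)
print()
print(oligo.fold_diagram(seq16, oligo.enumerate_hairpin_fold(seq16)))
print(oligo.fold_diagram(seq16, oligo.enumerate_homoduplex_fold(seq16)))
print(
    "The 16-mer folds into a 5-pair stem closed over the ATATTA loop, or\n"
    "pairs with a second copy into a 12-WC-pair duplex with tandem\n"
    "mismatches at positions ±2, ±3."
)
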