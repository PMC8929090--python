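"""Design allele-specific (ARMS) primers for one species of a panel.

The allele-specific primer ends (3') on the diagnostic SNP and carries a
deliberate mismatch at the third base from the 3' end; the mate primer is an
ordinary perfect-match primer placed to give a 100-1000 bp product.
"""

from barcodekey import align_panel_locus, design_allele_specific_pairs
from barcodekey.synthetic import PanelSimSpec, simulate_panel

panel, _ = simulate_panel(
    PanelSimSpec(species=5, locus_length=1000, divergence=0.0, snps=1, seed=3)
)
msa = align_panel_locus(panel.loci["locus1"])

pairs = design_allele_specific_pairs(msa, "sp2", locus="locus1")
print(f"{len(pairs)} candidate pairs for sp2, best five by penalty:")
for pair in pairs[:5]:
    allele_specific = pair.forward if pair.forward.site else pair.reverse
    print(f"  {pair.name}")
    print(f"    forward  5'-{pair.forward.residues}-3'")
    print(f"    reverse  5'-{pair.reverse.residues}-3'")
    print(f"    product {pair.product_length} bp | penalty {pair.penalty:.2f} | "
          f"allele-specific strand {allele_specific.strand}, "
          f"designed mismatch at 3' offset {allele_specific.designed_mismatch_offset}")
# The penalty combines Tm imbalance with length/GC deviation; a lower value
# means a more conventional, better-matched pair.
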