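# Motif -> predicted transported ion, by the residues at BR positions 85/89/96.
# Editable: these labels are clade-level generalizations, not certainties.
DTD: outward H+ pump
DTE: outward H+ pump
DTS: outward H+ pump
NDQ: Na+ pump
NTQ: Cl- pump
TSA: Cl- pump
TSD: Cl- pump
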