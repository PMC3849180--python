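# mirconsensus nearest-neighbor duplex parameters, version 1
# Turner-2004-style RNA stacking free energies (dG37, kcal/mol) for
# intermolecular duplex scoring. Doublet notation XY/WZ denotes the stack
#   5'-X Y-3'
#   3'-W Z-5'
# i.e. base pairs X:W and Y:Z. One canonical entry is stored per
# reversal-symmetric class (XY/WZ == ZW/YX); the loader expands the rest.
# Watson-Crick and G:U wobble pairs are allowed; wobble-containing values
# are approximate. Loop parameters: penalty = base + log_coeff * ln(size)
# with size = total unpaired nucleotides (bulge: one side unpaired only).
record	key	value
stack	AA/UU	-0.93
stack	AC/UG	-2.24
stack	AG/UC	-2.08
stack	AU/UA	-1.10
stack	CA/GU	-2.11
stack	CC/GG	-3.26
stack	CG/GC	-2.36
stack	GA/CU	-2.35
stack	GC/CG	-3.42
stack	UA/AU	-1.33
stack	AG/UU	-0.55
stack	AU/UG	-1.36
stack	CG/GU	-1.41
stack	CU/GG	-2.11
stack	GA/UU	-0.80
stack	GC/UG	-2.51
stack	GG/CU	-1.53
stack	GG/UU	-0.50
stack	GU/UG	-0.50
stack	UA/GU	-1.00
stack	UG/GU	0.30
param	duplex_init	4.09
param	bulge_base	3.80
param	internal_base	1.70
param	loop_log_coeff	1.08
param	max_loop	15
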