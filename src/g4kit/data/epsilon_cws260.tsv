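# Nearest-neighbor molar extinction coefficients at 260 nm, pH 7, 25 C.
# Source: Cantor, Warshaw & Shapiro (1970) Biopolymers 9:1059, as used by
# oligonucleotide vendors. Units: M^-1 cm^-1.
# Dinucleotide entries are whole-dimer coefficients (2x the per-residue
# values tabulated in the original reference); monomer entries are the
# single-nucleotide coefficients.
# kind	key	epsilon
monomer	A	15400
monomer	C	7400
monomer	G	11500
monomer	T	8700
doublet	AA	27400
doublet	AC	21200
doublet	AG	25000
doublet	AT	22800
doublet	CA	21200
doublet	CC	14600
doublet	CG	18000
doublet	CT	15200
doublet	GA	25200
doublet	GC	17600
doublet	GG	21600
doublet	GT	20000
doublet	TA	23400
doublet	TC	16200
doublet	TG	19000
doublet	TT	16800
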