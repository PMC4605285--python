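# Built-in RNA modification registry.
# delta_formula is the elemental composition ADDED to the unmodified
# nucleotide ("-" = mass-silent).  blocks_3prime_cleavage marks 2'-O-methyls,
# which protect the downstream phosphodiester bond from RNase T1/A cleavage.
code	target_base	delta_formula	placement	blocks_3prime_cleavage	mod_class
Y	U	-	backbone-isomer	False	pseudouridine
Am	A	CH2	ribose	True	Nm
Cm	C	CH2	ribose	True	Nm
Gm	G	CH2	ribose	True	Nm
Um	U	CH2	ribose	True	Nm
Ym	U	CH2	ribose	True	Nm
m1A	A	CH2	base	False	base_methyl
m6A	A	CH2	base	False	base_methyl
m5C	C	CH2	base	False	base_methyl
m7G	G	CH2	base	False	base_methyl
m1G	G	CH2	base	False	base_methyl
m3U	U	CH2	base	False	base_methyl
m62A	A	C2H4	base	False	base_dimethyl
ac4C	C	C2H2O	base	False	acetyl
m1acp3Y	U	C5H9NO2	base	False	composite
ce	U	C3H3N	base	False	adduct
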