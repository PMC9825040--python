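[*:1]F	fluoro
[*:1]Cl	chloro
[*:1]Br	bromo
[*:1]I	iodo
[*:1]C	methyl
[*:1]CC	ethyl
[*:1]CCC	propyl
[*:1]C(C)C	isopropyl
[*:1]C(C)(C)C	tert-butyl
[*:1]O	hydroxy
[*:1]OC	methoxy
[*:1]OCC	ethoxy
[*:1]OC(C)C	isopropoxy
[*:1]N	amino
[*:1]NC	methylamino
[*:1]N(C)C	dimethylamino
[*:1]C#N	cyano
[*:1]C(=O)C	acetyl
[*:1]C(=O)OC	methoxycarbonyl
[*:1]C(F)(F)F	trifluoromethyl
[*:1]S	thiol
[*:1]SC	methylthio
[*:1]CO	hydroxymethyl
[*:1]CCO	hydroxyethyl
[*:1]c1ccccc1	phenyl
[*:1]C=C	vinyl
[*:1]CC#N	cyanomethyl
[*:1]OC(F)F	difluoromethoxy
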