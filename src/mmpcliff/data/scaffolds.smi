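[*:1]c1ccc2c(c1)oc1ccccc12	dibenzofuran
[*:1]c1ccc2c(c1)sc1ccccc12	dibenzothiophene
[*:1]c1ccc2c(c1)[nH]c1ccccc12	carbazole
[*:1]c1ccc2c(c1)Cc1ccccc12	fluorene
[*:1]c1ccc2c(c1)C(=O)c1ccccc12	fluorenone
[*:1]c1ccc2cc3ccccc3cc2c1	anthracene
[*:1]c1ccc2ccc3ccccc3c2c1	phenanthrene
[*:1]c1ccc2nc3ccccc3cc2c1	acridine
[*:1]c1ccc2c(c1)Oc1ccccc1O2	dibenzodioxine
[*:1]c1ccc2c(c1)Nc1ccccc1S2	phenothiazine
[*:1]c1ccc2c(c1)Nc1ccccc1O2	phenoxazine
[*:1]c1ccc2c(c1)Cc1ccccc1O2	xanthene
[*:1]c1ccc2c(c1)C(=O)c1ccccc1C2=O	anthraquinone
[*:1]c1ccc2nc3ccccc3nc2c1	dibenzoquinoxaline
[*:1]c1ccc2cc3c(cc2c1)CCCC3	tetrahydroanthracene
[*:1]c1ccc2cc3c(cc2c1)OCCO3	naphthodioxine
[*:1]c1ccc2cc3c(cc2c1)OCO3	naphthodioxole
[*:1]c1ccc2cc3c(cc2c1)CCC3	cyclopenta-naphthalene
[*:1]c1ccc2c(c1)Sc1ccccc1S2	thianthrene
[*:1]c1ccc2c(c1)Oc1ccccc1S2	phenoxathiine
[*:1]c1ccc2c(c1)CCc1ccccc12	dihydroanthracene
[*:1]c1ccc2c(c1)CCCc1ccccc12	dihydrodibenzocycloheptene
[*:1]c1ccc2[nH]c3ccccc3c2c1	carbazole-2yl
[*:1]c1ccc2oc3ccccc3c2c1	dibenzofuran-2yl
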