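id,kind,fragment_smiles,name
nap2ox,cap,O(CC(=O)[*:1])c1ccc2ccccc2c1,2-naphthoxyacetyl
nap1ox,cap,O(CC(=O)[*:1])c1cccc2ccccc12,1-naphthoxyacetyl
brnap2ox,cap,Brc1ccc2cc(OCC(=O)[*:1])ccc2c1,6-bromo-2-naphthoxyacetyl
thnap2ox,cap,O(CC(=O)[*:1])c1ccc2c(c1)CCCC2,"5,6,7,8-tetrahydronaphthalen-2-yloxyacetyl"
cbz9ac,cap,O=C([*:1])Cn1c2ccccc2c2ccccc21,carbazol-9-ylacetyl
fmoc,cap,O=C([*:1])OCC1c2ccccc2-c2ccccc21,fluorenylmethoxycarbonyl
palmitoyl,cap,CCCCCCCCCCCCCCCC(=O)[*:1],hexadecanoyl (C15 alkyl chain)
myristoyl,cap,CCCCCCCCCCCCCC(=O)[*:1],tetradecanoyl (C13 alkyl chain)
cbz,cap,O=C([*:1])OCc1ccccc1,benzyloxycarbonyl
tolox,cap,Cc1ccc(OCC(=O)[*:1])cc1,4-methylphenoxyacetyl
gly,amino_acid,[*:1]NCC(=O)[*:2],glycine
ala,amino_acid,[*:1]N[C@@H](C)C(=O)[*:2],L-alanine
val,amino_acid,[*:1]N[C@@H](C(C)C)C(=O)[*:2],L-valine
leu,amino_acid,[*:1]N[C@@H](CC(C)C)C(=O)[*:2],L-leucine
ile,amino_acid,[*:1]N[C@@H]([C@@H](C)CC)C(=O)[*:2],L-isoleucine
phe,amino_acid,[*:1]N[C@@H](Cc1ccccc1)C(=O)[*:2],L-phenylalanine
met,amino_acid,[*:1]N[C@@H](CCSC)C(=O)[*:2],L-methionine
tyr,amino_acid,[*:1]N[C@@H](Cc1ccc(O)cc1)C(=O)[*:2],L-tyrosine
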