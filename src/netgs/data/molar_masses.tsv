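metabolite	molar_mass
glucose	180.16
sucrose	342.30
fructose	180.16
starch	162.14
citrate	192.12
malate	134.09
fumarate	116.07
succinate	118.09
nitrate	62.00
alanine	89.09
arginine	174.20
asparagine	132.12
aspartate	133.10
cysteine	121.16
glutamate	147.13
glutamine	146.15
glycine	75.07
histidine	155.15
isoleucine	131.17
leucine	131.17
lysine	146.19
methionine	149.21
phenylalanine	165.19
proline	115.13
serine	105.09
threonine	119.12
tryptophan	204.23
tyrosine	181.19
valine	117.15
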