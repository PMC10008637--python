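trait,population,shannon
Plant habit,LLR,0.68
Plant habit,CBL,0.66
Stem color,LLR,0.70
Stem color,CBL,0.68
Stem pubescence,LLR,0.85
Stem pubescence,CBL,0.83
Leaf shape,LLR,0.37
Leaf shape,CBL,0.49
Leaf color,LLR,0.34
Leaf color,CBL,0.32
Leaf pubescence,LLR,0.77
Leaf pubescence,CBL,0.58
Peduncle attitude,LLR,1.04
Peduncle attitude,CBL,1.07
Corolla color,LLR,0.26
Corolla color,CBL,0.06
Anther color,LLR,0.99
Anther color,CBL,0.99
Stigma color,LLR,0.47
Stigma color,CBL,0.61
Stigma exertion,LLR,0.65
Stigma exertion,CBL,0.62
Fruit shape,LLR,1.55
Fruit shape,CBL,1.32
Fruit color (before maturity),LLR,1.31
Fruit color (before maturity),CBL,1.30
Fruit color (at maturity),LLR,0.44
Fruit color (at maturity),CBL,0.52
Depth of stalk cavity,LLR,1.38
Depth of stalk cavity,CBL,1.38
Fruit glossiness,LLR,0.21
Fruit glossiness,CBL,0.06
Fruit texture of surface,LLR,1.06
Fruit texture of surface,CBL,1.09
Fruit shoulder shape,LLR,1.23
Fruit shoulder shape,CBL,1.28
Calyx aspect,LLR,1.01
Calyx aspect,CBL,0.95
Fruit shape of apex,LLR,1.04
Fruit shape of apex,CBL,1.17
Fruit navel appendages,LLR,0.56
Fruit navel appendages,CBL,0.68
Fruit spiciness,LLR,1.31
Fruit spiciness,CBL,1.29
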