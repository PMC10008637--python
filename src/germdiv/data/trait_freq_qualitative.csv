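trait,code,category,llr_pct,cbl_pct
Plant habit,1,Upright,17.0,11.8
Plant habit,2,Semi-upright,76.6,78.8
Plant habit,3,Prostrate,6.4,9.4
Stem color,1,Green,63.8,56.5
Stem color,2,Anthocyanin coloration of nodes,35.1,43.5
Stem color,3,Purple,1.1,0.0
Stem pubescence,1,Absent,8.5,16.5
Stem pubescence,2,Weak,72.3,71.8
Stem pubescence,3,Medium,16.0,10.6
Stem pubescence,4,Strong,3.2,1.2
Leaf shape,1,Broad elliptic,1.1,1.2
Leaf shape,2,Ovate,89.4,83.5
Leaf shape,3,Lanceolate,9.6,15.3
Leaf color,1,Light green,0.0,1.2
Leaf color,2,Green,89.4,92.9
Leaf color,3,Dark green,10.6,4.7
Leaf color,4,Purple,0.0,1.2
Leaf pubescence,1,Absent,41.5,72.9
Leaf pubescence,2,Weak,56.4,27.1
Leaf pubescence,3,Medium,2.1,0.0
Leaf pubescence,4,Strong,0.0,0.0
Peduncle attitude,1,Semi-drooping,19.1,22.4
Peduncle attitude,2,Drooping,44.7,36.5
Peduncle attitude,3,Erect,36.2,41.2
Corolla color,1,White,94.7,98.8
Corolla color,2,Light green,1.1,1.2
Corolla color,3,Light purple,2.1,0.0
Corolla color,4,Purple,2.1,0.0
Anther color,1,Yellow,2.1,5.9
Anther color,2,Blue,45.7,40.0
Anther color,3,Blue-violet,44.7,52.9
Anther color,4,Purple,7.4,1.2
Stigma color,1,White,87.2,81.2
Stigma color,2,Light purple,7.4,11.8
Stigma color,3,Purple,5.3,7.1
Stigma exertion,1,Shorter than stamens,3.2,1.2
Stigma exertion,2,Equal to stamens,21.3,24.7
Stigma exertion,3,Longer than stamens,75.5,74.1
Fruit shape,1,Lantern,35.1,44.7
Fruit shape,2,Cone,5.3,2.4
Fruit shape,3,Ox-horn,17.0,31.8
Fruit shape,4,Goat-horn,33.0,4.7
Fruit shape,5,Slender,4.3,14.1
Fruit shape,6,Helix,1.1,2.4
Fruit shape,7,Finger,1.1,0.0
Fruit shape,8,Spherical,2.1,0.0
Fruit shape,9,Teardrop,1.1,0.0
Fruit color (before maturity),1,Greenish white,3.2,1.2
Fruit color (before maturity),2,Light yellow,1.1,0.0
Fruit color (before maturity),3,Greenish yellow,3.2,8.2
Fruit color (before maturity),4,Light green,22.3,15.3
Fruit color (before maturity),5,Green,50.0,54.1
Fruit color (before maturity),6,Dark green,19.1,17.6
Fruit color (before maturity),7,Purple,1.1,3.5
Fruit color (at maturity),1,Yellow,2.1,5.9
Fruit color (at maturity),2,Orange,2.1,3.5
Fruit color (at maturity),3,Red,89.4,87.1
Fruit color (at maturity),4,Dark red,6.4,3.5
Depth of stalk cavity,1,Absent,28.7,23.5
Depth of stalk cavity,2,Shallow,20.2,27.1
Depth of stalk cavity,3,Medium,25.5,24.7
Depth of stalk cavity,4,Deep,25.5,24.7
Fruit glossiness,1,Absent,5.3,1.2
Fruit glossiness,2,Present,94.7,98.8
Fruit texture of surface,1,Smooth,54.3,38.8
Fruit texture of surface,2,Slightly wrinkled,31.9,47.1
Fruit texture of surface,3,Medium wrinkled,9.6,8.2
Fruit texture of surface,4,Strongly wrinkled,4.3,5.9
Fruit shoulder shape,1,Absent,13.8,12.9
Fruit shoulder shape,2,Bulge,51.1,43.5
Fruit shoulder shape,3,Slightly concave,19.1,17.6
Fruit shoulder shape,4,Concave,16.0,25.9
Calyx aspect,1,Non-enveloping,50.0,57.6
Calyx aspect,2,Medium-enveloping,33.0,28.2
Calyx aspect,3,Enveloping,17.0,14.1
Fruit shape of apex,1,Acute,56.4,45.9
Fruit shape of apex,2,Rounded,7.4,10.6
Fruit shape of apex,3,Depressed,30.9,35.3
Fruit shape of apex,4,Depressed with acute,5.3,8.2
Fruit navel appendages,1,Present,75.5,56.5
Fruit navel appendages,2,Absent,24.5,43.5
Fruit spiciness,1,Absent spicy,20.2,42.4
Fruit spiciness,2,Mildly spicy,42.6,27.1
Fruit spiciness,3,Medium spicy,14.9,12.9
Fruit spiciness,4,Spicy,22.3,17.6
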