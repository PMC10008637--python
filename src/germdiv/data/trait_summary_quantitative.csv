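trait,population,shannon,cv,max,min,range,mean,sd
Plant height (cm),LLR,2.04,22.3,168.3,38.3,130.0,112.5,25.0
Plant height (cm),CBL,2.01,16.3,143.3,62.8,80.5,102.0,16.6
Length of leaf blade (cm),LLR,1.54,19.5,21.1,5.4,15.6,12.4,2.4
Length of leaf blade (cm),CBL,2.04,26.6,26.4,7.9,18.5,16.4,4.4
Width of leaf blade (cm),LLR,1.70,23.6,10.6,2.5,8.2,5.6,1.3
Width of leaf blade (cm),CBL,2.03,27.7,12.1,3.9,8.2,7.5,2.1
Length of petiole (cm),LLR,1.61,23.5,10.1,1.7,8.4,5.7,1.3
Length of petiole (cm),CBL,2.04,29.1,13.7,3.5,10.2,8.0,2.3
Date of the first flower (d),LLR,1.93,13.0,124.4,73.6,50.9,92.3,12.0
Date of the first flower (d),CBL,1.70,11.7,124.4,54.1,70.3,84.0,9.8
First flowering node,LLR,2.06,35.6,23.8,5.2,18.7,10.2,3.6
First flowering node,CBL,1.75,22.9,16.3,4.5,11.8,9.7,2.2
Length of fruit pedicel (cm),LLR,2.17,24.3,7.3,2.4,4.9,4.1,1.0
Length of fruit pedicel (cm),CBL,2.04,27.6,9.0,2.6,6.4,5.0,1.4
Weight of single fruit (g),LLR,0.98,97.8,202.1,1.1,200.9,37.8,37.0
Weight of single fruit (g),CBL,1.86,79.9,409.9,6.4,403.5,121.7,97.2
Longitudinal diameter of fruit (cm),LLR,1.49,40.6,20.4,1.5,18.9,9.7,3.9
Longitudinal diameter of fruit (cm),CBL,1.87,36.2,36.4,7.4,29.1,18.5,6.7
Fruit transverse diameter (cm),LLR,1.76,56.7,9.8,0.8,9.0,3.6,2.0
Fruit transverse diameter (cm),CBL,1.90,51.2,11.3,1.1,10.1,5.0,2.6
Thickness of flesh (mm),LLR,1.65,42.1,5.9,0.7,5.3,2.6,1.1
Thickness of flesh (mm),CBL,2.01,43.6,9.1,1.4,7.7,3.9,1.7
Number of locules,LLR,1.87,20.5,4.3,2.0,2.3,2.8,0.6
Number of locules,CBL,1.70,18.4,4.3,2.0,2.3,3.2,0.6
Fruit firmness (Pa),LLR,1.73,50.0,89.4,11.9,77.5,30.5,15.3
Fruit firmness (Pa),CBL,1.80,41.4,65.7,10.4,55.3,26.6,11.0
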