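code,class
10,cropland
11,cropland
12,cropland
20,cropland
30,mosaic_cropland
40,mosaic_vegetation
50,forest
60,forest
61,forest
62,forest
70,forest
71,forest
72,forest
80,forest
81,forest
82,forest
90,forest
100,shrubland
110,shrubland
120,shrubland
121,shrubland
122,shrubland
130,grassland
140,other
150,other
151,other
152,other
153,other
160,forest
170,forest
180,shrubland
190,other
200,other
201,other
202,other
210,other
220,other
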