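Arrowheads, Airplanes, Diamonds, and Triangles
Bilateral Crowns
Criss Cross
Kites
Many Ridged Fans and Spades
Multi Dimpled Complex Polygons
Petals
Ridged Circles
Scoops
Single Dimpled Complex Polygons
Smooth
Spines
Tridents
Wedges
Other Branching
Other Geometric
Other Linear
Other Meandering
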