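state,name,population,latitude,longitude
AL,Alabama,4822023,32.8,-86.8
AK,Alaska,731449,64.0,-152.0
AZ,Arizona,6553255,34.3,-111.7
AR,Arkansas,2949131,34.9,-92.4
CA,California,38041430,37.2,-119.3
CO,Colorado,5187582,39.0,-105.5
CT,Connecticut,3590347,41.6,-72.7
DE,Delaware,917092,39.0,-75.5
DC,District of Columbia,632323,38.9,-77.0
FL,Florida,19317568,28.6,-82.4
GA,Georgia,9919945,32.6,-83.4
HI,Hawaii,1392313,20.8,-156.3
ID,Idaho,1595728,44.4,-114.6
IL,Illinois,12875255,40.0,-89.2
IN,Indiana,6537334,39.9,-86.3
IA,Iowa,3074186,42.0,-93.5
KS,Kansas,2885905,38.5,-98.4
KY,Kentucky,4380415,37.5,-85.3
LA,Louisiana,4601893,31.0,-92.0
ME,Maine,1329192,45.4,-69.2
MD,Maryland,5884563,39.0,-76.8
MA,Massachusetts,6646144,42.3,-71.8
MI,Michigan,9883360,44.3,-85.4
MN,Minnesota,5379139,46.3,-94.3
MS,Mississippi,2984926,32.7,-89.7
MO,Missouri,6021988,38.4,-92.5
MT,Montana,1005141,47.0,-109.6
NE,Nebraska,1855525,41.5,-99.8
NV,Nevada,2758931,39.3,-116.6
NH,New Hampshire,1320718,43.7,-71.6
NJ,New Jersey,8864590,40.1,-74.7
NM,New Mexico,2085538,34.4,-106.1
NY,New York,19570261,42.9,-75.5
NC,North Carolina,9752073,35.5,-79.4
ND,North Dakota,699628,47.4,-100.5
OH,Ohio,11544225,40.3,-82.8
OK,Oklahoma,3814820,35.6,-97.5
OR,Oregon,3899353,43.9,-120.6
PA,Pennsylvania,12763536,40.9,-77.8
RI,Rhode Island,1050292,41.7,-71.6
SC,South Carolina,4723723,33.9,-80.9
SD,South Dakota,833354,44.4,-100.2
TN,Tennessee,6456243,35.8,-86.3
TX,Texas,26059203,31.5,-99.3
UT,Utah,2855287,39.3,-111.7
VT,Vermont,626011,44.1,-72.7
VA,Virginia,8185867,37.5,-78.9
WA,Washington,6897012,47.4,-120.4
WV,West Virginia,1855413,38.6,-80.6
WI,Wisconsin,5726398,44.6,-89.7
WY,Wyoming,576412,43.0,-107.5
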