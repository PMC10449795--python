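participant,a53,iphone12,moto_g,pixel4,reported_mean,reported_std,dslr_contrast,iris_luminance,eye_color
1,111.3,106.6,26.7,426.8,186.7,211.8,89,116,blue
2,252.9,215.1,202.6,161.2,193.0,28.2,47,104,blue
3,80.9,6.1,125.7,142.3,91.4,74.3,60,84,blue
4,137.3,175.7,225.0,-29.9,123.6,135.2,31,63,light_brown
5,500.3,962.6,1956.2,205.4,1041.4,878.0,26,55,dark_brown
6,159.2,154.5,381.2,131.1,222.2,138.2,22,45,dark_brown
7,231.1,103.3,-65.7,277.2,104.9,171.5,20,42,dark_brown
8,185.7,941.9,597.2,107.7,549.0,419.2,13,36,dark_brown
9,180.6,310.9,482.6,349.1,380.9,90.1,15,35,dark_brown
10,216.7,396.1,3464.6,225.9,1362.2,1822.7,14,34,dark_brown
12,1579.2,134.8,2232.8,-232.9,711.6,1330.2,9,26,dark_brown
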