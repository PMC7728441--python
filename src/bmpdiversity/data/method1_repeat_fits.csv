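gene,repeat,sigma,lam,To0,r2
bambia,1,0.000414,0.000879,-95.84,0.9125
bmp4,1,0.000076,0.000452,-42.71,0.7060
cdx4,1,0.000220,0.000434,-81.48,0.6871
crabp2b,1,0.000041,0.000010,10.27,0.0951
eve1,1,0.000233,0.000514,-20.49,0.7132
foxi1,1,0.000371,0.000835,-91.10,0.7821
gata2a,1,0.000105,0.000336,-46.01,0.6056
id2a,1,0.000111,0.000539,-20.54,0.7354
klf2b,1,0.000394,0.001262,5.369,0.6880
smad6a,1,0.000016,0.000670,1.606,0.1780
smad7,1,0.000116,0.000765,-65.54,0.8043
sizzled,1,0.000222,0.000605,-82.09,0.6470
tfap2c,1,0.000041,0.000153,-15.90,0.1922
ved,1,0.000590,0.000590,-100.0,0.8072
bambia,2,0.000344,0.000564,90.73,0.6248
bmp4,2,0.000066,0.000474,-17.10,0.6114
cdx4,2,0.000169,0.000170,-26.84,0.2825
crabp2b,2,0.000056,0.000010,-43.72,0.2517
eve1,2,0.000158,0.000394,7.77,0.6689
foxi1,2,0.000413,0.001217,-14.67,0.7806
gata2a,2,0.000111,0.000399,-71.03,0.5647
id2a,2,0.000141,0.000522,-35.84,0.6967
klf2b,2,0.000708,0.003101,-62.70,0.6394
smad6a,2,0.000029,0.000340,-6.326,0.3140
smad7,2,0.000112,0.000613,-54.51,0.7397
sizzled,2,0.000217,0.000692,-99.99,0.6918
tfap2c,2,0.000056,0.000160,-27.15,0.4203
ved,2,0.000588,0.000554,-100.0,0.7354
bambia,3,0.000640,0.001045,-99.99,0.9362
bmp4,3,0.000094,0.000455,-73.00,0.7986
cdx4,3,0.000181,0.000468,-99.81,0.5390
crabp2b,3,0.000087,0.000010,-87.63,0.4399
eve1,3,0.000334,0.000568,-100.0,0.7789
foxi1,3,0.000505,0.001174,-6.052,0.8502
gata2a,3,0.000148,0.000491,-65.45,0.8464
id2a,3,0.000126,0.000579,9.476,0.8000
klf2b,3,0.000505,0.001407,-100.0,0.6530
smad6a,3,0.000051,0.000563,-25.92,0.8935
smad7,3,0.000095,0.000553,-19.75,0.5364
sizzled,3,0.000290,0.000721,-100.0,0.7169
tfap2c,3,0.000045,0.000378,-38.42,0.4709
ved,3,0.000602,0.000489,-100.0,0.6802
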