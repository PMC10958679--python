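quantity,percentile,a,b,c,d
mbd_vs_age,95,0.0158590893245159,-2.48827364899418,129.468298147669,
mbd_vs_age,90,0.0150093136786074,-2.36569339840154,117.058387994881,
mbd_vs_age,85,0.0169947953726012,-2.61296241099264,119.2756339392,
mbd_vs_age,80,0.0181604988914373,-2.72430043599688,117.786185105837,
mbd_vs_age,75,0.0170980650793476,-2.56156087824994,108.937944920187,
mbd_vs_age,70,0.0153521524182991,-2.29675134038753,96.9193320105205,
mbd_vs_age,65,0.0139234443090731,-2.06482066303825,86.1942596261178,
mbd_vs_age,60,0.0133474276966086,-1.93586438557909,78.7969203445515,
mbd_vs_age,55,0.0120258656714953,-1.71800473939478,69.1371036864403,
mbd_vs_age,50,0.0101207810347623,-1.43117563671504,57.7055571816715,
mbd_vs_age,45,0.00830370700081973,-1.16267761054262,47.2189394080279,
mbd_vs_age,40,0.00706789465540134,-0.985020366696941,40.1490865369569,
mbd_vs_age,35,0.00567105043709842,-0.780451937085959,32.1851457050436,
mbd_vs_age,30,0.00433908467600172,-0.59183983625958,25.1026783287918,
mbd_vs_age,25,0.00384762323173854,-0.514977208148349,21.6779489863451,
mbd_vs_age,20,0.00350334872002642,-0.460379635671465,18.939769820072,
mbd_vs_age,15,0.00334661384565518,-0.427574160659808,16.7306574543991,
mbd_vs_age,10,0.00297986835672837,-0.371166905786499,14.0175268149771,
mbd_vs_age,5,0.00343005129056988,-0.419996115338768,14.1931566472533,
mbd_vs_age,1,0.00132858467935213,-0.164305179095427,5.8659485827535,
cbt_vs_age,95,-0.0163082096576135,1.67466808574288,42.1174970236818,
cbt_vs_age,90,-0.0111167901865579,1.0984747527005,52.0927003795982,
cbt_vs_age,85,-0.0112286748985557,1.15848628399392,45.5299695199872,
cbt_vs_age,80,-0.0112498675459536,1.17608166649003,41.8608241446593,
cbt_vs_age,75,-0.0118149009243735,1.25846755343352,36.8016274706577,
cbt_vs_age,70,-0.0127573504204248,1.38474964626977,30.7909264303486,
cbt_vs_age,65,-0.0135713194916254,1.51011757244451,24.4545586007885,
cbt_vs_age,60,-0.0128757799205896,1.44279393890281,24.0804634956656,
cbt_vs_age,55,-0.0135438157984957,1.54067601428636,18.9328224243138,
cbt_vs_age,50,-0.0144265830595951,1.65923874763919,13.5230470040461,
cbt_vs_age,45,-0.0147242150929046,1.71307305853529,9.5036931304673,
cbt_vs_age,40,-0.015604956586238,1.84405820498268,3.37270387015403,
cbt_vs_age,35,-0.0169681424644554,2.0227624615883,-4.29513878067387,
cbt_vs_age,30,-0.0170410701040307,2.06137440551501,-8.25130116621652,
cbt_vs_age,25,-0.0157787830433886,1.91466476660036,-6.20260326740659,
cbt_vs_age,20,-0.0167122724127826,2.05662251531788,-13.7715008757536,
cbt_vs_age,15,-0.0166593687084327,2.05597964570877,-16.829569041281,
cbt_vs_age,10,-0.0133868967107769,1.67625338926533,-9.72284380395601,
cbt_vs_age,5,-0.0117337143854443,1.44402133600941,7.28889567607614,
cbt_vs_age,1,-0.010687280671682,1.24843361091542,-8.58485523551771,
mas_vs_cbt,95,-0.000857981929991203,0.117607691107588,-1.85402559722552,78.2022555926577
mas_vs_cbt,90,-0.000592865902141304,0.0764841057193271,-0.355338862532387,56.69267284191
mas_vs_cbt,85,-0.000502062808887621,0.0643671787604766,-0.0894005043005408,52.1524594379553
mas_vs_cbt,80,-0.000490074790135214,0.0654716660316138,-0.426212402184699,56.8145022678056
mas_vs_cbt,75,-0.000489359549370988,0.0678475338520391,-0.775303966044259,62.2361192272739
mas_vs_cbt,70,-0.000484375684427441,0.0682825308713444,-0.9253936322067,63.0863675363802
mas_vs_cbt,65,-0.000485092288697697,0.0699434860078412,-1.15105112504433,66.0339464074639
mas_vs_cbt,60,-0.000475585307884191,0.0695155417310928,-1.24956856606118,67.0777205062206
mas_vs_cbt,55,-0.000471103014802327,0.0696613323047411,-1.35030902153644,67.6079394785388
mas_vs_cbt,50,-0.000461597593211932,0.0689830527955643,-1.40573625859058,67.6294134547456
mas_vs_cbt,45,-0.000466329788241626,0.0705627962797692,-1.55995421317296,68.878678937271
mas_vs_cbt,40,-0.000473771586423172,0.0721002418411415,-1.6779633178177,68.9954708286938
mas_vs_cbt,35,-0.000479639973981733,0.0742166314915503,-1.8848622068108,71.7688651366056
mas_vs_cbt,30,-0.000479175421289918,0.0750857638663224,-2.01487788832269,72.98120227837
mas_vs_cbt,25,-0.000487400091693166,0.0771993702161223,-2.17832760193635,73.6611242299634
mas_vs_cbt,20,-0.000494545002821492,0.0788870961312435,-2.31763713659349,74.1860736373012
mas_vs_cbt,15,-0.000496194521304186,0.0800278149954698,-2.4524220139837,74.7454541201928
mas_vs_cbt,10,-0.000501343356137093,0.0817727858706914,-2.62534767391634,75.5292163052138
mas_vs_cbt,5,-0.000486317994560698,0.0800148816134606,-2.63124240006265,73.1446354411568
mas_vs_cbt,1,-0.000403226727200751,0.0671590191306269,-2.17030695461673,63.3658339605904
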