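Fp1,Fp2,F3,F4,C3,C4,P3,P4,O1,O2,F7,F8,T7,T8,P7,P8,Fz,Cz,Pz,Oz,FC1,FC2,CP1,CP2,FC5,FC6,CP5,CP6,TP9,TP10,POz
0.1623608866,0.2929597339,0.0505538824,0.2742710046,-0.1224373077,0.1661241076,-0.2411596530,-0.0052508384,-0.2629680085,-0.1339695916,-0.0158548813,0.2988012616,-0.1726727993,0.1961094321,-0.2716863250,0.0443150633,0.1717706722,0.0253527357,-0.1306701661,-0.2043101111,0.0269022591,0.1769649224,-0.1350345233,0.0255191042,-0.0825387596,0.2598194733,-0.2289155372,0.1249715135,-0.2418935807,0.1291003987,-0.1765343684
0.2947374289,0.1676621410,0.2729545379,0.0531684181,0.1648361253,-0.1221761424,-0.0083736736,-0.2446296354,-0.1331068018,-0.2615606765,0.2933941346,-0.0145627178,0.1962421096,-0.1702828951,0.0455718124,-0.2705480688,0.1745816532,0.0269462947,-0.1296300530,-0.2027419908,0.1786625140,0.0296078299,0.0221297373,-0.1383817262,0.2566223803,-0.0820476774,0.1197730255,-0.2341643143,0.1329815773,-0.2423861640,-0.1752791829
-0.3200156306,-0.3229953721,-0.2262338385,-0.2298674914,-0.0291383085,-0.0313648951,0.1753036785,0.1746108004,0.2777778040,0.2768858299,-0.1938521342,-0.1997805655,-0.0157830512,-0.0188224605,0.1590621391,0.1578919178,-0.2426753872,-0.0366415460,0.1823883275,0.2852149806,-0.1437335401,-0.1450328389,0.0794213331,0.0787552446,-0.1213038923,-0.1252383200,0.0771649126,0.0757968131,0.0770553185,0.0786401708,0.2465100018
0.2087509383,0.2001647460,0.2164415165,0.2013997560,-0.0081222836,-0.0133572012,-0.1534348387,-0.1544831817,-0.1708436546,-0.1707739590,0.0743017125,0.0544893994,-0.0890781153,-0.0898530486,-0.1582996726,-0.1583116467,0.4525122966,0.2389601302,-0.1404478336,-0.1707181885,0.3371853725,0.3333017982,-0.0622771424,-0.0661755101,0.0102792754,-0.0009354906,-0.1338692504,-0.1381337790,-0.1414821260,-0.1427360715,-0.1644539473
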