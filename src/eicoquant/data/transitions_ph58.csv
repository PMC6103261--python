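# Eicosanoid MRM-HR channel panel: one quantifier transition per analyte, negative-ion mode.
# Columns: m/z in Th, potentials in volts (DP = declustering potential, CE = collision energy),
# window_da = full width of the fragment extraction window, expected_rt_min at mobile-phase pH 5.8.
# Internal-standard (deuterated) rows carry their own channels and co-elute with the natural form;
# RvD1-d4 has no natural partner in the retention-time reference, its RT is set to RvD2's (assumption).
# "12-HETE" appears twice in the source panel with slightly different product m/z; both channels are
# kept under ids 12-HETE and 12-HETE-2.
analyte_id,common_name,is_internal_standard,internal_standard_id,precursor_mz,product_mz,dp_volts,ce_volts,window_da,expected_rt_min
LTC4,LTC4,false,LTC4-d5,624.2969,272.0893,-23,-40,0.05,5.09
LTD4,LTD4,false,LTD4-d5,495.2531,143.0464,-30,-29,0.05,6.9
LTE4,LTE4,false,LTE4-d5,438.2312,235.1529,-30,-30,0.05,7.9
RvD2,RvD2,false,RvD1-d4,375.217,141.0538,-23,-29,0.05,6.23
6-keto-PGF1a,6-keto-PGF1α,false,6-keto-PGF1a-d4,369.2274,163.1132,-26,-24,0.05,2.45
PGG2,PGG2,false,PGE2-d4,367.2121,235.0903,-27,-28,0.05,6.73
"10(S),17(S)-diHDoHE","10(S),17(S)-diHDoHE",false,RvD1-d4,359.2222,153.092,-23,-26,0.05,10.4
PGF2a,PGF2α,false,PGF2a-d4,353.2326,309.2179,-28,-38,0.05,4.63
PGE2,PGE2,false,PGE2-d4,351.2168,189.1294,-27,-25,0.05,5.2
PGD2,PGD2,false,PGD2-d4,351.2168,189.1295,-31,-25,0.05,5.56
15-keto-PGE2,15-keto-PGE2,false,PGE2-d4,349.2017,287.1995,-23,-28,0.05,5.99
"11,12-diHETrE","11,12-diHETrE",false,5-HETE-d8,337.2377,167.1086,-37,-29,0.05,12.94
LTB4,LTB4,false,12-epi-LTB4-d4,335.2221,129.0552,-25,-28,0.05,10.54
PGJ2,PGJ2,false,PGD2-d4,333.2065,189.129,-23,-23,0.05,8.65
11-HETE,11-HETE,false,12-HETE-d8,319.2272,167.1078,-25,-29,0.05,14.08
5-oxo-ETE,5-oxo-ETE,false,5-oxo-ETE-d7,317.2116,203.1825,-23,-33,0.05,14.68
"15-deoxy-d12,14-PGJ2","15-deoxi-δ12,14-PGJ2",false,"15-deoxy-d12,14-PGJ2-d4",315.1962,203.1422,-24,-31,0.05,13.23
AA,AA,false,AA-d8,303.2324,259.2447,-22,-31,0.05,17.17
EPA,EPA,false,AA-d8,301.2172,257.2306,-32,-30,0.05,16.71
11-trans-LTD4,11-trans-LTD4,false,LTD4-d5,495.262,143.0468,-30,-30,0.05,6.9
TXB2,TXB2,false,TXB2-d4,369.2277,169.0874,-22,-24,0.05,4.06
20-OH-PGE2,20-OH-PGE2,false,PGE2-d4,367.2119,287.1995,-30,-31,0.05,1.8
7(R)-Maresin-1,7(R)-Maresin-1,false,RvD1-d4,359.2221,250.1228,-30,-27,0.05,10.21
19-OH-PGB2,19-OH-PGB2,false,PGE2-d4,349.2015,175.1131,-28,-39,0.05,2.28
"14,15-diHETrE","14,15-diHETrE",false,5-HETE-d8,337.2377,207.1393,-22,-29,0.05,12.73
"5,6-diHETE","5,6-diHETE",false,5-HETE-d8,335.2211,115.0403,-35,-25,0.05,12.91
PGB2,PGB2,false,PGE2-d4,333.2067,175.1125,-27,-32,0.05,8.7
5-HETE,5-HETE,false,5-HETE-d8,319.2275,115.0388,-22,-31,0.05,14.41
12-oxo-ETE,12-oxo-ETE,false,5-oxo-ETE-d7,317.2116,153.13,-35,-30,0.05,14.69
20-OH-LTB4,20-OH-LTB4,false,12-epi-LTB4-d4,351.2195,129.0544,-27,-30,0.05,3.06
6-trans-LTB4,6-trans-LTB4,false,12-epi-LTB4-d4,335.2248,129.0557,-20,-27,0.05,10.09
12-HETE,12-HETE,false,12-HETE-d8,319.2289,179.1071,-27,-30,0.05,14.22
15-oxo-ETE,15-oxo-ETE,false,5-oxo-ETE-d7,317.2145,113.0979,-15,-28,0.05,13.99
"5S,6R-LXA4","5S,6R-LXA4",false,"5S,6R-LXA4-d5",351.2192,217.1598,-22,-25,0.05,5.93
8-HETE,8-HETE,false,5-HETE-d8,319.2297,155.072,-22,-30,0.05,14.22
PGH2,PGH2,false,PGE2-d4,351.2186,271.2051,-29,-24,0.05,7.61
12-HETE-2,12-HETE,false,12-HETE-d8,319.2291,179.1081,-27,-30,0.05,14.22
20-HETE,20-HETE,false,15-HETE-d8,319.2293,289.2165,-18,-34,0.05,13.35
15-HETE,15-HETE,false,15-HETE-d8,319.2351,175.1496,-33,-30,0.05,13.89
"5,6-DiHETrE","5,6-DiHETrE",false,5-HETE-d8,337.2427,145.0513,-27,-31,0.05,13.22
6-keto-PGF1a-d4,6-keto-PGF1α-d4,true,,373.2534,211.1287,-35,-30,0.05,2.45
TXB2-d4,TXB2-d4,true,,373.2524,173.1132,-24,-19,0.05,4.06
PGE2-d4,PGE2-d4,true,,355.2424,275.2333,-37,-23,0.05,5.2
PGD2-d4,PGD2-d4,true,,355.2424,237.1451,-46,-18,0.05,5.56
"15-deoxy-d12,14-PGJ2-d4","15-deoxi-δ-12,14-PGJ2-d4",true,,319.2216,275.2341,-27,-23,0.05,13.23
PGF2a-d4,PGF2α-d4,true,,357.2583,177.1486,-37,-39,0.05,4.63
LTB4-d4,LTB4-d4,true,,339.2479,183.0386,-29,-43,0.05,10.54
5-HETE-d8,5-HETE-d8,true,,327.2791,116.0473,-24,-25,0.05,14.41
12-HETE-d8,12-HETE-d8,true,,327.2791,184.139,-34,-25,0.05,14.22
15-HETE-d8,15-HETE-d8,true,,327.2791,226.184,-47,-27,0.05,13.89
5-oxo-ETE-d7,5-oxo-ETE-d7,true,,324.2554,210.223,-29,-32,0.05,14.68
RvD1-d4,RvD1-d4,true,,350.2491,220.1764,-24,-27,0.05,6.23
LTC4-d5,LTC4-d5,true,,629.3274,272.0899,-20,-39,0.05,5.09
LTE4-d5,LTE4-d5,true,,443.2634,338.2218,-34,-27,0.05,7.9
AA-d8,AA-d8,true,,311.2832,237.0907,-35,-36,0.05,17.17
LTD4-d5,LTD4-d5,true,,500.2848,482.2772,-26,-28,0.05,6.9
12-epi-LTB4-d4,12-epi-LTB4-d4,true,,339.2471,197.1152,-36,-26,0.05,10.54
"5S,6R-LXA4-d5","5S,6R-LXA4-d5",true,,356.2491,222.1907,-30,-28,0.05,5.93
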