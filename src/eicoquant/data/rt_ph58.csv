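# Expected retention times (min) for the eicosanoid panel at mobile-phase pH 5.8, with the
# calibration-curve correlation coefficient (r^2) and the on-column LLOQ (pg) reported for each
# analyte. Names are given as printed in the source reference table; the loader resolves them to
# panel analyte_ids via the bundled alias map (e.g. PDx, MaR-1, LXA4 are reference-table synonyms).
# The duplicated 12-HETE channel (12-HETE-2) shares 12-HETE's retention time.
common_name,rt_min,r_squared,lloq_pg
20-OH-LTB4,3.06,0.9986,0.05
LTC4,5.09,0.9987,0.09
PGB2,8.70,0.9993,0.02
15-keto-PGE2,5.99,0.9994,0.05
20-OH-PGE2,1.80,0.9989,0.05
TXB2,4.06,0.9987,0.05
LXA4,5.93,0.9993,0.09
PGD2,5.56,0.9988,0.05
6-keto-PGF1a,2.45,0.9963,0.18
PGE2,5.20,0.9993,0.02
RvD2,6.23,0.9989,0.09
PGF2a,4.63,0.9968,0.09
19-OH-PGB2,2.28,0.9982,0.09
PGG2,6.73,0.9919,0.37
LTB4,10.54,0.9981,0.02
LTD4,6.90,0.9993,0.05
LTE4,7.90,0.9987,0.09
6-trans-LTB4,10.09,0.9977,0.05
11-trans-LTD4,6.90,0.9991,0.09
PDx,10.40,0.9991,0.05
MaR-1,10.21,0.9986,0.05
PGH2,7.61,0.9966,0.09
PGJ2,8.65,0.9993,0.05
"15-deoxy-d12,14-PGJ2",13.23,0.9970,0.09
5-HETE,14.41,0.9989,0.05
AA,17.17,0.9675,0.09
5-oxo-ETE,14.68,0.9986,0.02
20-HETE,13.35,0.9977,0.09
"5,6-diHETE",12.91,0.9992,0.02
12-HETE,14.22,0.9993,0.05
12-HETE-2,14.22,0.9993,0.05
8-HETE,14.22,0.9984,0.02
11-HETE,14.08,0.9972,0.05
12-oxo-ETE,14.69,0.9980,0.05
15-oxo-ETE,13.99,0.9969,0.05
"11,12-diHETrE",12.94,0.9981,0.05
"14,15-diHETrE",12.73,0.9931,0.05
EPA,16.71,0.9951,0.09
"5,6-DiHETrE",13.22,0.9974,0.09
15-HETE,13.89,0.9967,0.09
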