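# Name alias map for the eicosanoid panel. The source tables use inconsistent names for the
# same compound (trivial synonyms such as PDx for 10(S),17(S)-diHDoHE, case variants such as
# 5,6-DiHETE, and internal-standard label mismatches such as TXB2-d5 for the TXB2-d4 channel).
# Every alias maps to the canonical analyte_id used in transitions_ph58.csv.
alias,canonical
PDx,"10(S),17(S)-diHDoHE"
MaR-1,7(R)-Maresin-1
Maresin-1,7(R)-Maresin-1
LXA4,"5S,6R-LXA4"
LXA4-d5,"5S,6R-LXA4-d5"
TXB2-d5,TXB2-d4
RvD1-d5,RvD1-d4
"5,6-DiHETE","5,6-diHETE"
"11,12-DiHETrE","11,12-diHETrE"
"14,15-DiHETrE","14,15-diHETrE"
6-keto-PGF1α,6-keto-PGF1a
6-keto-PGF1α-d4,6-keto-PGF1a-d4
6-keto-PGF1-d4,6-keto-PGF1a-d4
PGF2α,PGF2a
PGF2α-d4,PGF2a-d4
PGF2-d4,PGF2a-d4
"15-deoxi-δ12,14-PGJ2","15-deoxy-d12,14-PGJ2"
"15-deoxy-δ-12,14-PGJ2","15-deoxy-d12,14-PGJ2"
"15-deoxi-δ-12,14-PGJ2-d4","15-deoxy-d12,14-PGJ2-d4"
"15-deoxy-δ-12,14-PGJ2-d4","15-deoxy-d12,14-PGJ2-d4"
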