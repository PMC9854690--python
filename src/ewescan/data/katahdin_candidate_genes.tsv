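# Published candidate-gene set for fecundity in Katahdin ewes (two-method
# selection-signature scan; Ovis_aries_v4.0 coordinates).
gene	method	group	chrom	position
CNOT11	FST	high	3	100058810
ATG10	FST	high	5	79156925
RPS23	FST	high	5	79446021
ANK2	FST	high	6	12314476
CAMK2D	FST	high	6	11870774
STK32B	FST	high	6	103213333
UGT8	FST	high	6	11004274
ADIRF	ROH	high	25	41056054
ARHGAP22	ROH	high	25	42255625
GHITM	ROH	high	25	38626280
GLUD1	ROH	high	25	41085197
GRID1	ROH	high	25	39879600
LRIT1	ROH	high	25	38706733
MAPK8	ROH	high	25	42210625
MMRN2	ROH	high	25	41018603
TRNAC-GCA	ROH	high	25	39208014
VSTM4	ROH	high	25	42748968
HERC6	ROH	low	6	36181502
CCL28	ROH	low	16	31346400
GHR	ROH	low	16	31832298
HMGCS1	ROH	low	16	31409821
DPF2	ROH	low	21	42741418
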