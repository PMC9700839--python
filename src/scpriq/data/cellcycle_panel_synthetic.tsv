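protein	stage
CCND1	G1
CCNE1	G1
CDC6	G1
CDT1	G1
MCM6	G1
E2F1	G1
PCNA	S
RRM2	S
MCM2	S
GINS2	S
CDC45	S
FEN1	S
CCNB1	G2M
CDK1	G2M
TOP2A	G2M
AURKA	G2M
BUB1	G2M
CCNA2	G2M
PLK1	prophase
CDC25C	prophase
NEK2	prophase
HMMR	prophase
KIF11	prophase
CENPA	prometaphase
CENPE	prometaphase
KIF2C	prometaphase
NDC80	prometaphase
BUB1B	prometaphase
AURKB	prometaphase
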