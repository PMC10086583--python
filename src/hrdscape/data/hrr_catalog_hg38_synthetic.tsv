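# Curated 70-gene homologous-recombination-repair (HRR) catalog.
# SYNTHETIC STAND-IN: gene roster assembled from canonical HRR / Fanconi
# anemia / PARPi-sensitivity pathway members; GRCh38 coordinates are
# approximate (Mb-scale), adequate for overlap with multi-Mb CN segments.
symbol	chrom	start	end
ATM	chr11	108222000	108370000
ATR	chr3	142449000	142578000
ATRX	chrX	77504000	77786000
BAP1	chr3	52402000	52411000
BARD1	chr2	214725000	214810000
BCL2L1	chr20	31665000	31724000
BLM	chr15	90718000	90816000
BRCA1	chr17	43044000	43170000
BRCA2	chr13	32315000	32400000
BRIP1	chr17	61679000	61864000
CDK12	chr17	39461000	39560000
CHEK1	chr11	125624000	125676000
CHEK2	chr22	28687000	28742000
CLSPN	chr1	35730000	35770000
DMC1	chr22	38512000	38564000
DNA2	chr10	68806000	68850000
EME1	chr17	50341000	50351000
ERCC1	chr19	45407000	45451000
ERCC4	chr16	13920000	13952000
ETAA1	chr2	67400000	67415000
EXO1	chr1	241810000	241852000
FANCA	chr16	89737000	89817000
FANCB	chrX	14861000	14891000
FANCC	chr9	95099000	95318000
FANCD2	chr3	10026000	10101000
FANCE	chr6	35452000	35467000
FANCF	chr11	22623000	22626000
FANCG	chr9	35073000	35080000
FANCI	chr15	89244000	89317000
FANCL	chr2	58159000	58242000
FANCM	chr14	45136000	45200000
GEN1	chr2	17816000	17848000
H2AFX	chr11	119093000	119096000
HELQ	chr4	83346000	83402000
HUS1	chr7	47965000	47981000
MCM4	chr8	47960000	47978000
MDC1	chr6	30699000	30717000
MRE11	chr11	94404000	94480000
MUS81	chr11	65851000	65864000
NBN	chr8	89924000	89976000
PALB2	chr16	23603000	23642000
PARP1	chr1	226360000	226408000
PARP2	chr14	20343000	20357000
PARP3	chr3	51938000	51944000
POLQ	chr3	121433000	121547000
PPP2R2A	chr8	26293000	26372000
PTEN	chr10	87863000	87971000
RAD50	chr5	132556000	132646000
RAD51	chr15	40695000	40732000
RAD51B	chr14	67819000	68730000
RAD51C	chr17	58692000	58735000
RAD51D	chr17	35092000	35120000
RAD52	chr12	911000	980000
RAD54B	chr8	94388000	94489000
RAD54L	chr1	46246000	46278000
RECQL4	chr8	144511000	144517000
RNF168	chr3	196467000	196502000
RNF8	chr6	31628000	31670000
RPA1	chr17	1733000	1802000
RTEL1	chr20	63657000	63696000
SLX4	chr16	3580000	3611000
TEX15	chr8	30808000	30885000
TIMELESS	chr12	56423000	56457000
TIPIN	chr15	66336000	66370000
TOPBP1	chr3	133596000	133661000
TP53BP1	chr15	43403000	43511000
USP11	chrX	47232000	47248000
WRN	chr8	31033000	31176000
XRCC2	chr7	152644000	152684000
XRCC3	chr14	103697000	103715000
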