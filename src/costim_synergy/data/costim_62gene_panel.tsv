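gene_name	unigene_id	gene_symbol	fc_rna_92s	fc_cl264	fc_combo	reported_ratio
CD69 molecule	Hs.208854	CD69	2.4	6.1	64.2	7.6
BCL2-related protein A1	Hs.227817	BCL2A1	2.7	22.2	96.6	3.9
baculoviral IAP repeat containing 3	Hs.127799	BIRC3	1.2	6.4	25.6	3.4
RALBP1 associated Eps domain containing 2	Hs.186810	REPS2	1.0	2.4	10.3	3.1
Interferon, beta 1, fibroblast	Hs.93177	IFNB1	1.6	1.9	10.8	3.1
Suppressor of tumorigenicity 20	Hs.729127	ST20	1.3	4.8	18.5	3.0
Chemokine (C-C motif) ligand 2	Hs.303649	CCL2	0.6	41.4	126.0	3.0
CD44 molecule	Hs.502328	CD44	1.5	4.3	17.5	3.0
Early growth response 3	Hs.534313	EGR3	2.1	3.3	15.9	2.9
Tubulin tyrosine ligase-like family	Hs.520554	TTLL2	1.1	3.1	11.9	2.8
Oligonucleotide/oligosaccharide-binding fold containing 2A	Hs.591610	OBFC2A	1.7	12.4	38.6	2.7
Interleukin 6 (interferon, beta 2)	Hs.654458	IL-6	0.9	4.9	14.7	2.6
Nuclear factor of kappa light polypeptide gene enhancer in B cells inhibitor, alpha	Hs.81328	NFKBIA	1.6	6.2	19.6	2.5
MIR155 host gene (non-protein-coding) (MIR155HG), noncoding RNA.	N/A	MIR155HG	1.5	1.9	8.1	2.4
Chemokine (C-C motif) ligand 1	Hs.72918	CCL1	2.4	15.6	41.8	2.3
RasGEF domain family, member 1B	Hs.591696	RASGEF1B	1.1	3.3	10.2	2.3
CD70 molecule	Hs.501497	CD70	1.4	6.1	16.5	2.2
G protein-coupled receptor 183	Hs.784	GPR183	1.0	2.6	7.8	2.2
ADAM metallopeptidase with thrombospondin type 1 motif, 10	Hs.657508	ADAMTS10	1.0	1.9	6.1	2.1
ADAM metallopeptidase domain 19	Hs.483944	ADAM19	2.4	3.6	12.6	2.1
FSHD region gene 2 family, member C	Hs.274541	FRG2C	0.8	1.1	4.1	2.1
Interleukin 23, alpha subunit p19	Hs.98309	IL-23A	1.6	7.8	19.4	2.1
EF-hand calcium binding domain 3	Hs.152670	EFCAB3	1.0	1.3	4.8	2.1
Neutrophil cytosolic factor 2	Hs.587558	NCF2	1.8	3.8	11.5	2.1
Interleukin 1, beta	Hs.126256	IL-1B	1.0	7.3	17.0	2.1
Nuclear receptor subfamily 4, group A, member 3	Hs.279522	NR4A3	1.4	3.1	9.4	2.1
Tumor necrosis factor, alpha-induced protein 3	Hs.211600	TNFAIP3	1.5	3.5	10.2	2.1
Regulator of G-protein signaling 1	Hs.75256	RGS1	1.7	3.5	10.7	2.0
Serum/glucocorticoid regulated kinase 1	Hs.510078	SGK1	0.5	1.8	4.8	2.0
v-rel reticuloendotheliosis viral oncogene homolog	Hs.631886	REL	1.1	2.4	6.7	2.0
Immediate early response 3	Hs.76095	IER3	0.8	4.3	9.9	1.9
Nuclear factor of kappa light polypeptide gene enhancer in B cells inhibitor, zeta	Hs.319171	NFKBIZ	1.3	2.7	7.8	1.9
Chemokine (C-C motif) ligand 4-like 2	Hs.661942	CCL4L2	2.0	21.0	43.9	1.9
Interleukin 18 receptor 1	Hs.469521	IL-18R1	2.5	6.9	17.9	1.9
Interleukin 8 (IL8)	Hs.624	IL-8	1.8	2.4	7.9	1.9
CASP8 and FADD-like apoptosis regulator	Hs.390736	CFLAR	1.5	2.2	6.8	1.9
pim-2 oncogene	Hs.496096	PIM2	0.8	3.0	7.1	1.8
Spermidine/spermine N1-acetyltransferase 1	Hs.28491	SAT1	1.6	3.6	9.5	1.8
Interleukin 4 induced 1	Hs.574492	IL-4I1	1.2	4.0	9.4	1.8
Chemokine (C-X-C motif) ligand 10	Hs.632586	CXCL10	1.6	5.8	13.1	1.8
Solute carrier family 29 (nucleoside transporters), member 2	Hs.569017	SLC29A2	1.4	3.4	8.6	1.8
Long intergenic non-protein-coding RNA 173, noncoding RNA.	N/A	LINC00173	1.8	3.2	8.8	1.8
Mitogen-activated protein kinase kinase kinase 8	Hs.432453	MAP3K8	1.1	4.1	9.1	1.8
Signal transducer and activator of transcription 5A	Hs.437058	STAT5A	0.8	1.9	4.6	1.7
ADP-ribosylation factor-like 5B	Hs.25362	ARL5B	1.5	3.1	7.9	1.7
Ninjurin 1	Hs.494457	NINJ1	0.9	3.4	7.3	1.7
Wingless-type MMTV integration site family, member 10A	Hs.121540	WNT10A	1.2	5.8	11.6	1.6
B cell translocation gene 1, antiproliferative	Hs.255935	BTG1	1.5	2.6	6.7	1.6
Fascin homolog 1, actin-bundling protein (*Strongylocentrotus purpuratus*)	Hs.118400	FSCN1	0.5	1.6	3.5	1.6
CD83 molecule	Hs.595133	CD83	1.7	5.2	11.4	1.6
Platelet-derived growth factor alpha polypeptide	Hs.535898	PDGFA	1.4	2.3	6.1	1.6
Transcription factor EC	Hs.125962	TFEC	0.6	3.1	6.1	1.6
CD40 molecule, TNF receptor superfamily member 5	Hs.472860	CD40	1.0	4.1	8.4	1.6
POU class 2 homeobox 2	Hs.654420	POU2F2	0.6	3.2	6.2	1.6
Nuclear receptor coactivator 7	Hs.171426	NCOA7	1.6	2.7	6.8	1.6
Zinc finger protein 36, C3H type-like 1	Hs.85155	ZFP36L1	1.3	2.0	5.1	1.6
Solute carrier family 7, member 11	Hs.390594	SLC7A11	1.4	2.2	5.7	1.6
FSHD region gene 2	Hs.626907	FRG2	1.1	1.3	3.7	1.5
Homo sapiens microRNA miR-146 stem-loop	N/A	hsa-mir-146a	1.1	3.7	7.3	1.5
Homo sapiens microRNA miR-21 stem-loop	N/A	hsa-mir-21	1.6	1.7	5.1	1.5
BTB (POZ) domain containing 19	Hs.632400	BTBD19	0.8	1.7	3.9	1.5
ELOVL fatty acid elongase 6	Hs.412939	ELOVL6	1.1	1.7	4.2	1.5
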