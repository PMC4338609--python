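# Synthetic kinase-substrate library for simulation and demonstration.
# Windows are idealized 15-mer consensus substrates (site at position 8),
# not curated biology: CDK1_SYN is proline-directed ([S/T]-P-x-K), PKA_SYN
# basophilic (R-R-x-S-hydrophobic), CAMK2_SYN basophilic (R-x-x-[S/T]),
# SRC_SYN an E-E-I-Y-G-E-F tyrosine consensus.
kinase_id	group	family	residue_class	substrate_window
CDK1_SYN	CMGC	CDK	ST	AKRVLGESPLKKARL
CDK1_SYN	CMGC	CDK	ST	GQRTPAESPAKKRVL
CDK1_SYN	CMGC	CDK	ST	VDSEKAFTPQKKLSG
CDK1_SYN	CMGC	CDK	ST	LNAPGRESPSKRKLE
PKA_SYN	AGC	PKA	ST	GALSRRASLDFEQKA
PKA_SYN	AGC	PKA	ST	TPELRRFSLGEKAVD
PKA_SYN	AGC	PKA	ST	KDMVRRGTFSELAKN
PKA_SYN	AGC	PKA	ST	SGELRRSSLADVKEG
CAMK2_SYN	CAMK	CAMK2	ST	SNLKRQETVDCLKKF
CAMK2_SYN	CAMK	CAMK2	ST	AGIMRQASVNDLEKM
CAMK2_SYN	CAMK	CAMK2	ST	TEVLRAESVKDFGKL
SRC_SYN	TK	SRC	Y	TADGEEIYGEFDSAK
SRC_SYN	TK	SRC	Y	LSEDEEIYGEFFAGR
SRC_SYN	TK	SRC	Y	PGVAEEIYGEFDKLT
SRC_SYN	TK	SRC	Y	NQEGEEIYGEFEPSA
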