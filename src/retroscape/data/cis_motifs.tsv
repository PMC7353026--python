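# Default cis-regulatory element catalog for promoter scanning.
# Names and response categories follow the PlantCARE vocabulary commonly
# reported for plant promoters; the IUPAC consensi are field-convention
# placeholders, NOT authoritative PlantCARE matrices (those are not
# redistributable here).  Supply your own catalog for real analyses.
name	category	iupac
CAAT-box	Enhancer	CCAAT
G-Box	Light	CACGTG
ACE	Light	GACACGTAGA
Box 4	Light	ATTAAT
MRE	Light	AACCTAA
GT1-motif	Light	GGTTAA
TCT-motif	Light	TCTTAC
TCA-element	Light	CCATCTTTTT
ARE	Anaerobic	AAACCA
ABRE	Hormone	ACGTG
AuxRR-core	Hormone	GGTCCAT
TGA-element	Hormone	AACGAC
CGTCA-motif	Hormone	CGTCA
LTR	Abiotic stress	CCGAAA
TC-rich repeats	Abiotic stress	ATTTTCTTCA
MBS	Abiotic stress	CAACTG
GCN4_motif	Development	TGAGTCA
circadian	Development	CAANNNNATC
A-box	Other	CCGTCC
O2-site	Other	GATGAYRTGR
TATA-box	Core	TATAWAW
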