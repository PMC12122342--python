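ligand	receptor	category
CXCL16	CXCR6	cytokine
IL17A	IL17RA	cytokine
IL17F	IL17RA	cytokine
IL26	IL20RA	cytokine
IL26	IL10RB	cytokine
IL22	IL22RA1	cytokine
IL16	CD4	cytokine
CXCL12	CXCR4	cytokine
CCL20	CCR6	cytokine
TGFB1	TGFBR1	growth factor
EGF	EGFR	growth factor
HGF	MET	growth factor
CD274	PDCD1	immune checkpoint
CTLA4	CD80	immune checkpoint
LGALS9	HAVCR2	immune checkpoint
APP	CD74	other
MIF	CD74	other
ICAM1	ITGAL	other
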