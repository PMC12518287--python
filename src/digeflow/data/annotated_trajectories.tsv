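organ	protein	mean_control	mean_anoxia	mean_reaeration
shoot	RuBisCO small subunit	10.0	7.0	4.0
shoot	fructose-bisphosphate aldolase, chloroplastic	10.0	9.4	5.0
shoot	phosphoribulokinase	10.0	7.0	4.0
shoot	sedoheptulose-1,7-bisphosphatase	10.0	6.0	3.0
shoot	RuBisCO large subunit	5.0	10.0	4.0
shoot	heat shock cognate 70 kDa protein 2	6.0	10.0	5.0
shoot	20 kDa chaperonin, chloroplastic isoform X1	4.0	7.0	10.0
shoot	oxygen-evolving enhancer protein 1	3.0	6.0	10.0
shoot	oxygen-evolving enhancer protein 2	4.0	6.0	10.0
shoot	photosynthetic NDH subunit of lumenal location 5	4.0	7.0	10.0
shoot	stromal 70 kDa heat shock-related protein	5.0	7.0	10.0
shoot	transketolase	4.0	6.0	10.0
shoot	2-Cys peroxiredoxin BAS1	7.0	4.0	10.0
root	fructose-bisphosphate aldolase 3, cytoplasmic	10.0	6.0	3.0
root	peroxidase P7	10.0	7.0	4.0
root	Prb1	5.0	10.0	4.0
root	acidic PR-1 type pathogenesis-related protein	3.0	7.0	10.0
root	glucan endo-1,3-beta-glucosidase 3 isoform X2	4.0	7.0	10.0
root	cysteine-rich receptor-like protein kinase 6	3.0	6.0	10.0
root	chitinase 2	4.0	8.0	10.0
root	alpha-L-arabinofuranosidase 1 isoform X3	9.0	5.0	10.0
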