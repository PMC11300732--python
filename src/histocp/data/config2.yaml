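# Grouping configuration 2: minority morphologies merged into other_nuclei,
# uncertain labels into ambiguous.
tumor: tumor
lymphocyte: lymphocyte
fibroblast: fibroblast
plasma_cell: plasma_cell
macrophage: macrophage
vascular_endothelium: vascular_endothelium
mitotic_figure: other_nuclei
myoepithelium: other_nuclei
neutrophil: other_nuclei
ductal_epithelium: other_nuclei
eosinophil: other_nuclei
apoptotic_body: ambiguous
unlabeled: ambiguous
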