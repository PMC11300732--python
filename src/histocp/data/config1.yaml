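# Grouping configuration 1: all labels merged into a single detection class.
tumor: nuclei
lymphocyte: nuclei
fibroblast: nuclei
unlabeled: nuclei
plasma_cell: nuclei
macrophage: nuclei
vascular_endothelium: nuclei
ductal_epithelium: nuclei
apoptotic_body: nuclei
mitotic_figure: nuclei
myoepithelium: nuclei
neutrophil: nuclei
eosinophil: nuclei
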