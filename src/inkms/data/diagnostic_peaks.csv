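# Diagnostic ions separating the two manuscript authors (positive-mode DI-MS).
# source=table: the curated diagnostic list (16 ions, 8 per author).
# source=figure: an additional author-B ion quoted in the overview figure at
#   272.0655; it is close to, but distinct from, the tabulated 273.0289 and is
#   carried unannotated because the two cannot be reconciled from the record.
# adduct is M+H unless stated; formula empty where no prediction was made.
author,observed_mz,annotation,formula,adduct,source
A,207.0654,Citropten/Scoparone - natural plant metabolite,C11H10O4,M+H,table
A,273.0289,,,,table
A,283.1178,Bis(2-methoxyethyl) phthalate,C14H18O6,M+H,table
A,291.0842,,,,table
A,305.0996,,,,table
A,327.0782,Triphenyl phosphate,C18H15O4P,M+H,table
A,344.1049,,,,table
A,349.0602,,C14H12N4O5S,M+H,table
B,113.9639,,,,table
B,130.5259,,,,table
B,230.9904,Citric acid (potassium adduct),C6H8O7,M+K,table
B,243.0993,,C11H10N6O,M+H,table
B,258.0286,,,,table
B,328.1794,,C14H25N5O2S,M+H,table
B,364.9642,,,,table
B,377.2091,,C21H24N6O,M+H,table
B,272.0655,,,,figure
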