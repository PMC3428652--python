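Chemical Viewed Functionally|isa|Chemical|D|
Pharmacologic Substance|isa|Chemical Viewed Functionally|D|
Antibiotic|isa|Pharmacologic Substance|D|
Biomedical or Dental Material|isa|Chemical Viewed Functionally|D|
Biologically Active Substance|isa|Chemical Viewed Functionally|D|
Neuroreactive Substance or Biogenic Amine|isa|Biologically Active Substance|D|
Hormone|isa|Biologically Active Substance|D|
Enzyme|isa|Biologically Active Substance|D|
Vitamin|isa|Biologically Active Substance|D|
Immunologic Factor|isa|Biologically Active Substance|D|
Receptor|isa|Biologically Active Substance|D|
Indicator, Reagent, or Diagnostic Aid|isa|Chemical Viewed Functionally|D|
Hazardous or Poisonous Substance|isa|Chemical Viewed Functionally|D|
Chemical Viewed Structurally|isa|Chemical|D|
Organic Chemical|isa|Chemical Viewed Structurally|D|
Nucleic Acid, Nucleoside, or Nucleotide|isa|Organic Chemical|D|
Organophosphorus Compound|isa|Organic Chemical|D|
Amino Acid, Peptide, or Protein|isa|Organic Chemical|D|
Carbohydrate|isa|Organic Chemical|D|
Lipid|isa|Organic Chemical|D|
Steroid|isa|Lipid|D|
Eicosanoid|isa|Lipid|D|
Inorganic Chemical|isa|Chemical Viewed Structurally|D|
Element, Ion, or Isotope|isa|Inorganic Chemical|D|
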