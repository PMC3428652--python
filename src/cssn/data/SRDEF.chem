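STY|T103|Chemical|A1.4.1|A substance viewed from functional or structural perspectives.||||||
STY|T120|Chemical Viewed Functionally|A1.4.1.1|||||||
STY|T121|Pharmacologic Substance|A1.4.1.1.1|||||||
STY|T195|Antibiotic|A1.4.1.1.1.1|||||||
STY|T122|Biomedical or Dental Material|A1.4.1.1.2|||||||
STY|T123|Biologically Active Substance|A1.4.1.1.3|||||||
STY|T124|Neuroreactive Substance or Biogenic Amine|A1.4.1.1.3.1|||||||
STY|T125|Hormone|A1.4.1.1.3.2|||||||
STY|T126|Enzyme|A1.4.1.1.3.3|||||||
STY|T127|Vitamin|A1.4.1.1.3.4|||||||
STY|T129|Immunologic Factor|A1.4.1.1.3.5|||||||
STY|T192|Receptor|A1.4.1.1.3.6|||||||
STY|T130|Indicator, Reagent, or Diagnostic Aid|A1.4.1.1.4|||||||
STY|T131|Hazardous or Poisonous Substance|A1.4.1.1.5|||||||
STY|T104|Chemical Viewed Structurally|A1.4.1.2|||||||
STY|T109|Organic Chemical|A1.4.1.2.1|||||||
STY|T114|Nucleic Acid, Nucleoside, or Nucleotide|A1.4.1.2.1.5|||||||
STY|T115|Organophosphorus Compound|A1.4.1.2.1.6|||||||
STY|T116|Amino Acid, Peptide, or Protein|A1.4.1.2.1.7|||||||
STY|T118|Carbohydrate|A1.4.1.2.1.8|||||||
STY|T119|Lipid|A1.4.1.2.1.9|||||||
STY|T110|Steroid|A1.4.1.2.1.9.1|||||||
STY|T111|Eicosanoid|A1.4.1.2.1.9.2|||||||
STY|T197|Inorganic Chemical|A1.4.1.2.2|||||||
STY|T196|Element, Ion, or Isotope|A1.4.1.2.2.1|||||||
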