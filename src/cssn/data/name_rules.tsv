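tui	name	head_form	modifier_form	priority_class
T103	Chemical	Chemical	Chemical	root
T120	Chemical Viewed Functionally	Chemical Viewed Functionally	Functionally Viewed	general_functional
T121	Pharmacologic Substance	Pharmacologic Substance	Pharmacologic	general_functional
T123	Biologically Active Substance	Biologically Active Substance	Biologically Active	general_functional
T124	Neuroreactive Substance or Biogenic Amine	Neuroreactive Substance or Biogenic Amine	Neuroreactive or Biogenic Amine	general_functional
T129	Immunologic Factor	Immunologic Factor	Immunologic	general_functional
T131	Hazardous or Poisonous Substance	Hazardous or Poisonous Substance	Hazardous or Poisonous	general_functional
T104	Chemical Viewed Structurally	Chemical Viewed Structurally	Structurally Viewed	structural
T109	Organic Chemical	Organic Chemical	Organic	structural
T110	Steroid	Steroid	Steroid	structural
T111	Eicosanoid	Eicosanoid	Eicosanoid	structural
T114	Nucleic Acid, Nucleoside, or Nucleotide	Nucleic Acid, Nucleoside, or Nucleotide	Nucleic Acid, Nucleoside, or Nucleotide	structural
T115	Organophosphorus Compound	Organophosphorus Compound	Organophosphorus	structural
T116	Amino Acid, Peptide, or Protein	Amino Acid, Peptide, or Protein	Amino Acid, Peptide, or Protein	structural
T118	Carbohydrate	Carbohydrate	Carbohydrate	structural
T119	Lipid	Lipid	Lipid	structural
T196	Element, Ion, or Isotope	Element, Ion, or Isotope	Element, Ion, or Isotope	structural
T197	Inorganic Chemical	Inorganic Chemical	Inorganic	structural
T122	Biomedical or Dental Material	Biomedical or Dental Material	Biomedical or Dental	specific_functional
T125	Hormone	Hormone	Hormone	specific_functional
T126	Enzyme	Enzyme	Enzyme	specific_functional
T127	Vitamin	Vitamin	Vitamin	specific_functional
T130	Indicator, Reagent, or Diagnostic Aid	Indicator, Reagent, or Diagnostic Aid	Indicator, Reagent, or Diagnostic Aid	specific_functional
T192	Receptor	Receptor	Receptor	specific_functional
T195	Antibiotic	Antibiotic	Antibiotic	specific_functional
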