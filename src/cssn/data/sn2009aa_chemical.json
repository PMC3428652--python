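{
 "release": "2009AA",
 "root": "T103",
 "types": [
  {
   "tui": "T103",
   "name": "Chemical",
   "tree_number": "A1.4.1",
   "definition": "A substance viewed from functional or structural perspectives."
  },
  {
   "tui": "T120",
   "name": "Chemical Viewed Functionally",
   "tree_number": "A1.4.1.1",
   "definition": ""
  },
  {
   "tui": "T121",
   "name": "Pharmacologic Substance",
   "tree_number": "A1.4.1.1.1",
   "definition": ""
  },
  {
   "tui": "T195",
   "name": "Antibiotic",
   "tree_number": "A1.4.1.1.1.1",
   "definition": ""
  },
  {
   "tui": "T122",
   "name": "Biomedical or Dental Material",
   "tree_number": "A1.4.1.1.2",
   "definition": ""
  },
  {
   "tui": "T123",
   "name": "Biologically Active Substance",
   "tree_number": "A1.4.1.1.3",
   "definition": ""
  },
  {
   "tui": "T124",
   "name": "Neuroreactive Substance or Biogenic Amine",
   "tree_number": "A1.4.1.1.3.1",
   "definition": ""
  },
  {
   "tui": "T125",
   "name": "Hormone",
   "tree_number": "A1.4.1.1.3.2",
   "definition": ""
  },
  {
   "tui": "T126",
   "name": "Enzyme",
   "tree_number": "A1.4.1.1.3.3",
   "definition": ""
  },
  {
   "tui": "T127",
   "name": "Vitamin",
   "tree_number": "A1.4.1.1.3.4",
   "definition": ""
  },
  {
   "tui": "T129",
   "name": "Immunologic Factor",
   "tree_number": "A1.4.1.1.3.5",
   "definition": ""
  },
  {
   "tui": "T192",
   "name": "Receptor",
   "tree_number": "A1.4.1.1.3.6",
   "definition": ""
  },
  {
   "tui": "T130",
   "name": "Indicator, Reagent, or Diagnostic Aid",
   "tree_number": "A1.4.1.1.4",
   "definition": ""
  },
  {
   "tui": "T131",
   "name": "Hazardous or Poisonous Substance",
   "tree_number": "A1.4.1.1.5",
   "definition": ""
  },
  {
   "tui": "T104",
   "name": "Chemical Viewed Structurally",
   "tree_number": "A1.4.1.2",
   "definition": ""
  },
  {
   "tui": "T109",
   "name": "Organic Chemical",
   "tree_number": "A1.4.1.2.1",
   "definition": ""
  },
  {
   "tui": "T114",
   "name": "Nucleic Acid, Nucleoside, or Nucleotide",
   "tree_number": "A1.4.1.2.1.5",
   "definition": ""
  },
  {
   "tui": "T115",
   "name": "Organophosphorus Compound",
   "tree_number": "A1.4.1.2.1.6",
   "definition": ""
  },
  {
   "tui": "T116",
   "name": "Amino Acid, Peptide, or Protein",
   "tree_number": "A1.4.1.2.1.7",
   "definition": ""
  },
  {
   "tui": "T118",
   "name": "Carbohydrate",
   "tree_number": "A1.4.1.2.1.8",
   "definition": ""
  },
  {
   "tui": "T119",
   "name": "Lipid",
   "tree_number": "A1.4.1.2.1.9",
   "definition": ""
  },
  {
   "tui": "T110",
   "name": "Steroid",
   "tree_number": "A1.4.1.2.1.9.1",
   "definition": ""
  },
  {
   "tui": "T111",
   "name": "Eicosanoid",
   "tree_number": "A1.4.1.2.1.9.2",
   "definition": ""
  },
  {
   "tui": "T197",
   "name": "Inorganic Chemical",
   "tree_number": "A1.4.1.2.2",
   "definition": ""
  },
  {
   "tui": "T196",
   "name": "Element, Ion, or Isotope",
   "tree_number": "A1.4.1.2.2.1",
   "definition": ""
  }
 ],
 "edges": [
  [
   "T120",
   "T103"
  ],
  [
   "T121",
   "T120"
  ],
  [
   "T195",
   "T121"
  ],
  [
   "T122",
   "T120"
  ],
  [
   "T123",
   "T120"
  ],
  [
   "T124",
   "T123"
  ],
  [
   "T125",
   "T123"
  ],
  [
   "T126",
   "T123"
  ],
  [
   "T127",
   "T123"
  ],
  [
   "T129",
   "T123"
  ],
  [
   "T192",
   "T123"
  ],
  [
   "T130",
   "T120"
  ],
  [
   "T131",
   "T120"
  ],
  [
   "T104",
   "T103"
  ],
  [
   "T109",
   "T104"
  ],
  [
   "T114",
   "T109"
  ],
  [
   "T115",
   "T109"
  ],
  [
   "T116",
   "T109"
  ],
  [
   "T118",
   "T109"
  ],
  [
   "T119",
   "T109"
  ],
  [
   "T110",
   "T119"
  ],
  [
   "T111",
   "T119"
  ],
  [
   "T197",
   "T104"
  ],
  [
   "T196",
   "T197"
  ]
 ]
}
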