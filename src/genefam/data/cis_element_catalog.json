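{
 "name": "plant_cis_elements_consensus",
 "note": "Compact consensus catalog (IUPAC) for plant promoter elements; replaceable via --catalog.",
 "entries": [
  {
   "name": "HSE",
   "iupac": "AGAANNTTCT",
   "functional_class": "stress"
  },
  {
   "name": "ARE",
   "iupac": "TGGTTT",
   "functional_class": "stress"
  },
  {
   "name": "TC-rich-repeats",
   "iupac": "ATTTTCTTCA",
   "functional_class": "stress"
  },
  {
   "name": "MBS",
   "iupac": "CAACTG",
   "functional_class": "stress"
  },
  {
   "name": "LTR",
   "iupac": "CCGAAA",
   "functional_class": "stress"
  },
  {
   "name": "ABRE",
   "iupac": "TACGTG",
   "functional_class": "hormone"
  },
  {
   "name": "CGTCA-motif",
   "iupac": "CGTCA",
   "functional_class": "hormone"
  },
  {
   "name": "TCA-element",
   "iupac": "CCATCTTTTT",
   "functional_class": "hormone"
  },
  {
   "name": "GARE-motif",
   "iupac": "TCTGTTG",
   "functional_class": "hormone"
  },
  {
   "name": "TGA-element",
   "iupac": "AACGAC",
   "functional_class": "hormone"
  },
  {
   "name": "circadian",
   "iupac": "CAANNNNATC",
   "functional_class": "development"
  },
  {
   "name": "CAT-box",
   "iupac": "GCCACT",
   "functional_class": "development"
  },
  {
   "name": "CCGTCC-box",
   "iupac": "CCGTCC",
   "functional_class": "development"
  }
 ]
}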