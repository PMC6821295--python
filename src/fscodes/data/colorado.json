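{
 "name": "colorado",
 "codon_length": 3,
 "assignments": {
  "UUU": "G",
  "UUC": "I",
  "UUA": "K",
  "UUG": "D",
  "UCU": "F",
  "UCC": "K",
  "UCA": "N",
  "UCG": "G",
  "UAU": "Y",
  "UAC": "Q",
  "UAA": "S",
  "UAG": "F",
  "UGU": "R",
  "UGC": "T",
  "UGA": "I",
  "UGG": "W",
  "CUU": "V",
  "CUC": "K",
  "CUA": "Q",
  "CUG": "A",
  "CCU": "H",
  "CCC": "D",
  "CCA": "M",
  "CCG": "L",
  "CAU": "R",
  "CAC": "G",
  "CAA": "C",
  "CAG": "H",
  "CGU": "S",
  "CGC": "I",
  "CGA": "Y",
  "CGG": "R",
  "AUU": "P",
  "AUC": "E",
  "AUA": "A",
  "AUG": "L",
  "ACU": "E",
  "ACC": "*",
  "ACA": "V",
  "ACG": "Y",
  "AAU": "T",
  "AAC": "C",
  "AAA": "P",
  "AAG": "Q",
  "AGU": "V",
  "AGC": "W",
  "AGA": "D",
  "AGG": "M",
  "GUU": "E",
  "GUC": "S",
  "GUA": "C",
  "GUG": "P",
  "GCU": "M",
  "GCC": "L",
  "GCA": "H",
  "GCG": "N",
  "GAU": "F",
  "GAC": "W",
  "GAA": "R",
  "GAG": "T",
  "GGU": "K",
  "GGC": "N",
  "GGA": "A",
  "GGG": "I"
 }
}
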