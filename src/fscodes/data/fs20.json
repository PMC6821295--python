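{
 "name": "fs20",
 "codon_length": 3,
 "assignments": {
  "UUU": "-",
  "UUC": "A",
  "UUA": "-",
  "UUG": "-",
  "UCU": "-",
  "UCC": "-",
  "UCA": "C",
  "UCG": "-",
  "UAU": "-",
  "UAC": "-",
  "UAA": "-",
  "UAG": "D",
  "UGU": "E",
  "UGC": "-",
  "UGA": "-",
  "UGG": "F",
  "CUU": "G",
  "CUC": "-",
  "CUA": "-",
  "CUG": "-",
  "CCU": "-",
  "CCC": "-",
  "CCA": "-",
  "CCG": "H",
  "CAU": "-",
  "CAC": "I",
  "CAA": "-",
  "CAG": "-",
  "CGU": "-",
  "CGC": "K",
  "CGA": "L",
  "CGG": "-",
  "AUU": "-",
  "AUC": "-",
  "AUA": "-",
  "AUG": "M",
  "ACU": "N",
  "ACC": "-",
  "ACA": "-",
  "ACG": "P",
  "AAU": "-",
  "AAC": "-",
  "AAA": "Q",
  "AAG": "-",
  "AGU": "-",
  "AGC": "R",
  "AGA": "-",
  "AGG": "-",
  "GUU": "-",
  "GUC": "-",
  "GUA": "S",
  "GUG": "-",
  "GCU": "-",
  "GCC": "T",
  "GCA": "-",
  "GCG": "-",
  "GAU": "V",
  "GAC": "W",
  "GAA": "-",
  "GAG": "-",
  "GGU": "*",
  "GGC": "-",
  "GGA": "-",
  "GGG": "Y"
 }
}
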