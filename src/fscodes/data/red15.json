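{
 "name": "red15",
 "codon_length": 3,
 "assignments": {
  "UUU": "-",
  "UUC": "F",
  "UUA": "-",
  "UUG": "-",
  "UCU": "-",
  "UCC": "-",
  "UCA": "-",
  "UCG": "-",
  "UAU": "Y",
  "UAC": "-",
  "UAA": "*",
  "UAG": "*",
  "UGU": "-",
  "UGC": "-",
  "UGA": "*",
  "UGG": "W",
  "CUU": "L",
  "CUC": "-",
  "CUA": "-",
  "CUG": "-",
  "CCU": "-",
  "CCC": "-",
  "CCA": "-",
  "CCG": "P",
  "CAU": "-",
  "CAC": "H",
  "CAA": "-",
  "CAG": "-",
  "CGU": "-",
  "CGC": "-",
  "CGA": "R",
  "CGG": "-",
  "AUU": "-",
  "AUC": "-",
  "AUA": "-",
  "AUG": "M",
  "ACU": "-",
  "ACC": "T",
  "ACA": "-",
  "ACG": "-",
  "AAU": "-",
  "AAC": "-",
  "AAA": "K",
  "AAG": "-",
  "AGU": "S",
  "AGC": "-",
  "AGA": "-",
  "AGG": "-",
  "GUU": "-",
  "GUC": "-",
  "GUA": "V",
  "GUG": "-",
  "GCU": "A",
  "GCC": "-",
  "GCA": "-",
  "GCG": "-",
  "GAU": "-",
  "GAC": "-",
  "GAA": "-",
  "GAG": "E",
  "GGU": "-",
  "GGC": "G",
  "GGA": "-",
  "GGG": "-"
 }
}
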