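{
 "name": "fs16",
 "codon_length": 3,
 "assignments": {
  "UUU": "A",
  "UUC": "-",
  "UUA": "-",
  "UUG": "-",
  "UCU": "-",
  "UCC": "-",
  "UCA": "E",
  "UCG": "-",
  "UAU": "-",
  "UAC": "-",
  "UAA": "-",
  "UAG": "F",
  "UGU": "-",
  "UGC": "G",
  "UGA": "-",
  "UGG": "-",
  "CUU": "-",
  "CUC": "H",
  "CUA": "-",
  "CUG": "-",
  "CCU": "-",
  "CCC": "-",
  "CCA": "-",
  "CCG": "K",
  "CAU": "-",
  "CAC": "-",
  "CAA": "L",
  "CAG": "-",
  "CGU": "M",
  "CGC": "-",
  "CGA": "-",
  "CGG": "*",
  "AUU": "-",
  "AUC": "-",
  "AUA": "P",
  "AUG": "-",
  "ACU": "-",
  "ACC": "Q",
  "ACA": "-",
  "ACG": "-",
  "AAU": "R",
  "AAC": "-",
  "AAA": "-",
  "AAG": "-",
  "AGU": "-",
  "AGC": "-",
  "AGA": "-",
  "AGG": "S",
  "GUU": "-",
  "GUC": "-",
  "GUA": "-",
  "GUG": "T",
  "GCU": "V",
  "GCC": "-",
  "GCA": "-",
  "GCG": "-",
  "GAU": "-",
  "GAC": "W",
  "GAA": "-",
  "GAG": "-",
  "GGU": "-",
  "GGC": "-",
  "GGA": "Y",
  "GGG": "-"
 }
}
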