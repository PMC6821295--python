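{
 "name": "red20",
 "codon_length": 3,
 "assignments": {
  "UUU": "F",
  "UUC": "-",
  "UUA": "-",
  "UUG": "-",
  "UCU": "-",
  "UCC": "-",
  "UCA": "S",
  "UCG": "-",
  "UAU": "-",
  "UAC": "Y",
  "UAA": "*",
  "UAG": "*",
  "UGU": "C",
  "UGC": "-",
  "UGA": "*",
  "UGG": "W",
  "CUU": "-",
  "CUC": "-",
  "CUA": "-",
  "CUG": "L",
  "CCU": "P",
  "CCC": "-",
  "CCA": "-",
  "CCG": "-",
  "CAU": "-",
  "CAC": "H",
  "CAA": "Q",
  "CAG": "-",
  "CGU": "-",
  "CGC": "R",
  "CGA": "-",
  "CGG": "-",
  "AUU": "-",
  "AUC": "-",
  "AUA": "I",
  "AUG": "M",
  "ACU": "-",
  "ACC": "T",
  "ACA": "-",
  "ACG": "-",
  "AAU": "N",
  "AAC": "-",
  "AAA": "-",
  "AAG": "K",
  "AGU": "-",
  "AGC": "-",
  "AGA": "-",
  "AGG": "-",
  "GUU": "-",
  "GUC": "V",
  "GUA": "-",
  "GUG": "-",
  "GCU": "-",
  "GCC": "-",
  "GCA": "-",
  "GCG": "A",
  "GAU": "D",
  "GAC": "-",
  "GAA": "-",
  "GAG": "E",
  "GGU": "-",
  "GGC": "-",
  "GGA": "G",
  "GGG": "-"
 }
}
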