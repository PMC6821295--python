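{
 "name": "fsquad",
 "codon_length": 4,
 "assignments": {
  "UUUU": "-",
  "UUUC": "-",
  "UUUA": "-",
  "UUUG": "-",
  "UUCU": "-",
  "UUCC": "-",
  "UUCA": "-",
  "UUCG": "A",
  "UUAU": "-",
  "UUAC": "-",
  "UUAA": "C",
  "UUAG": "-",
  "UUGU": "-",
  "UUGC": "-",
  "UUGA": "-",
  "UUGG": "-",
  "UCUU": "-",
  "UCUC": "-",
  "UCUA": "-",
  "UCUG": "-",
  "UCCU": "-",
  "UCCC": "-",
  "UCCA": "D",
  "UCCG": "-",
  "UCAU": "-",
  "UCAC": "-",
  "UCAA": "-",
  "UCAG": "-",
  "UCGU": "-",
  "UCGC": "-",
  "UCGA": "-",
  "UCGG": "-",
  "UAUU": "-",
  "UAUC": "-",
  "UAUA": "-",
  "UAUG": "-",
  "UACU": "-",
  "UACC": "-",
  "UACA": "-",
  "UACG": "-",
  "UAAU": "-",
  "UAAC": "-",
  "UAAA": "-",
  "UAAG": "-",
  "UAGU": "-",
  "UAGC": "-",
  "UAGA": "-",
  "UAGG": "E",
  "UGUU": "-",
  "UGUC": "F",
  "UGUA": "-",
  "UGUG": "-",
  "UGCU": "G",
  "UGCC": "-",
  "UGCA": "-",
  "UGCG": "-",
  "UGAU": "-",
  "UGAC": "-",
  "UGAA": "-",
  "UGAG": "H",
  "UGGU": "-",
  "UGGC": "-",
  "UGGA": "*",
  "UGGG": "-",
  "CUUU": "-",
  "CUUC": "-",
  "CUUA": "-",
  "CUUG": "-",
  "CUCU": "-",
  "CUCC": "-",
  "CUCA": "-",
  "CUCG": "-",
  "CUAU": "-",
  "CUAC": "-",
  "CUAA": "-",
  "CUAG": "-",
  "CUGU": "I",
  "CUGC": "-",
  "CUGA": "-",
  "CUGG": "-",
  "CCUU": "-",
  "CCUC": "-",
  "CCUA": "-",
  "CCUG": "-",
  "CCCU": "-",
  "CCCC": "K",
  "CCCA": "-",
  "CCCG": "-",
  "CCAU": "-",
  "CCAC": "-",
  "CCAA": "-",
  "CCAG": "-",
  "CCGU": "-",
  "CCGC": "-",
  "CCGA": "-",
  "CCGG": "-",
  "CAUU": "-",
  "CAUC": "-",
  "CAUA": "-",
  "CAUG": "-",
  "CACU": "-",
  "CACC": "-",
  "CACA": "-",
  "CACG": "-",
  "CAAU": "-",
  "CAAC": "-",
  "CAAA": "-",
  "CAAG": "L",
  "CAGU": "-",
  "CAGC": "-",
  "CAGA": "M",
  "CAGG": "-",
  "CGUU": "-",
  "CGUC": "-",
  "CGUA": "-",
  "CGUG": "-",
  "CGCU": "-",
  "CGCC": "-",
  "CGCA": "-",
  "CGCG": "-",
  "CGAU": "-",
  "CGAC": "-",
  "CGAA": "-",
  "CGAG": "-",
  "CGGU": "-",
  "CGGC": "N",
  "CGGA": "-",
  "CGGG": "-",
  "AUUU": "-",
  "AUUC": "-",
  "AUUA": "P",
  "AUUG": "-",
  "AUCU": "-",
  "AUCC": "-",
  "AUCA": "-",
  "AUCG": "-",
  "AUAU": "-",
  "AUAC": "-",
  "AUAA": "-",
  "AUAG": "-",
  "AUGU": "-",
  "AUGC": "-",
  "AUGA": "-",
  "AUGG": "-",
  "ACUU": "-",
  "ACUC": "-",
  "ACUA": "-",
  "ACUG": "-",
  "ACCU": "-",
  "ACCC": "-",
  "ACCA": "-",
  "ACCG": "-",
  "ACAU": "-",
  "ACAC": "-",
  "ACAA": "-",
  "ACAG": "-",
  "ACGU": "-",
  "ACGC": "-",
  "ACGA": "-",
  "ACGG": "-",
  "AAUU": "Q",
  "AAUC": "-",
  "AAUA": "-",
  "AAUG": "-",
  "AACU": "-",
  "AACC": "-",
  "AACA": "-",
  "AACG": "-",
  "AAAU": "-",
  "AAAC": "-",
  "AAAA": "R",
  "AAAG": "-",
  "AAGU": "-",
  "AAGC": "-",
  "AAGA": "-",
  "AAGG": "-",
  "AGUU": "-",
  "AGUC": "-",
  "AGUA": "-",
  "AGUG": "S",
  "AGCU": "-",
  "AGCC": "-",
  "AGCA": "-",
  "AGCG": "-",
  "AGAU": "-",
  "AGAC": "-",
  "AGAA": "-",
  "AGAG": "-",
  "AGGU": "-",
  "AGGC": "-",
  "AGGA": "-",
  "AGGG": "-",
  "GUUU": "-",
  "GUUC": "-",
  "GUUA": "-",
  "GUUG": "-",
  "GUCU": "-",
  "GUCC": "-",
  "GUCA": "-",
  "GUCG": "-",
  "GUAU": "-",
  "GUAC": "-",
  "GUAA": "-",
  "GUAG": "-",
  "GUGU": "-",
  "GUGC": "-",
  "GUGA": "-",
  "GUGG": "-",
  "GCUU": "-",
  "GCUC": "-",
  "GCUA": "-",
  "GCUG": "-",
  "GCCU": "-",
  "GCCC": "-",
  "GCCA": "-",
  "GCCG": "-",
  "GCAU": "-",
  "GCAC": "-",
  "GCAA": "-",
  "GCAG": "-",
  "GCGU": "-",
  "GCGC": "-",
  "GCGA": "-",
  "GCGG": "-",
  "GAUU": "-",
  "GAUC": "-",
  "GAUA": "-",
  "GAUG": "T",
  "GACU": "-",
  "GACC": "-",
  "GACA": "V",
  "GACG": "-",
  "GAAU": "-",
  "GAAC": "-",
  "GAAA": "-",
  "GAAG": "-",
  "GAGU": "-",
  "GAGC": "-",
  "GAGA": "-",
  "GAGG": "-",
  "GGUU": "-",
  "GGUC": "-",
  "GGUA": "-",
  "GGUG": "-",
  "GGCU": "-",
  "GGCC": "W",
  "GGCA": "-",
  "GGCG": "-",
  "GGAU": "Y",
  "GGAC": "-",
  "GGAA": "-",
  "GGAG": "-",
  "GGGU": "-",
  "GGGC": "-",
  "GGGA": "-",
  "GGGG": "-"
 }
}
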