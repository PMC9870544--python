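{
  "PA": "joy",
  "PE": "joy",
  "PD": "good",
  "PH": "good",
  "PG": "good",
  "PB": "good",
  "PK": "good",
  "NA": "anger",
  "NB": "sadness",
  "NJ": "sadness",
  "NH": "sadness",
  "PF": "sadness",
  "NI": "fear",
  "NC": "fear",
  "NG": "fear",
  "ND": "disgust",
  "NE": "disgust",
  "NN": "disgust",
  "NK": "disgust",
  "NL": "disgust",
  "PC": "surprise"
}
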