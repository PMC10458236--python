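{
  "1": {
    "name": "ORes",
    "intercept": "3.9243",
    "terms": [["F09[O-S]", "0.6729"], ["SaaN", "0.121"], ["MDEN-12", "1.005"]],
    "n_train": 278
  },
  "2": {
    "name": "OStr",
    "intercept": "7.1639",
    "terms": [
      ["VE2sign_B(m)", "-47.2151"],
      ["MATS6i", "2.8662"],
      ["GATS7p", "-1.5036"],
      ["H-048", "-0.1826"],
      ["O-060", "0.5367"],
      ["B08[N-O]", "-0.3698"],
      ["F06[C-S]", "0.3948"],
      ["SsNH2", "-0.1856"],
      ["minHBint6", "0.0537"],
      ["MDEN-12", "1.8451"],
      ["MDEN-22", "0.1755"],
      ["minaaCH", "-0.8906"]
    ],
    "n_train": 278
  },
  "3": {
    "name": "2D-QSAR",
    "intercept": "4.5562",
    "terms": [
      ["MATS6i", "2.5829"],
      ["nCp", "-0.191"],
      ["O-060", "0.3196"],
      ["B03[O-S]", "0.6746"],
      ["SsNH2", "-0.2499"],
      ["maxHBd", "2.4853"],
      ["hmin", "-2.3712"],
      ["MDEN-12", "1.1784"],
      ["minaaCH", "-0.6509"]
    ],
    "n_train": 279
  },
  "4": {
    "name": "2D-QSAR-Full",
    "intercept": "4.7334",
    "terms": [
      ["MATS6i", "2.3826"],
      ["nCp", "-0.2387"],
      ["O-060", "0.3401"],
      ["B03[O-S]", "0.6301"],
      ["SsNH2", "-0.248"],
      ["maxHBd", "2.1364"],
      ["hmin", "-2.3442"],
      ["MDEN-12", "1.8332"],
      ["minaaCH", "-0.6324"]
    ],
    "n_train": 370
  },
  "5": {
    "name": "q-RASAR",
    "intercept": "-1.1683",
    "terms": [
      ["RA function (ED)", "0.9192"],
      ["CATS2D_07_AL", "0.0718"],
      ["LLS_02", "1.2875"]
    ],
    "n_train": 279
  },
  "6": {
    "name": "q-RASAR-Full",
    "intercept": "-1.1089",
    "terms": [
      ["RA function (ED)", "0.9149"],
      ["CATS2D_07_AL", "0.0667"],
      ["LLS_02", "1.3166"]
    ],
    "n_train": 370
  }
}
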