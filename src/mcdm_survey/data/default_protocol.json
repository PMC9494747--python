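{
  "n_stages": 5,
  "categories": [
    {
      "code": "SOI",
      "label": "soil information",
      "variables": [
        {"name": "soil type", "stage": 1},
        {"name": "soil texture", "stage": 1},
        {"name": "bulk density", "stage": 1},
        {"name": "SOC stock", "stage": 1},
        {"name": "SON stock", "stage": 1},
        {"name": "pH", "stage": 1},
        {"name": "soil mineral N", "stage": 1},
        {"name": "FC, WFPS, and CEC", "stage": 1},
        {"name": "other soil information", "stage": 1}
      ]
    },
    {
      "code": "CL",
      "label": "climate during experiment",
      "variables": [
        {"name": "air temperature", "stage": 1},
        {"name": "precipitation", "stage": 1},
        {"name": "solar radiation", "stage": 1},
        {"name": "air humidity", "stage": 1},
        {"name": "atm. pressure", "stage": 1},
        {"name": "other climate factors", "stage": 1}
      ]
    },
    {
      "code": "MPDE",
      "label": "management practices during experiment",
      "variables": [
        {"name": "crop residues", "stage": 1},
        {"name": "fertilization rates", "stage": 1},
        {"name": "fertilization mode", "stage": 1},
        {"name": "fertilizer type", "stage": 1},
        {"name": "irrigation", "stage": 1},
        {"name": "frequency of plowing", "stage": 1},
        {"name": "frequency other activities", "stage": 1},
        {"name": "intercropping", "stage": 1},
        {"name": "freq. harvest, grazing, and cut in grass", "stage": 1}
      ]
    },
    {
      "code": "SI",
      "label": "general site information",
      "variables": [
        {"name": "crop type", "stage": 1},
        {"name": "location", "stage": 1},
        {"name": "terrain info", "stage": 1},
        {"name": "experimental length", "stage": 1},
        {"name": "mean regional yield", "stage": 2}
      ]
    },
    {
      "code": "LTCL",
      "label": "long-term climate",
      "variables": [
        {"name": "air temperature", "stage": 2},
        {"name": "precipitation", "stage": 2},
        {"name": "solar radiation", "stage": 2},
        {"name": "air humidity", "stage": 2},
        {"name": "atm. pressure", "stage": 2},
        {"name": "other climate factors", "stage": 2}
      ]
    },
    {
      "code": "LTMP",
      "label": "long-term management practices",
      "variables": [
        {"name": "fertilization rates", "stage": 2},
        {"name": "fertilization mode", "stage": 2},
        {"name": "fertilizer type", "stage": 2},
        {"name": "irrigation", "stage": 2},
        {"name": "frequency of harvest", "stage": 2},
        {"name": "frequency of plowing", "stage": 2},
        {"name": "frequency other activities", "stage": 2},
        {"name": "crop residues", "stage": 2},
        {"name": "intercropping", "stage": 2},
        {"name": "land use history", "stage": 2}
      ]
    },
    {
      "code": "EDS",
      "label": "experimental data from site",
      "variables": [
        {"name": "annual extracted yield", "stage": 3},
        {"name": "vegetation data (phenology, LAI)", "stage": 3},
        {"name": "soil temperature", "stage": 4},
        {"name": "soil moisture", "stage": 4},
        {"name": "soil mineral N", "stage": 4},
        {"name": "SOC and SON", "stage": 5},
        {"name": "GPP and NEP", "stage": 5},
        {"name": "NEE and Reco", "stage": 5},
        {"name": "soil N losses", "stage": 5},
        {"name": "N2O and/or CH4", "stage": 5}
      ]
    }
  ]
}
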