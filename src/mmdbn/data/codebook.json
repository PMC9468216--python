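{
  "description": "Integer codings of the 11 study variables (10 predictors plus the multimorbidity outcome) for the CHARLS-style multimorbidity analysis.",
  "variables": [
    {
      "name": "physical_activity",
      "symbol": "x1",
      "ordinal": true,
      "codes": [[1, "light"], [2, "moderate"], [3, "vigorous"]]
    },
    {
      "name": "sex",
      "symbol": "x2",
      "ordinal": false,
      "codes": [[1, "men"], [2, "women"]]
    },
    {
      "name": "age",
      "symbol": "x3",
      "ordinal": true,
      "codes": [[1, "<=55"], [2, "<=65"], [3, "<=75"], [4, ">75"]]
    },
    {
      "name": "education",
      "symbol": "x4",
      "ordinal": true,
      "codes": [[1, "<=primary school"], [2, "<=high school"], [3, "<=college"], [4, ">college"]]
    },
    {
      "name": "residence",
      "symbol": "x5",
      "ordinal": false,
      "codes": [[1, "urban"], [2, "boundary"], [3, "rural"], [4, "special"]]
    },
    {
      "name": "marital_status",
      "symbol": "x6",
      "ordinal": false,
      "codes": [[1, "married"], [2, "divorced"], [3, "widowed"], [4, "never married"]]
    },
    {
      "name": "sleep",
      "symbol": "x7",
      "ordinal": true,
      "codes": [[1, "<=5 h"], [2, "<=6 h"], [3, "<=7 h"], [4, "<=8 h"], [5, ">8 h"]]
    },
    {
      "name": "nap",
      "symbol": "x8",
      "ordinal": true,
      "codes": [[1, "0 min"], [2, "<=30 min"], [3, ">30 min"]]
    },
    {
      "name": "smoking",
      "symbol": "x9",
      "ordinal": false,
      "codes": [[0, "no"], [1, "yes"]]
    },
    {
      "name": "alcohol",
      "symbol": "x10",
      "ordinal": false,
      "codes": [[0, "no"], [1, "yes"]]
    },
    {
      "name": "mmd",
      "symbol": "y",
      "ordinal": false,
      "codes": [[0, "no"], [1, "yes"]]
    }
  ]
}
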