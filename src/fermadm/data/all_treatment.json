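{
 "schema_version": 1,
 "description": "Leukemia (ALL) treatment-selection case: four therapy alternatives judged on five attributes over three evaluation periods, with time weights eps and attribute weights omega.",
 "alternatives": ["Chemotherapy", "HSCT", "Radiation", "CAR-T"],
 "attributes": ["SurvivalRate", "Remission", "SideEffects", "Efficiency", "Reliability"],
 "periods": ["2017-2019", "2019-2021", "2021-2023"],
 "time_weights": [0.2, 0.3, 0.5],
 "attribute_weights": [0.3, 0.25, 0.1, 0.2, 0.15],
 "matrices": [
  [
   [[0.7, 0.4], [0.6, 0.5], [0.9, 0.6], [0.8, 0.4], [0.7, 0.3]],
   [[0.8, 0.6], [0.7, 0.8], [0.7, 0.4], [0.7, 0.6], [0.6, 0.6]],
   [[0.6, 0.8], [0.5, 0.7], [0.8, 0.5], [0.7, 0.5], [0.5, 0.4]],
   [[0.9, 0.6], [0.8, 0.4], [0.5, 0.8], [0.6, 0.4], [0.7, 0.5]]
  ],
  [
   [[0.6, 0.7], [0.7, 0.6], [0.8, 0.6], [0.8, 0.7], [0.7, 0.5]],
   [[0.7, 0.6], [0.8, 0.7], [0.6, 0.5], [0.6, 0.9], [0.6, 0.5]],
   [[0.5, 0.7], [0.6, 0.6], [0.7, 0.5], [0.7, 0.6], [0.5, 0.6]],
   [[0.7, 0.5], [0.7, 0.5], [0.4, 0.7], [0.7, 0.4], [0.8, 0.6]]
  ],
  [
   [[0.7, 0.5], [0.7, 0.5], [0.9, 0.4], [0.8, 0.5], [0.8, 0.4]],
   [[0.8, 0.7], [0.8, 0.5], [0.7, 0.5], [0.7, 0.6], [0.7, 0.8]],
   [[0.6, 0.5], [0.6, 0.4], [0.8, 0.6], [0.6, 0.4], [0.6, 0.5]],
   [[0.9, 0.5], [0.8, 0.5], [0.3, 0.4], [0.9, 0.5], [0.8, 0.5]]
  ]
 ]
}
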