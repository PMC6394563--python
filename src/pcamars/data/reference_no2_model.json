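{
 "comment": "Published Tehran NO2 PCAMARS model over the first two principal-component scores (x1, x2); units ug/m3. BF3 is the two-way interaction of BF2 with a hinge in x1.",
 "intercept": 76.358,
 "coefficients": [-16.112, 32.65, -8.6937, 44.605],
 "basis": [
  [{"var_index": 0, "sign": 1, "knot": -2.3324}],
  [{"var_index": 1, "sign": -1, "knot": 0.55517}],
  [{"var_index": 1, "sign": -1, "knot": 0.55517},
   {"var_index": 0, "sign": -1, "knot": 2.8871}],
  [{"var_index": 0, "sign": 1, "knot": 2.8871}]
 ],
 "gcv": 0.0,
 "sse": 0.0,
 "penalty": 3.0,
 "n_train": 21
}
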