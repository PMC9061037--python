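{
  "description": "Reference quadratic-in-LET, linear-in-dose yield correlation parameters per DSB category: Yield(D, L) = D * (a*L^2 + b*L + c), per cell assuming a 6 Gbp genome. D in Gy, L in keV/um.",
  "version": 1,
  "categories": {
    "simple_DSB": {
      "a": -2.44e-3, "a_err": 0.36e-3,
      "b": 3.98e-1, "b_err": 0.12e-1,
      "c": 1.64e1, "c_err": 0.01e1
    },
    "simple_DSB_with_base": {
      "a": -6.77e-4, "a_err": 1.46e-4,
      "b": 2.09e-1, "b_err": 0.1e-1,
      "c": 2.38, "c_err": 0.03
    },
    "complex_DSB": {
      "a": 1.29e-3, "a_err": 0.28e-3,
      "b": 3.16e-1, "b_err": 0.01e-1,
      "c": 4.86, "c_err": 0.05
    },
    "complex_DSB_with_base": {
      "a": 3.47e-3, "a_err": 0.21e-3,
      "b": 1.41e-1, "b_err": 0.0,
      "c": 1.56, "c_err": 0.04
    }
  }
}
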