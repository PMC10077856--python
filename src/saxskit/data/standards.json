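{
  "cholesteryl_palmitate": {
    "description": "Lamellar calibration standard for line-collimation SAXS cameras. Nominal first-order crystalline layer spacing 5.25 nm with its second and third orders; reconstruction of commonly quoted literature values — override with a user constants file if your reference differs.",
    "d_nm": [5.25, 2.625, 1.75]
  },
  "silver_behenate": {
    "description": "Common low-angle calibrant; first three orders of the 5.8380 nm layer spacing (Huang et al., 1993).",
    "d_nm": [5.838, 2.919, 1.946]
  }
}
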