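{
  "description": "Published 14-pair L1-penalized Cox risk model for HPV-negative HNSC (coefficients transcribed from the source study's risk formula). Risk score = sum of coefficient * pair score.",
  "endpoint": "OS",
  "lambda": null,
  "coefficients": {
    "GNAI2_FPR1": 0.175589783027359,
    "GNAI2_EDNRB": -0.0128431897633999,
    "CCL19_CCR10": -0.108050441595785,
    "SLIT2_ROBO4": -0.342190215420395,
    "LAMC2_ITGA6": -0.0910650517305777,
    "VEGFC_LYVE1": 0.130137931298295,
    "PLAU_ITGA5": 0.0431468647033098,
    "L1CAM_ITGA5": 0.279226243223637,
    "CCL17_CCR4": -0.0154870550240251,
    "AGRN_ITGB1": -0.127059688838762,
    "APP_NCSTN": 0.384422861030184,
    "CXCL13_CXCR3": -0.251637937042456,
    "IL1A_IL1RAP": 0.176155924945072,
    "COL5A1_ITGB1": -0.0457893288731351
  }
}
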