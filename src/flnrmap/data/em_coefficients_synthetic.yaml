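# SYNTHETIC example coefficients for the EM1/EM2/EM5 model forms.
#
# These are placeholder values for demonstration and testing only; the
# canonical per-PFT parameters are published in the original model papers
# and are NOT reproduced here.  Units: n1 in (umol m-2 s-1)/(g N m-2),
# n2 and intercept in umol m-2 s-1; climate weights per the predictor's
# unit; co2 weight per ppm with co2_ppm the scalar mixing ratio.
EM1:
  form: linear_lnc
  coefficients:
    CRO: {n1: 28.0, n2: 12.0}
    DBF: {n1: 24.0, n2: 14.0}
    EBF: {n1: 22.0, n2: 10.0}
    ENF: {n1: 18.0, n2: 16.0}
    MF:  {n1: 21.0, n2: 13.0}
    GRA: {n1: 30.0, n2: 10.0}
    SH:  {n1: 26.0, n2: 9.0}
    WET: {n1: 27.0, n2: 11.0}
EM2:
  form: linear_lnc
  coefficients:
    CRO: {n1: 28.0, n2: 12.0}
    DBF: {n1: 24.0, n2: 14.0}
    EBF: {n1: 14.0, n2: 10.0}   # reduced EBF slope: implicit P limitation
    ENF: {n1: 18.0, n2: 16.0}
    MF:  {n1: 21.0, n2: 13.0}
    GRA: {n1: 30.0, n2: 10.0}
    SH:  {n1: 26.0, n2: 9.0}
    WET: {n1: 27.0, n2: 11.0}
EM5:
  form: linear_climate
  coefficients:
    CRO: {intercept: 45.0, tair: 0.6, pp: -0.004, par: 0.015, co2: 0.0, co2_ppm: 400.0}
    DBF: {intercept: 50.0, tair: 0.4, pp: -0.003, par: 0.012, co2: 0.0, co2_ppm: 400.0}
    EBF: {intercept: 40.0, tair: 0.3, pp: -0.002, par: 0.010, co2: 0.0, co2_ppm: 400.0}
    ENF: {intercept: 55.0, tair: 0.5, pp: -0.004, par: 0.008, co2: 0.0, co2_ppm: 400.0}
    MF:  {intercept: 50.0, tair: 0.4, pp: -0.003, par: 0.010, co2: 0.0, co2_ppm: 400.0}
    GRA: {intercept: 48.0, tair: 0.7, pp: -0.005, par: 0.014, co2: 0.0, co2_ppm: 400.0}
    SH:  {intercept: 42.0, tair: 0.6, pp: -0.004, par: 0.012, co2: 0.0, co2_ppm: 400.0}
    WET: {intercept: 44.0, tair: 0.5, pp: -0.003, par: 0.011, co2: 0.0, co2_ppm: 400.0}
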