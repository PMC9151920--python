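# Published parameter-search grids (per seeding condition), fitted hexads,
# and reference threshold / MSSCD / inflection densities.
table1_grids:
  1:
    r_p: [0.03, 0.13, 0.23, 0.33, 0.43, 0.53, 0.63, 0.73, 0.83, 0.93]
    K: [1.03, 1.23, 1.43, 1.63, 1.83, 2.03, 2.23, 2.43, 2.63, 2.83]
    n: [0.0035, 0.0095, 0.0155, 0.0215, 0.0275, 0.0335, 0.0395, 0.0455, 0.0515, 0.0575]
    alpha: [0.90, 1.15, 1.40, 1.65, 1.90, 2.15, 2.40, 2.65, 2.90, 3.15]
    beta: [0.19, 0.59, 0.99, 1.39, 1.79, 2.19, 2.59, 2.99, 3.39, 3.79]
    delta: [0.2, 1.0, 1.8, 2.6, 3.4, 4.2, 5.0, 5.8, 6.6, 7.4]
  2:
    r_p: [0.01, 0.07, 0.13, 0.19, 0.25, 0.31, 0.37, 0.43, 0.49, 0.55]
    K: [2.22, 2.61, 3.00, 3.39, 3.78, 4.17, 4.56, 4.95, 5.34, 5.73]
    n: [0.004, 0.014, 0.024, 0.034, 0.044, 0.054, 0.064, 0.074, 0.084, 0.094]
    alpha: [0.22, 0.42, 0.62, 0.82, 1.02, 1.22, 1.42, 1.62, 1.82, 2.02]
    beta: [0.1, 0.5, 0.9, 1.3, 1.7, 2.1, 2.5, 2.9, 3.3, 3.7]
    delta: [0.08, 0.32, 0.56, 0.80, 1.04, 1.28, 1.52, 1.76, 2.00, 2.24]
  3:
    r_p: [0.00, 0.13, 0.26, 0.39, 0.52, 0.65, 0.78, 0.91, 1.04, 1.17]
    K: [1.00, 2.56, 4.12, 5.68, 7.24, 8.80, 10.36, 11.92, 13.48, 15.04]
    n: [0.0057, 0.0157, 0.0257, 0.0357, 0.0457, 0.0557, 0.0657, 0.0757, 0.0857, 0.0957]
    alpha: [0.30, 0.99, 1.68, 2.37, 3.06, 3.75, 4.44, 5.13, 5.82, 6.51]
    beta: [1.44, 2.38, 3.32, 4.26, 5.20, 6.14, 7.08, 8.02, 8.96, 9.90]
    delta: [0.025, 0.030, 0.035, 0.040, 0.045, 0.050, 0.055, 0.060, 0.065, 0.070]
table2_hexads:
  1: {r_p: 0.13, K: 1.43, n: 0.0095, alpha: 1.15, beta: 0.99, delta: 0.2}
  2: {r_p: 0.13, K: 3.39, n: 0.074, alpha: 0.42, beta: 1.3, delta: 0.08}
  3: {r_p: 0.13, K: 2.56, n: 0.0757, alpha: 0.99, beta: 1.44, delta: 0.07}
table3_reference:
  1: {threshold: 0.0671, mssd: 1.3507, inflection_low: 0.0359, inflection_high: 0.9325}
  2: {threshold: 0.2062, mssd: 2.1799, inflection_low: 0.0897, inflection_high: 1.4152}
  3: {threshold: 0.6549, mssd: 1.9761, inflection_low: 0.3109, inflection_high: 1.478}
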