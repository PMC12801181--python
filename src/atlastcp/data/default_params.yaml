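# Reference radiosensitivity parameter set for prostate EBRT TCP modelling.
#
# alpha_*   : log-normal inter-patient distribution of the LQ alpha coefficient
#             (arithmetic mean / SD in Gy^-1, hard truncation window).
# ab_single : Gleason-grade-independent alpha/beta ratio (Gy).
# gp_alpha  : Gleason-Pattern-dependent alpha (Gy^-1); strictly decreasing with
#             pattern (more aggressive pattern -> more radioresistant).
# gs_ab     : Gleason-Score-dependent alpha/beta ratios (Gy); strictly
#             increasing with score, constrained to [1, 8.3] Gy.
version: 1
alpha_mean: 0.15
alpha_sd: 0.04
alpha_low: 0.05
alpha_high: 0.40
ab_single: 1.77
gp_alpha:
  2: 0.194
  3: 0.128
  4: 0.124
  5: 0.102
gs_ab:
  "2+2": 1.54
  "3+2": 1.87
  "3+3": 2.05
  "3+4": 2.11
  "4+3": 2.16
  "4+4": 2.34
  "4+5": 2.67
  "5+4": 2.92
  "5+5": 3.05
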