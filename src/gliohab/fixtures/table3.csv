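map,habitat,c1,c2,c3,c4,c5,c6,c7,c8,c9,c10,c11,c12,c13,c14,c15,c16,c17
Vp,1,5.90,8.80,3.72,0.98,7.67,7.04,5.85,2.86,6.42,2.32,4.90,2.00,1.28,9.25,7.51,6.60,5.95
Vp,2,5.39,8.43,3.40,1.16,5.14,5.15,6.55,2.63,5.36,2.27,4.47,1.91,1.36,7.48,8.45,6.71,6.67
Vp,3,4.79,8.16,2.66,1.22,5.20,4.37,5.45,1.72,3.14,2.07,3.52,1.75,1.08,7.80,5.95,5.91,4.77
Vp,4,4.74,7.46,2.84,1.10,4.82,4.41,5.25,1.69,2.97,1.91,3.25,1.55,1.10,7.04,6.18,6.12,4.59
Vp,5,2.65,4.90,1.28,0.68,2.18,0.92,2.48,1.13,1.21,0.97,1.22,0.65,0.24,2.40,2.69,3.06,2.36
Vp,6,2.79,5.76,1.45,0.71,2.71,2.08,2.96,1.20,1.16,1.28,1.26,0.71,0.34,2.47,2.96,3.71,2.86
Vp,7,0.86,4.44,0.64,0.51,1.26,0.01,1.17,1.03,1.03,0.65,0.94,0.11,0.18,1.77,0.47,1.30,1.16
Vp,8,1.66,4.80,0.66,0.47,1.75,0.15,1.46,0.99,1.02,0.91,1.07,0.21,0.33,1.92,0.84,2.15,1.72
Vp,whole,1.94,5.89,0.83,0.64,2.32,0.25,1.88,1.14,1.40,1.14,1.23,0.31,0.43,2.81,1.15,3.84,1.67
FAZA,1,0.77,1.55,1.26,0.73,1.97,1.73,2.08,1.38,1.06,1.52,0.84,1.38,0.41,3.45,1.48,1.43,1.05
FAZA,2,1.00,1.26,1.86,1.13,1.95,1.87,2.48,1.14,1.90,1.76,0.83,2.00,0.44,3.45,1.38,1.48,1.38
FAZA,3,0.30,0.70,0.69,0.33,1.03,0.81,1.04,0.42,0.37,0.61,0.31,0.46,0.26,1.28,0.54,0.84,0.47
FAZA,4,0.45,0.70,0.65,0.34,1.12,0.88,0.99,0.39,0.37,0.65,0.30,0.78,0.26,1.21,0.57,0.83,0.66
FAZA,5,0.73,1.69,1.64,0.66,1.81,1.66,1.92,0.74,0.69,1.76,0.64,1.22,0.37,3.46,1.33,1.27,0.87
FAZA,6,0.84,1.29,1.97,0.77,1.75,2.21,2.09,0.73,0.88,1.68,0.65,1.52,0.40,3.44,1.15,1.38,0.97
FAZA,7,0.13,0.43,0.12,0.27,0.56,0.16,0.23,0.37,0.33,0.31,0.25,0.22,0.25,0.44,0.15,0.40,0.30
FAZA,8,0.22,0.46,0.16,0.26,0.88,0.21,0.28,0.36,0.32,0.33,0.20,0.29,0.26,0.56,0.19,0.56,0.45
FAZA,whole,0.24,0.63,0.18,0.31,1.31,0.25,0.47,0.38,0.34,0.45,0.24,0.35,0.30,1.79,0.26,0.92,0.42
MD,1,1.60,1.05,1.54,1.22,0.97,1.49,1.64,0.49,1.26,1.24,1.45,1.28,1.48,1.46,1.70,1.24,0.95
MD,2,0.99,0.85,1.13,0.86,0.81,1.13,1.15,0.40,1.03,0.90,1.08,0.95,1.19,1.12,1.20,0.88,0.76
MD,3,1.68,1.05,1.65,1.33,1.04,1.45,1.65,0.50,1.20,1.30,1.40,1.39,1.51,1.46,1.64,1.27,0.99
MD,4,1.10,0.79,1.15,1.02,0.73,1.14,1.23,0.40,0.98,0.93,1.01,1.03,1.21,1.15,1.20,0.89,0.81
MD,5,1.51,1.28,1.61,1.20,0.95,1.57,1.70,0.51,1.23,1.29,1.71,1.27,1.50,1.42,1.84,1.31,0.95
MD,6,0.98,0.83,1.25,0.89,0.78,1.09,1.21,0.41,0.98,0.92,1.04,0.92,1.22,1.15,1.30,0.97,0.71
MD,7,1.85,1.04,1.72,1.26,1.01,1.53,1.63,0.49,1.17,1.36,1.40,1.37,1.56,1.46,1.61,1.31,0.99
MD,8,1.22,0.78,1.30,1.00,0.72,1.15,1.27,0.41,1.00,0.95,0.96,1.06,1.26,1.13,1.23,0.97,0.83
MD,whole,1.41,0.84,1.58,1.14,0.84,1.33,1.39,0.46,1.07,0.97,1.02,1.13,1.41,1.27,1.50,1.01,0.88
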