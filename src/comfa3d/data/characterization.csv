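id,formula,mz_mh,calcd_pct_C,calcd_pct_H,calcd_pct_N
D1,C18H18FN3S,328.1,66.03,5.54,12.83
D2,C18H18ClN3S,344.1,62.87,5.28,12.22
D3,C18H18BrN3S,388.1,55.67,4.67,10.82
D4,C19H21N3S,324.1,70.55,6.54,12.99
D5,C19H21N3OS,340.1,67.23,6.24,12.38
D6,C18H19N3OS,326.1,66.43,5.88,12.91
D7,C18H18N4O2S,355.1,61.0,5.12,15.81
D8,C18H18FN3S,328.1,66.03,5.54,12.83
D9,C18H18ClN3S,344.1,62.87,5.28,12.22
D10,C18H18BrN3S,388.1,55.67,4.67,10.82
D11,C16H12Cl2FN3S,368.0,52.18,3.28,11.41
D12,C16H12Cl3N3S,383.0,49.95,3.14,10.92
D13,C16H12BrCl2N3S,427.0,44.78,2.82,9.79
D14,C17H15Cl2N3S,364.0,56.05,4.15,11.53
D15,C17H15Cl2N3OS,380.0,53.69,3.98,11.05
D16,C16H13Cl2N3OS,366.0,52.47,3.58,11.47
D17,C16H12Cl2N4O2S,395.0,48.62,3.06,14.17
D18,C16H12Cl2FN3S,368.0,52.18,3.28,11.41
D19,C16H12Cl3N3S,383.0,49.95,3.14,10.92
D20,C16H12BrCl2N3S,427.0,44.78,2.82,9.79
D21,C16H12Br2FN3S,455.0,42.04,2.65,9.19
D22,C16H12Br2ClN3S,471.0,40.58,2.55,8.87
D23,C16H12Br3N3S,515.0,37.09,2.33,8.11
D24,C17H15Br2N3S,451.0,45.05,3.34,9.27
D25,C17H15Br2N3OS,467.0,43.52,3.22,8.96
D26,C16H13Br2N3OS,453.0,42.22,2.88,9.23
D27,C16H12Br2N4O2S,482.0,39.69,2.5,11.57
D28,C16H12Br2FN3S,455.0,42.04,2.65,9.19
D29,C16H12Br2ClN3S,471.0,40.58,2.55,8.81
D30,C16H12Br3N3S,515.0,37.09,2.33,8.11
F1,C17H13Cl2FN2O,351.0,58.14,3.73,7.98
F2,C17H13Cl3N2O,367.0,55.54,3.56,7.62
F3,C17H13BrCl2N2O,410.9,49.55,3.18,6.8
F4,C18H16Cl2N2O,347.1,62.26,4.64,8.07
F5,C18H16Cl2N2O2,363.1,59.52,4.44,7.71
F6,C17H13Cl3N2O,367.0,55.54,3.56,7.62
F7,C17H14Cl2N2O,333.1,61.28,4.23,8.41
F8,C19H18Cl2N2O3,393.1,58.03,4.61,7.12
F9,C19H19FN2O,311.2,73.53,6.17,9.03
F10,C19H19ClN2O,327.1,69.83,5.86,8.57
F11,C19H19BrN2O,371.1,61.47,5.16,7.55
F12,C20H22N2O,307.2,78.4,7.24,9.14
F13,C20H22N2O2,323.2,74.51,6.88,8.69
F14,C19H19ClN2O,327.1,69.83,5.86,8.57
F15,C19H20N2O,293.2,78.05,6.89,9.58
F16,C21H24N2O3,353.2,71.57,6.86,7.95
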