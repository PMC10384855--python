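subject,roi,gy_per_gbq
F-1,heart,2.28
F-1,liver,26.89
F-1,spleen,5.14
F-1,adrenal_left,12.35
F-1,adrenal_right,13.52
F-1,kidney_left,3.97
F-1,kidney_right,5.32
F-1,marrow_spine,7.87
F-1,marrow_left_shoulder,6.16
F-1,marrow_right_shoulder,6.27
M-1,heart,1.43
M-1,liver,23.49
M-1,spleen,3.93
M-1,adrenal_left,7.42
M-1,adrenal_right,9.18
M-1,kidney_left,2.75
M-1,kidney_right,3.69
M-1,marrow_spine,4.44
M-1,marrow_left_shoulder,5.40
M-1,marrow_right_shoulder,5.67
M-1,testes,0.90
M-2,heart,1.66
M-2,liver,24.34
M-2,spleen,5.31
M-2,adrenal_left,9.74
M-2,adrenal_right,9.08
M-2,kidney_left,2.76
M-2,kidney_right,5.41
M-2,marrow_spine,5.00
M-2,marrow_left_shoulder,5.33
M-2,marrow_right_shoulder,5.00
M-2,testes,0.80
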