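0.06444272 0.75657594 -0.65072266
0.81100107 -0.22119408 -0.54161835
0.84124266 0.24885739 -0.47997999
-0.61558164 0.72627108 -0.30592411
-0.19007902 0.93691399 -0.29336351
0.31732608 0.90348758 -0.28812211
0.70901216 0.65224089 -0.26811113
0.80584430 -0.56278810 -0.18407747
0.98937192 -0.04575417 -0.13802084
0.91189528 0.40826071 0.04207358
0.09769951 0.98962489 0.10534410
-0.44356790 0.89000093 0.10557399
0.55829221 0.81576127 0.15114023
0.90796975 -0.36763791 0.20108033
0.93272539 0.07188014 0.35335053
-0.13465242 0.87476171 0.46546823
0.71135720 0.51141391 0.48210657
-0.53383468 0.64774913 0.54354539
0.31797819 0.76656384 0.55791554
0.70783003 -0.33738586 0.62060248
-0.48748147 -0.56240178 0.66788177
0.35135632 -0.61253607 0.70805954
0.66868794 0.11243351 0.73499330
-0.07573943 0.57344782 0.81573350
-0.45123686 0.29884175 0.84087984
-0.52214913 -0.13923361 0.84141208
0.33650659 0.37764560 0.86263962
-0.09264042 -0.36996253 0.92441629
0.33764595 -0.16879303 0.92601519
-0.04959557 0.09791096 0.99395861
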