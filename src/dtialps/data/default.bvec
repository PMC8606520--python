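0.00000000 -0.91741572 -0.79628398 -0.63379521 -0.60284388 -0.55739015 -0.42745089 -0.33278894 -0.18091095 -0.02522100 0.01051600 0.03610699 0.16230295 0.24089396 0.39094188 0.57429911 0.59669911 0.61500502 0.83315695 0.93652174 0.94381678
0.00000000 -0.01093500 0.55260699 -0.76456726 -0.21480796 0.43077611 -0.68065983 0.88373983 0.15398096 -0.98263705 -0.34520007 0.64483582 -0.75760376 0.92217186 0.15956995 -0.78532415 -0.38686207 0.60052002 0.11232299 0.35057490 -0.27300894
0.00000000 0.39777988 0.24608400 0.11722004 0.76839885 0.70975219 0.59496885 0.32902194 0.97137073 0.18381601 0.93847020 0.76346778 0.63221380 0.30260395 0.90647773 0.23118504 0.70305613 0.51102302 0.54150997 0.00492600 0.18621496
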