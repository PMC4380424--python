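compound_id,R,R1,R2,mh_mz,t_half_min
1,CH3,H,3-CF3-Ph,537.24,4.51
2,CH3,H,2-pyridyl,470.25,4.57
3,CH3,H,2-Cl-Ph,503.22,4.12
4,CH3,H,2-F-Ph,487.25,5.52
5,CH3,H,2-pyrimidinyl,471.25,3.52
6,H,H,2-pyrimidinyl,457.23,5.29
7,H,H,2-pyridyl,456.23,6.02
8,H,H,3-CF3-Ph,523.23,5.40
9,OCH3,H,2-pyridyl,486.24,4.44
10,OCH3,H,2-F-Ph,503.24,4.87
11,OCH3,H,2-pyrimidinyl,487.24,4.00
12,Cl,H,2-pyridyl,490.2,3.31
13,Cl,H,2-pyrimidinyl,491.12,2.76
14,F,H,2-pyridyl,474.22,4.41
15,F,H,2-pyrimidinyl,475.22,4.40
16,H,F,2-pyridyl,474.22,7.04
17,H,F,2-pyrimidinyl,475.22,9.25
18,H,H,2-Cl-Ph,493.23,5.49
19,H,OCH3,2-F-Ph,507.27,6.57
20,H,OCH3,2-pyridyl,490.28,6.83
21,H,OCH3,2-pyrimidinyl,491.27,7.42
22,Cl,H,3-CF3-Ph,561.22,4.40
23,CH3,H,2-pyrimidinyl,475.28,5.24
24,OCH3,H,2-Cl-Ph,523.24,3.26
25,H,H,2-F-Ph,479.28,5.77
26,F,H,2-Cl-Ph,511.22,4.21
27,F,H,3-CF3-Ph,545.25,4.14
28,F,H,2-CH3-Ph,491.28,3.77
29,F,H,2-pyridyl,478.26,6.81
30,H,H,2-pyrimidinyl,461.26,9.32
buspirone,,,,,6.59
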