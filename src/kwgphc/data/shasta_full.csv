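0.667157
0.287785
0.126977
0.768563
0.703119
0.729986
0.767135
0.811159
0.829569
0.726164
0.423813
0.715158
0.640395
0.363359
0.463726
0.371904
0.291172
0.414087
0.650691
0.538082
0.744881
0.722613
0.561238
0.813964
0.709025
0.668612
0.524947
0.605979
0.715850
0.529518
0.824860
0.742025
0.468782
0.345075
0.425334
0.767070
0.679829
0.613911
0.461618
0.294834
0.392917
0.688100
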