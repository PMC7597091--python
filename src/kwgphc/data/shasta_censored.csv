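0.126977
0.291172
0.345075
0.371904
0.414087
0.425334
0.463726
0.524947
0.538082
0.605979
0.640395
0.667157
0.679829
0.703119
0.715158
0.722613
0.729986
0.744881
0.767135
0.811159
0.824860
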