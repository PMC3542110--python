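copy_number	n_lineages
1	335
2	41
3	9
4	1
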