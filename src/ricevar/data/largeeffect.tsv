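# Large-effect line-specific SNP counts by class (premature termination,
# initiation-codon change, termination-codon change), transcribed from the
# published text; the Total row holds the printed overall count.
Class	Count
premature_stop	187
start_loss	27
stop_loss	49
Total	263
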