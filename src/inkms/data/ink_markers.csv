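# Empirical marker ions for historical ink types (positive-mode DI-MS).
# The ivory-black marker has a fractional m/z and is carried as an empirical
# value without a formula assignment.
ink_name,marker_mz
iron gall,90.9479
ivory black,130.5259
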