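# Karyotype arm fractions used to convert between RPHC and FL coordinates.
# short_arm_fraction (f_s) values are reconstruction choices (not published): chosen so
# that converted FL values match the study's printed FL figures (6.5/10.9/13.4% on
# chromosome 2). total_length in relative units.
chromosome_id	short_arm_fraction	total_length
2	0.335	100.0
6	0.40	100.0
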