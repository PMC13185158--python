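# RhlB (426 aa) structural annotation. Domain A/B boundaries are shown only
# graphically in the source structural model and are APPROXIMATE and
# user-editable; secondary-structure intervals transcribe stated residue
# ranges. 1-based closed intervals.
category	label	start	end
domain	A	1	160
domain	B	200	426
helix	alpha5	74	95
helix	alpha7_transmembrane	110	199
helix	alpha12	309	315
helix	alpha13	325	333
helix	alpha14	347	357
sheet	beta_30_35	30	35
turn	alpha_turn_305_308	305	308
turn	beta_turn_322_324	322	324
loop	short_loop_7_13	7	13
loop	long_loop_225_240	225	240
loop	medium_loop_258_266	258	266
loop	short_loop_341_346	341	346
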