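# Documented recodings applied to the published base matrix (the Claeson
# et al. 2010 core as later extended) before the eagle-ray analysis.
# Columns: taxon, character (1-based), old state (* = not stated by the
# source), new state, source note.
# Note: coding updates to characters 52, 54, 55, 64 and 65 following Blanco
# are documented only at the character level (no taxon/state values are
# printed), so they cannot be expressed as cell edits here.
taxon	char	old	new	note
Aetomylaeus	9	*	{0 1}	postorbital process recoded polymorphic (0/1) after Aschliman
Myliobatis	16	*	{0 1}	jaw-antimere fusion polymorphic; M. freminvillei shows the plesiomorphic unfused state
Aetomylaeus	27	1	2	mesopterygium absent/fused to scapulocoracoid, after White
Weissobatis	27	*	1	mesopterygium fragmented, after Hovestadt & Hovestadt-Euler
Rhinoptera	30	*	1	greatly elongated median prepelvic process present
Mobula	30	*	1	greatly elongated median prepelvic process present
Myliobatis	50	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Myliobatis	51	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Myliobatis	52	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Aetomylaeus	50	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Aetomylaeus	51	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Aetomylaeus	52	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Myliobatis	63	*	{0 1}	tooth-morphology variation: coding not restrictable to one state
Rhinoptera	50	1	0	changed from (1) to (0) following the original description
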