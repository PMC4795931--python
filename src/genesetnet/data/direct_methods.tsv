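method_id	label
MI:0018	two hybrid
MI:0055	fluorescent resonance energy transfer
MI:0872	atomic force microscopy
MI:0397	two hybrid array
MI:0727	lexa b52 complementation
MI:0112	ubiquitin reconstruction
MI:0047	far western blotting
Y2H	yeast two-hybrid (generic tag)
FRET	fluorescence resonance energy transfer (generic tag)
AFM	atomic force microscopy (generic tag)
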