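# N-terminal fatty-acyl chains, given as the free beta-hydroxy fatty acid.
# The acyl increment (acid minus water) is derived, never stored.
# columns: name	acid_formula
3-OH-14-Me-palmitoyl	C17H34O3
3-OH-hexadecanoyl	C16H32O3
3-OH-pentadecanoyl	C15H30O3
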