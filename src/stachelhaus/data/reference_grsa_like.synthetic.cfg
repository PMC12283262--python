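# Side-car config for the synthetic GrsA-like reference profile.
# 1-based positions in the reference sequence.
signature_positions = 235,236,239,278,299,301,322,330,331,517
a8_a9_interval = 340,510
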