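>root synthetic 70-residue domain root (HD-seeded, stationary elsewhere)
VGCWALFGNFLVEYLSAMGMVFILNCWKVHDCFHAVKSQNEHCRTSEGMEADWICEGTYIGQSASYGVVD
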