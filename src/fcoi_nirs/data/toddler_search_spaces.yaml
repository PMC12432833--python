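# Bilateral inferior-frontal search spaces for the toddler (3-wavelength) montage.
LIFG: [56, 57, 59, 64, 66]
RIFG: [17, 18, 25, 26, 27]
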