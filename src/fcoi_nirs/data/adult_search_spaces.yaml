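# Bilateral inferior-frontal search spaces for the adult (2-wavelength) montage.
# Channel ids refer to montage channel labels.
LIFG: [68, 69, 70, 71, 72, 73, 75]
RIFG: [5, 13, 14, 17, 19, 20]
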