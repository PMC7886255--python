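# Steady states of the 60-variable Boolean model of the Drosophila
# melanogaster segment-polarity gene network (four cell compartments,
# 15 genes/proteins each).  One stable attractor per line; column j is
# variable x_j, 1 = expressed / high concentration.
000000001001101000000001001101100000001001101100000001001101
000111100010000000111100010000111000011111110111000011111110
000000011111110000111100010000111000011111110100000001001101
011000011111110000111100010000111000011111110100000001001101
000000011111110000111101000000111000011111110100000001001101
011000011111110000111101000000111000011111110100000001001101
000111100010000000000011111110100000001001101111000011111110
000111101000000000000011111110100000001001101111000011111110
000111100010000011000011111110100000001001101111000011111110
000111101000000011000011111110100000001001101111000011111110
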