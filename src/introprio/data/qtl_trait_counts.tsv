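trait	qtl_n	chromosomes
Flowering time	20	3, 4, 6, 7, 8, 9, 11
Flower number	11	1, 2, 3, 5, 6, 11
Inflorescence number	2	1, 3
Flowers per inflorescence	10	1, 2, 3, 4, 5, 12
Inflorescence with a single cyme	7	2, 5, 10, 12
Stigma length/protrusion/exertion	13	1, 2, 3, 4, 6, 7
Anther length	3	1, 2, 7
Pollen number	1	7
Pollen viability	1	11
Fruit set	8	3, 4, 7, 11, 12
Fruit number	10	1, 2, 3, 4, 6, 7, 9, 12
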