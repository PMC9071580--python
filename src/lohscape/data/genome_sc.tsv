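# Approximate S. cerevisiae (R64-like) chromosome lengths and centromere midpoints, bp.
# Swappable: any TSV with the same columns can be supplied instead.
chrom	length	cen_pos
chrI	230218	151465
chrII	813184	238207
chrIII	316620	114385
chrIV	1531933	449711
chrV	576874	151987
chrVI	270161	148510
chrVII	1090940	496920
chrVIII	562643	105586
chrIX	439888	355629
chrX	745751	436307
chrXI	666816	440129
chrXII	1078177	150828
chrXIII	924431	268031
chrXIV	784333	628758
chrXV	1091291	326584
chrXVI	948066	555957
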