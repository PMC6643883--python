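# S. cerevisiae (sacCer3) centromere midpoints, 1-based bp
chrI	151524
chrII	238265
chrIII	114443
chrIV	449766
chrV	152045
chrVI	148568
chrVII	497096
chrVIII	105761
chrIX	355687
chrX	436366
chrXI	440187
chrXII	150888
chrXIII	268090
chrXIV	628817
chrXV	326643
chrXVI	556015
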