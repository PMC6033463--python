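>apoE4_mature 299 aa, Arg112/Arg158 isoform, 1-based mature numbering
KVEQAVETEPEPELRQQTEWQSGQRWELALGRFWDYLRWVQTLSEQVQEE
LLSSQVTQELRALMDETMKELKAYKSELEEQLTPVAEETRARLSKELQAA
QARLGADMEDVRGRLVQYRGEVQAMLGQSTEELRVRLASHLRKLRKRLLR
DADDLQKRLAVYQAGAREGAERGLSAIRERLGPLVEQGRVRAATVGSLAG
QPLQERAQAWGERLRARMEEMGSRTRDRLDEVKEQVAEVRAKLEEQAQQI
RLQAEAFQARLKSWFEPLVEDMQRQWAGLVEKVQAAVGTSAAPVPSDNH
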