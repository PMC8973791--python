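CN	methylamine
Nc1ccccc1	aniline
CC=O	acetaldehyde
OB(O)c1ccccc1	phenylboronic acid
CCBr	ethyl bromide
O=C=Nc1ccccc1	phenyl isocyanate
NC1CC1	cyclopropylamine
NCCO	ethanolamine
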