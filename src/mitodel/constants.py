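"""Organism- and assay-level constants for *C. elegans* mtDNA work."""

#: somatic cell count of the adult hermaphrodite
N_CELLS = 959

#: typical total mtDNA copies per adult worm
COPIES_PER_WORM = 300_000

#: scanned window of the mitochondrial genome (1-based, inclusive)
REGION_LO = 1800
REGION_HI = 10_800

#: length of the mitochondrial reference genome (NCBI X54252.1)
MT_GENOME_LENGTH = 13_794
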