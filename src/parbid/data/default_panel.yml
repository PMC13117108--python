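# Species-discriminating diagnostic PCR panel for the Metarhizium PARB clade.
# Each pair amplifies only from its cognate species' rIGS template; a
# specimen is identified when exactly one reaction yields a product of the
# expected size.
size_tolerance: 0.15
max_product: 3000
pairs:
  - pair_name: mani-ID
    cognate_species: "Metarhizium anisopliae"
    expected_size: 850
    forward: {name: manihyb-IDF2, sequence: GACACGCGTTGCGTTGT}
    reverse: {name: mani-IDR2, sequence: ACTGCCATTCGCGCGGAG}
  - pair_name: mhyb-ID
    cognate_species: "Metarhizium hybridum"
    expected_size: 850
    forward: {name: manihyb-IDF2, sequence: GACACGCGTTGCGTTGT}
    reverse: {name: mhyb-IDR2, sequence: GCCCTACCAAACTGCGAG}
  - pair_name: mppi-ID
    cognate_species: "Metarhizium parapingshaense"
    expected_size: 250
    forward: {name: mppi-IDF2, sequence: GTGGTTCTAGAGGGAAAAATCTGCCAAGTC}
    reverse: {name: mppi-IDR2, sequence: CAAGTAAATCTACAAAGTCCAAAAATTG}
  - pair_name: mpin-ID
    cognate_species: "Metarhizium pingshaense"
    expected_size: 700
    forward: {name: mpin-IDF2, sequence: ATCAATCGCAGCCTACCCGGTAAGTATAAG}
    reverse: {name: mpin-IDR2, sequence: GCCAAAATACTAGGAACTTGTATA}
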