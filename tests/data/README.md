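Optional real-structure inputs.

Place `1LYZ.pdb` and `5LTM.pdb` (RCSB PDB entries) here to enable the
worked-example distance checks in tests/test_acceptance.py and the
corresponding entries in scripts/acceptance.py; everything else in the
suite runs from generated fixtures.
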