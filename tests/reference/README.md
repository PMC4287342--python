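# Reference structures (not bundled)

The spot-check tests in `tests/test_acceptance.py` compare detection and
superposition output against published binding sites and core RMSDs for
real PDB entries. Coordinate files are not redistributed with this package;
to enable those tests, download the entries in PDB format from
https://files.rcsb.org/download/ and place them here as lowercase
`<id>.pdb`:

    4v2y.pdb  4tz4.pdb  4tzc.pdb  4ci2.pdb  3hcg.pdb  3eqt.pdb  3hcj.pdb

Without these files the corresponding tests fail with a message pointing
here; all other tests are self-contained (synthetic structures generated at
test time).
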