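# External reference structures (not bundled)

Three acceptance tests validate the pipeline against real photosystem I
depositions. The coordinate files are third-party data, several megabytes
each, and are not distributed with this package. To run those tests, download
them from the Protein Data Bank and place them here:

* `1jb0.cif` (or `.pdb`) — the 2.5 Å *Thermosynechococcus elongatus* PSI
  X-ray structure, PDB accession **1JB0** (https://www.rcsb.org/structure/1JB0).
  Used for the 96-chlorophyll / 22-carotenoid monomer census and the
  2.98 Å special-pair keto–threonine hydrogen bond.
* `frl_psi.cif` (or `6pnj.cif`) — a far-red-light-acclimated PSI cryo-EM
  model. Used for the 89-chlorophyll / 21-carotenoid census, the weakened
  3.47 Å special-pair hydrogen bond, and the chlorophyll-f candidate-site
  scan.

Without these files the corresponding tests fail with an explanatory
message; all other tests run fully offline against synthetic fixtures.
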