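# Methods

This note records the models, conventions and numerical choices behind
`psipig`, and what its synthetic benchmarks do and do not demonstrate about
real data.

## Problem setting

Far-red-light-acclimated photosystem I (FRL-PSI) incorporates ~8%
chlorophyll f in place of chlorophyll a. Chl f carries a formyl group at the
chlorin C2 position where Chl a carries a methyl — a one-oxygen difference
that cannot be resolved directly in a ~3 Å density map. Two independent
lines of evidence substitute for direct observation:

1. **Structural inference.** A formyl oxygen is a hydrogen-bond acceptor;
   a protein or water donor poised next to the C2 substituent can make a
   site selective for Chl f. The same logic identified Chl b (C7 formyl)
   sites in early light-harvesting-complex structures. Supporting signals
   are low local sequence conservation between the FRL paralogs and their
   white-light counterparts, and structural remodelling of the site
   (changed axial ligand, lost or gained neighbouring pigments).
2. **Pigment biochemistry.** Reversed-phase HPLC of extracted pigments,
   quantified per monomer against the phylloquinone internal standard
   (PSI binds exactly two phylloquinones).

`psipig` implements both lines plus the supporting machinery (census,
geometry, superposition, conservation).

## Structure handling

Coordinates are read with gemmi from PDB or mmCIF; only the first model of
multi-model files is used. Alternate conformers are collapsed per atom name
to the highest-occupancy location, ties broken by alphabetically first
alt-loc id, so the census is deterministic under file reordering. Residue
numbering is taken verbatim; coordinates are Å throughout.

Cofactors are classified by residue code through a `LigandCodeTable`
(defaults: CLA→Chl a, CL0→Chl a′, CHL→Chl b, F6C→Chl f, BCR/ECN→carotenoid,
PQN/PHQ→phylloquinone, LHG/LMG→lipids, LMT→detergent, SF4→[4Fe-4S],
HOH→water). Depositions vary in their ligand vocabulary, so the table is
fully overrideable from the CLI config; an unknown code on a residue that
carries a central Mg raises a warning rather than being silently binned as
"other", because a missed chlorophyll variant corrupts every census total
downstream.

## Chlorin geometry

Macrocycle atoms are mapped to IUPAC positions C1–C20/N21–N24 through a
configurable name table. The default table follows the chemical-component-
dictionary chlorophyll convention, whose ring letters are offset by one from
the IUPAC rings (the CCD "ring A" carries the C17 propionate and C18 methyl
of IUPAC ring D); hence IUPAC C2 = CCD `C2B` and the 13¹-keto oxygen is
`OBD`. Mapping requires the Mg and ≥20 of the 24 macrocycle heavy atoms, and
validates consecutive ring-carbon distances against 1.2–1.7 Å to catch a
wrong name table early.

* **Ring plane**: least-squares plane through all mapped macrocycle heavy
  atoms (the smallest-variance right-singular direction of the centred
  coordinates), not a 4-nitrogen plane — robust to a few missing atoms. The
  normal's sign is arbitrary; every angle consumer folds into [0°, 90°],
  since only parallelism is meaningful.
* **C2 substituent**: the unique non-ring heavy atom within 1.8 Å of C2
  (covalent C–C ≈ 1.5 Å; the cutoff excludes ≥2.4 Å contacts). Zero or
  multiple candidates are hard errors.
* **Stacking**: chlorophyll pairs with Mg–Mg ≤ 9 Å; connected components of
  the pair graph give monomer/dimer/trimer labels. No field-standard cutoff
  exists; 9 Å is a package choice that captures closely coupled antenna
  pairs while excluding lattice neighbours, and it is configurable.
* **Axial ligands**: non-pigment heavy atoms 1.9–3.0 Å from the Mg,
  classified (His side chain, water, backbone carbonyl, side-chain O, lipid
  headgroup, other). An empty list is a valid five-coordinate result.
* **Formyl probe**: a hypothetical formyl oxygen is modelled 1.2 Å beyond
  the substituent carbon along the C2→substituent direction — a linear
  simplification of sp² geometry, adequate for the clash screen it feeds
  and configurable where it is not.

## Chlorophyll-f site score

For each chlorophyll the scan reports donors whose distance to the C2
substituent heavy atom lies in 2.4–3.5 Å (donors ≤3.2 Å flagged strong).
The substituent atom is a proxy for the formyl oxygen of a hypothetical
Chl f — the real oxygen would sit up to ~0.5 Å further out; the window
brackets observed donor–acceptor distances with that slack in mind. No
donor–hydrogen angle is used because coordinate models carry no hydrogens;
the criterion is distance-only. Carbonyl-type oxygens in the window are
listed separately as non-donor polar contacts and never scored.

The ranking score is an explicit formalisation (not a community standard):

    score = w1·hbond + w2·(1 − local_conservation) + w3·site_change

with `hbond` = 1 at ≤2.6 Å decaying linearly to 0 at the window edge,
`local_conservation` the mean windowed-identity of residues within 8 Å of
the ring, and `site_change` ∈ {0,1} for a changed axial ligand or a
lost/gained neighbouring site. Missing evidence contributes 0; weights
default to (1,1,1); ties order alphabetically by site label so ranking is
independent of input order and monotone in each evidence channel.

## Superposition and site correspondence

Kabsch superposition (SVD, reflection-corrected to det +1) is computed on
Cα atoms of alignment-paired residues only — pigments are never fit targets
because their displacement is the quantity being measured. Configurations
with fewer than 3 pairs or collinear points are rejected. Pigment sites are
then matched greedily, shortest distance first, each site used once, within
a 2.5 Å Mg–Mg cutoff after transformation (centroids for Mg-free pigments;
only like categories are matched). Unmatched reference sites are "lost",
unmatched query sites "gained". Greedy matching equals exhaustive optimal
matching whenever sites are displaced by less than half the cutoff and
distinct sites are separated by more than the cutoff — the regime real
homologous photosystems occupy; the test suite verifies the equality on
such fixtures. Conserved pigments inherit the community label (reference
chain letter + last two digits of the reference residue number).

## Sequence conservation

Global alignment is Needleman–Wunsch with affine gaps (Gotoh three-matrix
recurrence), BLOSUM62, gap open 10 and extend 0.5, where a gap of length L
costs `open + (L−1)·extend` and switching gap strands opens a new gap.
Traceback resolves ties diagonal > up > left, so alignments are
deterministic. Scores are verified in the tests against exhaustive path
enumeration (short sequences) and against an independently configured
Biopython aligner.

Percent identity defaults to identities over columns excluding terminal gap
overhangs (internal gap columns count in the denominator); an alternative
mode divides by the shorter sequence length. The per-residue track is the
fraction of identical columns in an 11-column window centred on each query
residue (truncated at the ends; gap columns count as mismatches), mapped
onto structure chains through an explicit numbering offset and exportable
through the B-factor channel for visualisation. The identity matrices this
module produces will not numerically match tables produced by other
aligners with other parameters; no exact reproduction of third-party
percentages is promised.

## HPLC quantitation

Each chromatogram is a single-wavelength trace (270 nm phylloquinone,
453 nm β-carotene, 458 nm echinenone, 665 nm Chl a, 705 nm Chl f). Peaks
are seeded from local maxima (prominence defaults to 5% of the trace's
dynamic range, floored at 1 mOD and at 8× a robust noise estimate from the
differenced trace) and refined by nonlinear least squares of a
sum-of-Gaussians plus a linear baseline, with an analytic Jacobian,
non-negative amplitudes and positive widths. Iteration stops on relative
parameter change below 1e-8 or at the iteration budget; non-finite
solutions are errors. Baseline handling is linear per trace — a package
choice, as is assignment of fitted peaks to species by retention-time
window per channel (largest peak in the window wins; later-eluting cis
isomers are smaller satellites).

Amounts follow `M [µmol] = dilution · Area·FR / (ε·l)` with ε per species
(Chl a 70 540, Chl f 71 110, β-carotene 141 000, echinenone 120 000,
phylloquinone 17 900 M⁻¹cm⁻¹), flow rate 0.5 ml/min and path length
0.98 cm by default. Copies per monomer are `2·M(species)/M(phylloquinone)`;
dilution factors outside {1, 3, 5} are allowed with a warning. Stoichiometry
is invariant to injection amount, flow rate and dilution because they cancel
through the internal standard. Expected copies under an assumed total
(default 90 chlorophylls) rescale the measured chlorophyll copies to that
total.

## Synthetic generators

The chlorin template is built analytically: idealised pyrrole geometry
(N at 2.05 Å from the ring centre, Cα at (2.837, ±1.121), Cβ at
(4.206, ±0.675) in the local frame, meso carbons at 3.45 Å radius), exactly
planar, with a C2 substituent carbon at 1.50 Å and a 13¹-keto carbonyl.
Bond lengths land in 1.33–1.55 Å. Exact planarity and closed-form positions
make every downstream geometric claim checkable to machine precision; the
price is that the template is *not* a refined chlorophyll (no ring-D
pucker, no phytyl tail, no side-chain realism).

Toy structures place template copies by user-specified proper rotations and
translations, with donor atoms planted at exact distances from the C2
substituent and axial ligands along the ring normal; assembly fails if any
two pigments come within 1 Å. Simulated chromatograms invert the
quantitation equation from a chosen stoichiometry — defaults are the
measured FRL-PSI composition (Chl a 89.1, Chl f 7.1, phylloquinone 2 fixed,
carotenoids 15.8 split by the measured 1.82 β-carotene/echinenone ratio) at
1×10⁻⁴ µmol of monomer per injection, which puts the tallest peak near one
optical-density unit — plus linear baseline drift and seeded Gaussian noise
(optionally scaled to a fraction of each channel's peak amplitude). All
generator output is reproducible from (spec, seed); the default seed is
7521.

**What passing the synthetic benchmarks shows** — and does not. Exact
donor-distance recovery, superposition residuals at machine precision and
1%/5% stoichiometry round trips demonstrate that the algorithms are
implemented correctly under the stated study conditions. They do not
demonstrate robustness to real-data pathologies the generators omit:
non-Gaussian peak shapes and gradient drift, partially occupied or
mis-modelled cofactors, alternative ligand vocabularies, hydrogen-bond
geometry beyond a distance criterion, or water-mediated donor networks
(waters are generally invisible at ~3 Å resolution and the scan does not
attempt them). Acceptance checks against real depositions live in the test
suite but require the third-party coordinate files described in
`data/external/README.md`.

## Problem sizes

The default test-suite and acceptance-script workloads are sized for a
single CPU: 20-seed quantitation round trips on ~1500-sample traces, 100
single-pigment donor fixtures, 20-trial superposition and matching checks,
and alignment oracles on sequences of length ≤6 (where exhaustive
enumeration is feasible). All sizes are parameters, not limits of the
implementation.

## Known limitations

* Census totals report file contents verbatim; no attempt is made to
  reconcile a deposition's stated cofactor totals with the modelled ones
  (unmodelled or partially resolved cofactors stay uncounted).
* The additive site score is a transparent formalisation of qualitative
  evidence; its weights have no fitted meaning.
* Pairwise alignment only (to a chosen anchor); no multiple-sequence
  alignment or phylogenetics.
* No excitonic-coupling or transition-dipole calculations; stacking labels
  are geometric only.
* No retention-time modelling; peak-to-species assignment windows must fit
  the actual elution programme.
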