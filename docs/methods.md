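# Methods

This note documents the models, conventions and numerical choices behind
pocketpipe, and what the synthetic benchmarks do and do not demonstrate.

## Structures, atoms and counting conventions

PDB parsing and writing go through gemmi; FASTA through Biopython. The
public residue identifier everywhere is the author numbering
`(chain, residue number, insertion code)` — pocket-detector outputs refer to
author numbering, so nothing is ever renumbered. Alternate locations are
collapsed to the highest-occupancy conformer (ties: first encountered).
Nonstandard residues map to `X` in sequences but keep their heavy atoms in
all counts.

All atom statistics (T_a, TC_a, P_a, OP_c) count **heavy polymer atoms
only**. Crystal structures usually carry no hydrogens while models and MD
snapshots may, and a Poisson statistic mixing the two conventions would not
be comparable across inputs; `count_atoms(..., include_hydrogens=True)`
exists for callers who need the alternative. Hetero atoms (ligands, waters)
never enter polymer counts.

## Alignment and conservation

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`, configured to the EMBOSS Needle defaults: BLOSUM62,
gap open 10, gap extend 0.5, end gaps free. Gap costs follow the EMBOSS
convention — a gap of length L costs `open + L·extend` — which maps to
Biopython as `open_gap_score = −(open+extend)`, `extend_gap_score = −extend`.
The engine's first optimal traceback is reported; it is deterministic for
fixed inputs, which is the property the pipeline needs (co-optimal
alignments can differ between implementations, so score, not gap placement,
is what cross-implementation tests compare; the frozen reference score in
the test suite comes from an independent implementation of the same scoring
scheme).

Column classes: *identical* (same letter), *conserved* (different letters,
substitution score strictly positive — the EMBOSS "similar" convention),
*gap*, else *mismatch*. Percent identity divides identical columns by the
full alignment length including gap columns (EMBOSS convention). Identity
conventions differ slightly between alignment tools (e.g. BLAST divides by
the shorter-sequence or alignment span); at the ~92% identity level typical
of close templates the conventions agree to within about one point on
indel-free pairs, which is why the identity check carries a ±2-point band.

The conservation map projects identical/conserved columns onto target
residues (erroring on the first discordant position if the alignment does
not match the structure-derived sequence) and computes TC_a by heavy-atom
census of those residues.

## Consensus ranking

Within each detector, z = (raw − mean)/sd with the **sample** standard
deviation (n−1): candidate lists are short, and the n−1 form is the
standard small-sample choice. A method with one pocket gets z = 0 and rank
1; a zero-variance method gets all z = 0 plus a warning. Ties break by
larger lining-residue count (bigger pockets are more often real), then
pocket id. Detectors that publish no comparable score (solvent-mapping site
lists) load with a null score and are excluded from ranking — mirroring a
workflow in which only two of three detectors produce rankable scores. The
per-method top-3 lists are pooled (union), and each scored pocket keeps its
method provenance; pooling rather than intersecting keeps pockets found by
a single detector in play and lets the conservation statistic arbitrate.

## Conservation-enrichment scoring

For a pocket with P_a lining heavy atoms of which OP_c belong to
identical/conserved residues, the expectation under uniformly spread
conservation is EP_c = TC_a·P_a/T_a. Pockets are ranked by OP_c/EP_c; ties
break by lower Poisson mass, larger P_a, then pocket id. When a detector
reports explicit lining atoms they are used for both P_a and OP_c;
otherwise both counts use all heavy atoms of the lining residues — the two
counts must share an atom universe or the ratio is biased.

The significance descriptor is the Poisson probability mass at OP_c with
mean EP_c, `exp(−EP_c)·EP_c^OP_c/OP_c!`, evaluated as
`exp(OP_c·ln EP_c − EP_c − lnΓ(OP_c+1))` so counts up to ~10⁶ neither
overflow nor lose leading digits. This mass is a *descriptor*, not a
calibrated tail probability — a pocket can have a small mass simply because
EP_c is large; an `upper_tail` mode (P(X ≥ OP_c)) is provided for users who
want a one-sided p-value. No multiple-testing correction is applied across
pockets.

A second descriptor evaluates the Poisson form at the (generally
non-integer) ratio r = OP_c/EP_c: `λ^r·e^(−λ)/Γ(r+1)`, with λ the mean
ratio over the scored candidate set (the "population mean" of the ratios,
recomputed per run). The factorial of a non-integer is read as Γ(r+1) — the
only consistent generalization. Both the ratio and this descriptor are
emitted so either can be ranked on; selection uses the ratio.

## Docking post-processing

K_i = exp(ΔG/RT) with R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹ and
T = 298.15 K by default — the reporting convention of AutoDock-class
engines, which reproduces typical published (ΔG, K_i) pairs to within the
rounding of the printed energy (≈1%). Both R's temperature argument and T
are exposed.

Hydrogen bonds are geometric: donor–acceptor distance ≤ 3.5 Å (closed
boundary) and, when an explicit hydrogen sits on the donor (same residue,
within 1.25 Å), the H–donor–acceptor angle ≤ 30° (0° = collinear D–H…A).
Structures without hydrogens — the common case for crystal structures and
docked poses — use the distance criterion alone and flag each record
`distance_only`. Donor/acceptor roles are supplied explicitly (a two-column
role file in the CLI); chemical perception of donors/acceptors is out of
scope.

## Trajectory metrics

Trajectories are multi-model PDB files (text, dependency-free); binary MD
formats are out of scope. Internally all geometry is in Å; every reported
series is in nm, matching MD-tooling convention.

Superposition is weighted least-squares (Kabsch) via
`scipy.spatial.transform.Rotation.align_vectors` after weighted centering;
the returned rotation is always proper. Fewer than 3 atoms or a collinear
reference raises, since the rotation is then underdetermined.

* **RMSD**: each frame is fitted to the reference frame on the selection
  (backbone N/CA/C/O, Cα, or custom), then RMSD is computed on the same
  selection.
* **Rg**: mass-weighted by default (standard atomic masses by element;
  unweighted mode sets all masses to 1).
* **RMSF**: frames are fitted to the time-average structure, iterated two
  passes (fit → new mean → refit), then per-residue RMSF averages squared
  deviations over frames and the residue's selected atoms. Note the global
  fit absorbs a fraction ~k/(3N) of any localized displacement (k = 6 fit
  degrees of freedom, N fitted atoms), so idealized identities like
  "RMSF = displacement" hold to a few percent in systems of realistic size.
* **H-bond series**: the docking criterion applied per frame; donor
  hydrogens are identified once from frame-0 geometry (topology is fixed);
  per-pair occupancy = fraction of frames within criteria.
* **Distance matrix**: per frame, entry (i,j) is the minimum heavy-atom
  distance between residues i and j, capped at 1.5 nm (a conventional
  contact-map truncation); the matrix is the per-entry mean over frames.
  Both the mean off-diagonal entry and the total sum are reported, since
  aggregate "mean distance" summaries in the literature are ambiguous
  between the two normalizations.

## Synthetic data: what it emulates, and what it does not

The generator is fully deterministic given an integer seed (NumPy
`default_rng` seeded per stage; no time, locale or platform dependence) and
round-trips through the package's own writers/readers.

* **Structure**: an ideal α-helix (rise 1.5 Å, radius 2.3 Å, 100°/residue →
  consecutive Cα–Cα ≈ 3.83 Å) with N/CA/C/O (+CB except Gly) heavy atoms.
  Geometry is schematic — no rotamers, no physical side chains, no solvent.
* **Homolog pair**: indel-free by default, with *exactly* the requested
  number of identical and conserved (positive-BLOSUM62-pair) positions and
  strict mismatches (negative score) elsewhere; the per-position truth
  table is returned. Indel-free generation makes residue-level projection
  of conservation exact, isolating tests of the scoring scheme from
  alignment errors; real remote homologies contain indels, so aligner
  robustness is exercised separately. Cysteine is excluded from conserved
  positions (it has no positive BLOSUM62 partner). Defaults: 100 residues,
  identity 0.30, conserved 0.20 — a background conservation density of 0.5,
  the maximum compatible with the 2× pocket enrichment used in the
  benchmark (enrichment × density must not exceed 1).
* **Pockets**: 5 disjoint 10-residue pockets (≈45 heavy atoms each). At
  enrichment e > 1 the true pocket receives a deterministic
  `round(min(1, e·density)·size)` conserved residues and decoys sample the
  remaining residues uniformly; at e = 1 *all* pockets are drawn
  exchangeably (uniform without replacement), giving an exact null for
  calibration. Two mock detectors score a shared latent quality (true
  pocket 1.0, decoys in [0.2, 0.8]) on deliberately different affine scales,
  optionally perturbed by rank noise.
* **Trajectory**: per-frame smooth rigid rotation/translation of the
  structure plus iid Gaussian coordinate noise σ (default 0.1 Å), frames 2 ps
  apart. Frame 0 carries no noise — it is the rigid-motion-only
  reference — so the post-fit RMSD against frame 0 has expectation ≈ σ√3
  (up to the small k/(3N) fit absorption), rather than σ√6 as it would
  against a noisy reference. The noise model has no conformational
  dynamics, so passing trajectory tests demonstrates correctness of the
  metric operators, not realism of any simulated ensemble.

## Benchmark sizes and what passing shows

The standard benchmark runs 200 replicates at 2× enrichment (recovery of
the implanted pocket ≥ 95% through the full align→consensus→score path) and
200 at 1× (selection rate statistically at chance, binomial test), plus a
2000-frame σ = 0.1 Å trajectory (RMSD/RMSF within 5% of σ√3) and small
brute-force oracles for the aligner (linear-gap DP), the Poisson mass
(extended-precision arithmetic) and superposition (multi-start numeric
minimization, independent QCP implementation). These sizes give sampling
error well inside the asserted bands while keeping a full run to seconds.

Passing these benchmarks shows the statistical machinery is implemented
correctly and is well calibrated on its own assumptions. It does not show
that the conservation-enrichment heuristic identifies functional pockets on
real receptors — that depends on the biological premise that binding
pockets are enriched in residues conserved with respect to a relevant
reference domain, which synthetic data takes as given. Reproducing absolute
MD observables of any specific receptor (RMSD/Rg plateaus, contact-map
aggregates) requires running the simulation itself and is explicitly out of
scope; the trajectory operators here are the analysis half only.

## Known limitations

* PDB only (no mmCIF); no bond perception; no assembly generation.
* Pairwise global alignment only — no MSA, no local mode, no profiles.
* Donor/acceptor roles must be supplied; no chemistry perception.
* The Poisson mass is a descriptor, not a calibrated p-value (see above).
* Residue-level conservation projection treats a residue's atoms as all
  conserved or all not; atom-level gradation exists only when detectors
  supply explicit lining atoms.
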