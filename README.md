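# pocketpipe

Conservation-guided nomination of a ligand-binding pocket on a candidate
receptor, with docking post-processing and molecular-dynamics trajectory
metrics — as a tested, reusable Python pipeline.

## The problem

Given a receptor structure with no known ligand-binding site, which surface
pocket is the functional one? Pocket-detection programs (alpha-shape,
cavity-grid and solvent-mapping servers) each propose candidates, but their
raw scores live in incommensurable units, and none of them uses evolutionary
information. This package implements a workflow that combines both signals:

1. **Consensus ranking.** Each detector's pocket scores are standardized to
   z-scores within the method, and the top *k* (default 3) pockets per
   method are carried forward (the Metapocket recipe).
2. **Conservation enrichment.** The target sequence is globally aligned
   (Needleman–Wunsch, affine gaps, EMBOSS Needle defaults: BLOSUM62,
   gap open 10, gap extend 0.5, free end gaps) to a reference
   ligand-binding-domain sequence — e.g. the AhR ligand-binding domain when
   asking whether a receptor could bind dioxin-class ligands. Columns are
   classified *identical* or *conserved* (positive substitution score), and
   projected onto the target structure. With

   - T_a — total heavy atoms of the protein,
   - TC_a — heavy atoms of residues classified identical/conserved,
   - P_a — heavy atoms lining a candidate pocket,
   - OP_c — lining heavy atoms belonging to identical/conserved residues,

   the expected conserved-atom count of a pocket under a uniform spread of
   conservation is

   **EP_c = TC_a · P_a / T_a**,

   and each pocket is ranked by the enrichment ratio **OP_c / EP_c** with a
   Poisson probability mass **p = e^(−EP_c) · EP_c^(OP_c) / OP_c!** as the
   significance descriptor (evaluated through log-gamma; an upper-tail mode
   is also available). The pocket with the highest ratio and lowest p is
   nominated as the binding pocket.
3. **Docking post-processing.** A docking engine's binding free energy
   ΔG (kcal/mol) is converted to an inhibition constant via
   **K_i = exp(ΔG / RT)** (R = 1.987×10⁻³ kcal mol⁻¹ K⁻¹, T = 298.15 K),
   and receptor–ligand hydrogen bonds are detected geometrically
   (donor–acceptor ≤ 3.5 Å; H–donor–acceptor angle ≤ 30° when hydrogens are
   present).
4. **Trajectory metrics.** For multi-model PDB trajectories: least-squares
   (Kabsch) superposition, per-frame RMSD and radius of gyration,
   per-residue RMSF about the refitted time-average structure, hydrogen-bond
   time series with occupancies, and mean smallest-distance residue
   matrices — all reported in nm.

A deterministic synthetic-data generator produces every input with known
ground truth (structures, homolog pairs with exact per-position conservation,
pocket-detector records with an implanted true pocket, rigid-motion + noise
trajectories), so the whole chain is testable offline.

## Worked example

```bash
pocketpipe simulate --seed 3 --out demo
pocketpipe pocket-score --structure demo/structure.pdb \
    --reference demo/reference.fasta --pockets demo/pockets.json \
    --out demo/scores
# selected pocket P5 (castp): OPc/EPc = 1.915, p = 1.04e-05
```

The generator implanted pocket `P5` on conservation-enriched residues
(`demo/truth.json` confirms `"true_pocket_id": "P5"`); the pipeline
recovered it with a conserved-atom enrichment of 1.9× over expectation and
Poisson mass 1×10⁻⁵. `demo/scores/` holds the consensus ranking, the full
score table (P_a, OP_c, EP_c, ratio, p, descriptor per pocket), the
conservation map and a manifest that reproduces the run bit for bit.

```bash
pocketpipe dock-post --energy -7.41 --out demo/dock
# Ki = 3.7 uM at 298.15 K
pocketpipe traj --trajectory demo/trajectory.pdb --out demo/traj
# 200 frames: mean RMSD 0.0172 nm, mean Rg 4.3365 nm
```

A binding energy of −7.41 kcal/mol corresponds to K_i ≈ 3.7 µM; the
trajectory (rigid motion + 0.1 Å Gaussian coordinate noise) shows exactly
the post-fit RMSD the noise model predicts (σ√3 = 0.0173 nm).

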