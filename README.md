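# twn-rencod

Binding-site comparison through topological water networks.

Proteins with similar folds can bind the same inhibitor with activities
spanning five orders of magnitude, and classical binding-site comparison
scores (residue identity, surface overlap, interaction fields) often fail
to explain that spread. One physical feature those scores ignore is the
*aqueous environment* of the pocket: the ensemble of hydrogen-bonded water
networks a binding site organises around itself. This package compares two
binding sites by comparing those water networks.

## Method

The input for each protein is a restrained-solvent MD trajectory of the apo
state: the protein is held fixed and only water moves, so one static set of
binding-site backbone coordinates describes the pocket in every frame.
Per frame:

1. **TWN detection.** Every water pair's TIP3P interaction energy is

       v(a,b) = k_e Σᵢ Σⱼ qᵢ qⱼ / rᵢⱼ + A/r_OO¹² − C/r_OO⁶

   (nine Coulomb site terms over (O,H,H)×(O,H,H) plus one oxygen–oxygen
   Lennard-Jones term; k_e = 332.0636 kcal·Å·e⁻²·mol⁻¹, q_O = −0.834 e,
   q_H = +0.417 e, A = 582 000 kcal·Å¹²·mol⁻¹, C = 595 kcal·Å⁶·mol⁻¹).
   A pair with v ≤ −2.25 kcal·mol⁻¹ counts as hydrogen bonded. A
   *topological water network* (TWN) here is a 3-membered ring: three
   waters whose three pair energies all meet the criterion.

2. **Encoding.** For each ring centroid near the binding site, distances
   to the 4 backbone atoms (N, Cα, C, O) of every site residue are
   computed — 16 residues × 4 atoms = 64 columns by default, with residues
   matched position-by-position between kinases (KLIFS-style). Each frame
   keeps, per atom, the minimum centroid distance, binned into hydration
   shells: **A** < 5 Å, **B** 5–7.5 Å, **C** 7.5–10 Å, **D** ≥ 10 Å.

3. **Reordering and similarity.** Because similar TWNs occur in different
   frames of the two trajectories, the query protein's frames are greedily
   reordered: reference frames are visited in order and each takes the
   unassigned query frame with the smallest L1 difference in distance
   values. Similarity is then the fraction of matched class labels over
   all (frame, atom) cells — 1.0 means identical encodings.

A synthetic-trajectory generator with *planted* water rings provides ground
truth for every stage, so the whole pipeline is testable without running MD.

## Worked example

Generate two synthetic trajectories with the same two planted TWN sites
(one always present, one present in 80 % of frames), plus a third with the
planted waters jittered by σ = 1 Å, then compare them against a 16-residue
site:

```sh
twn-rencod simulate --spec spec_a.yaml --out a.pdb      # seed 11
twn-rencod simulate --spec spec_c.yaml --out c.pdb      # seed 12, same sites
twn-rencod simulate --spec spec_b.yaml --out b.pdb      # seed 12, jitter 1 A
twn-rencod detect  --trajectory a.pdb --out a_rings.tsv
twn-rencod compare --ref-trajectory a.pdb --ref-site site.yaml \
                   --query-trajectory c.pdb --query-site site.yaml --out ac.json
```

`detect` reports 17 rings in 10 frames (two planted sites, one sometimes
absent); each ring row carries its three pair energies, all ≈ −3.52
kcal·mol⁻¹, comfortably below the −2.25 criterion. The comparisons print:

| pair | similarity | reading |
|------|-----------|---------|
| a vs c (same sites, different realisation) | 0.9875 | 632/640 cells match; the few mismatches are frames where the 80 %-site differs |
| a vs b (planted waters jittered 1 Å) | 0.0484 | jitter breaks most rings, so query frames encode far shells while the reference encodes near ones |

A similarity of 1.0 is returned whenever the two encodings are identical up
to frame order (e.g. a trajectory against a shuffled copy of itself).

`twn-rencod correlate` relates pairwise similarities to inhibitor potency:
it computes Pearson/Kendall/Spearman correlation between similarity values
and activity differences |log₁₀ Kd_i − log₁₀ Kd_j| across protein pairs.

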