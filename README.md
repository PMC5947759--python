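# mrforge

Search-model factories for molecular replacement (MR) from a **single
distant homologue**.

When the closest structurally characterised relative of a crystallographic
target shares only 10–30 % sequence identity, conventional MR with the
deposited structure usually fails: the divergent parts of the homologue
add noise that swamps the signal from the conserved core. `mrforge`
automates two complementary ways of turning one homologous structure into a
large pool of candidate search models that sample possible conserved cores:

1. **Ensemble mode.** The single structure is expanded into a conformational
   ensemble by constraint-based distance geometry: tiered distance bounds
   are read off the input (covalent bonds ±0.5 %, bond-angle and planar
   pairs ±1.5 %, dihedral pairs ±5 %, backbone H-bonds ±10 %, all other
   contacts < 6 Å within −20 %/+25 %, plus a van der Waals exclusion floor),
   and randomised coordinates are corrected pair by pair until every bound
   is satisfied. The ensemble (500 conformations by default) is clustered
   on pairwise Cα RMSD; each cluster's per-residue variance profile — from
   iterative reweighted superposition, weights 1/(σ²ᵣ + ε) — fixes a
   residue removal order, and graded truncation (retain k/20 of the
   residues, k = 20…1) × three subclustering radii (1, 2, 3 Å) × three
   side-chain treatments (all-atom / reliable rotamers / poly-alanine)
   yields **180 ensemble search models per cluster**, 540 when the top
   three clusters are used.
2. **Single-model mode.** One structure is truncated over the same 20
   levels and 3 side-chain treatments according to any per-residue score
   (higher score = removed earlier): **60 search models per score column**.
   Scores can come from a plain-text score file (residue numbers + named
   columns) or from built-in metrics: weighted contact number
   WCNᵢ = Σ_{j≠i} 1/d(Cαᵢ, Cαⱼ)² (emitted negated, since well-packed
   residues should be kept), Shrake–Rupley solvent-accessible surface area,
   residue-averaged B factors, and ensemble variance. Packing and rigidity
   correlate with evolutionary conservation, which makes these cheap
   profiles useful proxies when sequence information is scarce.

The output is a directory of PDB files (multi-MODEL for ensembles), a
tab-separated manifest and a run log. Running the MR programs themselves
(Phaser, SHELXE, MrBUMP, …) is out of scope: `models.lst` is written for
hand-off, and the conventional success criteria (SHELXE CC > 25 % with
average chain length > 10) apply downstream.

## Worked example

```python
from mrforge import fixtures
from mrforge.structure_io import write_models
from mrforge.pipeline import PipelineConfig, run_ensemble_mode

protein = fixtures.make_helix_with_tail(20, 10)      # 30-residue demo chain
write_models([protein], "demo.pdb")

cfg = PipelineConfig(n_structures=50, seed=1)        # small demo ensemble
out = run_ensemble_mode("demo.pdb", "A", "demo_models", cfg)
print(open(out / "run.log").read())
```

prints (abridged):

```
ensemble: 50 accepted, 0 discarded
clusters: sizes [23, 12, 5], cutoff 0.768 A
search models written: 180
```

The 50 accepted conformations all satisfy every distance bound to within
0.05 Å. The largest cluster (23 members) drives truncation; 20 levels × 3
radii × 3 side-chain modes give the 180 models listed in
`demo_models/manifest.tsv`:

```
           model_id                           file  cluster  n_residues side_chain_mode  subcluster_radius  n_members
 c1_t100_r1_allatom  models/c1_t100_r1_allatom.pdb        1          30         allatom                  1         23
c1_t100_r1_reliable models/c1_t100_r1_reliable.pdb        1          30        reliable                  1         23
 c1_t100_r1_polyala  models/c1_t100_r1_polyala.pdb        1          30         polyala                  1         23
  c1_t95_r1_allatom   models/c1_t95_r1_allatom.pdb        1          28         allatom                  1         23
```

`c1_t95_r1_allatom` keeps the 28 least-variable residues
(⌊30 × 19/20⌋ = 28) of cluster 1's members within 1 Å of its centroid.

The same structure can be truncated by its packing profile from the shell:

```sh
mrforge single-model-mode -single_model demo.pdb --metrics wcn \
        --out demo_single        # -> 60 models (20 levels x 3 treatments)
mrforge single-model-mode -single_model demo.pdb \
        -truncation_scorefile scores.txt -truncation_scorefile_header flex \
        --out demo_scored
```

A score file is a header line plus one row per residue
(`res flex\n1 0.52\n2 0.61\n…`); every extra column adds another 60 models
to the pool.

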