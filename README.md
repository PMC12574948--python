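# tcrkit

Structural analysis of T-cell receptors (TCRs) and TCR:peptide-MHC
complexes: parsing, IMGT annotation, docking-geometry calculation and
scoring, RMSD evaluation, interface interaction profiling, and residue-graph
export for machine learning.

## Who this is for

TCRs trigger adaptive immune signalling only when they engage a
peptide-MHC (pMHC) in a restricted range of orientations. Docking programs
and structure predictors routinely emit poses outside that range, and
sifting them by hand does not scale. `tcrkit` gives structural
immunologists and method developers a single toolkit that reads solved or
predicted structures (PDB/mmCIF), recognises the chains of a TCR:pMHC
complex, and quantifies each pose so that non-canonical binders can be
flagged, filtered or scored in batch.

## The model

For a complex the toolkit builds two geometric objects:

* **MHC groove frame** — origin at the centroid of the groove Cα atoms
  (class I α1+α2 platform; class II α1+β1), groove axis **ĝ** = first
  principal component of that point cloud oriented along the peptide N→C
  direction, plane normal **n̂** = third principal component oriented toward
  the TCR.
* **TCR pseudo-axis** — unit vector **û** from the Vα to the Vβ disulfide
  anchor, each anchor being the centroid of the Cα atoms at IMGT positions
  23 and 104 of that domain.

Three descriptors follow:

* **scanning angle** θ — signed angle between the projection of **û** onto
  the groove plane and **ĝ** (right-hand rule about **n̂**), in (−180°, 180°];
* **pitch** φ — tilt of **û** out of the groove plane, in [0°, 90°];
* **distance** d — TCR centre to groove origin (Å); the `adapted` method
  projects it onto **n̂**, the `rudolph` and `singh` conventions use the
  full Euclidean distance (`singh` fits the frame on the helix residues
  only).

Poses with |θ| ≤ 90° are **canonical** polarity, otherwise **reverse**.
A pose is scored against reference distributions fitted to
signalling-competent complexes — Normal for θ, Gamma for φ, Gaussian
mixture for d — with the knowledge-based score

    η = −α₁ log N(θ | μ, σ) − α₂ log Γ(φ | k, s, loc) − α₃ log GMM(d)

Lower η means a more canonical pose. `fit_parameters` re-estimates all
distribution parameters from any set of reference geometries (maximum
likelihood; the mixture by EM with k-means++ initialization).

The toolkit also provides Kabsch superposition, region-wise TCR RMSD over
IMGT correspondence, CAPRI-style interface RMSD (10 Å heavy-atom interface,
backbone atoms), geometric detection of hydrogen bonds, salt bridges,
hydrophobic contacts and π-stacking, and residue-graph serialization with
configurable node/edge featurization.

## Worked example

Every module runs end-to-end on generated toy complexes with known ground
truth — no downloads needed:

```python
from tcrkit import *

spec = ToyComplexSpec(scanning=40.0, pitch=10.0, distance=25.0, seed=1)
structure, truth = make_toy_complex(spec)
model = classify_model(structure.first)
for ch in model.chains:
    print(f"chain {ch.id}: {ch.chain_type.value} ({len(ch.residues)} residues)")
cx = assemble_complexes(model, structure_id=structure.id)[0]
desc = calculate_geometry(cx, method="adapted")
print(f"scanning={desc.scanning_angle:.2f} deg  pitch={desc.pitch:.2f} deg  "
      f"distance={desc.distance:.2f} A  polarity={desc.polarity}")
print(f"eta = {score_geometry(desc, default_parameters()):.3f}")
table = detect_interactions(cx)
print(f"{len(table)} interface interactions")
g = build_graph(cx)
print(f"graph: {g.n_nodes} nodes, {len(g.edges)} edges")
```

prints

```
chain A: TCR_ALPHA (128 residues)
chain B: TCR_BETA (128 residues)
chain C: PEPTIDE (9 residues)
chain M: MHC1_HEAVY (180 residues)
chain N: B2M (99 residues)
scanning=40.00 deg  pitch=10.00 deg  distance=25.00 A  polarity=canonical
eta = 8.837
90 interface interactions
graph: 544 nodes, 25214 edges
```

The chain classification is by sequence alignment to packaged references,
the geometry recovers the construction parameters exactly, and η is the
pose's negative log-likelihood under the packaged default distributions
(lower = more canonical).

The same pipeline is available from the shell for batch processing:

```bash
tcrkit make-fixture --count 5 --seed 1 --out-dir fixtures
tcrkit geometry 'fixtures/*.pdb' --method adapted --out geometry.csv
tcrkit score    'fixtures/*.pdb' --out scores.csv
tcrkit interactions 'fixtures/*.pdb' --out-dir interactions
tcrkit graph-dataset 'fixtures/*.pdb' --out-dir graphs
```

Per-file failures are logged and skipped; the exit status is non-zero only
when no input succeeds.

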