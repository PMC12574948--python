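# Methods

This note records the conventions, parameter choices and limitations behind
`tcrkit`. Everything stated here is computed by the package itself; the
test suite and `scripts/acceptance.py` exercise every claim.

## Parsing and chain recognition

Structures are read with gemmi (PDB and mmCIF) into a small hierarchical
model (structure → model → chain → residue → atom). Waters are dropped by
default; alternate locations collapse to the highest-occupancy conformer
(ties resolved toward altloc `A`); author numbering and insertion codes are
preserved verbatim, with IMGT numbers stored in parallel and never
overwriting them. Multi-model files keep every model; downstream
convenience functions use the first model unless asked otherwise.

Chains are classified by global pairwise alignment (BLOSUM62, affine gap
open 10 / extend 1, free end gaps) against packaged reference sequences:
one IMGT-numbered V-domain consensus per TCR locus (α, β, γ, δ) and
G-domain references for the MHC class I heavy chain, β2-microglobulin and
the MHC class II α1/β1 domains. A reference *hit* requires identity ≥ 0.30
over aligned columns **and** aligned coverage of at least half the
reference; the coverage condition is what lets short chains fall through to
the peptide rule (≤ 25 standard residues and no hit → `PEPTIDE`; presented
peptides are 8–15-mers, the margin allows extended antigens). Longer chains
without a hit are `UNKNOWN` and are reported, not dropped.

The V-domain consensus references are idealized synthetic scaffolds that
occupy **every** IMGT position 1–128 (conserved Cys 23/104, Trp 41, Phe
118), so alignment columns map directly onto IMGT numbers. They are
alignment anchors, not germline sequences; the identity threshold of 0.30
makes residue-level fidelity of the references non-critical. This
alignment-transfer design replaces profile-HMM numbering: it is
deterministic, dependency-free, and adequate for chains already known to be
TCRs; highly divergent or heavily engineered sequences may need a true HMM
numberer.

Complex assembly pairs each α-like chain with its nearest β-like chain and
assigns every antigen chain (MHC, peptide) to the nearest TCR pair, using
Euclidean distances between Cα centroids of the variable domains
(approximated as the first 125 residues). Ties closer than 0.1 Å resolve by
chain id. Multiple well-separated TCR:pMHC copies per file assemble into
separate complexes; apo TCRs become complexes with no antigen.

## IMGT annotation

Region delimitations: FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65, FR3
66–104, CDR3 105–117, FR4 118–128. CDR3 is renumbered by loop length
between the anchors at 104 and 118: positions fill from both ends (105…,
…117); loops shorter than 13 leave gaps at the top (112 side first); longer
loops insert letter codes symmetrically around 111/112 (order along the
chain: 111A, 111B, …, 112B, 112A), with the odd extra insertion on the 112
side — a two-residue insertion is numbered 111A, 112A. Residues after the
last numbered position are labelled `CONSTANT`; numbering is idempotent and
unaffected by removing the constant domain.

## Binding geometry

The MHC groove frame is fitted by principal component analysis of the
groove Cα cloud: class I heavy-chain residues 1–180 (α1+α2 platform),
class II α 1–85 plus β 1–90 (author numbering; configurable in
`geometry.GROOVE_RANGES`). PCA axes are sign-ambiguous, so the groove axis
is oriented along the peptide N→C direction (platform chain direction when
no peptide is present) and the plane normal toward the TCR Cα centroid.
Fewer than 20 groove Cα atoms is an error.

The TCR axis runs from the Vα to the Vβ disulfide anchor; each anchor is
the centroid of the Cα atoms at IMGT 23 and 104 of that domain (Sγ atoms
opt-in via `use_sg=True`; Cα is the default because side chains are often
missing). The TCR centre is the midpoint of the two anchors.

Descriptors: scanning angle = signed angle between the in-plane projection
of the TCR axis and the groove axis (right-hand rule about the normal,
range (−180°, 180°]); pitch = arcsin of the axis/normal dot product, range
[0°, 90°]; distance per method — `adapted` projects the centre-to-origin
vector onto the groove normal (elevation above the platform), `rudolph` and
`singh` report the full Euclidean distance, with `singh` fitting the groove
frame on helix-only residue subsets (class I 50–85 and 140–175; class II α
45–78, β 50–83). The three method tags are this package's conventions for
the classical scanning-angle constructions plus an adapted variant; they
share one angular construction and differ as stated. Polarity is a pure
function of the scanning angle: canonical iff |θ| ≤ 90° (closed interval).
A TCR axis within 1e-6 of the groove normal leaves the scanning angle
undefined and raises an error rather than returning an arbitrary value.
Angles are reported in degrees; radians are used internally.

## The η score

η = Σᵢ −αᵢ log pᵢ(x) over the three descriptor distributions: Normal
(scanning), Gamma with location offset (pitch, default loc 0), K-component
Gaussian mixture (distance). A pitch below the Gamma location has zero
density and yields η = +∞ as the out-of-support sentinel. Reverse-polarity
poses are scored by the same formula and carry their polarity flag so they
can be filtered separately — distinguishing them is a label, not a score
term. Weights αᵢ default to (1, 1, 1).

Fitting: Normal by sample mean/SD (MLE); Gamma by maximum likelihood with
the location fixed at 0 (scipy); the distance mixture by a hand-written 1-D
EM with k-means++ initialization, convergence when the log-likelihood gain
drops below 1e-8 or after 500 iterations, and a hard assertion that the
log-likelihood never decreases between iterations (the EM trace is exposed
for inspection; the independent cross-check against scikit-learn's
GaussianMixture lives in the test suite). Fitting requires ≥ 10
canonical-polarity descriptors and at least K distinct distances.

The packaged default parameters
(`data/default_score_parameters.json`: μ=40°, σ=15°; Gamma k=2, s=5; equal
two-component mixture at 25/31 Å, σ=2) are defaults fitted to the package's
synthetic canonical reference pool. They make the score runnable out of the
box; for real poses, fit parameters on a curated set of signalling-competent
complexes with `fit_parameters`.

## RMSD

Kabsch superposition by SVD with a determinant guard (always a proper
rotation, also for collinear/rank-deficient inputs). TCR-to-TCR RMSD
matches residues by IMGT number, superposes on one region selection
(default: the four frameworks) and measures over another without
refitting; atoms `CA`, `backbone` (N, Cα, C, O) or `all` (common atom
names). Positions missing from either side are skipped and counted in the
coverage report. Interface RMSD follows the CAPRI convention: interface
residues are those of either binding partner with any heavy atom within the
cutoff (default 10 Å) of the other partner *in the reference*; the pose is
superposed on the interface backbone atoms and the RMSD reported over those
same atoms. MHC/peptide residue correspondence is by global sequence
alignment, TCR chains by IMGT number.

## Interaction profiling

Heavy-atom geometric rules with packaged per-residue chemistry tables
(donors/acceptors, charged groups, apolar carbons, aromatic rings):
hydrogen bond ≤ 3.5 Å donor–acceptor; salt bridge ≤ 5.5 Å between charged
group centroids (His counts as cationic and as aromatic — deliberate double
counting across kinds); hydrophobic ≤ 4.0 Å apolar C–C, one shortest pair
per residue pair; π-stacking ≤ 5.5 Å ring-centroid distance with interplane
angle ≤ 30° (parallel) or 60–90° (T-shaped). Hydrogens are not required or
used; an explicit angle criterion would need protonated models. Residues
adjacent in sequence are never paired. All cutoffs are overridable through
`InteractionConfig`. Detection uses a k-d tree for candidate pruning and is
verified against a naive all-pairs oracle in the tests. Tables export to
CSV losslessly; per-chain-pair heatmap matrices cover every residue (zeros
included) and their cell sum equals the interaction count.

## Residue graphs

Nodes are standard residues with a Cα atom, ordered content-based (chain
id, then residue number + insertion code) so graphs are invariant to chain
order in the file. Default features: 20-dim amino-acid one-hot plus Cα
coordinates; default edges: Cα–Cα distance ≤ 10 Å (k-nearest available,
symmetrized); default edge feature: the distance. Node labels come from
chain classification (TCRalpha, TCRbeta, peptide, MHC; β2m counts as MHC).
Selector/featurizer/label rules are plug-in registries keyed by name.
Graphs serialize to a framework-neutral zip (node CSV + edge CSV + JSON
metadata) with pinned timestamps, so identical inputs produce byte-identical
datasets; dataset builds log and record per-file failures in a manifest.

## Synthetic fixtures

`make_toy_complex` builds complexes in which every downstream quantity is
known by construction: a planar MHC platform whose PCA axes are exact
(x-symmetric rows with balanced ±y counts), a peptide along +x above the
plane, and V-domain stubs carrying the packaged consensus sequences whose
disulfide-anchor centroids realize a requested (scanning, pitch, distance)
exactly at zero noise. The TCR centre sits on the groove normal, where the
Euclidean and projected distance conventions coincide, so all three methods
recover the requested distance. The CDR3 loops descend toward the antigen
so bound fixtures have a genuine interface. Row spacings are chosen so that
no atom pair sits exactly on a detection cutoff (exact-boundary pairs would
make set-valued outputs unstable under rigid motion). Gaussian coordinate
noise (`noise_sigma`) and multi-copy layouts (150 Å apart) are available;
a fixed seed makes output byte-identical.

These fixtures are deliberately not physical: residues are Cα-centred stubs
with schematic backbone offsets, no side-chain geometry, and idealized
planar grooves. Passing tests therefore demonstrate the correctness of the
geometric and statistical machinery, not robustness to crystallographic
disorder, missing density, engineered constructs or genuinely non-planar
grooves.

## Problem sizes and numerical behaviour

The test suite and acceptance script run on generated inputs at the
following sizes, chosen to pin the properties tightly while staying
desk-scale: the geometry round-trip covers the full grid scanning
−170…170° × pitch 0…80° at 25 Å for all three methods (486 descriptor
computations, max error ~1e-13°); rigid-motion invariance uses 100 random
rotations+translations (descriptors every time, RMSD/interactions/graphs on
every 10th); Kabsch is compared with an independent quaternion-eigenvalue
oracle on 100 random 50-point instances and against 1000 random rotations;
parameter recovery uses 5000 sampled descriptors; ranking uses 200 natives
vs 200 decoys whose location parameters are shifted by 3 SD; the
interaction oracle runs 50 random ≤200-atom complexes.

Known variance: with two mixture components 3 SD apart at n=5000, the
mixture weights and sigmas are the hardest parameters — their relative
recovery error is typically 2–9% depending on the sampling seed, while the
Normal and Gamma parameters recover well under 1%. The EM can in principle
find a single-component-dominated local optimum for pathological
initializations; k-means++ initialization and the monotone-likelihood
assertion guard the cases exercised here.

## Limitations

- Numbering is alignment-transfer, not HMM-based; γδ TCRs use their own
  consensus scaffolds but identical region boundaries.
- MHC residues stay on author numbering; groove residue ranges assume
  conventional G-domain numbering and are configurable for renumbered
  inputs.
- The interaction detector omits water-mediated bridges, halogen bonds,
  π-cation and metal coordination, and uses heavy-atom distance rules only.
- No biological-assembly expansion; the first model of multi-model files is
  used unless `all_models=True`.
- `fetch_structure` needs network access; everything else runs offline.
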