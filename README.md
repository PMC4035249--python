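# dynafit

Cross-validation of protein–ligand MD ensembles against per-residue NMR
dynamics.

When a small molecule binds a flat, exposed protein surface rather than a
deep pocket, no single crystal structure captures the complex: the ligand
samples a set of interconverting conformations. `dynafit` implements the
analysis that identifies, inside a long MD trajectory, the time interval (a
*conformational substate*) whose computed per-residue dynamic fingerprint
best matches what NMR measures on the real system — and then characterizes
that ensemble structurally. It was built with the FGF2–sm27 class of
problems in mind (a growth factor with an inhibitor on its heparin-binding
face) but is generic over any apo/holo pair of trajectories.

## What it computes

**Local flexibility from distance fluctuations.** For protein residues *i*,
*j* with instantaneous Cα–Cα distance *d<sub>ij</sub>(t)*, the
distance-fluctuation matrix is

&nbsp;&nbsp;&nbsp;&nbsp;*A<sub>ij</sub>* = ⟨*d<sub>ij</sub>*²⟩ − ⟨*d<sub>ij</sub>*⟩²

(rigid-motion invariant — no superposition needed). The per-residue local
flexibility contracts *A* over sequence neighbours *j* ∈ {*i*±1, *i*±2},

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>i</sub>* = Σ<sub>j</sub> *f*(⟨*d<sub>ij</sub>*⟩) *A<sub>ij</sub>*,&nbsp;&nbsp;
*f*(*d*) = 1 / (1 + e<sup>*k*(*d* − *d*₀)</sup>),

with *d*₀ = 7 Å, *k* = 2 Å⁻¹, so only spatially proximal neighbours
contribute. Mobile residues (high *p*) have low heteronuclear ¹H→¹⁵N NOE, so
*p* profiles are scored against NOE profiles by *anti*correlation.

**S² order parameters (iRED).** Backbone N–H unit vectors **e**<sub>i</sub>(t)
enter the isotropic reorientational eigenmode matrix
*M<sub>ij</sub>* = ⟨P₂(**e**<sub>i</sub>·**e**<sub>j</sub>)⟩; its five
largest eigenmodes carry overall tumbling and the internal modes give
*S²<sub>i</sub>* = 1 − Σ<sub>m>5</sub> λ<sub>m</sub>⟨i|m⟩². A rank-5
diagonal-completion refinement (on by default) removes the O(5/N) leakage
bias of the plain mode sum at small vector counts; a Cartesian
second-moment plateau estimator serves as an independent cross-check on
tumbling-free ensembles.

**Water mean residence times.** A water is in residue *r*'s first hydration
shell when its oxygen is within 3.5 Å of *r*'s terminal heavy reference
atom(s) and that atom is its nearest protein heavy-atom contact. The
survival autocorrelation of the boolean indicator *N<sub>j</sub>(t)* is
integrated into an MRT per residue; holo/apo MRT ratios map
binding-induced hydration changes.

**Substate selection.** The trajectory is cut into consecutive windows
(e.g. 100 ns each); every window's computed S² and *p* profiles are
Pearson-correlated with the experimental S² and NOE tables over the jointly
valid residues, windows are ranked (max r² for S², most negative r for
flexibility/NOE), and a consensus ranking across the two observables names
the representative ensemble. That window's ligand COM ↔ side-chain COM
distance distributions (contact residues: any heavy atom within 6.5 Å of
the ligand in the starting structure) summarize how the ligand sits on the
surface.

## Worked example

No real trajectories ship with the package; the synthetic generator builds
a desk-scale apo/holo pair (40 residues, 1,000 frames at 10 ps = ten
100-frame windows) in which one window of each run is planted to match the
pseudo-experimental profiles — window 2–3 ns of the holo run and 8–9 ns of
the apo run:

```bash
dynafit synth --preset paper-mini --seed 7 --out demo
cd demo
dynafit run --config run.yaml
```

prints

```
apo: consensus top window 8-9 ns (frames 800-900)
holo: consensus top window 2-3 ns (frames 200-300)
outputs in results
```

i.e. both planted windows are recovered. `results/summary.json` holds the
full per-window correlation tables — for this seed the holo 2–3 ns window
scores r² = 0.987 against the S² table and r = −0.967 against the NOE
table, far ahead of every decoy window — plus the ligand ensemble summary
(contact residues 19 and 20; residue 20's distance distribution has median
6.06 Å with 100 % of frames below 8 Å) and the per-residue holo/apo MRT
ratio, which is ≈ 1 everywhere except the four residues generated with 4×
slower water escape (measured ratios 3.4–4.6). Per-stage CSV tables land
in `results/apo/`, `results/holo/`.

The stage CLIs (`dynafit flex | s2 | mrt | select | ligdist`) expose the
same computations on arbitrary trajectory/topology pairs.

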