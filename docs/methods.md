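# Methods

This note records the models implemented in `dynafit`, the assumptions they
rest on, the tunable parameters and their defaults, what the synthetic data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model and units

Coordinates are Angstrom, time is picoseconds, throughout. Protein residues
are renumbered contiguously from 1 internally; original file numbering is
retained as labels for reporting. All per-residue observables travel as a
`ResidueProfile` — values plus a boolean validity mask — and masked entries
are excluded from every statistic. Experimental tables list only measured
residues; unlisted residues (unassigned resonances, prolines) become masked
entries on read.

## Local flexibility

The distance-fluctuation matrix is the variance of the inter-Cα distance,
`A_ij = Var(d_ij)`, accumulated from per-frame sums of `d` and `d²`. Because
`d` is bounded (tens of Å) and double precision carries ~16 digits, the
cancellation in `E[d²] − E[d]²` leaves absolute errors below ~1e-12 Å², well
under any signal of interest; negative rounding residues are clamped to
zero. An option reports the standard deviation instead of the variance.

Local flexibility is `p_i = Σ_j f(<d_ij>) A_ij` over the existing sequence
neighbours `j ∈ {i−2, i−1, i+1, i+2}` (termini simply truncate the set).
The sigmoid `f(d) = 1/(1 + exp(k (d − d0)))` uses `d0 = 7 Å` and
`k = 2 Å⁻¹` by default; `f(d0) = 0.5` exactly. The steepness of the
published analyses of this type is not recoverable, so `k` is exposed as a
parameter; 2 Å⁻¹ makes the weight fall from 0.88 to 0.12 across ±1 Å around
the midpoint, a conventional "about 7 Å" contact softness. `f` is applied
to the time-mean distance, not per frame, so `p` remains a weighted sum of
variances. Whole-trajectory profiles are always recomputed on the full
frame range — a variance is not the mean of window variances.

## S² order parameters

`ired_s2` builds `M_ij = <P2(e_i · e_j)>` over backbone N→H unit vectors
(prolines and residues without an amide H are masked). `M` depends only on
inter-vector angles, so no frame superposition is performed and global
rotation leaves it unchanged. Eigenvalues are sorted descending; with
isotropic overall tumbling the five largest modes span the five-dimensional
second-order harmonic subspace of the mean orientations, and the plain
mode-sum estimate is `S²_i = 1 − Σ_{m>5} λ_m <i|m>²`.

With a finite number of vectors N this mode sum is biased: a fraction of
order 5/N of each vector's internal variance lies inside the global
subspace and is wrongly attributed to tumbling, inflating S² by roughly
`(1 − S²)·5/N` (≈ 0.1 for N = 50 fully mobile vectors). The default
`small_sample_correction` therefore recovers S² differently. When internal
motions are uncorrelated between vectors, `M = S + diag(1 − S²_i)` where
`S_ij` is the static-orientation Gram matrix — positive semidefinite of
rank ≤ 5. The off-diagonal of `S` is then known *exactly* from `M`, and the
unknown diagonal (`S_ii = S²_i`) is filled in by alternating projection
onto the rank-5 PSD cone (`_complete_static_diagonal`). On fixtures this
removes the leakage bias entirely, for homogeneous and heterogeneous
per-residue mobility alike, with and without tumbling. The correction
assumes inter-residue independence of internal motions; for real proteins
with strongly correlated internal modes the plain mode sum
(`small_sample_correction=False`) is the conservative choice, and at
realistic residue counts (N ≳ 130) the two differ by < 0.01.

`direct_s2` computes the t→∞ plateau from Cartesian second moments,
`S² = 3/2 (⟨x²⟩² + ⟨y²⟩² + ⟨z²⟩² + 2⟨xy⟩² + 2⟨xz⟩² + 2⟨yz⟩²) − 1/2`. It is
valid only in a tumbling-free (molecular) frame and exists as the
independent cross-check for the synthetic ensembles, which are generated in
that frame. S² is computed over each full window, not block-averaged within
it; `n_global_modes` (default 5) and the window stride are parameters.

## Hydration shells and residence times

Shell membership: water oxygen within `cutoff = 3.5 Å` (the first minimum
of the water–charged-group radial distribution function) of a residue's
terminal heavy reference atoms (side-chain tips: LYS→NZ, ARG→NH1/NH2,
GLY→CA, ...; shipped as an overridable table), *and* that atom is the
water's nearest protein heavy-atom contact, ties to the lower residue
index. The second condition makes shell assignment a partition — no water
counts toward two residues. Two relaxations are available: nearest
*terminal* atom only, and nearest heavy atom of any kind (`all_atom`),
because "reference sites are side-chain tips" and "count all atoms" are
both defensible readings of common practice; `terminal_nearest` is the
default and the choice matters little when shells are well separated.

The survival autocorrelation
`z(τ) = <N(t)·Π_{s=t..t+τ} N(s)> / <N(t)>` is computed exactly from the
run-length histogram of the indicator (numerator `Σ_r max(L_r − τ, 0)`,
denominator the count of eligible occupied origins), so it costs O(runs)
rather than O(frames²). The intermittent variant `<N(t)N(t+τ)>/<N(t)>` is
computed by FFT. MRT = Δt · Σ_τ z(τ), integrated from τ = 0 up to the first
lag with z < 0.01 or half the trajectory, whichever comes first; the
z-floor truncates a geometric tail and biases the integral by at most ~1 %
at the slowest kinetics used here. An `allow_gap` option closes excursions
of ≤ n frames before the run-length analysis. Shells occupied through the
entire observation window are censored: the MRT is reported as the full
trajectory length and flagged, an observation-limited lower bound rather
than an estimate. Unoccupied shells are masked in profiles. The holo/apo
ratio masks residues with zero apo MRT.

## Window selection

Pearson correlation (Spearman available) over the jointly valid residues,
requiring ≥ 3 shared residues and nonzero variance on both sides — a flat
profile raises an error rather than producing NaN. Criteria: `max_r2`
(S² vs experimental S²), `max_abs_r`, and `max_anticorr` (local flexibility
vs NOE, ranked by most negative r). Windows are consecutive and
non-overlapping by default (an overlapping stride exists); ties break by
earlier frame range; windows whose correlation fails are ranked last with
the error recorded. No numeric "good enough" threshold is applied — the
method is comparative, and the report ranks all windows. A residue-range
filter (e.g. excluding a disordered N-terminus) can be applied before
correlation. Consensus across observables orders windows by mean rank, ties
by best single rank, then frame range.

## Ligand ensemble

Contact residues: any protein heavy atom within 6.5 Å of any ligand heavy
atom in the starting structure. Distances are ligand heavy-atom mass-
weighted COM to side-chain heavy-atom COM (glycine falls back to Cα);
hydrogens can be included by flag, and a nearest-atom variant of the
distance is a documented alternative left out of the default because COM
distances are what ensemble histograms compare best. Histograms use 0.5 Å
bins from zero with shared edges across residues; summaries report mean,
median, modal bin centre and the fraction of frames below 8 Å.

## Synthetic data: what it emulates, what it does not

The generator plants analytically known truth so that every stage is
testable without external data. The reference geometry mirrors a 1 μs /
100,000-frame production run shrunk 100-fold: 1,000 frames at 10 ps
spacing, ten 100-frame windows — chosen so the full pipeline runs in
seconds while preserving the ten-window selection structure.

* **Flexibility regimes** — each residue's four atoms displace rigidly by
  i.i.d. Gaussian vectors with a per-residue, per-segment amplitude σ
  (default patterns span 0.15–0.45 Å, typical folded-protein Cα
  fluctuation scales). For σ ≪ d, `Var(d_ij) ≈ σ_i² + σ_j²`; the
  Monte-Carlo oracle in the tests checks the exact value.
* **Cone vectors** — N–H vectors are redrawn i.i.d. uniformly inside a cone
  each frame (fast-exchange limit). The plateau S² equals the closed form
  `[cos θ₀ (1 + cos θ₀)/2]²` regardless of the reorientation timescale,
  which removes a nuisance parameter; what is *not* emulated is any finite
  correlation time or exchange between motional models.
* **Waters** — two-state Markov teleportation between an in-shell position
  (2.95–3.05 Å above the residue's CB, within the 3.5 Å shell) and bulk,
  escape probability `k_escape` per frame: continuous residences are
  geometric with mean exactly `1/k_escape` frames. Waters ride their site
  residue's displacement so the planted kinetics are not truncated by the
  residue's own motion. Diffusive approach/retreat, re-entrant encounters
  and shell-to-shell exchange are deliberately absent — the MRT estimator
  must not depend on how waters move between states.
* **Ligand** — a rigid three-atom cluster whose COM distance to a reference
  side chain is drawn per frame from a truncated Gaussian along a fixed
  outward direction; distances to other residues emerge geometrically.
* **Pseudo-experimental profiles** — analytic truth plus i.i.d. Gaussian
  noise and a random invalid mask (default 8 %, emulating unassigned
  residues). Default noise: 0.02 on S², 0.03 on NOE, 10 % on hydration
  ratios — typical reported uncertainties for well-behaved backbone
  relaxation data.
* **Study fixture** — one smooth target amplitude pattern is planted in one
  window of each run (defaults: holo window 2, apo window 8 — at the
  emulated 100× scale, the 200–300 ns and 800–900 ns intervals of a
  microsecond run);
  other windows receive independent decoy patterns. Cone semi-angles map
  linearly from amplitudes (10°–65°, S² ≈ 0.96 down to 0.09), so the S² and
  flexibility fingerprints of a window are mutually consistent. The NOE
  table is an affine anti-transform of the target local flexibility; the
  hydration table encodes a 4× escape slowdown at four residues of the holo
  run.

Passing these tests therefore demonstrates correctness of the estimators
and the selection machinery under known ground truth; it does not
demonstrate force-field accuracy, convergence of real trajectories, or the
validity of the NMR observables themselves, all of which live outside the
package.

## Numerical and reproducibility choices

* All generators are seed-deterministic (bit-identical output for identical
  spec + seed); the pipeline writes wall-clock timings only to the log so
  the JSON summary is byte-identical across reruns of the same config.
* Trajectories are analysed without re-imaging or global fitting by
  default: distance-based observables are rigid-motion invariant and iRED
  separates tumbling by construction, so a superposition step would only
  add a second, redundant correction.
* The iRED matrix is accumulated in double precision in frame chunks;
  `trace(M) = n_valid` holds to 1e-8 and is asserted in tests. S² values
  outside [0, 1] by more than 1e-6 trigger a warning before clamping.
* Hydration neighbour search is chunked exact vectorised distance
  evaluation sized to keep memory modest; a plain double-loop
  implementation ships alongside and the two must agree exactly (asserted
  in tests and in the acceptance script).
* Degenerate inputs fail loudly: fewer than two frames for a variance,
  fewer than three shared residues or a zero-variance profile for a
  correlation, no waters for an occupancy, unknown residue names for a
  terminal-atom lookup.

## Known limitations

* The iRED small-sample correction assumes internal motions uncorrelated
  across residues (exact for the synthetic fixtures, approximate for real
  proteins); the uncorrected estimator remains available.
* `direct_s2` is meaningless on tumbling trajectories; it is a cross-check,
  not a production estimator.
* Exchange-broadened or sub-τ_m experimental artefacts (R_ex, anisotropic
  diffusion) are not modelled — experimental profiles are consumed as-is.
* The ligand generator varies one distance degree of freedom; orientational
  ligand dynamics and multi-site hopping are not emulated.
* Windowing drops a trailing remainder shorter than one window (logged).
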