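"""Synthetic trajectories, waters, ligands and pseudo-experimental profiles.

Every generator here plants analytically known ground truth and returns it
alongside the data, so each pipeline stage can be validated without any
external download:

* :func:`generate_flex_trajectory` — Gaussian per-residue positional noise
  with a segment-wise amplitude schedule (a planted time-dependent regime
  change), for the distance-fluctuation analysis;
* :func:`generate_cone_vectors` — bond vectors resampled i.i.d. inside a
  cone each frame (the fast-exchange limit of diffusion in a cone), whose
  plateau order parameter is the closed form
  ``S2 = [cos(t0) (1 + cos(t0)) / 2]**2``;
* :func:`generate_waters` — two-state Markov waters teleporting between an
  in-shell site and bulk, with continuous-residence MRT exactly
  ``1/k_escape`` frames;
* :func:`generate_ligand_ensemble` — a ligand whose COM-to-side-chain
  distance to a reference residue follows a specified (truncated) Gaussian;
* :func:`generate_experimental_profile` — truth + i.i.d. Gaussian noise with
  a random invalid-residue mask (emulating unassigned residues/prolines);
* :func:`generate_study_fixture` — the desk-scale composite emulating the
  reference study geometry shrunk 100-fold: 1,000 frames at 10 ps spacing in
  ten 100-frame windows, one window of each run planted to match the
  pseudo-experimental profiles.

All generators are seed-deterministic: identical spec + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flexibility import SigmoidFilter
from .trajectory_io import ResidueProfile, Topology, Trajectory

WATER_RESNAME = "WAT"
LIGAND_RESNAME = "LIG"

# ---------------------------------------------------------------------------
# specs


@dataclass
class FlexibilityRegimeSpec:
    """Segment-wise per-residue displacement amplitudes (Å)."""

    n_residues: int
    segments: list  # [(n_frames, amplitude scalar or (n_residues,) array)]
    mean_structure: str = "extended"  # or explicit (n_residues, 3) CA array
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        norm = []
        for n_frames, amp in self.segments:
            if n_frames < 2:
                raise ValueError("segment frame counts must be >= 2")
            amp = np.broadcast_to(np.asarray(amp, dtype=float),
                                  (self.n_residues,)).copy()
            if np.any(amp < 0):
                raise ValueError("amplitudes must be >= 0")
            norm.append((int(n_frames), amp))
        self.segments = norm

    @property
    def total_frames(self) -> int:
        return sum(n for n, _ in self.segments)


@dataclass
class ConeVectorSpec:
    """Restricted reorientation inside a cone of given semi-angle (deg)."""

    n_vectors: int
    cone_semiangle: float | np.ndarray
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        ang = np.broadcast_to(np.asarray(self.cone_semiangle, dtype=float),
                              (self.n_vectors,)).copy()
        if np.any((ang < 0) | (ang > 180)):
            raise ValueError("cone semi-angle must be within [0, 180] degrees")
        self.cone_semiangle = ang


@dataclass
class WaterKineticsSpec:
    """Two-state (shell/bulk) Markov kinetics per water, rates per frame."""

    n_waters: int
    k_escape: float | np.ndarray
    k_return: float = 0.2
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        k = np.broadcast_to(np.asarray(self.k_escape, dtype=float),
                            (self.n_waters,)).copy()
        if np.any((k <= 0) | (k > 1)) or not 0 < self.k_return <= 1:
            raise ValueError("rates must lie in (0, 1]")
        self.k_escape = k


# ---------------------------------------------------------------------------
# topology / geometry builders

_RESIDUE_TEMPLATE = (  # name, element, offset from CA (Å)
    ("N", "N", (-1.20, 0.90, 0.00)),
    ("H", "H", (-1.20, 0.90, 1.01)),
    ("CA", "C", (0.00, 0.00, 0.00)),
    ("CB", "C", (0.00, 0.00, 1.50)),
)


def _ca_positions(n_residues: int, mean_structure, rng) -> np.ndarray:
    if not isinstance(mean_structure, str):
        pos = np.asarray(mean_structure, dtype=float)
        if pos.shape != (n_residues, 3):
            raise ValueError("explicit mean structure must be (n_residues, 3)")
        return pos
    i = np.arange(n_residues)
    if mean_structure == "extended":
        return np.stack([3.8 * i, np.zeros_like(i, float),
                         np.zeros_like(i, float)], axis=1)
    if mean_structure == "helix-like":
        phi = np.deg2rad(100.0) * i
        return np.stack([2.3 * np.cos(phi), 2.3 * np.sin(phi), 1.5 * i], axis=1)
    if mean_structure == "random-walk":
        steps = rng.normal(size=(n_residues, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(3.8 * steps[1:], axis=0)])
        return pos
    raise ValueError(f"unknown mean structure tag {mean_structure!r}")


def build_topology(n_residues: int, n_waters: int = 0, n_ligand_atoms: int = 0,
                   resname: str = "ALA", mean_structure="extended",
                   seed: int = 0) -> tuple[Topology, np.ndarray]:
    """Minimal protein(+ligand)(+waters) topology and base coordinates.

    Each protein residue carries N, H, CA and CB atoms in an extended (or
    helix-like / random-walk) chain; the ligand is a small rigid heavy-atom
    cluster and each water a single oxygen.
    """
    rng = np.random.default_rng(seed)
    ca = _ca_positions(n_residues, mean_structure, rng)
    names, elements, resi, resn, comp = [], [], [], [], []
    coords = []
    for r in range(n_residues):
        for name, el, off in _RESIDUE_TEMPLATE:
            names.append(name)
            elements.append(el)
            resi.append(r + 1)
            resn.append(resname)
            comp.append("protein")
            coords.append(ca[r] + np.asarray(off))
    next_res = n_residues + 1
    if n_ligand_atoms:
        centre = ca[n_residues // 2] + np.array([0.0, 8.0, 0.0])
        ring = np.linspace(0, 2 * np.pi, n_ligand_atoms, endpoint=False)
        for k in range(n_ligand_atoms):
            names.append(f"C{k + 1}")
            elements.append("C")
            resi.append(next_res)
            resn.append(LIGAND_RESNAME)
            comp.append("ligand")
            coords.append(centre + 0.8 * np.array([np.cos(ring[k]),
                                                   np.sin(ring[k]), 0.0]))
        next_res += 1
    for w in range(n_waters):
        names.append("O")
        elements.append("O")
        resi.append(next_res + w)
        resn.append(WATER_RESNAME)
        comp.append("water")
        coords.append(np.array([0.0, -30.0 - 3.0 * w, 0.0]))
    masses = [{"N": 14.007, "H": 1.008, "C": 12.011, "O": 15.999}[e]
              for e in elements]
    top = Topology(atom_names=names, elements=elements, masses=masses,
                   residue_index=resi, residue_names=resn, components=comp,
                   residue_labels=resi,
                   ligand_resnames=frozenset({LIGAND_RESNAME}),
                   water_resnames=frozenset({WATER_RESNAME}))
    return top, np.asarray(coords)


# ---------------------------------------------------------------------------
# flexibility regimes


def generate_flex_trajectory(spec: FlexibilityRegimeSpec,
                             frame_spacing: float = 10.0
                             ) -> tuple[Trajectory, list[ResidueProfile]]:
    """Trajectory with planted segment-wise Gaussian residue displacements.

    Each residue's four atoms are displaced rigidly by an isotropic Gaussian
    vector redrawn every frame with the segment's per-residue standard
    deviation. Returns the trajectory and, per segment, the true amplitude
    profile.
    """
    rng = np.random.default_rng(spec.seed)
    top, base = build_topology(spec.n_residues,
                               mean_structure=spec.mean_structure,
                               seed=spec.seed)
    n_atoms_per_res = len(_RESIDUE_TEMPLATE)
    frames = np.empty((spec.total_frames, top.n_atoms, 3))
    truths = []
    t0 = 0
    for n_frames, amp in spec.segments:
        eps = rng.normal(size=(n_frames, spec.n_residues, 3)) * amp[None, :, None]
        disp = np.repeat(eps, n_atoms_per_res, axis=1)
        frames[t0:t0 + n_frames] = base[None] + disp
        truths.append(ResidueProfile(np.arange(1, spec.n_residues + 1),
                                     amp.copy(),
                                     np.ones(spec.n_residues, dtype=bool),
                                     label="amplitude"))
        t0 += n_frames
    return Trajectory(top, frames, frame_spacing), truths


def expected_local_flexibility(ca_positions: np.ndarray,
                               amplitudes: np.ndarray,
                               filter: SigmoidFilter | None = None
                               ) -> ResidueProfile:
    """Analytic local-flexibility target for Gaussian residue displacements.

    For displacement amplitudes small relative to the inter-residue distance,
    ``Var(d_ij) ≈ σ_i² + σ_j²`` (projection of the independent displacement
    difference on the pair axis), so
    ``p_i ≈ Σ_{j∈i±1,i±2} f(d_ij) (σ_i² + σ_j²)``.
    """
    filt = filter if filter is not None else SigmoidFilter()
    sig2 = np.asarray(amplitudes, dtype=float) ** 2
    n = sig2.size
    p = np.zeros(n)
    for off in (-2, -1, 1, 2):
        i = np.arange(n)
        j = i + off
        ok = (j >= 0) & (j < n)
        d = np.linalg.norm(ca_positions[i[ok]] - ca_positions[j[ok]], axis=1)
        p[i[ok]] += filt(d) * (sig2[i[ok]] + sig2[j[ok]])
    return ResidueProfile(np.arange(1, n + 1), p, np.ones(n, dtype=bool),
                          label="local_flexibility")


# ---------------------------------------------------------------------------
# cone vectors


def analytic_cone_s2(theta_deg) -> np.ndarray | float:
    """Closed-form order parameter for uniform motion inside a cone."""
    c = np.cos(np.deg2rad(theta_deg))
    return (c * (1.0 + c) / 2.0) ** 2


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``axis`` (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(z @ axis)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def sample_cone(axis: np.ndarray, semiangle_deg: float, n: int, rng
                ) -> np.ndarray:
    """``n`` unit vectors uniform over the spherical cap around ``axis``."""
    theta = np.deg2rad(semiangle_deg)
    cos_t = 1.0 - rng.random(n) * (1.0 - np.cos(theta))
    sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
    phi = rng.random(n) * 2.0 * np.pi
    local = np.stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=-1)
    return local @ _rotation_to(np.asarray(axis, float)).T


def random_unit_vectors(n: int, rng) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_cone_vectors(spec: ConeVectorSpec, tumbling: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame unit vectors inside per-vector cones, plus analytic S².

    Vectors are redrawn independently inside the cone each frame (the
    fast-exchange limit: the plateau S² is the closed form regardless of the
    reorientation timescale). With ``tumbling=True`` an additional common
    random rotation is applied per frame, emulating overall molecular
    reorientation (only the iRED estimator is then valid).
    """
    rng = np.random.default_rng(spec.seed)
    axes = random_unit_vectors(spec.n_vectors, rng)
    V = np.empty((spec.n_frames, spec.n_vectors, 3))
    for i in range(spec.n_vectors):
        V[:, i, :] = sample_cone(axes[i], float(spec.cone_semiangle[i]),
                                 spec.n_frames, rng)
    if tumbling:
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(spec.n_frames, random_state=rng).as_matrix()
        V = np.einsum("tab,tib->tia", rots, V)
    return V, np.asarray(analytic_cone_s2(spec.cone_semiangle))


# ---------------------------------------------------------------------------
# waters


def _shell_site_offsets(n: int, rng, max_tilt_deg: float = 10.0,
                        r_lo: float = 2.95, r_hi: float = 3.05) -> np.ndarray:
    """Random offsets within a narrow upward cone, |offset| in [r_lo, r_hi)."""
    direction = sample_cone(np.array([0.0, 0.0, 1.0]), max_tilt_deg, n, rng)
    radii = r_lo + rng.random(n) * (r_hi - r_lo)
    return direction * radii[:, None]


def generate_waters(spec: WaterKineticsSpec, topology: Topology,
                    base_coords: np.ndarray, site_residues=None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Two-state Markov water oxygen coordinate series with exact MRT truth.

    Water ``w`` alternates between an in-shell position (2.8–3.2 Å above the
    CB reference atom of its site residue, within the 3.5 Å shell) and a bulk
    position far outside any shell; it escapes the shell with per-frame
    probability ``k_escape`` and returns with probability ``k_return``.
    Continuous residence lengths are geometric, so the true MRT is exactly
    ``1/k_escape`` frames. Returns ``(coords (n_frames, n_waters, 3),
    true MRT in frames per water)``.
    """
    rng = np.random.default_rng(spec.seed)
    prot_res = topology.protein_residue_indices
    if site_residues is None:
        site_residues = [int(prot_res[w % prot_res.size])
                         for w in range(spec.n_waters)]
    sites = np.empty((spec.n_waters, 3))
    for w, r in enumerate(site_residues):
        cb = topology.atom_selection(component="protein", residue=int(r),
                                     name="CB")
        if cb.size == 0:
            raise ValueError(f"site residue {r} has no CB reference atom")
        sites[w] = base_coords[cb[0]]
    bulk = sites + np.array([0.0, 0.0, 30.0]) \
        + np.arange(spec.n_waters)[:, None] * np.array([0.0, 0.0, 2.0])

    T, n_w = spec.n_frames, spec.n_waters
    offs = _shell_site_offsets(T * n_w, rng).reshape(T, n_w, 3)
    u = rng.random((T, n_w))
    states = np.empty((T, n_w), dtype=bool)
    state = np.ones(n_w, dtype=bool)  # start in shell
    for t in range(T):
        states[t] = state
        escape = state & (u[t] < spec.k_escape)
        ret = (~state) & (u[t] < spec.k_return)
        state = (state & ~escape) | ret
    coords = np.where(states[:, :, None], sites[None] + offs, bulk[None])
    return coords, 1.0 / spec.k_escape


# ---------------------------------------------------------------------------
# ligand


def _sidechain_com(topology: Topology, base_coords: np.ndarray,
                   residue: int) -> np.ndarray:
    from .ligand_ensemble import sidechain_heavy_indices

    idx = sidechain_heavy_indices(topology, residue)
    m = topology.masses[idx]
    return (base_coords[idx] * m[:, None]).sum(axis=0) / m.sum()


def generate_ligand_ensemble(distance_specs: dict, topology: Topology,
                             base_coords: np.ndarray, n_frames: int,
                             seed: int = 0, max_attempts: int = 1000
                             ) -> tuple[np.ndarray, dict]:
    """Ligand coordinates whose COM distance to a reference side chain is
    Gaussian.

    ``distance_specs`` maps residue index → (mean Å, sd Å); the first entry
    is the designated reference, whose COM–side-chain-COM distance is drawn
    from the specified Gaussian truncated at zero each frame (the ligand
    moves along a fixed outward direction). Distances to the other listed
    residues emerge geometrically. Returns the ligand-atom coordinate series
    and the spec dict as ground truth.
    """
    lig_idx = topology.atom_selection(component="ligand")
    if lig_idx.size == 0:
        raise ValueError("topology contains no ligand atoms")
    ref_residue = next(iter(distance_specs))
    mean, sd = distance_specs[ref_residue]
    rng = np.random.default_rng(seed)
    anchor = _sidechain_com(topology, base_coords, int(ref_residue))
    prot = topology.atom_selection(component="protein")
    centroid = base_coords[prot].mean(axis=0)
    direction = anchor - centroid
    direction[2] += 4.0  # bias upward, away from the chain axis
    direction /= np.linalg.norm(direction)

    template = base_coords[lig_idx] - _ligand_com(topology, base_coords, lig_idx)
    d = np.full(n_frames, mean) if sd == 0 else rng.normal(mean, sd, n_frames)
    d[0] = mean  # frame 0 is the nominal docked pose (the starting structure)
    for _ in range(max_attempts):
        bad = d < 0
        if not bad.any():
            break
        d[bad] = rng.normal(mean, sd, int(bad.sum()))
    else:
        raise ValueError("could not draw non-negative distances after "
                         f"{max_attempts} attempts (mean={mean}, sd={sd})")
    coords = (anchor[None, None, :] + d[:, None, None] * direction[None, None, :]
              + template[None, :, :])
    return coords, dict(distance_specs)


def _ligand_com(topology: Topology, coords: np.ndarray,
                lig_idx: np.ndarray) -> np.ndarray:
    m = topology.masses[lig_idx]
    return (coords[lig_idx] * m[:, None]).sum(axis=0) / m.sum()


# ---------------------------------------------------------------------------
# pseudo-experimental profiles


def generate_experimental_profile(truth: ResidueProfile, noise_sd: float,
                                  mask_fraction: float, seed: int = 0
                                  ) -> ResidueProfile:
    """Truth + i.i.d. Gaussian noise, with a random invalid subset."""
    if noise_sd < 0 or not 0 <= mask_fraction < 1:
        raise ValueError("noise_sd must be >= 0 and mask_fraction in [0, 1)")
    rng = np.random.default_rng(seed)
    values = truth.values + rng.normal(0.0, noise_sd, size=truth.values.size) \
        if noise_sd > 0 else truth.values.copy()
    mask = truth.mask.copy()
    if mask_fraction > 0:
        drop = rng.random(mask.size) < mask_fraction
        mask &= ~drop
    return ResidueProfile(truth.residue_index, values, mask, label=truth.label,
                          sigma=np.full(values.size, noise_sd) if noise_sd > 0 else None)


# ---------------------------------------------------------------------------
# composite desk-scale study fixture


def _smooth_profile(n: int, rng, lo: float, hi: float,
                    kernel_width: float = 2.0) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled into [lo, hi]."""
    white = rng.normal(size=n + 20)
    x = np.arange(-6, 7)
    kernel = np.exp(-0.5 * (x / kernel_width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(white, kernel, mode="same")[10:10 + n]
    span = smooth.max() - smooth.min()
    if span < 1e-12:
        return np.full(n, 0.5 * (lo + hi))
    return lo + (smooth - smooth.min()) / span * (hi - lo)


@dataclass
class StudyFixture:
    """Desk-scale apo/holo system with planted best-match windows."""

    apo: Trajectory
    holo: Trajectory
    exp_s2: ResidueProfile
    exp_noe: ResidueProfile
    exp_hydration_ratio: ResidueProfile
    planted_window_apo: int
    planted_window_holo: int
    window_frames: int
    target_amplitude: np.ndarray
    target_cone_deg: np.ndarray
    hydration_slow_residues: list
    ligand_specs: dict = field(default_factory=dict)


# amplitude range (Å) of the per-window flexibility patterns, and the cone
# semi-angle range (deg) they map onto
_AMP_RANGE = (0.15, 0.45)
_CONE_RANGE = (10.0, 65.0)

# default pseudo-experimental noise levels (units of each observable)
_NOISE_S2 = 0.02
_NOISE_NOE = 0.03
_NOISE_HYD = 0.10
_MASK_FRACTION = 0.08


def _amp_to_cone(amp: np.ndarray) -> np.ndarray:
    lo, hi = _AMP_RANGE
    t = np.clip((amp - lo) / (hi - lo), 0.0, 1.0)
    return _CONE_RANGE[0] + t * (_CONE_RANGE[1] - _CONE_RANGE[0])


def _build_run(n_residues, n_windows, window_frames, patterns,
               topology, base, rng, frame_spacing, waters_spec=None,
               water_sites=None, ligand_specs=None):
    """Assemble one trajectory run from per-window amplitude patterns.

    Shell waters ride their site residue's displacement so the planted
    escape kinetics are not perturbed by the residue's own motion.
    """
    n_frames = n_windows * window_frames
    n_atoms_per_res = len(_RESIDUE_TEMPLATE)
    prot_atoms = n_residues * n_atoms_per_res
    coords = np.empty((n_frames, topology.n_atoms, 3))
    coords[:] = base[None]

    # per-frame rigid residue displacements following the window schedule
    disp = np.empty((n_frames, n_residues, 3))
    for w in range(n_windows):
        sl = slice(w * window_frames, (w + 1) * window_frames)
        disp[sl] = rng.normal(size=(window_frames, n_residues, 3)) \
            * patterns[w][None, :, None]
    coords[:, :prot_atoms] = base[None, :prot_atoms] + \
        np.repeat(disp, n_atoms_per_res, axis=1)

    # N-H cone wobble on top of the rigid residue displacement
    h_local = next(k for k, (nm, _, _) in enumerate(_RESIDUE_TEMPLATE) if nm == "H")
    n_local = next(k for k, (nm, _, _) in enumerate(_RESIDUE_TEMPLATE) if nm == "N")
    h_idx = np.arange(n_residues) * n_atoms_per_res + h_local
    n_idx = np.arange(n_residues) * n_atoms_per_res + n_local
    axes = random_unit_vectors(n_residues, rng)
    for w in range(n_windows):
        sl = slice(w * window_frames, (w + 1) * window_frames)
        cone = _amp_to_cone(patterns[w])
        for i in range(n_residues):
            vec = sample_cone(axes[i], float(cone[i]), window_frames, rng)
            coords[sl, h_idx[i]] = coords[sl, n_idx[i]] + 1.01 * vec

    if ligand_specs:
        lig_idx = topology.atom_selection(component="ligand")
        lig_coords, _ = generate_ligand_ensemble(
            ligand_specs, topology, base, n_frames,
            seed=int(rng.integers(2**31)))
        coords[:, lig_idx, :] = lig_coords
    if waters_spec is not None:
        wat_idx = _water_indices(topology)
        wat_coords, _ = generate_waters(waters_spec, topology, base,
                                        site_residues=water_sites)
        site_arr = np.asarray(water_sites) - 1
        coords[:, wat_idx, :] = wat_coords + disp[:, site_arr, :]
    return Trajectory(topology, coords, frame_spacing)


def _water_indices(top: Topology) -> np.ndarray:
    return top.atom_selection(component="water")


def generate_study_fixture(seed: int = 0, n_residues: int = 40,
                           n_windows: int = 10, window_frames: int = 100,
                           planted_window_apo: int = 8,
                           planted_window_holo: int = 2,
                           frame_spacing: float = 10.0,
                           waters_per_residue: int = 2,
                           base_k_escape: float = 0.25,
                           hydration_slowdown: float = 4.0,
                           noise_scale: float = 1.0,
                           with_waters: bool = True) -> StudyFixture:
    """Build the paired apo/holo desk-scale fixture with planted truth.

    One smooth target flexibility pattern is planted in window
    ``planted_window_holo`` of the holo run and ``planted_window_apo`` of the
    apo run; all other windows receive independent decoy patterns. The
    pseudo-experimental S² profile is the analytic cone value of the target
    pattern, the pseudo-experimental NOE profile is an affine anti-transform
    of the target local flexibility, and the hydration-ratio profile encodes
    the planted holo water slowdown — so window selection against these
    profiles must recover the planted windows.
    """
    root = np.random.default_rng(seed)
    seeds = root.integers(2**31, size=8)

    patt_rng = np.random.default_rng(seeds[0])
    target = _smooth_profile(n_residues, patt_rng, *_AMP_RANGE)
    apo_patterns = [target if w == planted_window_apo else
                    _smooth_profile(n_residues, patt_rng, *_AMP_RANGE)
                    for w in range(n_windows)]
    holo_patterns = [target if w == planted_window_holo else
                     _smooth_profile(n_residues, patt_rng, *_AMP_RANGE)
                     for w in range(n_windows)]

    n_waters = waters_per_residue * n_residues if with_waters else 0
    n_frames = n_windows * window_frames

    top_apo, base_apo = build_topology(n_residues, n_waters=n_waters, seed=seed)
    top_holo, base_holo = build_topology(n_residues, n_waters=n_waters,
                                         n_ligand_atoms=3, seed=seed)

    slow = sorted({max(2, n_residues // 8), n_residues // 3,
                   2 * n_residues // 3, n_residues - 3})
    water_sites = [1 + (w % n_residues) for w in range(n_waters)]
    k_apo = np.full(n_waters, base_k_escape) if with_waters else None
    k_holo = None
    if with_waters:
        k_holo = np.full(n_waters, base_k_escape)
        for w, r in enumerate(water_sites):
            if r in slow:
                k_holo[w] = base_k_escape / hydration_slowdown
    waters_apo = WaterKineticsSpec(n_waters, k_apo, n_frames=n_frames,
                                   seed=int(seeds[1])) if with_waters else None
    waters_holo = WaterKineticsSpec(n_waters, k_holo, n_frames=n_frames,
                                    seed=int(seeds[2])) if with_waters else None

    # docked pose: ligand in contact with the reference residue (COM distance
    # inside the 6.5 A starting-structure contact cutoff), fluctuating around
    # it over the run
    ref_residue = int(np.argmin(np.abs(np.arange(1, n_residues + 1)
                                       - n_residues // 2))) + 1
    ligand_specs = {ref_residue: (6.0, 0.6)}

    apo = _build_run(n_residues, n_windows, window_frames,
                     apo_patterns, top_apo, base_apo,
                     np.random.default_rng(seeds[3]), frame_spacing,
                     waters_spec=waters_apo, water_sites=water_sites)
    holo = _build_run(n_residues, n_windows, window_frames,
                      holo_patterns, top_holo, base_holo,
                      np.random.default_rng(seeds[4]), frame_spacing,
                      waters_spec=waters_holo, water_sites=water_sites,
                      ligand_specs=ligand_specs)

    # pseudo-experimental profiles from the target pattern
    resi = np.arange(1, n_residues + 1)
    target_cone = _amp_to_cone(target)
    s2_truth = ResidueProfile(resi, analytic_cone_s2(target_cone),
                              np.ones(n_residues, bool), label="S2")
    exp_s2 = generate_experimental_profile(
        s2_truth, _NOISE_S2 * noise_scale, _MASK_FRACTION, seed=int(seeds[5]))

    ca = _ca_positions(n_residues, "extended", root)
    p_truth = expected_local_flexibility(ca, target)
    noe_vals = 0.86 - 0.55 * p_truth.values / p_truth.values.max()
    noe_truth = ResidueProfile(resi, noe_vals, np.ones(n_residues, bool),
                               label="hetNOE")
    exp_noe = generate_experimental_profile(
        noe_truth, _NOISE_NOE * noise_scale, _MASK_FRACTION, seed=int(seeds[6]))

    hyd_vals = np.ones(n_residues)
    for r in slow:
        hyd_vals[r - 1] = hydration_slowdown
    hyd_truth = ResidueProfile(resi, hyd_vals, np.ones(n_residues, bool),
                               label="hydration_ratio")
    exp_hyd = generate_experimental_profile(
        hyd_truth, _NOISE_HYD * noise_scale, 0.0, seed=int(seeds[7]))

    return StudyFixture(apo=apo, holo=holo, exp_s2=exp_s2, exp_noe=exp_noe,
                        exp_hydration_ratio=exp_hyd,
                        planted_window_apo=planted_window_apo,
                        planted_window_holo=planted_window_holo,
                        window_frames=window_frames,
                        target_amplitude=target, target_cone_deg=target_cone,
                        hydration_slow_residues=slow,
                        ligand_specs=ligand_specs)


def write_fixture(fixture: StudyFixture, outdir) -> dict:
    """Write the fixture to disk (PDB + DCD + profile tables); return paths."""
    from pathlib import Path

    from .trajectory_io import write_profile, write_structure, write_trajectory

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, traj in (("apo", fixture.apo), ("holo", fixture.holo)):
        pdb = outdir / f"{tag}.pdb"
        dcd = outdir / f"{tag}.dcd"
        write_structure(traj.topology, traj.coordinates[0], pdb)
        write_trajectory(traj, dcd)
        paths[f"{tag}_topology"] = str(pdb)
        paths[f"{tag}_trajectory"] = str(dcd)
    for tag, prof in (("s2", fixture.exp_s2), ("noe", fixture.exp_noe),
                      ("hydration_ratio", fixture.exp_hydration_ratio)):
        p = outdir / f"experimental_{tag}.csv"
        write_profile(prof, p)
        paths[f"experimental_{tag}"] = str(p)
    truth = outdir / "truth.csv"
    with open(truth, "w") as fh:
        fh.write("residue target_amplitude target_cone_deg\n")
        for i in range(fixture.target_amplitude.size):
            fh.write(f"{i + 1} {fixture.target_amplitude[i]:.6f} "
                     f"{fixture.target_cone_deg[i]:.4f}\n")
    paths["truth"] = str(truth)
    paths["planted_window_apo"] = fixture.planted_window_apo
    paths["planted_window_holo"] = fixture.planted_window_holo
    return paths
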