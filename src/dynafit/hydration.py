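"""Water mean residence times (MRT) in per-residue hydration shells.

A water belongs to the first hydration shell of residue r at frame t when its
oxygen lies within a distance cutoff (default 3.5 Å, the first minimum of the
water–charged-side-chain radial distribution function) of r's terminal
non-hydrogen reference atom(s), and that terminal atom is the water's nearest
protein heavy-atom contact overall — the second condition makes the shell
assignment a partition (no water is counted into two residues' shells; ties
go to the lower residue index). Alternative assignment modes relax either
condition.

From the boolean indicator ``N_j(t)`` the residence autocorrelation is built:

* survival mode (default):  z(tau) = <N(t) prod_{s=t..t+tau} N(s)> / <N(t)>
  — the probability that a water found in the shell remains there
  continuously for tau further frames;
* intermittent mode:        z(tau) = <N(t) N(t+tau)> / <N(t)>.

The MRT is the discrete time integral  MRT = dt * sum_tau z(tau), evaluated
up to the lag where z first drops below a floor (default 0.01) or half the
window, whichever comes first. For waters that never leave within the
observation window, the MRT is censored at the trajectory length and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .trajectory_io import ResidueProfile, Trajectory


def load_terminal_atom_table(path: str | Path | None = None) -> dict[str, tuple[str, ...]]:
    """Residue-name → terminal heavy atom names mapping (overridable)."""
    if path is None:
        source = resources.files("dynafit").joinpath("data/terminal_heavy_atoms.tsv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        resname, atoms = line.split(None, 1)
        table[resname] = tuple(a.strip() for a in atoms.split(","))
    return table


@dataclass
class ShellOccupancy:
    """Boolean waters × frames shell-membership indicator for one residue."""

    residue_index: int
    indicator: np.ndarray  # (n_waters, n_frames) bool
    cutoff: float = 3.5
    reference_atoms: tuple = ()
    frame_spacing: float = 10.0

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=bool)
        if self.indicator.ndim != 2:
            raise ValueError("indicator must be (n_waters, n_frames)")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ResidenceCurve:
    """Residence autocorrelation and the MRT derived from it."""

    lags: np.ndarray
    z: np.ndarray
    mrt: float  # ps
    censored: bool = False
    occupied: bool = True
    fit_quality: float | None = None
    fit_mrt: float | None = None


def _water_oxygen_indices(top) -> np.ndarray:
    sel = (top.components == "water") & np.array(
        [str(e).upper() == "O" for e in top.elements])
    return np.flatnonzero(sel)


def _shell_owners(trajectory: Trajectory, cutoff: float,
                  assignment: str,
                  terminal_table: dict[str, tuple[str, ...]] | None = None,
                  chunk_frames: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per (frame, water) owning residue index, or 0 when unassigned.

    Returns ``(owners, water_atom_indices)``. Assignment modes:

    * ``terminal_nearest`` (default): the water's globally nearest protein
      heavy atom must be a terminal reference atom; its residue owns the
      water if that distance is < cutoff.
    * ``terminal_only``: nearest *terminal* atom owns the water if < cutoff.
    * ``all_atom``: nearest protein heavy atom of any kind owns the water if
      < cutoff ("calculated for all atoms").
    """
    if assignment not in ("terminal_nearest", "terminal_only", "all_atom"):
        raise ValueError(f"unknown assignment mode {assignment!r}")
    top = trajectory.topology
    waters = _water_oxygen_indices(top)
    if waters.size == 0:
        raise ValueError("no water oxygen atoms in topology")
    table = terminal_table if terminal_table is not None else load_terminal_atom_table()

    heavy = top.atom_selection(component="protein", heavy_only=True)
    if heavy.size == 0:
        raise ValueError("no protein heavy atoms in topology")
    is_terminal = np.zeros(heavy.size, dtype=bool)
    for k, a in enumerate(heavy):
        resname = str(top.residue_names[a])
        if resname in table and str(top.atom_names[a]) in table[resname]:
            is_terminal[k] = True
    if assignment == "terminal_only":
        heavy = heavy[is_terminal]
        is_terminal = np.ones(heavy.size, dtype=bool)
    if assignment in ("terminal_nearest", "terminal_only") and not is_terminal.any():
        raise ValueError("no terminal reference atoms found for any residue")
    atom_res = top.residue_index[heavy]

    n_frames, n_w = trajectory.n_frames, waters.size
    owners = np.zeros((n_frames, n_w), dtype=np.int32)
    if chunk_frames is None:
        # keep the (chunk, n_w, n_heavy, 3) difference block modest in memory
        chunk_frames = max(1, int(1e7 / max(1, n_w * heavy.size)))
    c2 = cutoff * cutoff
    for start in range(0, n_frames, chunk_frames):
        wx = trajectory.coordinates[start:start + chunk_frames, waters, :]
        px = trajectory.coordinates[start:start + chunk_frames, heavy, :]
        diff = wx[:, :, None, :] - px[:, None, :, :]
        d2 = np.einsum("twak,twak->twa", diff, diff)
        nearest = np.argmin(d2, axis=2)  # first minimum -> lowest residue idx
        mind2 = np.take_along_axis(d2, nearest[:, :, None], axis=2)[:, :, 0]
        ok = mind2 < c2
        if assignment == "terminal_nearest":
            ok &= is_terminal[nearest]
        owners[start:start + chunk_frames] = np.where(ok, atom_res[nearest], 0)
    return owners, waters


def shell_occupancy(trajectory: Trajectory, residue: int, cutoff: float = 3.5,
                    assignment: str = "terminal_nearest",
                    terminal_table: dict[str, tuple[str, ...]] | None = None,
                    _owners: np.ndarray | None = None) -> ShellOccupancy:
    """Boolean shell-membership indicator N_j(t) for one residue."""
    top = trajectory.topology
    table = terminal_table if terminal_table is not None else load_terminal_atom_table()
    resname = str(top.residue_names[top.residue_index == residue][0])
    if assignment != "all_atom" and resname not in table:
        raise ValueError(f"residue {residue} ({resname}) has no terminal "
                         f"heavy-atom mapping")
    if _owners is None:
        _owners, _ = _shell_owners(trajectory, cutoff, assignment, table)
    indicator = (_owners == residue).T  # (n_waters, n_frames)
    ref = ()
    if resname in table:
        ref = tuple(f"{residue}:{a}" for a in table[resname])
    return ShellOccupancy(residue, indicator, cutoff, ref,
                          frame_spacing=trajectory.frame_spacing)


def shell_occupancy_bruteforce(trajectory: Trajectory, residue: int,
                               cutoff: float = 3.5,
                               assignment: str = "terminal_nearest",
                               terminal_table=None) -> ShellOccupancy:
    """Plain double-loop reference implementation of :func:`shell_occupancy`."""
    top = trajectory.topology
    table = terminal_table if terminal_table is not None else load_terminal_atom_table()
    waters = _water_oxygen_indices(top)
    heavy = top.atom_selection(component="protein", heavy_only=True)
    term = [str(top.residue_names[a]) in table
            and str(top.atom_names[a]) in table[str(top.residue_names[a])]
            for a in heavy]
    if assignment == "terminal_only":
        heavy = heavy[np.asarray(term)]
        term = [True] * heavy.size
    ind = np.zeros((waters.size, trajectory.n_frames), dtype=bool)
    for t in range(trajectory.n_frames):
        for wi, w in enumerate(waters):
            best, best_a = np.inf, -1
            for ai, a in enumerate(heavy):
                d2 = float(np.sum((trajectory.coordinates[t, w]
                                   - trajectory.coordinates[t, a]) ** 2))
                if d2 < best:
                    best, best_a = d2, ai
            if best_a < 0 or best >= cutoff * cutoff:
                continue
            if assignment == "terminal_nearest" and not term[best_a]:
                continue
            if top.residue_index[heavy[best_a]] == residue:
                ind[wi, t] = True
    resname = str(top.residue_names[top.residue_index == residue][0])
    ref = tuple(f"{residue}:{a}" for a in table.get(resname, ()))
    return ShellOccupancy(residue, ind, cutoff, ref,
                          frame_spacing=trajectory.frame_spacing)


def _run_lengths(row: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a boolean series."""
    padded = np.concatenate(([False], row, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return ends - starts


def residence_autocorrelation(occ: ShellOccupancy, mode: str = "survival",
                              z_floor: float = 0.01,
                              allow_gap: int = 0,
                              exponential_fit: bool = False) -> ResidenceCurve:
    """Residence autocorrelation z(tau) and the MRT (ps) derived from it."""
    if mode not in ("survival", "intermittent"):
        raise ValueError("mode must be 'survival' or 'intermittent'")
    ind = occ.indicator
    n_w, T = ind.shape
    dt = occ.frame_spacing
    total_occ = int(ind.sum())
    if total_occ == 0:
        return ResidenceCurve(np.array([0]), np.array([np.nan]), 0.0,
                              censored=False, occupied=False)
    max_lag = T // 2

    if mode == "survival":
        work = ind
        if allow_gap > 0:
            # close excursions of <= allow_gap frames before run-length analysis
            work = ind.copy()
            for w in range(n_w):
                row = work[w]
                gaps = _run_lengths(~row)
                if gaps.size == 0:
                    continue
                padded = np.concatenate(([True], row, [True]))
                edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
                for s, e in zip(edges[::2], edges[1::2]):
                    interior = s > 0 and e < T
                    if interior and (e - s) <= allow_gap:
                        row[s:e] = True
        runs = np.concatenate([_run_lengths(work[w]) for w in range(n_w)])
        max_run = int(runs.max())
        lag_cap = min(max_lag, max_run)
        # num(tau) = sum_r max(L_r - tau, 0), via a run-length histogram
        hist = np.bincount(runs, minlength=max_run + 2).astype(float)
        length_axis = np.arange(max_run + 2, dtype=float)
        cnt_ge = np.cumsum(hist[::-1])[::-1]          # runs with L >= x
        sum_ge = np.cumsum((hist * length_axis)[::-1])[::-1]
        taus = np.arange(lag_cap + 1)
        num = sum_ge[taus + 1] - taus * cnt_ge[taus + 1]
        # occupied origins t <= T-1-tau: total minus occupancy of last tau frames
        tail = np.concatenate(([0], np.cumsum(work[:, ::-1].sum(axis=0))))
        denom = work.sum() - tail[taus]
        with np.errstate(invalid="ignore", divide="ignore"):
            z_all = np.where(denom > 0, num / denom, 0.0)
        saturated = max_run >= max_lag  # z has not decayed to 0 by half-window
    else:
        # intermittent: sum over waters of N(t) N(t+tau), via FFT correlation
        taus = np.arange(max_lag + 1)
        nfft = 1 << int(np.ceil(np.log2(2 * T)))
        num = np.zeros(max_lag + 1)
        for w in range(n_w):
            f = np.fft.rfft(ind[w].astype(float), nfft)
            corr = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
            num += corr
        num = np.round(num)
        tail = np.concatenate(([0], np.cumsum(ind[:, ::-1].sum(axis=0))))
        denom = ind.sum() - tail[taus]
        with np.errstate(invalid="ignore", divide="ignore"):
            z_all = np.where(denom > 0, num / denom, 0.0)
        saturated = True

    below = np.flatnonzero(z_all < z_floor)
    stop = int(below[0]) if below.size else len(z_all) - 1
    lags = taus[:stop + 1]
    z = z_all[:stop + 1]
    censored = below.size == 0 and saturated and z_all[-1] >= z_floor
    if censored:
        mrt = T * dt  # observation-limited lower bound
    else:
        mrt = float(z.sum()) * dt

    fit_q = fit_mrt = None
    if exponential_fit and len(lags) >= 3 and np.all(z[: len(lags)] > 0):
        # log-linear least squares on z(tau) = exp(-tau/tau0)
        tau_axis = lags.astype(float)
        coeffs = np.polyfit(tau_axis, np.log(z), 1)
        if coeffs[0] < 0:
            fit_mrt = float(-1.0 / coeffs[0]) * dt
            pred = np.polyval(coeffs, tau_axis)
            resid = np.log(z) - pred
            ss_tot = np.sum((np.log(z) - np.log(z).mean()) ** 2)
            fit_q = float(1 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 1.0
    return ResidenceCurve(lags, z, mrt, censored=censored, occupied=True,
                          fit_quality=fit_q, fit_mrt=fit_mrt)


def mrt_profile(trajectory: Trajectory, residues=None, cutoff: float = 3.5,
                mode: str = "survival", assignment: str = "terminal_nearest",
                terminal_table=None, **corr_kwargs) -> ResidueProfile:
    """Per-residue water MRT profile (ps); unoccupied residues are masked."""
    top = trajectory.topology
    table = terminal_table if terminal_table is not None else load_terminal_atom_table()
    if residues is None:
        residues = [int(r) for r in top.protein_residue_indices
                    if str(top.residue_names[top.residue_index == r][0]) in table
                    or assignment == "all_atom"]
    residues = list(residues)
    owners, _ = _shell_owners(trajectory, cutoff, assignment, table)
    all_res = top.protein_residue_indices
    values = np.full(all_res.size, np.nan)
    mask = np.zeros(all_res.size, dtype=bool)
    pos = {int(r): k for k, r in enumerate(all_res)}
    for r in residues:
        occ = shell_occupancy(trajectory, r, cutoff, assignment, table,
                              _owners=owners)
        curve = residence_autocorrelation(occ, mode=mode, **corr_kwargs)
        if curve.occupied:
            values[pos[r]] = curve.mrt
            mask[pos[r]] = True
    return ResidueProfile(all_res, values, mask, label="MRT")


def mrt_ratio(holo: ResidueProfile, apo: ResidueProfile) -> ResidueProfile:
    """holo/apo MRT ratio per residue; apo zeros are masked with a warning."""
    if not np.array_equal(holo.residue_index, apo.residue_index):
        raise ValueError("profiles cover different residue ranges")
    mask = holo.mask & apo.mask
    zero_apo = mask & (apo.values == 0)
    if zero_apo.any():
        warnings.warn(f"masking {int(zero_apo.sum())} residues with zero apo MRT")
        mask &= ~zero_apo
    if not mask.any():
        raise ValueError("no shared valid residues between holo and apo MRT")
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(mask, holo.values / apo.values, np.nan)
    return ResidueProfile(holo.residue_index, values, mask, label="MRT_ratio")
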