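"""Ligand–residue distance distributions of a selected ensemble.

Characterizes a conformational substate by the distance between the ligand's
center of mass and the side-chain center of mass of each contacting residue,
accumulated over the frames of the selected window and summarized as
histograms. Contact residues are defined on the starting structure: any
residue with a heavy atom within 6.5 Å of a ligand heavy atom. Residues whose
distance distribution is centered below ~8 Å are the persistent anchors of
the ligand on the protein surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import Topology, Trajectory

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA", "HN"}


@dataclass
class DistanceDistribution:
    """Per-residue ligand COM – side-chain COM distance samples (Å)."""

    residue_index: int
    samples: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples < 0):
            raise ValueError("distances must be >= 0")
        if int(self.counts.sum()) != self.samples.size:
            raise ValueError("histogram counts must sum to the sample count")

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    @property
    def mode_bin_center(self) -> float:
        k = int(np.argmax(self.counts))
        return float(0.5 * (self.bin_edges[k] + self.bin_edges[k + 1]))

    def fraction_below(self, threshold: float = 8.0) -> float:
        return float(np.mean(self.samples < threshold))


def ligand_heavy_indices(topology: Topology) -> np.ndarray:
    idx = topology.atom_selection(component="ligand", heavy_only=True)
    if idx.size == 0:
        raise ValueError("topology contains no ligand heavy atoms")
    return idx


def sidechain_heavy_indices(topology: Topology, residue: int) -> np.ndarray:
    """Heavy side-chain atoms of a residue; glycine falls back to CA."""
    res_atoms = topology.atom_selection(component="protein", residue=residue,
                                        heavy_only=True)
    if res_atoms.size == 0:
        raise ValueError(f"residue {residue} has no heavy atoms")
    side = np.array([a for a in res_atoms
                     if str(topology.atom_names[a]) not in BACKBONE_NAMES])
    if side.size == 0:
        ca = topology.atom_selection(component="protein", residue=residue,
                                     name="CA")
        if ca.size == 0:
            raise ValueError(f"residue {residue} has neither side-chain heavy "
                             f"atoms nor CA")
        side = ca
    return side


def contact_residues(structure: Trajectory, cutoff: float = 6.5,
                     frame: int = 0) -> list[int]:
    """Residues with any heavy atom within ``cutoff`` of a ligand heavy atom.

    Evaluated on a single frame (the starting structure by default).
    """
    top = structure.topology
    lig = ligand_heavy_indices(top)
    prot = top.atom_selection(component="protein", heavy_only=True)
    x = structure.coordinates[frame]
    diff = x[prot][:, None, :] - x[lig][None, :, :]
    d2 = np.einsum("pqk,pqk->pq", diff, diff)
    close = (d2 < cutoff * cutoff).any(axis=1)
    return sorted({int(r) for r in top.residue_index[prot[close]]})


def _mass_weighted_com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """COM over the second axis of an (n_frames, n_atoms, 3) block."""
    return (coords * masses[None, :, None]).sum(axis=1) / masses.sum()


def com_distance_series(trajectory: Trajectory, residues,
                        frame_range: tuple[int, int] | None = None,
                        bin_width: float = 0.5,
                        include_hydrogens: bool = False
                        ) -> list[DistanceDistribution]:
    """Ligand-COM to side-chain-COM distance distribution per residue.

    Histograms use ``bin_width`` Å bins from 0 to one bin past the largest
    sample, shared across residues so the histograms are directly
    comparable.
    """
    residues = list(residues)
    if not residues:
        raise ValueError("no residues given for distance distributions")
    top = trajectory.topology
    lig = (top.atom_selection(component="ligand") if include_hydrogens
           else ligand_heavy_indices(top))
    if lig.size == 0:
        raise ValueError("topology contains no ligand atoms")
    coords = trajectory.slice_frames(frame_range)
    lig_com = _mass_weighted_com(coords[:, lig, :], top.masses[lig])
    all_samples = {}
    for r in residues:
        side = sidechain_heavy_indices(top, int(r))
        side_com = _mass_weighted_com(coords[:, side, :], top.masses[side])
        all_samples[int(r)] = np.linalg.norm(lig_com - side_com, axis=1)
    top_edge = max(s.max() for s in all_samples.values()) + bin_width
    edges = np.arange(0.0, top_edge + bin_width, bin_width)
    out = []
    for r, samples in all_samples.items():
        counts, _ = np.histogram(samples, bins=edges)
        out.append(DistanceDistribution(r, samples, edges, counts))
    return out


def summarize_ensemble(distributions: list[DistanceDistribution],
                       threshold: float = 8.0) -> pd.DataFrame:
    """Per-residue summary table, sorted by median distance ascending."""
    if not distributions:
        raise ValueError("no distance distributions to summarize")
    rows = [{
        "residue": d.residue_index,
        "mean": d.mean,
        "median": d.median,
        "mode_bin_center": d.mode_bin_center,
        f"fraction_below_{threshold:g}A": d.fraction_below(threshold),
        "n_frames": d.samples.size,
    } for d in distributions]
    df = pd.DataFrame(rows)
    return df.sort_values(["median", "residue"], kind="stable",
                          ignore_index=True)
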