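"""Structure/trajectory readers and the internal atom/residue data model.

The internal model is deliberately minimal: a :class:`Topology` of annotated
atoms partitioned into protein / ligand / water / other components, a
:class:`Trajectory` holding a dense ``(n_frames, n_atoms, 3)`` coordinate
array in Angstrom with a uniform frame spacing in picoseconds, and a
:class:`ResidueProfile`, the per-residue scalar series (with validity mask)
in which every computed or experimental observable is exchanged.

File formats are handled by MDAnalysis; this module only adapts them to the
internal model. Protein residues are renumbered contiguously from 1 while the
original author/PDB numbers are kept as labels for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# Standard amino-acid residue names used to classify protein atoms.
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX", "ASH", "GLH", "LYN",
}

DEFAULT_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845,
}


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


@dataclass
class Topology:
    """Annotated atom list partitioned into components.

    ``residue_index`` is contiguous 1-based over protein residues after
    renumbering; ligand/water/other residues continue the numbering after the
    protein block. ``residue_label`` keeps the original residue number from
    the source file for reporting.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    residue_index: np.ndarray  # 1-based internal numbering
    residue_names: np.ndarray
    components: np.ndarray  # 'protein' | 'ligand' | 'water' | 'other'
    residue_labels: np.ndarray  # original residue numbers, aligned to atoms
    ligand_resnames: frozenset = frozenset()
    water_resnames: frozenset = frozenset(DEFAULT_WATER_RESNAMES)

    def __post_init__(self) -> None:
        for name in ("atom_names", "elements", "residue_names", "components"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.residue_labels = np.asarray(self.residue_labels, dtype=int)
        n = len(self.atom_names)
        if not all(
            len(a) == n
            for a in (self.elements, self.masses, self.residue_index,
                      self.residue_names, self.components, self.residue_labels)
        ):
            raise ValueError("topology arrays must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("every atom must have mass > 0")
        if any(not e for e in self.elements):
            raise ValueError("every atom must have a nonempty element")
        valid = {"protein", "ligand", "water", "other"}
        if not set(self.components) <= valid:
            raise ValueError(f"unknown component tag in {set(self.components) - valid}")
        prot = self.residue_index[self.components == "protein"]
        if prot.size:
            uniq = np.unique(prot)
            if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
                raise ValueError("protein residues must form a contiguous 1-based range")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return int(np.unique(self.residue_index).size)

    @property
    def protein_residue_indices(self) -> np.ndarray:
        """Sorted 1-based indices of protein residues."""
        return np.unique(self.residue_index[self.components == "protein"])

    @property
    def n_protein_residues(self) -> int:
        return int(self.protein_residue_indices.size)

    def atom_selection(self, component: str | None = None,
                       residue: int | None = None,
                       name: str | None = None,
                       heavy_only: bool = False) -> np.ndarray:
        """Return atom indices matching the given filters."""
        sel = np.ones(self.n_atoms, dtype=bool)
        if component is not None:
            sel &= self.components == component
        if residue is not None:
            sel &= self.residue_index == residue
        if name is not None:
            sel &= self.atom_names == name
        if heavy_only:
            sel &= np.array([e.upper() != "H" for e in self.elements])
        return np.flatnonzero(sel)

    def ca_indices(self) -> np.ndarray:
        """Atom index of the Cα of each protein residue, in residue order."""
        out = []
        for r in self.protein_residue_indices:
            idx = self.atom_selection(component="protein", residue=int(r), name="CA")
            if idx.size == 0:
                resname = self.residue_names[self.residue_index == r][0]
                raise ValueError(f"residue {r} ({resname}) has no CA atom")
            out.append(idx[0])
        return np.asarray(out, dtype=int)

    def residue_label_of(self, residue: int) -> int:
        """Original (source-file) residue number of internal residue index."""
        labels = self.residue_labels[self.residue_index == residue]
        if labels.size == 0:
            raise KeyError(f"no residue with internal index {residue}")
        return int(labels[0])


@dataclass
class Trajectory:
    """Ordered coordinate frames bound to a topology.

    Coordinates in Angstrom, frame spacing in picoseconds.
    """

    topology: Topology
    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float = 10.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology atom count {self.topology.n_atoms}")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be > 0")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def total_time(self) -> float:
        """Time between the first and last frame, ps."""
        return (self.n_frames - 1) * self.frame_spacing

    def slice_frames(self, frame_range: tuple[int, int] | None) -> np.ndarray:
        """Coordinates for half-open ``[first, last)``; None means all frames."""
        if frame_range is None:
            return self.coordinates
        first, last = frame_range
        if not (0 <= first < last <= self.n_frames):
            raise ValueError(f"invalid frame range {frame_range} for "
                             f"{self.n_frames}-frame trajectory")
        return self.coordinates[first:last]


@dataclass
class ResidueProfile:
    """Per-residue scalar series with a validity mask."""

    residue_index: np.ndarray
    values: np.ndarray
    mask: np.ndarray  # True = valid
    label: str = ""
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.values) == len(self.mask) == len(self.residue_index)):
            raise ValueError("residue_index, values and mask must align")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.values):
                raise ValueError("sigma must align with values")

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"residue": self.residue_index,
                           "value": self.values, "valid": self.mask})
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df


def _classify(resname: str, ligand_resnames: set, water_resnames: set) -> str:
    if resname in water_resnames:
        return "water"
    if resname in ligand_resnames:
        return "ligand"
    if resname in PROTEIN_RESNAMES:
        return "protein"
    return "other"


def _infer_element(atom_name: str, resname: str, component: str) -> str:
    """Infer the element from a PDB atom name."""
    name = atom_name.strip()
    if not name:
        raise FormatError("atom with empty name: cannot infer element")
    two = name[:2].upper()
    if component in ("protein", "water", "ligand"):
        # biomolecular names start with the one-letter element
        lead = name.lstrip("0123456789")
        if not lead:
            raise FormatError(f"cannot infer element for atom name {atom_name!r}")
        if component != "ligand" and lead[0].upper() in "HCNOSP":
            return lead[0].upper()
    if two in _ELEMENT_MASSES and len(name) > 1 and not name[1].isdigit():
        return two.capitalize() if len(two) > 1 else two
    lead = name.lstrip("0123456789")
    if lead and lead[0].upper() in _ELEMENT_MASSES:
        return lead[0].upper()
    raise FormatError(f"cannot infer element for atom name {atom_name!r} ({resname})")


def _mass_of(element: str) -> float:
    try:
        return _ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise FormatError(f"no mass known for element {element!r}") from None


def _topology_from_universe(u, ligand_resnames: set, water_resnames: set
                            ) -> Topology:
    atoms = u.atoms
    if hasattr(atoms, "icodes") and any(str(i).strip() for i in atoms.icodes):
        raise FormatError("insertion codes are not supported; renumber the PDB")
    names = [str(n) for n in atoms.names]
    resnames = [str(r).strip() for r in atoms.resnames]
    resids = [int(r) for r in atoms.resids]
    components = [_classify(r, ligand_resnames, water_resnames) for r in resnames]

    elements = []
    have_elems = hasattr(atoms, "elements")
    for i, name in enumerate(names):
        el = str(atoms.elements[i]).strip() if have_elems else ""
        if not el:
            el = _infer_element(name, resnames[i], components[i])
            warnings.warn(f"element inferred from atom name {name!r} -> {el}",
                          stacklevel=3)
        elements.append(el.capitalize() if len(el) > 1 else el.upper())
    masses = [_mass_of(e) for e in elements]

    # renumber: protein residues first (contiguous from 1), then the rest in
    # file order, keyed by (original resid, resname) transitions
    internal = np.empty(len(names), dtype=int)
    seen: dict[tuple, int] = {}
    order = []  # residue keys in file order
    for i in range(len(names)):
        key = (resids[i], resnames[i], atoms.segids[i] if hasattr(atoms, "segids") else "")
        if key not in seen:
            seen[key] = len(order)
            order.append((key, components[i]))
    prot_keys = [k for k, c in order if c == "protein"]
    other_keys = [k for k, c in order if c != "protein"]
    mapping = {k: j + 1 for j, k in enumerate(prot_keys)}
    mapping.update({k: len(prot_keys) + j + 1 for j, k in enumerate(other_keys)})
    for i in range(len(names)):
        key = (resids[i], resnames[i], atoms.segids[i] if hasattr(atoms, "segids") else "")
        internal[i] = mapping[key]

    return Topology(
        atom_names=names, elements=elements, masses=masses,
        residue_index=internal, residue_names=resnames,
        components=components, residue_labels=resids,
        ligand_resnames=frozenset(ligand_resnames),
        water_resnames=frozenset(water_resnames),
    )


def read_structure(path: str | Path, ligand_resnames: set = frozenset(),
                   water_resnames: set | None = None
                   ) -> tuple[Topology, Trajectory]:
    """Read a PDB structure into a Topology and a single-frame Trajectory."""
    import MDAnalysis as mda

    if water_resnames is None:
        water_resnames = set(DEFAULT_WATER_RESNAMES)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # MDAnalysis raises assorted types
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    top = _topology_from_universe(u, set(ligand_resnames), set(water_resnames))
    coords = np.asarray(u.atoms.positions, dtype=float)[None, :, :]
    return top, Trajectory(top, coords, frame_spacing=1.0)


def read_trajectory(topology: Topology, path: str | Path,
                    frame_spacing: float = 10.0) -> Trajectory:
    """Read a coordinate trajectory (multi-model PDB, DCD or XTC)."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, trajectory=True)
        try:
            u.load_new(str(path))
        except (ValueError, OSError, EOFError) as exc:
            raise FormatError(
                f"cannot load trajectory {path} for a {topology.n_atoms}-atom "
                f"topology: {exc}") from exc
        frames = []
        try:
            for ts in u.trajectory:
                if ts.positions.shape[0] != topology.n_atoms:
                    raise FormatError(
                        f"frame {len(frames)}: atom count {ts.positions.shape[0]} "
                        f"!= topology atom count {topology.n_atoms}")
                frames.append(np.array(ts.positions, dtype=float))
        except (OSError, EOFError) as exc:
            raise FormatError(
                f"truncated trajectory at frame {len(frames)}: {exc}") from exc
    if not frames:
        raise FormatError(f"no frames found in {path}")
    return Trajectory(topology, np.stack(frames), frame_spacing=frame_spacing)


def _universe_from(topology: Topology, coordinates: np.ndarray):
    import MDAnalysis as mda

    n_res_keys, res_ids = np.unique(topology.residue_index, return_inverse=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(topology.n_atoms, n_residues=len(n_res_keys),
                               atom_resindex=res_ids, trajectory=True)
        u.add_TopologyAttr("names", [str(n) for n in topology.atom_names])
        u.add_TopologyAttr("elements", [str(e) for e in topology.elements])
        u.add_TopologyAttr("masses", topology.masses)
        resnames, resids = [], []
        for key in n_res_keys:
            at = np.flatnonzero(topology.residue_index == key)[0]
            resnames.append(str(topology.residue_names[at]))
            resids.append(int(topology.residue_labels[at]))
        u.add_TopologyAttr("resnames", resnames)
        u.add_TopologyAttr("resids", resids)
        u.atoms.positions = coordinates
    return u


def write_structure(topology: Topology, coordinates: np.ndarray,
                    path: str | Path) -> None:
    """Write a single-frame PDB."""
    u = _universe_from(topology, np.asarray(coordinates, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB or DCD, chosen by extension."""
    import MDAnalysis as mda

    u = _universe_from(trajectory.topology, trajectory.coordinates[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=trajectory.topology.n_atoms) as w:
            for frame in trajectory.coordinates:
                u.atoms.positions = frame
                w.write(u.atoms)


def read_profile(path: str | Path, n_residues: int | None = None,
                 label: str = "") -> ResidueProfile:
    """Read a per-residue table (``residue value [sigma]``; '#' comments).

    Rows absent from the table are masked invalid, emulating unassigned
    residues/prolines. The profile spans residues 1..n_residues (or 1..max
    listed index if ``n_residues`` is not given).
    """
    path = Path(path)
    rows: list[tuple[int, float, float | None]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if parts[0].lower() in ("residue", "res"):
                continue  # header line
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'residue value "
                                  f"[sigma]', got {raw.strip()!r}")
            try:
                resi = int(parts[0])
                value = float(parts[1])
                sig = float(parts[2]) if len(parts) > 2 else None
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric entry in {raw.strip()!r}") from None
            rows.append((resi, value, sig))
    seen = [r for r, _, _ in rows]
    if len(seen) != len(set(seen)):
        dup = sorted({r for r in seen if seen.count(r) > 1})
        raise FormatError(f"{path}: duplicate residue index {dup}")
    n = n_residues if n_residues is not None else (max(seen) if seen else 0)
    values = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    sigma = np.full(n, np.nan)
    any_sigma = False
    for resi, value, sig in rows:
        if not 1 <= resi <= n:
            raise FormatError(f"{path}: residue index {resi} outside 1..{n}")
        values[resi - 1] = value
        mask[resi - 1] = True
        if sig is not None:
            sigma[resi - 1] = sig
            any_sigma = True
    return ResidueProfile(np.arange(1, n + 1), values, mask, label=label,
                          sigma=sigma if any_sigma else None)


def write_profile(profile: ResidueProfile, path: str | Path) -> None:
    """Write a profile table; invalid residues are omitted (not zero-filled)."""
    with open(path, "w") as fh:
        if profile.label:
            fh.write(f"# {profile.label}\n")
        fh.write("residue value" + (" sigma" if profile.sigma is not None else "") + "\n")
        for i in range(len(profile.values)):
            if not profile.mask[i]:
                continue
            line = f"{profile.residue_index[i]} {profile.values[i]:.10g}"
            if profile.sigma is not None:
                line += f" {profile.sigma[i]:.10g}"
            fh.write(line + "\n")
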