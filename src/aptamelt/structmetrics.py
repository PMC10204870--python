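"""Desk-scale trajectory metrics: RMSD, RMSF, hydrogen bonds, contacts.

Operates on multi-model PDB files (one MODEL block per frame) the way MD
post-processing tools read trajectories, but with no dependence on an MD
engine: RMSD after optimal (Kabsch) superposition, per-residue RMSF about
the iterated mean structure, geometric hydrogen-bond detection with
per-trajectory occupancy statistics, and protein-nucleic binding-site
contact enumeration.

Geometric criteria are configurable and recorded in outputs: hydrogen bonds
use a donor-acceptor heavy-atom distance cutoff (default 3.5 A) and, when
hydrogens are present, a donor-hydrogen-acceptor angle cutoff (default 120
degrees); binding sites use a 4.0 A heavy-atom contact cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

DEFAULT_HBOND_DIST = 3.5  # A, donor-acceptor heavy atoms
DEFAULT_HBOND_ANGLE = 120.0  # degrees, donor-hydrogen-acceptor
DEFAULT_CONTACT_CUTOFF = 4.0  # A, any heavy-atom pair
DEFAULT_OCCUPANCY_THRESHOLD = 0.5
COVALENT_H_DIST = 1.25  # A, donor-hydrogen bond length ceiling

ATOM_COLUMNS = ["serial", "name", "element", "resname", "resnum", "chain"]


@dataclass
class Trajectory:
    """Multi-frame coordinates over a fixed atom table.

    ``coords`` has shape (n_frames, n_atoms, 3) in Angstrom; ``atoms`` is a
    DataFrame with columns serial, name, element, resname, resnum, chain in
    source order; ``selections`` holds named atom-index subsets.
    """

    coords: np.ndarray
    atoms: pd.DataFrame
    selections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table does not match coordinate array")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_chain(self, chain: str) -> np.ndarray:
        return np.flatnonzero((self.atoms["chain"] == chain).to_numpy())

    def heavy_atoms(self) -> np.ndarray:
        return np.flatnonzero((self.atoms["element"] != "H").to_numpy())

    def atom_label(self, i: int) -> str:
        a = self.atoms.iloc[i]
        return f"{a['chain']}:{a['resnum']}:{a['resname']}:{a['name']}"


@dataclass(frozen=True)
class HBond:
    """A geometric hydrogen bond between a donor and an acceptor atom."""

    donor: int
    acceptor: int
    hydrogen: int | None
    distance: float  # A, donor-acceptor heavy atoms
    angle: float  # degrees; NaN in heavy-atom-only mode
    occupancy: float = 1.0  # fraction of frames present


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_frames(path) -> Trajectory:
    """Read a (multi-model) PDB file into a Trajectory.

    Each MODEL block becomes one frame; a file without MODEL records yields
    a single frame. Atom metadata comes from the fixed PDB columns of the
    first model; all models must carry the same atoms.
    """
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure("traj", str(path))
    except Exception as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc

    models = list(structure)
    if not models:
        raise ValueError(f"no models found in {path}")

    def model_atoms(model):
        return [a for chain in model for res in chain for a in res]

    first = model_atoms(models[0])
    rows = []
    for atom in first:
        res = atom.get_parent()
        rows.append(
            {
                "serial": atom.serial_number,
                "name": atom.get_name(),
                "element": (atom.element or "").strip().upper() or atom.get_name()[0],
                "resname": res.get_resname().strip(),
                "resnum": res.id[1],
                "chain": res.get_parent().id,
            }
        )
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)

    key = [(r["chain"], r["resnum"], r["name"]) for r in rows]
    coords = np.empty((len(models), len(first), 3))
    coords[0] = np.array([a.coord for a in first], dtype=float)
    for m, model in enumerate(models[1:], start=1):
        atoms_m = model_atoms(model)
        if len(atoms_m) != len(first):
            raise ValueError(
                f"model {model.id} has {len(atoms_m)} atoms, expected {len(first)}"
            )
        key_m = [
            (a.get_parent().get_parent().id, a.get_parent().id[1], a.get_name())
            for a in atoms_m
        ]
        if key_m != key:
            raise ValueError(f"model {model.id}: atom table differs from the first model")
        coords[m] = np.array([a.coord for a in atoms_m], dtype=float)
    return Trajectory(coords=coords, atoms=atoms)


def write_frames(traj: Trajectory, path) -> None:
    """Write a Trajectory as a multi-model PDB file (fixed-column format)."""
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, (_, a) in enumerate(traj.atoms.iterrows()):
                x, y, z = traj.coords[m, i]
                name = a["name"]
                # PDB convention: 1-3 char names start in column 14
                name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
                fh.write(
                    f"ATOM  {int(a['serial']) % 100000:5d} {name_field} "
                    f"{a['resname']:<3s} {a['chain']}{int(a['resnum']):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                    f"{a['element']:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# superposition and fluctuation
# ---------------------------------------------------------------------------


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centered ``mobile`` onto ``reference``.

    SVD of the covariance matrix; a reflection (det = -1) is corrected by
    flipping the smallest singular direction, so the result is always a
    proper rotation.
    """
    h = mobile.T @ reference
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def kabsch_rmsd(frame_a: np.ndarray, frame_b: np.ndarray, selection=None) -> float:
    """Minimal RMSD between two frames after optimal rigid superposition."""
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if selection is not None:
        a = a[selection]
        b = b[selection]
    if a.shape != b.shape:
        raise ValueError("selections must have equal size in both frames")
    if len(a) < 3:
        raise ValueError("superposition requires >= 3 atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    rot = kabsch_rotation(a, b)
    diff = a @ rot.T - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Return ``mobile`` rigidly superposed onto ``reference``."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ rot.T + rc


def rmsd_series(traj: Trajectory, reference: int = 0, selection=None) -> pd.Series:
    """Per-frame Kabsch RMSD (A) to a reference frame (default frame 0)."""
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    ref = traj.coords[reference][sel]
    vals = [kabsch_rmsd(traj.coords[m][sel], ref) for m in range(traj.n_frames)]
    return pd.Series(vals, name="rmsd_A")


def rmsf(
    traj: Trajectory,
    selection=None,
    reference: np.ndarray | None = None,
    n_iter: int = 2,
    superpose_frames: bool = True,
) -> pd.DataFrame:
    """Per-residue RMSF (A) about the mean structure.

    Frames are superposed onto the reference (default: the iterated mean
    structure, ``n_iter`` refinement passes), per-atom fluctuations
    sqrt(<|x_i - <x_i>|^2>) are computed, and atoms are averaged within
    residues. ``superpose_frames=False`` skips the fit, for trajectories
    already in a common frame.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires >= 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    frames = traj.coords[:, sel, :].copy()
    if superpose_frames:
        ref = frames[0] if reference is None else np.asarray(reference, dtype=float)
        for _ in range(max(1, n_iter)):
            frames = np.array([superpose(f, ref) for f in frames])
            if reference is None:
                ref = frames.mean(axis=0)
    mean = frames.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))
    sub = traj.atoms.iloc[sel].copy()
    sub["rmsf_A"] = per_atom
    out = (
        sub.groupby(["chain", "resnum"], sort=True)
        .agg(resname=("resname", "first"), rmsf_A=("rmsf_A", "mean"))
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------


def _dha_angle(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    v1 = d - h
    v2 = a - h
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(float(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    coords: np.ndarray,
    atoms: pd.DataFrame,
    dist_cutoff: float = DEFAULT_HBOND_DIST,
    angle_cutoff: float = DEFAULT_HBOND_ANGLE,
) -> list[HBond]:
    """Geometric hydrogen bonds in a single frame.

    Donors and acceptors are N/O heavy atoms; atoms of the same residue are
    never paired. When the structure contains hydrogens, a donor must carry
    a covalently bonded hydrogen (within 1.25 A) and the best
    donor-hydrogen-acceptor angle must reach ``angle_cutoff``; without any
    hydrogens the check degrades to the distance criterion alone
    (heavy-atom-only mode) and every N/O may act as donor.
    """
    coords = np.asarray(coords, dtype=float)
    elements = atoms["element"].to_numpy()
    no_idx = np.flatnonzero((elements == "N") | (elements == "O"))
    h_idx = np.flatnonzero(elements == "H")
    res_key = list(zip(atoms["chain"], atoms["resnum"]))

    have_h = len(h_idx) > 0
    attached: dict[int, list[int]] = {}
    if have_h:
        if len(no_idx):
            dmat = cdist(coords[no_idx], coords[h_idx])
            for row, heavy in enumerate(no_idx):
                attached[int(heavy)] = [int(h_idx[c]) for c in np.flatnonzero(dmat[row] <= COVALENT_H_DIST)]
        donors = [i for i in no_idx if attached.get(int(i))]
    else:
        donors = list(no_idx)

    bonds: list[HBond] = []
    for d in donors:
        for a in no_idx:
            if a == d or res_key[a] == res_key[d]:
                continue
            dist = float(np.linalg.norm(coords[d] - coords[a]))
            if dist > dist_cutoff:
                continue
            if have_h:
                best_h, best_ang = None, -1.0
                for h in attached[int(d)]:
                    ang = _dha_angle(coords[d], coords[h], coords[a])
                    if ang > best_ang:
                        best_h, best_ang = h, ang
                if best_ang < angle_cutoff:
                    continue
                bonds.append(HBond(int(d), int(a), int(best_h), dist, best_ang))
            else:
                bonds.append(HBond(int(d), int(a), None, dist, float("nan")))
    return bonds


def hbond_statistics(
    traj: Trajectory,
    dist_cutoff: float = DEFAULT_HBOND_DIST,
    angle_cutoff: float = DEFAULT_HBOND_ANGLE,
) -> pd.DataFrame:
    """Per-bond occupancy and mean distance over a trajectory.

    Bonds are keyed by (donor, acceptor); occupancy is the fraction of
    frames in which the bond is present and the distance is averaged over
    those frames only. Sorted by occupancy descending (then donor label).
    """
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    present: dict[tuple[int, int], list[float]] = {}
    for m in range(traj.n_frames):
        for b in detect_hbonds(traj.coords[m], traj.atoms, dist_cutoff, angle_cutoff):
            present.setdefault((b.donor, b.acceptor), []).append(b.distance)
    rows = [
        {
            "donor": traj.atom_label(d),
            "acceptor": traj.atom_label(a),
            "donor_index": d,
            "acceptor_index": a,
            "occupancy": len(dists) / traj.n_frames,
            "mean_distance_A": float(np.mean(dists)),
        }
        for (d, a), dists in present.items()
    ]
    df = pd.DataFrame(
        rows,
        columns=["donor", "acceptor", "donor_index", "acceptor_index", "occupancy", "mean_distance_A"],
    )
    if len(df):
        df = df.sort_values(["occupancy", "donor"], ascending=[False, True]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# binding sites
# ---------------------------------------------------------------------------


def binding_sites(
    traj: Trajectory,
    selection_a,
    selection_b,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    occupancy_threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> pd.DataFrame:
    """Residue-level contact pairs across a binary interface.

    A binding site is a distinct (residue in selection A, residue in
    selection B) pair with any heavy-atom pair closer than ``cutoff``. For a
    multi-frame trajectory only pairs present in at least
    ``occupancy_threshold`` of frames are reported. The selections (e.g.
    protein chain vs nucleic chain) must be disjoint.
    """
    sel_a = np.asarray(selection_a)
    sel_b = np.asarray(selection_b)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("selections must be disjoint")
    heavy = set(traj.heavy_atoms().tolist())
    sel_a = np.array([i for i in sel_a if i in heavy], dtype=int)
    sel_b = np.array([i for i in sel_b if i in heavy], dtype=int)

    res_a = list(zip(traj.atoms["chain"].iloc[sel_a], traj.atoms["resnum"].iloc[sel_a]))
    res_b = list(zip(traj.atoms["chain"].iloc[sel_b], traj.atoms["resnum"].iloc[sel_b]))
    resname = {
        (c, n): rn
        for c, n, rn in zip(traj.atoms["chain"], traj.atoms["resnum"], traj.atoms["resname"])
    }

    counts: dict[tuple, int] = {}
    for m in range(traj.n_frames):
        dmat = cdist(traj.coords[m][sel_a], traj.coords[m][sel_b])
        frame_pairs = set()
        for i, j in zip(*np.nonzero(dmat < cutoff)):
            frame_pairs.add((res_a[i], res_b[j]))
        for pair in frame_pairs:
            counts[pair] = counts.get(pair, 0) + 1
    min_frames = occupancy_threshold * traj.n_frames if traj.n_frames > 1 else 1
    rows = [
        {
            "chain_a": ra[0],
            "resnum_a": ra[1],
            "resname_a": resname[ra],
            "chain_b": rb[0],
            "resnum_b": rb[1],
            "resname_b": resname[rb],
            "occupancy": c / traj.n_frames,
        }
        for (ra, rb), c in counts.items()
        if c >= min_frames
    ]
    df = pd.DataFrame(
        rows,
        columns=["chain_a", "resnum_a", "resname_a", "chain_b", "resnum_b", "resname_b", "occupancy"],
    )
    if len(df):
        df = df.sort_values(["chain_a", "resnum_a", "chain_b", "resnum_b"]).reset_index(drop=True)
    return df
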