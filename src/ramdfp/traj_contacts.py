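"""Per-frame geometric typing of protein-ligand contacts in dissociation trajectories.

Each trajectory frame is converted to a 7-bit interaction string per
contacted residue (hydrophobic, aromatic face-to-face, aromatic
edge-to-face, H-bond donor, H-bond acceptor, cationic, anionic — donor /
cationic refer to the ligand side), which is then collapsed to the four
contact categories used as machine-learning features: hydrogen bond (HB),
aromatic (ARO), ionic (IP), and apolar (APO). A dissociation event is
recorded at the first frame where the ligand centre of mass has moved a
threshold distance (default 30 Angstrom) from its initial bound position.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ramdfp.atom_typing import (
    AtomTypingError,
    LigandTyping,
    element_mass,
    one_letter,
    protein_flags,
    protein_rings,
)

__all__ = [
    "BIT_NAMES",
    "CATEGORIES",
    "FrameSeries",
    "GeometricCutoffs",
    "IFSeries",
    "InteractionBits",
    "TrajectoryError",
    "detect_dissociation",
    "fingerprint_trajectory",
    "group_to_categories",
    "read_trajectory",
    "type_interactions",
]

#: order of the 7 interaction-type bits
BIT_NAMES = ("hydrophobic", "aro_face", "aro_edge",
             "hb_donor", "hb_acceptor", "cationic", "anionic")

#: the four contact categories, in canonical order
CATEGORIES = ("HB", "ARO", "IP", "APO")

_CATEGORY_RANK = {c: i for i, c in enumerate(CATEGORIES)}


class TrajectoryError(ValueError):
    """Raised for unreadable trajectories, atom-count mismatches, empty selections."""


@dataclass(frozen=True)
class GeometricCutoffs:
    """Geometric contact criteria (distances in Angstrom, angles in degrees).

    Defaults follow common interaction-fingerprint conventions; they are
    package conventions, configurable per analysis.
    """

    hb_distance: float = 3.5        # donor-acceptor heavy-atom distance
    hb_donor_angle: float = 120.0   # minimum D-H...A angle (if H present)
    hydrophobic_distance: float = 4.5   # apolar C...C
    aro_face_distance: float = 4.4      # ring-centroid distance, stacked
    aro_face_angle: float = 30.0        # maximum ring-plane angle, stacked
    aro_edge_distance: float = 5.5      # ring-centroid distance, T-shaped
    aro_edge_angle: float = 60.0        # minimum ring-plane angle, T-shaped
    ionic_distance: float = 4.0         # opposite formal-charge centres

    def __post_init__(self):
        for name in ("hb_distance", "hydrophobic_distance", "aro_face_distance",
                     "aro_edge_distance", "ionic_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hb_donor_angle", "aro_face_angle", "aro_edge_angle"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must be within [0, 180] degrees")


@dataclass
class InteractionBits:
    """7-bit interaction record for one residue in one frame."""

    resid: int
    bits: np.ndarray  # shape (7,), values in {0, 1}, order = BIT_NAMES

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (7,) or not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be seven binary flags")


@dataclass
class _Atoms:
    """Typed atom collection (ligand or protein side)."""

    names: list
    elements: list
    masses: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    cation: np.ndarray
    anion: np.ndarray
    apolar: np.ndarray
    rings: list          # list of index arrays (ligand) or (resid, idx) pairs
    resids: np.ndarray | None = None   # protein only
    resnames: list | None = None       # protein only

    @property
    def is_hydrogen(self):
        return np.array([e.upper() == "H" for e in self.elements])


@dataclass
class FrameSeries:
    """Coordinates of one dissociation trajectory with typed ligand/protein atoms.

    Coordinates are in Angstrom, times in nanoseconds, frames 0-indexed.
    """

    compound_id: str
    replica_id: str
    trajectory_id: str
    frame_times: np.ndarray
    ligand: _Atoms
    protein: _Atoms
    ligand_coords: np.ndarray    # (n_frames, n_ligand_atoms, 3)
    protein_coords: np.ndarray   # (n_frames, n_protein_atoms, 3)
    ligand_com_per_frame: np.ndarray = field(init=False)
    initial_com: np.ndarray = field(init=False)

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, float)
        if self.ligand_coords.ndim != 3 or self.protein_coords.ndim != 3:
            raise TrajectoryError("coordinate arrays must be (frames, atoms, 3)")
        if len(self.frame_times) != self.n_frames:
            raise TrajectoryError("frame_times length does not match frame count")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise TrajectoryError("frame_times must be strictly increasing")
        w = self.ligand.masses / self.ligand.masses.sum()
        self.ligand_com_per_frame = np.einsum(
            "fas,a->fs", self.ligand_coords, w)
        self.initial_com = self.ligand_com_per_frame[0].copy()

    @property
    def n_frames(self) -> int:
        return self.ligand_coords.shape[0]


def detect_dissociation(series: FrameSeries, threshold: float = 30.0):
    """First frame index at which the ligand COM displacement reaches ``threshold``.

    Returns ``None`` (censored) when the threshold is never reached.
    """
    if series.n_frames < 1:
        raise TrajectoryError("trajectory has no frames")
    disp = np.linalg.norm(
        series.ligand_com_per_frame - series.initial_com, axis=1)
    hits = np.nonzero(disp >= threshold)[0]
    return int(hits[0]) if hits.size else None


def group_to_categories(bits: InteractionBits) -> dict:
    """Collapse a 7-bit interaction record to the four contact categories.

    HB = donor OR acceptor; ARO = face OR edge; IP = cationic OR anionic;
    APO = hydrophobic.
    """
    b = bits.bits
    return {
        "HB": int(b[3] | b[4]),
        "ARO": int(b[1] | b[2]),
        "IP": int(b[5] | b[6]),
        "APO": int(b[0]),
    }


def _ring_geometry(coords, idx):
    centroid = coords[idx].mean(axis=0)
    centered = coords[idx] - centroid
    # ring normal = smallest-variance direction of the ring atoms
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[-1]


def _plane_angle(n1, n2) -> float:
    cosang = abs(float(np.dot(n1, n2)) /
                 (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _donor_angle_ok(d_xyz, a_xyz, all_xyz, hydrogen_mask, min_angle) -> bool:
    """D-H...A angle criterion; passes on distance alone if no H is bonded to D."""
    h_xyz = all_xyz[hydrogen_mask]
    if h_xyz.size == 0:
        return True
    dh = np.linalg.norm(h_xyz - d_xyz, axis=1)
    bonded = h_xyz[dh < 1.3]
    if bonded.size == 0:
        return True
    for h in bonded:
        v1 = d_xyz - h
        v2 = a_xyz - h
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang >= min_angle:
            return True
    return False


def type_interactions(series: FrameSeries, frame: int,
                      cutoffs: GeometricCutoffs | None = None):
    """Geometrically type all protein-ligand interactions in one frame.

    Returns one :class:`InteractionBits` per residue with at least one flag
    set; residues without any contact are omitted.
    """
    cutoffs = cutoffs or GeometricCutoffs()
    lig, prot = series.ligand, series.protein
    if not (lig.donor.any() or lig.acceptor.any() or lig.cation.any()
            or lig.anion.any() or lig.apolar.any() or lig.rings):
        raise AtomTypingError(
            "ligand has no typed atoms (donor/acceptor/charge/apolar/ring); "
            "supply a ligand typing table")
    lx = series.ligand_coords[frame]
    px = series.protein_coords[frame]
    resids = prot.resids
    bits: dict[int, np.ndarray] = {}

    def setbit(rid, k):
        bits.setdefault(int(rid), np.zeros(7, np.uint8))[k] = 1

    dist = cdist(lx, px)
    lig_h = lig.is_hydrogen
    prot_h = prot.is_hydrogen

    # hydrophobic: apolar carbon pairs
    li, pi = np.nonzero(dist[np.ix_(lig.apolar.nonzero()[0],
                                    prot.apolar.nonzero()[0])]
                        <= cutoffs.hydrophobic_distance)
    for p in prot.apolar.nonzero()[0][np.unique(pi)]:
        setbit(resids[p], 0)

    # hydrogen bonds, ligand donating
    for i in lig.donor.nonzero()[0]:
        for j in prot.acceptor.nonzero()[0]:
            if dist[i, j] <= cutoffs.hb_distance and _donor_angle_ok(
                    lx[i], px[j], lx, lig_h, cutoffs.hb_donor_angle):
                setbit(resids[j], 3)
    # hydrogen bonds, ligand accepting
    for i in lig.acceptor.nonzero()[0]:
        for j in prot.donor.nonzero()[0]:
            if dist[i, j] <= cutoffs.hb_distance and _donor_angle_ok(
                    px[j], lx[i], px, prot_h, cutoffs.hb_donor_angle):
                setbit(resids[j], 4)

    # ionic: opposite formal-charge centres
    for i in lig.cation.nonzero()[0]:
        for j in prot.anion.nonzero()[0]:
            if dist[i, j] <= cutoffs.ionic_distance:
                setbit(resids[j], 5)
    for i in lig.anion.nonzero()[0]:
        for j in prot.cation.nonzero()[0]:
            if dist[i, j] <= cutoffs.ionic_distance:
                setbit(resids[j], 6)

    # aromatic ring-ring interactions
    for lring in lig.rings:
        lc, ln = _ring_geometry(lx, lring)
        for rid, pring in prot.rings:
            pc, pn = _ring_geometry(px, pring)
            d = float(np.linalg.norm(lc - pc))
            if d > max(cutoffs.aro_face_distance, cutoffs.aro_edge_distance):
                continue
            ang = _plane_angle(ln, pn)
            if d <= cutoffs.aro_face_distance and ang <= cutoffs.aro_face_angle:
                setbit(rid, 1)
            if d <= cutoffs.aro_edge_distance and ang >= cutoffs.aro_edge_angle:
                setbit(rid, 2)

    return [InteractionBits(rid, b) for rid, b in sorted(bits.items())]


def _feature_name(resid: int, resname: str, category: str) -> str:
    return f"{one_letter(resname)}{resid}-{category}"


def _canonical_key(name: str):
    """Sort key: ascending residue number, then HB < ARO < IP < APO."""
    try:
        stem, cat = name.rsplit("-", 1)
        num = int("".join(ch for ch in stem if ch.isdigit()))
        return (0, num, _CATEGORY_RANK.get(cat, len(CATEGORIES)), name)
    except (ValueError, KeyError):
        return (1, 0, 0, name)


@dataclass
class IFSeries:
    """Per-frame binary contact vectors over (residue, category) features."""

    compound_id: str
    replica_id: str
    trajectory_id: str
    feature_names: list
    frames: np.ndarray              # (n_frames, n_features) of {0,1}
    dissociation_frame: int | None  # None = censored
    frame_times: np.ndarray | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.uint8)
        if self.frames.ndim != 2 or self.frames.shape[1] != len(self.feature_names):
            raise ValueError("frames must be (n_frames, n_features)")
        if not np.isin(self.frames, (0, 1)).all():
            raise ValueError("fingerprint values must be 0 or 1")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.frames, columns=self.feature_names)

    def to_csv(self, path) -> None:
        """CSV of per-frame bits plus a JSON metadata sidecar (same stem)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {
            "compound_id": self.compound_id,
            "replica_id": self.replica_id,
            "trajectory_id": self.trajectory_id,
            "dissociation_frame": self.dissociation_frame,
            "frame_times_ns": (None if self.frame_times is None
                               else list(map(float, self.frame_times))),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path) -> "IFSeries":
        path = Path(path)
        table = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        times = meta.get("frame_times_ns")
        return cls(
            compound_id=meta.get("compound_id", path.stem),
            replica_id=meta.get("replica_id", ""),
            trajectory_id=meta.get("trajectory_id", path.stem),
            feature_names=list(table.columns),
            frames=table.to_numpy(),
            dissociation_frame=meta.get("dissociation_frame"),
            frame_times=None if times is None else np.asarray(times, float),
        )


def fingerprint_trajectory(series: FrameSeries,
                           cutoffs: GeometricCutoffs | None = None,
                           dissociation_threshold: float = 30.0) -> IFSeries:
    """Fingerprint every frame and assemble the trajectory's IF matrix.

    Features are the union of all (residue, category) contacts observed in
    any frame, ordered canonically (residue number, then HB/ARO/IP/APO).
    """
    cutoffs = cutoffs or GeometricCutoffs()
    resname_of = {int(r): n for r, n in
                  zip(series.protein.resids, series.protein.resnames)}
    per_frame: list[dict] = []
    for f in range(series.n_frames):
        row = {}
        for rec in type_interactions(series, f, cutoffs):
            cats = group_to_categories(rec)
            for cat, v in cats.items():
                if v:
                    row[_feature_name(rec.resid, resname_of[rec.resid], cat)] = 1
        per_frame.append(row)
    names = sorted({k for row in per_frame for k in row}, key=_canonical_key)
    mat = np.zeros((series.n_frames, len(names)), np.uint8)
    col = {n: i for i, n in enumerate(names)}
    for f, row in enumerate(per_frame):
        for k in row:
            mat[f, col[k]] = 1
    return IFSeries(
        compound_id=series.compound_id,
        replica_id=series.replica_id,
        trajectory_id=series.trajectory_id,
        feature_names=names,
        frames=mat,
        dissociation_frame=detect_dissociation(series, dissociation_threshold),
        frame_times=series.frame_times,
    )


def read_trajectory(topology_path, frames_path=None, ligand_selection="resname LIG",
                    ligand_typing: LigandTyping | str | Path | dict | None = None,
                    compound_id="", replica_id="", trajectory_id="",
                    dt_ns: float = 1.0) -> FrameSeries:
    """Read a PDB topology plus DCD/XTC/multi-model-PDB frames into a FrameSeries.

    ``ligand_typing`` supplies the ligand pharmacophore table (see
    :class:`~ramdfp.atom_typing.LigandTyping`); protein atoms are typed from
    the built-in amino-acid dictionaries. Frame times come from the
    trajectory when present, else ``dt_ns`` per frame.
    """
    import MDAnalysis as mda

    if isinstance(ligand_typing, (str, Path)):
        ligand_typing = LigandTyping.from_json(ligand_typing)
    elif isinstance(ligand_typing, dict):
        ligand_typing = LigandTyping(**ligand_typing)
    elif ligand_typing is None:
        ligand_typing = LigandTyping()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if frames_path is None:
                u = mda.Universe(str(topology_path))
            else:
                u = mda.Universe(str(topology_path), str(frames_path))
        except (ValueError, OSError, EOFError) as exc:
            raise TrajectoryError(
                f"cannot read trajectory (atom-count mismatch or unreadable "
                f"frame stream): {exc}") from exc

        lig_ag = u.select_atoms(ligand_selection)
        if lig_ag.n_atoms == 0:
            raise TrajectoryError(
                f"ligand selection {ligand_selection!r} matches no atoms")
        prot_ag = u.select_atoms("protein")

        def _elements(ag):
            try:
                return [e.capitalize() for e in ag.elements]
            except mda.exceptions.NoDataError:
                return [mda.topology.guessers.guess_atom_element(n)
                        for n in ag.names]

        lig_elements = _elements(lig_ag)
        prot_elements = _elements(prot_ag)
        lig_masses = np.array([
            ligand_typing.masses.get(n, element_mass(e))
            for n, e in zip(lig_ag.names, lig_elements)])
        d, a, c, an, ap = ligand_typing.flag_arrays(list(lig_ag.names))
        ligand = _Atoms(
            names=list(lig_ag.names), elements=lig_elements, masses=lig_masses,
            donor=d, acceptor=a, cation=c, anion=an, apolar=ap,
            rings=ligand_typing.ring_indices(list(lig_ag.names)))

        pd_, pa, pc, pan, pap = protein_flags(
            list(prot_ag.resnames), list(prot_ag.names), prot_elements)
        protein = _Atoms(
            names=list(prot_ag.names), elements=prot_elements,
            masses=np.array([element_mass(e) for e in prot_elements]),
            donor=pd_, acceptor=pa, cation=pc, anion=pan, apolar=pap,
            rings=protein_rings(prot_ag.resids, prot_ag.resnames, prot_ag.names),
            resids=prot_ag.resids.astype(int), resnames=list(prot_ag.resnames))

        lig_xyz, prot_xyz, times = [], [], []
        try:
            for ts in u.trajectory:
                lig_xyz.append(lig_ag.positions.copy())
                prot_xyz.append(prot_ag.positions.copy())
                times.append(ts.time / 1000.0)  # ps -> ns
        except (ValueError, OSError, EOFError) as exc:
            raise TrajectoryError(f"frame stream error: {exc}") from exc

    times = np.asarray(times)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(lig_xyz)) * dt_ns
    return FrameSeries(
        compound_id=compound_id, replica_id=replica_id,
        trajectory_id=trajectory_id or Path(str(frames_path or topology_path)).stem,
        frame_times=times,
        ligand=ligand, protein=protein,
        ligand_coords=np.stack(lig_xyz), protein_coords=np.stack(prot_xyz))
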