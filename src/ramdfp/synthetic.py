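"""Synthetic inputs for the pipeline: contact streams, egress times, compound sets,
and toy protein-ligand coordinate fixtures.

These generators define the study conditions under which the pipeline is
validated without any simulation data: binary contact streams with a bound
phase, scheduled contact loss and an egress event; replica-structured
egress-time samples; compound sets with a planted linear
occurrence -> log-residence-time law; and a miniature protein-ligand
complex written in standard formats (PDB topology + DCD frames) in which
every contact archetype satisfies the geometric cutoffs by construction
and is broken at a scripted frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ramdfp.featurize import FeatureMatrix
from ramdfp.tau import EgressTimes, Replica
from ramdfp.traj_contacts import IFSeries

__all__ = [
    "ContactSchedule",
    "PlantedModel",
    "ToyComplex",
    "gen_blobs",
    "gen_compound_set",
    "gen_egress_times",
    "gen_if_series",
    "gen_scaling_dataset",
    "gen_toy_complex",
    "random_contact_schedule",
]


# ---------------------------------------------------------------- IF streams

@dataclass
class ContactSchedule:
    """Scripted contact-loss schedule for one synthetic trajectory.

    ``loss_frame`` maps feature -> first frame at which the contact is
    absent (None = never lost); after loss a contact transiently re-forms
    in a frame with probability ``reformation_prob``.
    """

    feature_names: list
    n_frames: int
    loss_frame: dict = field(default_factory=dict)
    bound: list | None = None          # default: all features
    reformation_prob: float = 0.0
    egress_frame: int | None = None

    def __post_init__(self):
        if self.bound is None:
            self.bound = list(self.feature_names)
        if not self.bound:
            raise ValueError("bound set must be non-empty")
        if self.egress_frame is not None:
            for f, lf in self.loss_frame.items():
                if lf is not None and lf > self.egress_frame:
                    raise ValueError(
                        f"loss frame of {f!r} exceeds the egress frame")


def gen_if_series(schedule: ContactSchedule, seed: int = 0,
                  compound_id: str = "synthetic", replica_id: str = "r1",
                  trajectory_id: str = "t1") -> IFSeries:
    """Binary fingerprint stream realizing a contact schedule (seeded)."""
    rng = np.random.default_rng(seed)
    bound = set(schedule.bound)
    mat = np.zeros((schedule.n_frames, len(schedule.feature_names)), np.uint8)
    for j, name in enumerate(schedule.feature_names):
        if name not in bound:
            continue
        lf = schedule.loss_frame.get(name)
        for f in range(schedule.n_frames):
            if lf is None or f < lf:
                mat[f, j] = 1
            elif schedule.reformation_prob > 0:
                mat[f, j] = rng.random() < schedule.reformation_prob
    return IFSeries(compound_id=compound_id, replica_id=replica_id,
                    trajectory_id=trajectory_id,
                    feature_names=list(schedule.feature_names),
                    frames=mat, dissociation_frame=schedule.egress_frame)


def random_contact_schedule(seed: int, n_features: int = 14,
                            bound_size: int = 12,
                            n_frames: int = 60) -> ContactSchedule:
    """Random schedule with a bound set of ``bound_size`` contacts and an egress."""
    rng = np.random.default_rng(seed)
    names = [f"X{i + 1}-HB" for i in range(n_features)]
    bound = list(rng.choice(names, size=bound_size, replace=False))
    egress = int(rng.integers(n_frames // 2, n_frames))
    loss = {}
    for name in bound:
        if rng.random() < 0.9:
            loss[name] = int(rng.integers(1, egress + 1))
    return ContactSchedule(feature_names=names, n_frames=n_frames,
                           loss_frame=loss, bound=bound,
                           egress_frame=egress)


# -------------------------------------------------------------- compound set

@dataclass
class PlantedModel:
    """Ground-truth linear law: label = intercept + weights . occurrence + noise."""

    weights: np.ndarray
    intercept: float = -1.0
    noise_sd: float = 0.3

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def gen_compound_set(n_compounds: int = 94, n_features: int = 47,
                     model: PlantedModel | None = None, seed: int = 0,
                     noise_sd: float = 0.3, signal_sd: float = 1.5,
                     intercept: float = -1.0,
                     n_outliers: int = 14, n_indazoles: int = 45):
    """Compound feature matrix with a planted occurrence -> log(1/k_off) law.

    Occurrences are drawn from a low-occurrence-skewed Beta(0.7, 1.6);
    when no planted model is given, Gaussian weights are rescaled so the
    noise-free label spread is ``signal_sd`` and the label range mimics
    measured log10(1/k_off) spreads (roughly -4 to 2). Compounds are
    annotated with scaffold groups (outlier / indazole / other) in the
    study's proportions so that constrained splitting can be exercised.
    Returns ``(FeatureMatrix, manifest)`` with the full ground truth.
    """
    if n_compounds < 10:
        raise ValueError("need at least 10 compounds")
    rng = np.random.default_rng(seed)
    X = rng.beta(0.7, 1.6, size=(n_compounds, n_features))
    if model is None:
        w = rng.normal(size=n_features)
        spread = float((X @ w).std())
        w *= signal_sd / spread if spread > 0 else 1.0
        model = PlantedModel(weights=w, intercept=intercept,
                             noise_sd=noise_sd)
    y = (model.intercept + X @ model.weights
         + rng.normal(0.0, model.noise_sd, size=n_compounds))
    ids = [f"cpd{i + 1:03d}" for i in range(n_compounds)]
    features = [f"X{i + 1}-HB" for i in range(n_features)]
    groups = (["outlier"] * n_outliers + ["indazole"] * n_indazoles
              + ["other"] * (n_compounds - n_outliers - n_indazoles))
    matrix = FeatureMatrix(
        values=pd.DataFrame(X, index=ids, columns=features),
        labels=pd.Series(y, index=ids),
        annotations=pd.DataFrame({"group": groups[:n_compounds]}, index=ids))
    manifest = {"weights": [float(v) for v in model.weights],
                "intercept": float(model.intercept),
                "noise_sd": float(model.noise_sd),
                "seed": int(seed)}
    return matrix, manifest


# -------------------------------------------------------------- egress times

def gen_egress_times(n_replicas: int = 4, n_traj: int = 15,
                     distribution: str = "lognormal",
                     params: dict | None = None, seed: int = 0,
                     compound_id: str = "synthetic") -> EgressTimes:
    """Replica-structured egress-time samples (ns), deterministic under seed.

    ``lognormal``: params ``median`` (ns) and ``sigma`` (ln-scale spread);
    ``exponential``: param ``mean`` (ns); ``point``: param ``value``.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    replicas = []
    for r in range(n_replicas):
        if distribution == "lognormal":
            m = params.get("median", 1.0)
            s = params.get("sigma", 0.4)
            times = m * np.exp(s * rng.standard_normal(n_traj))
        elif distribution == "exponential":
            times = rng.exponential(params.get("mean", 1.0), size=n_traj)
        elif distribution == "point":
            times = np.full(n_traj, float(params.get("value", 1.0)))
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        replicas.append(Replica(f"rep{r + 1}", times))
    return EgressTimes(compound_id, replicas)


def gen_scaling_dataset(n_compounds: int = 80, slope: float = 0.39,
                        intercept: float = -0.52,
                        log_inv_koff_range=(-4.0, 2.0),
                        sigma_ln: float = 0.4, n_replicas: int = 4,
                        n_traj: int = 15, seed: int = 0):
    """Per-compound egress samples whose medians follow a log-linear law.

    log10(tauRAMD [ns]) = slope * log10(1/k_off [s]) + intercept, the form
    and magnitude of empirical tauRAMD-to-experiment scalings. Returns
    ``(egress_list, koffs, truth)``.
    """
    rng = np.random.default_rng(seed)
    egress_list, koffs = [], {}
    xs = rng.uniform(*log_inv_koff_range, size=n_compounds)
    for i, x in enumerate(np.sort(xs)):
        cid = f"cpd{i + 1:03d}"
        median_ns = 10.0 ** (slope * x + intercept)
        egress_list.append(gen_egress_times(
            n_replicas, n_traj, "lognormal",
            {"median": median_ns, "sigma": sigma_ln},
            seed=int(rng.integers(2 ** 31 - 1)), compound_id=cid))
        koffs[cid] = 10.0 ** (-x)
    truth = {"slope": slope, "intercept": intercept, "sigma_ln": sigma_ln}
    return egress_list, koffs, truth


def gen_blobs(n_blobs: int = 3, n_per_blob: int = 50, n_features: int = 4,
              spread: float = 0.08, label_gap: float = 1.0, seed: int = 0):
    """Well-separated Gaussian blobs in [0, 1] feature space with ordered labels.

    Blob centres sit on the diagonal of the unit cube; blob ``i`` carries
    residence-time labels around ``i * label_gap``. Returns
    ``(values, labels, truth)`` with ``truth`` the planted blob index per
    compound.
    """
    rng = np.random.default_rng(seed)
    centers = np.linspace(0.2, 0.8, n_blobs)[:, None] * np.ones(n_features)
    X = np.vstack([rng.normal(c, spread, (n_per_blob, n_features))
                   for c in centers]).clip(0.0, 1.0)
    truth = np.repeat(np.arange(n_blobs), n_per_blob)
    labels = truth * label_gap + rng.normal(0.0, 0.1 * label_gap, len(truth))
    ids = [f"cpd{i + 1:03d}" for i in range(len(truth))]
    values = pd.DataFrame(X, index=ids,
                          columns=[f"X{j + 1}-HB" for j in range(n_features)])
    return values, pd.Series(labels, index=ids), truth


# ------------------------------------------------------------- toy complexes

_ARCHETYPES = ("hb", "apolar", "ionic", "aro_face", "aro_edge")

#: archetype -> (residue one-letter+number, category) of the feature it creates
ARCHETYPE_FEATURES = {
    "hb": "D93-HB",
    "apolar": "F138-APO",
    "ionic": "K58-IP",
    "aro_face": "Y139-ARO",
    "aro_edge": "W162-ARO",
}


@dataclass
class ToyComplex:
    """Paths and ground truth of a generated toy protein-ligand fixture."""

    topology_path: Path
    trajectory_path: Path
    ligand_typing: dict
    expected_pattern: dict        # feature -> per-frame 0/1 list
    expected_dissociation: int | None
    n_frames: int


def _hexagon(center, radius=1.39, plane="xy", phase=0.0):
    angles = phase + np.arange(6) * np.pi / 3
    pts = np.zeros((6, 3))
    if plane == "xy":
        pts[:, 0] = radius * np.cos(angles)
        pts[:, 1] = radius * np.sin(angles)
    elif plane == "yz":
        pts[:, 1] = radius * np.cos(angles)
        pts[:, 2] = radius * np.sin(angles)
    return pts + np.asarray(center, float)


def _pdb_line(serial, name, resname, chain, resid, xyz, element, hetatm=False):
    record = "HETATM" if hetatm else "ATOM  "
    return (f"{record}{serial:5d} {name:<4s}{resname:>4s} {chain}{resid:4d}"
            f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2s}")


def gen_toy_complex(recipe: dict, outdir, n_frames: int = 16,
                    seed: int = 0) -> ToyComplex:
    """Write a miniature complex whose contacts realize a break schedule.

    ``recipe`` maps archetype (hb, apolar, ionic, aro_face, aro_edge) to
    the frame at which that contact is broken (None = never), plus the
    optional key ``egress`` giving the frame at which the whole ligand
    leaves (ligand COM crosses the 30 Angstrom egress criterion). The
    protein is static; each ligand group jumps 15 Angstrom out of its site
    at its break frame, and the whole ligand 200 Angstrom at egress.
    Writes ``toy.pdb`` (topology) and ``toy.dcd`` (frames) to ``outdir``.
    """
    recipe = dict(recipe)
    egress = recipe.pop("egress", None)
    unknown = set(recipe) - set(_ARCHETYPES)
    if unknown:
        raise ValueError(f"unsupported contact archetypes: {sorted(unknown)}")
    if egress is not None and egress >= n_frames:
        raise ValueError("egress frame beyond trajectory length")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- static protein sites, far apart so archetypes cannot cross-talk
    protein = []  # (name, resname, resid, xyz, element)

    def res(resname, resid, atoms):
        for name, xyz, elem in atoms:
            protein.append((name, resname, resid, np.asarray(xyz, float), elem))

    res("ASP", 93, [  # ligand donor N-H targets the backbone O at the origin
        ("N", (-2.2, 1.5, 0.0), "N"), ("CA", (-1.2, 1.0, 0.0), "C"),
        ("C", (-0.6, 0.4, 0.2), "C"), ("O", (0.0, 0.0, 0.0), "O"),
        ("CB", (0.8, 3.0, 0.0), "C"), ("CG", (0.3, 4.2, 0.0), "C"),
        ("OD1", (-0.9, 4.5, 0.0), "O"), ("OD2", (1.1, 5.3, 0.0), "O")])
    res("LYS", 58, [  # NZ charge centre at (40, 0, 0)
        ("N", (36.0, 3.0, 0.0), "N"), ("CA", (37.0, 3.5, 0.5), "C"),
        ("C", (38.0, 3.0, 0.0), "C"), ("O", (38.5, 4.0, 0.0), "O"),
        ("CB", (37.5, 1.2, 1.0), "C"), ("CG", (38.2, 0.8, 0.2), "C"),
        ("CD", (38.9, 0.4, 0.1), "C"), ("CE", (39.5, 0.2, 0.0), "C"),
        ("NZ", (40.0, 0.0, 0.0), "N")])
    phe_ring = _hexagon((0.0, 40.0, 0.0), plane="xy")
    res("PHE", 138, [("N", (-4.0, 43.0, 0.0), "N"), ("CA", (-3.0, 42.6, 0.3), "C"),
                     ("C", (-2.4, 43.4, 0.0), "C"), ("O", (-2.0, 44.4, 0.2), "O"),
                     ("CB", (-2.4, 41.3, -0.4), "C"),
                     ("CG", tuple(phe_ring[0]), "C"),
                     ("CD1", tuple(phe_ring[1]), "C"),
                     ("CE1", tuple(phe_ring[2]), "C"),
                     ("CZ", tuple(phe_ring[3]), "C"),
                     ("CE2", tuple(phe_ring[4]), "C"),
                     ("CD2", tuple(phe_ring[5]), "C")])
    tyr_ring = _hexagon((40.0, 40.0, 0.0), plane="xy")
    res("TYR", 139, [("N", (36.0, 43.0, 0.0), "N"), ("CA", (37.0, 42.6, 0.3), "C"),
                     ("C", (37.6, 43.4, 0.0), "C"), ("O", (38.0, 44.4, 0.2), "O"),
                     ("CB", (37.6, 41.3, -0.4), "C"),
                     ("CG", tuple(tyr_ring[0]), "C"),
                     ("CD1", tuple(tyr_ring[1]), "C"),
                     ("CE1", tuple(tyr_ring[2]), "C"),
                     ("CZ", tuple(tyr_ring[3]), "C"),
                     ("CE2", tuple(tyr_ring[4]), "C"),
                     ("CD2", tuple(tyr_ring[5]), "C"),
                     ("OH", (40.0, 36.2, 0.0), "O")])
    trp_ring = _hexagon((80.0, 0.0, 0.0), plane="xy")
    res("TRP", 162, [("N", (76.0, 3.0, 0.0), "N"), ("CA", (77.0, 2.6, 0.3), "C"),
                     ("C", (77.6, 3.4, 0.0), "C"), ("O", (78.0, 4.4, 0.2), "O"),
                     ("CB", (77.6, 1.3, -0.4), "C"),
                     ("CD2", tuple(trp_ring[0]), "C"),
                     ("CE2", tuple(trp_ring[1]), "C"),
                     ("CZ2", tuple(trp_ring[2]), "C"),
                     ("CH2", tuple(trp_ring[3]), "C"),
                     ("CZ3", tuple(trp_ring[4]), "C"),
                     ("CE3", tuple(trp_ring[5]), "C")])

    # --- ligand groups per archetype (base positions satisfy the cutoffs)
    lig_atoms = []          # (name, xyz, element)
    typing_atoms = {}
    typing_rings = []
    groups = {}             # archetype -> atom-name list

    if "hb" in recipe:      # N-H donor, 2.9 A from ASP93 backbone O, angle ~158 deg
        lig_atoms += [("N1", (2.9, 0.0, 0.0), "N"),
                      ("H1", (1.93, 0.25, 0.0), "H")]
        typing_atoms["N1"] = {"donor": True}
        groups["hb"] = ["N1", "H1"]
    if "ionic" in recipe:   # carboxylate O, 3.5 A from LYS58 NZ
        lig_atoms += [("O1", (43.5, 0.0, 0.0), "O")]
        typing_atoms["O1"] = {"anionic": True}
        groups["ionic"] = ["O1"]
    if "apolar" in recipe:  # methyl C, ~4.1 A above the PHE138 ring atoms
        lig_atoms += [("C1", (0.0, 40.0, 3.9), "C")]
        typing_atoms["C1"] = {"apolar": True}
        groups["apolar"] = ["C1"]
    if "aro_face" in recipe:  # benzene stacked on TYR139, centroid 3.8 A, parallel
        ring = _hexagon((40.0, 40.0, 3.8), plane="xy", phase=np.pi / 6)
        names = [f"CF{i + 1}" for i in range(6)]
        lig_atoms += [(n, tuple(p), "C") for n, p in zip(names, ring)]
        typing_rings.append(names)
        groups["aro_face"] = names
    if "aro_edge" in recipe:  # benzene perpendicular to TRP162, centroid 5.0 A
        ring = _hexagon((80.0, 0.0, 5.0), plane="yz")
        names = [f"CE{i + 1}" for i in range(6)]
        lig_atoms += [(n, tuple(p), "C") for n, p in zip(names, ring)]
        typing_rings.append(names)
        groups["aro_edge"] = names
    # anchor atom: typed but placed far from every site (keeps the ligand
    # selection and typing non-empty for contact-free recipes)
    lig_atoms += [("CX", (200.0, 200.0, 200.0), "C")]
    typing_atoms["CX"] = {"apolar": True}

    # --- frame evolution
    lig_base = np.array([xyz for _, xyz, _ in lig_atoms], float)
    lig_names = [n for n, _, _ in lig_atoms]
    frames = []
    for f in range(n_frames):
        coords = lig_base.copy()
        for arch, break_frame in recipe.items():
            if break_frame is not None and f >= break_frame:
                for name in groups[arch]:
                    coords[lig_names.index(name), 2] += 15.0
        if egress is not None and f >= egress:
            coords = lig_base + np.array([0.0, 0.0, 200.0])
        frames.append(coords)

    # --- write PDB topology + DCD frames
    top = outdir / "toy.pdb"
    lines = []
    serial = 1
    for name, resname, resid, xyz, elem in protein:
        lines.append(_pdb_line(serial, name, resname, "A", resid, xyz, elem))
        serial += 1
    for (name, xyz, elem), pos in zip(lig_atoms, frames[0]):
        lines.append(_pdb_line(serial, name, "LIG", "L", 1, pos, elem,
                               hetatm=True))
        serial += 1
    lines.append("END")
    top.write_text("\n".join(lines) + "\n")

    traj = outdir / "toy.dcd"
    import warnings

    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(top))
        prot_xyz = np.array([xyz for _, _, _, xyz, _ in protein])
        with mda.Writer(str(traj), n_atoms=u.atoms.n_atoms) as writer:
            for coords in frames:
                u.atoms.positions = np.vstack([prot_xyz, coords])
                writer.write(u.atoms)

    typing = {"atoms": typing_atoms, "rings": typing_rings, "masses": {}}
    (outdir / "toy_ligand_typing.json").write_text(json.dumps(typing, indent=1))

    expected = {}
    for arch, break_frame in recipe.items():
        pattern = []
        for f in range(n_frames):
            present = (break_frame is None or f < break_frame)
            if egress is not None and f >= egress:
                present = False
            pattern.append(int(present))
        expected[ARCHETYPE_FEATURES[arch]] = pattern
    return ToyComplex(topology_path=top, trajectory_path=traj,
                      ligand_typing=typing, expected_pattern=expected,
                      expected_dissociation=egress, n_frames=n_frames)
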