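"""Synthetic inputs with known ground truth for every pipeline stage.

Generators emit (1) toy helical receptor + cyclic-peptide-like ligand
complexes in PDB form with planted contacts, hydrogen bonds, salt bridges
and residue substitutions; (2) multi-residue chi-angle trajectories as
mixtures of wrapped-Gaussian peaks with planted cross-residue coupling and
per-trajectory identity-coded residues; (3) noisy FP titrations from the
exact binding isotherm or the competition sigmoid.  Every generator is a
pure function of its spec (seed included) and returns a machine-readable
truth manifest next to the data.

Toy-complex geometry is idealised: residues sit on a stretched helical
spiral (7 A rise per residue), which keeps every non-planted residue more
than 8 A from the ligand while planted features are realised exactly at
their construction distances (contacts 4.0 A, hydrogen bonds 2.9 A / 165
deg, salt bridges 3.2 A).  Realism is limited to what the detectors
measure -- distances and angles -- which is what construction-oracle
testing needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .errors import GenerationError
from .fpfit import FPTitration, binding_isotherm, competition_curve
from .rotamers import DEFAULT_PEAKS, DihedralSeries, wrap_angle
from .structio import Structure

# Helical-spiral receptor geometry (Angstrom / degrees).
RISE = 7.0
RADIUS = 2.3
TWIST_DEG = 100.0
CONTACT_DIST = 4.0
HBOND_DIST = 2.9
HBOND_ANGLE_DEG = 165.0
SALT_DIST = 3.2
DECOY_CLEARANCE = 9.0
MIN_NONPLANT_DIST = 7.9  # enforced clearance for non-planted residues


# ---------------------------------------------------------------------------
# Toy complex
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Recipe for a toy receptor--ligand complex with planted features.

    ``contacts``, ``hbonds`` and ``salt_bridges`` list receptor residue
    numbers (chain A); each consumes one ligand residue.  ``substitutions``
    maps receptor residue numbers to residue names (salt-bridge residues
    are forced to ARG).  ``ligand_offset`` pushes the non-planted ligand
    residues further out radially.
    """

    n_receptor: int = 12
    n_ligand: int = 4
    contacts: tuple[int, ...] = ()
    hbonds: tuple[int, ...] = ()
    salt_bridges: tuple[int, ...] = ()
    substitutions: dict[int, str] = field(default_factory=dict)
    ligand_offset: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_receptor < 3 or self.n_ligand < 3:
            raise GenerationError("need >= 3 receptor and >= 3 ligand residues")
        planted = list(self.contacts) + list(self.hbonds) + list(self.salt_bridges)
        if len(set(planted)) != len(planted):
            raise GenerationError("overlapping plants on one receptor residue")
        if len(planted) > self.n_ligand:
            raise GenerationError("more planted features than ligand residues")
        for r in planted:
            if not 1 <= r <= self.n_receptor:
                raise GenerationError(f"receptor residue {r} out of range")
        for r in self.salt_bridges:
            sub = self.substitutions.get(r, "ARG")
            if sub != "ARG":
                raise GenerationError(
                    f"salt-bridge residue {r} must be ARG, got {sub}"
                )


# Side-chain stub layouts: list of (atom name, radial steps beyond CA).
_SIDECHAINS: dict[str, list[tuple[str, float, float]]] = {
    # (name, radial offset from CA, tangential offset)
    "ALA": [("CB", 1.53, 0.0)],
    "ASP": [("CB", 1.5, 0.0), ("CG", 3.0, 0.0),
            ("OD1", 3.0 + 1.25 * math.cos(math.radians(30)), 1.25 * math.sin(math.radians(30))),
            ("OD2", 3.0 + 1.25 * math.cos(math.radians(30)), -1.25 * math.sin(math.radians(30)))],
    "ARG": [("CB", 1.5, 0.0), ("CG", 2.9, 0.0), ("CD", 4.3, 0.0),
            ("NE", 5.7, 0.0), ("CZ", 7.03, 0.0),
            ("NH1", 7.03 + 1.33 * math.cos(math.radians(30)), 1.33 * math.sin(math.radians(30))),
            ("NH2", 7.03 + 1.33 * math.cos(math.radians(30)), -1.33 * math.sin(math.radians(30)))],
}


def _frame(resnum: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(CA position, radial, tangential, axial unit vectors) of residue ``resnum``."""
    i = resnum - 1
    phi = math.radians(TWIST_DEG) * i
    rhat = np.array([math.cos(phi), math.sin(phi), 0.0])
    that = np.array([-math.sin(phi), math.cos(phi), 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    ca = RADIUS * rhat + i * RISE * zhat
    return ca, rhat, that, zhat


def _element_of(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclass
class _AtomRec:
    chain: str
    resnum: int
    resname: str
    name: str
    xyz: np.ndarray
    hetero: bool = False


def _receptor_atoms(spec: ToyComplexSpec) -> list[_AtomRec]:
    subs = dict(spec.substitutions)
    for r in spec.salt_bridges:
        subs[r] = "ARG"
    atoms: list[_AtomRec] = []
    for resnum in range(1, spec.n_receptor + 1):
        resname = subs.get(resnum, "ALA")
        ca, rhat, that, zhat = _frame(resnum)
        n = ca - 1.2 * zhat + 0.8 * that
        c = ca + 1.2 * zhat + 0.8 * that
        o = c + 1.23 * rhat
        for name, xyz in (("N", n), ("CA", ca), ("C", c), ("O", o)):
            atoms.append(_AtomRec("A", resnum, resname, name, xyz))
        stub = _SIDECHAINS.get(resname, [("CB", 1.53, 0.0)])
        for name, dr, dt in stub:
            atoms.append(_AtomRec("A", resnum, resname, name, ca + dr * rhat + dt * that))
    return atoms


def _ligand_residue_contact(resnum: int, target: int) -> list[_AtomRec]:
    ca_r, rhat, that, _ = _frame(target)
    cb = ca_r + 1.53 * rhat  # ALA CB of the target (substituted stubs still have CB)
    ca = cb + CONTACT_DIST * rhat
    n = ca + 1.45 * that
    c = ca - 1.45 * that
    o = c + 1.23 * rhat
    return [
        _AtomRec("B", resnum, "GLY", "N", n),
        _AtomRec("B", resnum, "GLY", "CA", ca),
        _AtomRec("B", resnum, "GLY", "C", c),
        _AtomRec("B", resnum, "GLY", "O", o),
    ]


def _ligand_residue_hbond(resnum: int, target: int) -> list[_AtomRec]:
    ca_r, rhat, that, zhat = _frame(target)
    o_rec = ca_r + 1.2 * zhat + 0.8 * that + 1.23 * rhat  # backbone carbonyl O
    n = o_rec + HBOND_DIST * rhat
    ang = math.radians(180.0 - HBOND_ANGLE_DEG)
    vhat = math.cos(ang) * rhat + math.sin(ang) * that
    ca = n + 1.45 * vhat
    c = ca + 1.5 * rhat
    o = c + 1.23 * rhat
    return [
        _AtomRec("B", resnum, "GLY", "N", n),
        _AtomRec("B", resnum, "GLY", "CA", ca),
        _AtomRec("B", resnum, "GLY", "C", c),
        _AtomRec("B", resnum, "GLY", "O", o),
    ]


def _ligand_residue_salt(resnum: int, target: int) -> list[_AtomRec]:
    ca_r, rhat, that, _ = _frame(target)
    nh1 = (
        ca_r
        + (7.03 + 1.33 * math.cos(math.radians(30))) * rhat
        + 1.33 * math.sin(math.radians(30)) * that
    )
    od1 = nh1 + SALT_DIST * rhat
    cg = od1 + 1.25 * rhat
    od2 = cg + 1.25 * (math.cos(math.radians(60)) * rhat + math.sin(math.radians(60)) * that)
    cb = cg + 1.5 * rhat
    ca = cb + 1.5 * rhat
    n = ca + 1.45 * that
    c = ca - 1.45 * that
    o = c + 1.23 * rhat
    recs = [("OD1", od1), ("CG", cg), ("OD2", od2), ("CB", cb),
            ("CA", ca), ("N", n), ("C", c), ("O", o)]
    return [_AtomRec("B", resnum, "ASP", nm, xyz) for nm, xyz in recs]


def _ligand_residue_decoy(
    resnum: int, j: int, n_decoys: int, spec: ToyComplexSpec,
    receptor_max_radius: float, z_range: tuple[float, float],
    rng: np.random.Generator,
) -> list[_AtomRec]:
    r_far = receptor_max_radius + DECOY_CLEARANCE + spec.ligand_offset
    phi = 2.4 * j
    rhat = np.array([math.cos(phi), math.sin(phi), 0.0])
    that = np.array([-math.sin(phi), math.cos(phi), 0.0])
    frac = (j + 0.5) / max(n_decoys, 1)
    z = z_range[0] + frac * (z_range[1] - z_range[0])
    jitter = rng.uniform(-0.2, 0.2, size=3)
    ca = r_far * rhat + np.array([0.0, 0.0, z]) + jitter
    n = ca + 1.45 * that
    c = ca - 1.45 * that
    o = c + 1.23 * rhat
    het = resnum % 2 == 0  # ATOM/HETATM hybrid, as in a chemically linked macrocycle
    return [
        _AtomRec("B", resnum, "GLY", "N", n, het),
        _AtomRec("B", resnum, "GLY", "CA", ca, het),
        _AtomRec("B", resnum, "GLY", "C", c, het),
        _AtomRec("B", resnum, "GLY", "O", o, het),
    ]


def _to_structure(atoms: list[_AtomRec], label: str) -> Structure:
    n = len(atoms)
    arr = struc.AtomArray(n)
    arr.coord = np.round(np.array([a.xyz for a in atoms], float), 3)
    arr.chain_id = np.array([a.chain for a in atoms])
    arr.res_id = np.array([a.resnum for a in atoms])
    arr.ins_code = np.array([""] * n)
    arr.res_name = np.array([a.resname for a in atoms])
    arr.atom_name = np.array([a.name for a in atoms])
    arr.element = np.array([_element_of(a.name) for a in atoms])
    arr.hetero = np.array([a.hetero for a in atoms])
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    return Structure(arr, id=label)


def make_toy_complex(spec: ToyComplexSpec) -> tuple[Structure, dict]:
    """Build a toy complex realising the planted features, plus a truth manifest.

    Raises :class:`GenerationError` when the requested plants cannot be
    realised with the required clearances (verified numerically after
    construction, not merely assumed).
    """
    rng = np.random.default_rng(spec.seed)
    receptor = _receptor_atoms(spec)
    planted = (
        [(r, "contact") for r in spec.contacts]
        + [(r, "hbond") for r in spec.hbonds]
        + [(r, "salt") for r in spec.salt_bridges]
    )
    ligand: list[_AtomRec] = []
    manifest_hbonds, manifest_salts = [], []
    lig_resnum = 0
    for target, kind in planted:
        lig_resnum += 1
        if kind == "contact":
            ligand += _ligand_residue_contact(lig_resnum, target)
        elif kind == "hbond":
            ligand += _ligand_residue_hbond(lig_resnum, target)
            manifest_hbonds.append(
                {
                    "donor": {"chain": "B", "resnum": lig_resnum, "atom": "N"},
                    "acceptor": {"chain": "A", "resnum": target, "atom": "O"},
                    "distance": HBOND_DIST,
                    "angle": HBOND_ANGLE_DEG,
                }
            )
        else:
            ligand += _ligand_residue_salt(lig_resnum, target)
            manifest_salts.append(
                {
                    "cation": {"chain": "A", "resnum": target, "resname": "ARG"},
                    "anion": {"chain": "B", "resnum": lig_resnum, "resname": "ASP"},
                    "distance": SALT_DIST,
                }
            )
    rec_xyz = np.array([a.xyz for a in receptor])
    receptor_max_radius = float(np.linalg.norm(rec_xyz[:, :2], axis=1).max())
    z_range = (float(rec_xyz[:, 2].min()), float(rec_xyz[:, 2].max()))
    n_decoys = spec.n_ligand - len(planted)
    for j in range(n_decoys):
        lig_resnum += 1
        ligand += _ligand_residue_decoy(
            lig_resnum, j, n_decoys, spec, receptor_max_radius, z_range, rng
        )

    # Verify the construction honours the clearances it promises.
    lig_xyz = np.array([a.xyz for a in ligand])
    planted_set = {r for r, _ in planted}
    for resnum in range(1, spec.n_receptor + 1):
        res_xyz = np.array([a.xyz for a in receptor if a.resnum == resnum])
        d = np.linalg.norm(res_xyz[:, None, :] - lig_xyz[None, :, :], axis=2).min()
        if resnum in planted_set and d > 4.5 + 1e-6:
            raise GenerationError(f"planted residue {resnum} not realised ({d:.2f} A)")
        if resnum not in planted_set and d < MIN_NONPLANT_DIST:
            raise GenerationError(
                f"non-planted residue {resnum} only {d:.2f} A from ligand "
                "(overlapping plants)"
            )

    structure = _to_structure(receptor + ligand, label=f"toy-complex-seed{spec.seed}")
    manifest = {
        "receptor_chain": "A",
        "ligand_chain": "B",
        "contact_residues": sorted(planted_set),
        "hbonds": manifest_hbonds,
        "salt_bridges": manifest_salts,
        "substitutions": {
            **{int(k): v for k, v in spec.substitutions.items()},
            **{int(r): "ARG" for r in spec.salt_bridges},
        },
        "seed": spec.seed,
    }
    return structure, manifest


def make_ideal_sidechain(chi1: float) -> Structure:
    """Single MET residue whose chi1 (N-CA-CB-CG) equals ``chi1`` exactly.

    Used as a construction oracle for the dihedral/chi machinery.
    """
    n = np.array([1.45, 0.0, 0.0])
    ca = np.zeros(3)
    cb = np.array([0.0, 1.53, 0.0])
    b1 = (cb - ca) / np.linalg.norm(cb - ca)
    u = n - ca - np.dot(n - ca, b1) * b1
    u /= np.linalg.norm(u)
    w = np.cross(b1, u)
    theta = math.radians(109.5)
    from .rotamers import compute_dihedral

    for sign in (1.0, -1.0):
        v = math.cos(chi1) * u + sign * math.sin(chi1) * w
        cg = cb + 1.52 * (math.sin(theta) * v + math.cos(theta) * b1)
        got = compute_dihedral(n, ca, cb, cg)
        if abs(wrap_angle(got - chi1)) < 1e-9:
            break
    atoms = [
        _AtomRec("A", 1, "MET", "N", n),
        _AtomRec("A", 1, "MET", "CA", ca),
        _AtomRec("A", 1, "MET", "CB", cb),
        _AtomRec("A", 1, "MET", "CG", cg),
    ]
    s = _to_structure(atoms, "ideal-sidechain")
    # Keep full float precision for the oracle (bypass PDB rounding).
    s.array.coord = np.array([n, ca, cb, cg])
    return s


# ---------------------------------------------------------------------------
# Chi-angle trajectories
# ---------------------------------------------------------------------------

@dataclass
class ChiSeriesSpec:
    """Recipe for multi-residue rotamer-state trajectories.

    Each non-identity residue hops between wrapped-Gaussian peaks via a
    persistent two-state chain whose stationary distribution equals the
    requested occupancies.  A coupled pair (i, j, c) rebuilds residue j
    frame-wise as a copy of residue i with probability ``c`` (otherwise its
    own independent chain), so c = 1 gives identical series and c = 0
    independence while marginals stay intact when occupancies match.
    Identity-coded residues carry a constant 0/1 amino-acid-type value per
    trajectory.
    """

    residues: tuple[str, ...] = ("F104:chi1", "F112:chi1")
    peaks: dict[str, tuple[float, ...]] = field(default_factory=dict)
    occupancies: dict[str, tuple[float, ...]] = field(default_factory=dict)
    coupled_pairs: tuple[tuple[str, str, float], ...] = ()
    identity_residues: dict[str, tuple[int, ...]] = field(default_factory=dict)
    n_frames: int = 1000
    n_trajectories: int = 1
    width: float = 0.3
    switch_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for label, occ in self.occupancies.items():
            if abs(sum(occ) - 1.0) > 1e-9:
                raise ValueError(f"occupancies of {label!r} must sum to 1")
        targets = [j for _, j, _ in self.coupled_pairs]
        if len(set(targets)) != len(targets):
            raise ValueError("a residue may be the driven member of one pair only")
        for i, j, c in self.coupled_pairs:
            if not 0.0 <= c <= 1.0:
                raise ValueError("coupling strength must be in [0, 1]")
            if i not in self.residues or j not in self.residues:
                raise ValueError(f"coupled pair ({i}, {j}) not in residues")
        for label, vals in self.identity_residues.items():
            if len(vals) != self.n_trajectories:
                raise ValueError(
                    f"identity residue {label!r} needs one value per trajectory"
                )


def _state_chain(
    rng: np.random.Generator, occ: np.ndarray, n: int, switch: float
) -> np.ndarray:
    fresh = rng.choice(occ.size, size=n, p=occ)
    redraw = rng.random(n) < switch
    states = np.empty(n, dtype=int)
    states[0] = fresh[0]
    for f in range(1, n):
        states[f] = fresh[f] if redraw[f] else states[f - 1]
    return states


def simulate_chi_series(spec: ChiSeriesSpec) -> tuple[DihedralSeries, dict]:
    """Draw chi-angle trajectories with planted occupancies and couplings."""
    rng = np.random.default_rng(spec.seed)
    driven = {j: (i, c) for i, j, c in spec.coupled_pairs}
    parts = []
    for t in range(spec.n_trajectories):
        cols: dict[str, np.ndarray] = {
            "frame": np.arange(spec.n_frames),
            "traj": np.full(spec.n_frames, f"traj{t}"),
        }
        states: dict[str, np.ndarray] = {}
        for label in spec.residues:
            if label in spec.identity_residues:
                continue
            occ = np.asarray(spec.occupancies.get(label, (0.5, 0.5)), float)
            states[label] = _state_chain(rng, occ, spec.n_frames, spec.switch_prob)
        for j, (i, c) in driven.items():
            if i in spec.identity_residues:
                continue
            copy = rng.random(spec.n_frames) < c
            states[j] = np.where(copy, states[i], states[j])
        for label in spec.residues:
            if label in spec.identity_residues:
                cols[label] = np.full(
                    spec.n_frames, float(spec.identity_residues[label][t])
                )
            else:
                centers = np.asarray(spec.peaks.get(label, DEFAULT_PEAKS), float)
                noise = rng.normal(0.0, spec.width, size=spec.n_frames)
                cols[label] = wrap_angle(centers[states[label]] + noise)
        parts.append(pd.DataFrame(cols))
    series = DihedralSeries(
        pd.concat(parts, ignore_index=True),
        identity_columns=frozenset(spec.identity_residues),
    )
    manifest = {
        "residues": list(spec.residues),
        "occupancies": {
            l: list(spec.occupancies.get(l, (0.5, 0.5)))
            for l in spec.residues
            if l not in spec.identity_residues
        },
        "coupled_pairs": [list(p) for p in spec.coupled_pairs],
        "identity_residues": {k: list(v) for k, v in spec.identity_residues.items()},
        "n_frames": spec.n_frames,
        "n_trajectories": spec.n_trajectories,
        "width": spec.width,
        "seed": spec.seed,
    }
    return series, manifest


# ---------------------------------------------------------------------------
# FP titrations
# ---------------------------------------------------------------------------

@dataclass
class FPSpec:
    """Recipe for a noisy FP titration.

    Binding mode follows the assay design of a 20 nM labelled peptide
    titrated with 60--1000 nM protein, measured in duplicate wells (12
    concentrations x 2 replicates, the usual plate layout for anisotropy
    titrations); competition mode spans 1 nM to 30 uM competitor.
    ``sigma`` is Gaussian noise as a fraction of the dynamic range
    (Amax - A0).
    """

    mode: str = "binding"  # or "competition"
    kd: float = 200.0  # nM (binding) -- or EC50 in nM (competition)
    c: float = 20.0  # nM labelled peptide
    a0: float = 0.05
    amax: float = 0.25
    x: np.ndarray | None = None
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("binding", "competition"):
            raise ValueError("mode must be 'binding' or 'competition'")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.x is not None:
            self.x = np.asarray(self.x, float)
            if self.mode == "competition" and np.any(self.x <= 0):
                raise ValueError("design points must be positive")


def simulate_fp_titration(spec: FPSpec):
    """Noisy titration from the exact model curve; seeded and deterministic.

    Binding mode returns an :class:`FPTitration` (x in nM); competition
    mode returns ``(conc_molar, y)`` arrays for :func:`fit_competition`.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "binding":
        x = spec.x if spec.x is not None else np.repeat(np.geomspace(60.0, 1000.0, 12), 2)
        y = binding_isotherm(x, spec.c, spec.kd, spec.a0, spec.amax)
        y = y + rng.normal(0.0, spec.sigma * (spec.amax - spec.a0), size=x.size)
        return FPTitration(x=x, y=y, c=spec.c)
    conc = spec.x if spec.x is not None else np.geomspace(1e-9, 30e-6, 12)
    logec50 = math.log10(spec.kd * 1e-9)
    y = competition_curve(np.log10(conc), spec.a0, spec.amax, logec50)
    y = y + rng.normal(0.0, spec.sigma * (spec.amax - spec.a0), size=conc.size)
    return conc, y
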