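"""Interface geometry of protein--peptide complexes.

Implements the structural quantities reported for groove-binding cyclic
peptides: contact residues within a distance cutoff, conservation comparison
between homologous complexes, geometric hydrogen-bond and salt-bridge
detection, exact minimum distances, Shrake--Rupley solvent-accessible
surface area (SASA), buried interface area, and Kabsch C-alpha
superposition / RMSD.

Conventions
-----------
* All lengths in Angstrom, areas in Angstrom^2, angles in degrees.
* Hydrogens are ignored by the distance-based detectors (crystal structures
  of this resolution class carry none); the hydrogen-bond criterion is the
  standard heavy-atom one: donor--acceptor distance <= 3.5 A and
  antecedent--donor--acceptor angle >= 120 deg.
* The salt-bridge criterion is the Barlow--Thornton N--O distance <= 4.0 A
  between a cationic nitrogen group (Arg guanidinium, Lys NZ, His imidazole)
  and a carboxylate oxygen group (Asp/Glu side chain, C-terminal OXT).
* SASA uses golden-spiral sphere points (default 960) with probe 1.4 A and
  the element radii table C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    InvalidPairingError,
    NoReceptorError,
    UnderdeterminedError,
    UnknownElementError,
)
from .structio import Atom, AtomSet, Structure

# Van der Waals radii (Angstrom) used by the SASA calculation.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}

DEFAULT_PROBE = 1.4
DEFAULT_SPHERE_POINTS = 960
HBOND_DMAX = 3.5
HBOND_ANGLE_MIN = 120.0
SALT_BRIDGE_DMAX = 4.0
COVALENT_CUTOFF = 1.8  # heavy-atom bond detection for donor antecedents

ResidueKey = tuple[str, int, str]  # (chain, resnum, icode)

# Cation / anion group atom names per residue type.
CATION_ATOMS = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
ANION_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
TERMINAL_CARBOXYLATE = ("OXT",)


# ---------------------------------------------------------------------------
# Contact residues
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactResidue:
    chain: str
    resnum: int
    icode: str
    resname: str
    min_distance: float

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.resnum, self.icode)


@dataclass
class ContactReport:
    """Residues of the receptor with any heavy atom within ``cutoff`` of the ligand."""

    ligand: AtomSet
    cutoff: float
    residues: list[ContactResidue]

    def keys(self) -> list[ResidueKey]:
        return [r.key for r in self.residues]

    def resname(self, key: ResidueKey) -> str:
        for r in self.residues:
            if r.key == key:
                return r.resname
        raise KeyError(key)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chain": r.chain,
                    "resnum": r.resnum,
                    "icode": r.icode,
                    "resname": r.resname,
                    "min_distance": r.min_distance,
                }
                for r in self.residues
            ]
        )


def _receptor_indices(
    complex: Structure, ligand: AtomSet, include_waters: bool
) -> np.ndarray:
    mask = np.ones(len(complex), dtype=bool)
    mask[ligand.indices] = False
    mask &= complex.heavy_mask
    if not include_waters:
        mask &= ~complex.water_mask
    return np.flatnonzero(mask)


def contact_residues(
    complex: Structure,
    ligand: AtomSet,
    cutoff: float = 5.0,
    include_waters: bool = False,
) -> ContactReport:
    """Enumerate receptor residues within ``cutoff`` A of any ligand heavy atom.

    The receptor is the complex minus the ligand selection minus waters
    (unless ``include_waters``); hydrogens are ignored on both sides.
    Residues are sorted by (chain, resnum, icode) and each carries its
    minimum heavy-atom distance to the ligand.
    """
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec_idx = _receptor_indices(complex, ligand, include_waters)
    if rec_idx.size == 0:
        raise NoReceptorError("ligand selection covers the whole structure")

    lig_heavy = ligand.intersect_mask(complex.heavy_mask)
    if len(lig_heavy) == 0:
        raise ValueError("ligand selection contains no heavy atoms")
    tree = cKDTree(lig_heavy.coords)
    dists, _ = tree.query(complex.coords[rec_idx], k=1)

    per_res: dict[ResidueKey, tuple[str, float]] = {}
    a = complex.array
    for i, d in zip(rec_idx, dists):
        key = (str(a.chain_id[i]), int(a.res_id[i]), str(a.ins_code[i]))
        prev = per_res.get(key)
        if prev is None or d < prev[1]:
            per_res[key] = (str(a.res_name[i]), float(d))

    rows = [
        ContactResidue(k[0], k[1], k[2], resname, dist)
        for k, (resname, dist) in per_res.items()
        if dist <= cutoff
    ]
    rows.sort(key=lambda r: (r.chain, r.resnum, r.icode))
    return ContactReport(ligand=ligand, cutoff=cutoff, residues=rows)


# ---------------------------------------------------------------------------
# Conservation comparison
# ---------------------------------------------------------------------------

@dataclass
class ConservationComparison:
    """Contact residues of two homologous complexes partitioned by identity."""

    conserved: list[tuple[ContactResidue, ContactResidue]]
    non_conserved: list[tuple[ContactResidue, ContactResidue]]
    unpaired_a: list[ContactResidue]
    unpaired_b: list[ContactResidue]

    @property
    def n_non_conserved(self) -> int:
        return len(self.non_conserved)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for status, pairs in (
            ("conserved", self.conserved),
            ("non_conserved", self.non_conserved),
        ):
            for ra, rb in pairs:
                rows.append(
                    {
                        "status": status,
                        "chain_a": ra.chain, "resnum_a": ra.resnum, "resname_a": ra.resname,
                        "chain_b": rb.chain, "resnum_b": rb.resnum, "resname_b": rb.resname,
                    }
                )
        return pd.DataFrame(rows)


def _normalize_pairing(pairing) -> dict[ResidueKey, ResidueKey]:
    """Accept a dict or iterable of key pairs; keys are (chain, resnum[, icode])."""

    def norm(k) -> ResidueKey:
        if isinstance(k, str):
            chain, resnum = k.split(":")
            return (chain, int(resnum), "")
        k = tuple(k)
        return (str(k[0]), int(k[1]), str(k[2]) if len(k) > 2 else "")

    items = pairing.items() if hasattr(pairing, "items") else list(pairing)
    out: dict[ResidueKey, ResidueKey] = {}
    seen_targets: dict[ResidueKey, ResidueKey] = {}
    for ka, kb in items:
        ka, kb = norm(ka), norm(kb)
        if ka in out and out[ka] != kb:
            raise InvalidPairingError(f"residue {ka} mapped to two targets")
        if kb in seen_targets and seen_targets[kb] != ka:
            raise InvalidPairingError(f"residue {kb} is the target of two residues")
        out[ka] = kb
        seen_targets[kb] = ka
    return out


def pairing_from_sequences(
    a: Structure, b: Structure, chain_a: str, chain_b: str
) -> dict[ResidueKey, ResidueKey]:
    """Residue pairing of two homologous chains from a global sequence alignment.

    Convenience builder only -- an explicit pairing map remains the source of
    truth wherever one is supplied.  Non-standard residues align as 'X'.
    """
    import biotite.sequence as seq
    import biotite.sequence.align as align

    three_to_one = {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }

    def chain_residues(s: Structure, chain: str):
        keys, letters = [], []
        for key, resname, idx in s.residues():
            if key[0] != chain or resname in WATER_RESNAMES:
                continue
            if not np.any(s.array.atom_name[idx] == "CA"):
                continue
            keys.append(key)
            letters.append(three_to_one.get(resname, "X"))
        return keys, "".join(letters)

    keys_a, seq_a = chain_residues(a, chain_a)
    keys_b, seq_b = chain_residues(b, chain_b)
    matrix = align.SubstitutionMatrix.std_protein_matrix()
    alignment = align.align_optimal(
        seq.ProteinSequence(seq_a), seq.ProteinSequence(seq_b), matrix
    )[0]
    pairing: dict[ResidueKey, ResidueKey] = {}
    for i, j in alignment.trace:
        if i != -1 and j != -1:
            pairing[keys_a[i]] = keys_b[j]
    return pairing


def load_pairing(path) -> dict[ResidueKey, ResidueKey]:
    """Read a residue pairing map from two-column text (``A:111  B:104``).

    Lines starting with ``#`` are comments.  The map is validated to be
    one-to-one.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ka, kb = line.split()
            pairs.append((ka, kb))
    return _normalize_pairing(pairs)


def compare_conservation(
    report_a: ContactReport, report_b: ContactReport, pairing
) -> ConservationComparison:
    """Partition paired contact residues into conserved / non-conserved.

    ``pairing`` maps report-A residue keys to report-B residue keys
    (dict or iterable of pairs; keys are ``(chain, resnum)`` tuples or
    ``"chain:resnum"`` strings).  A pair is non-conserved iff the residue
    names differ.  Residues without a partner in both reports are flagged
    in ``unpaired_a`` / ``unpaired_b``, not errored.
    """
    pmap = _normalize_pairing(pairing)
    by_key_b = {r.key: r for r in report_b.residues}
    conserved, non_conserved, unpaired_a = [], [], []
    matched_b: set[ResidueKey] = set()
    for ra in report_a.residues:
        target = pmap.get(ra.key)
        rb = by_key_b.get(target) if target is not None else None
        if rb is None:
            unpaired_a.append(ra)
            continue
        matched_b.add(rb.key)
        (conserved if ra.resname == rb.resname else non_conserved).append((ra, rb))
    unpaired_b = [r for r in report_b.residues if r.key not in matched_b]
    return ConservationComparison(conserved, non_conserved, unpaired_a, unpaired_b)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def min_distance(a: AtomSet, b: AtomSet, heavy_only: bool = True) -> float:
    """Exact minimum distance over all (heavy) atom pairs of two disjoint sets."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both atom sets must be non-empty")
    if a.structure is b.structure and np.intersect1d(a.indices, b.indices).size:
        raise ValueError("atom sets overlap")
    if heavy_only:
        a = a.intersect_mask(a.structure.heavy_mask)
        b = b.intersect_mask(b.structure.heavy_mask)
        if len(a) == 0 or len(b) == 0:
            raise ValueError("no heavy atoms left in one of the sets")
    return float(cdist(a.coords, b.coords).min())


# ---------------------------------------------------------------------------
# Hydrogen bonds and salt bridges
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    donor: Atom
    acceptor: Atom
    distance: float
    angle: float  # antecedent-donor-acceptor, degrees (max over antecedents)

    def __str__(self) -> str:
        d, a = self.donor, self.acceptor
        return (
            f"{d.chain}:{d.resname}{d.resnum}:{d.name} -> "
            f"{a.chain}:{a.resname}{a.resnum}:{a.name} "
            f"({self.distance:.2f} A, {self.angle:.0f} deg)"
        )


@dataclass(frozen=True)
class SaltBridge:
    cation: tuple[ResidueKey, str]  # residue key, resname
    anion: tuple[ResidueKey, str]
    cation_atom: Atom
    anion_atom: Atom
    distance: float

    def __str__(self) -> str:
        (ck, crn), (ak, arn) = self.cation, self.anion
        return (
            f"{ck[0]}:{crn}{ck[1]} <-> {ak[0]}:{arn}{ak[1]} "
            f"({self.distance:.2f} A)"
        )


def _polar_indices(s: Structure, atom_set: AtomSet) -> np.ndarray:
    sub = atom_set.intersect_mask(
        np.isin(s.array.element, ["N", "O"]) & s.heavy_mask
    )
    return sub.indices


def _antecedents(s: Structure, idx: int, tree: cKDTree) -> list[int]:
    """Heavy atoms covalently bonded (distance-based) to atom ``idx``."""
    near = tree.query_ball_point(s.coords[idx], COVALENT_CUTOFF)
    return [j for j in near if j != idx and s.heavy_mask[j]]


def _angle_deg(p_a: np.ndarray, p_b: np.ndarray, p_c: np.ndarray) -> float:
    v1, v2 = p_a - p_b, p_c - p_b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    complex: Structure,
    group_a: AtomSet,
    group_b: AtomSet,
    dmax: float = HBOND_DMAX,
    angle_min: float = HBOND_ANGLE_MIN,
) -> list[HBond]:
    """Geometric heavy-atom hydrogen bonds between two atom groups.

    Every N/O atom with a covalently bonded heavy antecedent is a candidate
    donor; every N/O atom is a candidate acceptor.  A bond is reported when
    the donor--acceptor distance is <= ``dmax`` and the best
    antecedent--donor--acceptor angle is >= ``angle_min``.  Both directions
    are examined; the returned list is sorted by distance.
    """
    tree = cKDTree(complex.coords)
    polar_a = _polar_indices(complex, group_a)
    polar_b = _polar_indices(complex, group_b)
    bonds: list[HBond] = []
    for donors, acceptors in ((polar_a, polar_b), (polar_b, polar_a)):
        if donors.size == 0 or acceptors.size == 0:
            continue
        acc_tree = cKDTree(complex.coords[acceptors])
        for d in donors:
            ants = _antecedents(complex, int(d), tree)
            if not ants:
                continue
            for k in acc_tree.query_ball_point(complex.coords[d], dmax):
                a = int(acceptors[k])
                if a == d:
                    continue
                dist = float(np.linalg.norm(complex.coords[d] - complex.coords[a]))
                best = max(
                    _angle_deg(complex.coords[t], complex.coords[d], complex.coords[a])
                    for t in ants
                )
                if best >= angle_min:
                    bonds.append(
                        HBond(complex.atom(int(d)), complex.atom(a), dist, best)
                    )
    bonds.sort(key=lambda h: h.distance)
    return bonds


def _charged_groups(
    s: Structure, atom_set: AtomSet, table: dict[str, tuple[str, ...]], extra: tuple[str, ...] = ()
) -> dict[tuple[ResidueKey, str], list[int]]:
    groups: dict[tuple[ResidueKey, str], list[int]] = {}
    for i in atom_set.indices:
        atom = s.atom(int(i))
        names = table.get(atom.resname, ())
        if atom.name in names or atom.name in extra:
            groups.setdefault((atom.residue_key(), atom.resname), []).append(int(i))
    return groups


def detect_salt_bridges(
    complex: Structure,
    group_a: AtomSet,
    group_b: AtomSet,
    dmax: float = SALT_BRIDGE_DMAX,
) -> list[SaltBridge]:
    """Salt bridges between two atom groups (cation-N to anion-O <= ``dmax``).

    Cation groups: Arg guanidinium N, Lys NZ, His imidazole N.  Anion
    groups: Asp/Glu carboxylate O and terminal OXT.  One bridge is reported
    per residue pair, at the minimum N--O distance.
    """
    bridges: list[SaltBridge] = []
    for cat_set, an_set in ((group_a, group_b), (group_b, group_a)):
        cations = _charged_groups(complex, cat_set, CATION_ATOMS)
        anions = _charged_groups(complex, an_set, ANION_ATOMS, TERMINAL_CARBOXYLATE)
        for (ckey, crn), cidx in cations.items():
            for (akey, arn), aidx in anions.items():
                d = cdist(complex.coords[cidx], complex.coords[aidx])
                pos = np.unravel_index(np.argmin(d), d.shape)
                if d[pos] <= dmax:
                    bridges.append(
                        SaltBridge(
                            cation=((ckey), crn),
                            anion=((akey), arn),
                            cation_atom=complex.atom(cidx[pos[0]]),
                            anion_atom=complex.atom(aidx[pos[1]]),
                            distance=float(d[pos]),
                        )
                    )
    # Deduplicate residue pairs found from both directions.
    seen: set[tuple[ResidueKey, ResidueKey]] = set()
    unique = []
    for b in sorted(bridges, key=lambda b: b.distance):
        key = (b.cation[0], b.anion[0])
        if key not in seen:
            seen.add(key)
            unique.append(b)
    return unique


# ---------------------------------------------------------------------------
# Shrake--Rupley SASA
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    """Per-atom/per-residue solvent-accessible surface area in Angstrom^2."""

    per_atom: pd.Series  # indexed by atom index into the structure
    per_residue: pd.Series  # indexed by (chain, resnum, icode)
    total: float
    probe: float
    n_points: int

    def residue_area(self, chain: str, resnum: int, icode: str = "") -> float:
        return float(self.per_residue.get((chain, resnum, icode), 0.0))


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = np.pi * (1.0 + 5.0**0.5) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(theta), r * np.sin(theta), z))


def _radii_for(structure: Structure, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(len(structure))
    missing = []
    for i, el in enumerate(structure.array.element):
        r = radii.get(str(el).upper())
        if r is None:
            atom = structure.atom(i)
            missing.append(f"{atom.chain}:{atom.resname}{atom.resnum}:{atom.name} ({el!r})")
        else:
            out[i] = r
    if missing:
        raise UnknownElementError(
            "no van der Waals radius for atoms: " + ", ".join(missing)
        )
    return out


def shrake_rupley_sasa(
    structure: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SPHERE_POINTS,
    subset: AtomSet | None = None,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake--Rupley SASA by golden-spiral sphere-point counting.

    The area of each atom in ``subset`` (default: all atoms) is computed
    against *all* atoms of the structure, so a subset result reflects
    occlusion by the full structure.  Deterministic for fixed ``n_points``.
    """
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    radii = radii if radii is not None else VDW_RADII
    rads = _radii_for(structure, radii)
    extended = rads + probe
    coords = structure.coords.astype(float)
    targets = subset.indices if subset is not None else np.arange(len(structure))

    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    rmax = float(extended.max())
    per_atom = np.zeros(len(structure))
    for i in targets:
        ri = extended[i]
        pts = coords[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        if neighbors:
            nb = np.asarray(neighbors, dtype=int)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (extended[nb] ** 2)[None, :]).any(axis=1)
            exposed = np.count_nonzero(~buried)
        else:
            exposed = n_points
        per_atom[i] = 4.0 * np.pi * ri * ri * exposed / n_points

    per_atom_s = pd.Series(per_atom[targets], index=pd.Index(targets, name="atom"))
    a = structure.array
    keys = pd.MultiIndex.from_tuples(
        [(str(a.chain_id[i]), int(a.res_id[i]), str(a.ins_code[i])) for i in targets],
        names=["chain", "resnum", "icode"],
    )
    per_res = pd.Series(per_atom_s.to_numpy(), index=keys).groupby(
        level=["chain", "resnum", "icode"]
    ).sum()
    return SasaResult(
        per_atom=per_atom_s,
        per_residue=per_res,
        total=float(per_atom_s.sum()),
        probe=probe,
        n_points=n_points,
    )


# ---------------------------------------------------------------------------
# Buried interface
# ---------------------------------------------------------------------------

@dataclass
class BuriedInterfaceResult:
    """SASA lost on complex formation, as the half-sum convention plus per side."""

    buried: float  # 0.5 * (SASA_receptor + SASA_ligand - SASA_complex)
    dsasa_receptor: float
    dsasa_ligand: float
    sasa_receptor: float
    sasa_ligand: float
    sasa_complex: float


def buried_interface(
    complex: Structure,
    ligand: AtomSet,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_SPHERE_POINTS,
    include_waters: bool = False,
) -> BuriedInterfaceResult:
    """Buried interface area between the ligand selection and the receptor.

    Reported as the half-sum convention
    ``0.5 * [SASA(receptor) + SASA(ligand) - SASA(complex)]`` with per-side
    delta-SASA also emitted.  Waters are excluded from the receptor by
    default; hydrogens, if present, participate with their table radius.
    """
    if len(ligand) == 0:
        raise ValueError("ligand selection is empty")
    rec_mask = np.ones(len(complex), dtype=bool)
    rec_mask[ligand.indices] = False
    if not include_waters:
        rec_mask &= ~complex.water_mask
    rec_idx = np.flatnonzero(rec_mask)
    if rec_idx.size == 0:
        raise NoReceptorError("ligand selection covers the whole structure")

    receptor_alone = complex.subset(rec_idx)
    ligand_alone = complex.subset(ligand.indices)
    both_idx = np.concatenate([rec_idx, ligand.indices])
    pair = complex.subset(np.sort(both_idx))

    s_rec = shrake_rupley_sasa(receptor_alone, probe, n_points)
    s_lig = shrake_rupley_sasa(ligand_alone, probe, n_points)
    s_cpx = shrake_rupley_sasa(pair, probe, n_points)

    # Split the complex SASA between the two sides.
    in_ligand = np.isin(np.sort(both_idx), ligand.indices)
    cpx_atoms = s_cpx.per_atom.to_numpy()
    s_cpx_lig = float(cpx_atoms[in_ligand].sum())
    s_cpx_rec = float(cpx_atoms[~in_ligand].sum())

    d_rec = s_rec.total - s_cpx_rec
    d_lig = s_lig.total - s_cpx_lig
    return BuriedInterfaceResult(
        buried=0.5 * (s_rec.total + s_lig.total - s_cpx.total),
        dsasa_receptor=d_rec,
        dsasa_ligand=d_lig,
        sasa_receptor=s_rec.total,
        sasa_ligand=s_lig.total,
        sasa_complex=s_cpx.total,
    )


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_pairs: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rotation+translation mapping point set ``p`` onto ``q``.

    Returns (rotation, translation, rmsd); the reflection case is resolved
    to a proper rotation (det = +1).
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = qc - pc @ rot.T
    diff = (p @ rot.T + trans) - q
    rmsd = float(np.sqrt((diff**2).sum() / len(p)))
    return rot, trans, rmsd


def superpose_calpha(
    a: Structure, b: Structure, pairing=None
) -> SuperpositionResult:
    """Kabsch superposition of paired C-alpha atoms of two structures.

    ``pairing`` maps residue keys of ``a`` to residue keys of ``b``
    (see :func:`compare_conservation` for accepted forms); when omitted,
    residues sharing (chain, resnum, icode) are paired.  Requires at least
    three pairs.
    """
    def calpha_map(s: Structure) -> dict[ResidueKey, int]:
        arr = s.array
        out = {}
        for i in np.flatnonzero(arr.atom_name == "CA"):
            if str(arr.element[i]) == "C":
                out[(str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.ins_code[i]))] = int(i)
        return out

    ca_a, ca_b = calpha_map(a), calpha_map(b)
    if pairing is None:
        keys = [k for k in ca_a if k in ca_b]
        pairs = [(ca_a[k], ca_b[k]) for k in keys]
    else:
        pmap = _normalize_pairing(pairing)
        pairs = [
            (ca_a[ka], ca_b[kb])
            for ka, kb in pmap.items()
            if ka in ca_a and kb in ca_b
        ]
    if len(pairs) < 3:
        raise UnderdeterminedError(
            f"only {len(pairs)} paired C-alpha atoms; need at least 3"
        )
    p = a.coords[[i for i, _ in pairs]]
    q = b.coords[[j for _, j in pairs]]
    rot, trans, rmsd = kabsch(p, q)
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, n_pairs=len(pairs))
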