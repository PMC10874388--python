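"""Side-chain chi angles, rotamer-state assignment and state-correlation networks.

Chi1/chi2 dihedrals are computed from structures or columnar time series,
assigned to named rotamer states (Peak1 near -1.5 rad, Peak2 near +3 rad by
default) under circular distance, and the pooled discrete-state series of
many residues are summarised as a pairwise association network (Cramer's V
by default, normalised mutual information as an alternative).

Identity-coded residues carry an amino-acid-type state instead of an angle
(0/1, constant within a trajectory); they pass through state assignment
unchanged so that a mutation site can enter the correlation network on the
same footing as a rotamer state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats.contingency import association

from .errors import CollinearError, MissingAtomError, NoChiError
from .structio import Structure

TWO_PI = 2.0 * math.pi

#: Default rotamer-state peak centers in radians: Peak1 and Peak2.
DEFAULT_PEAKS = (-1.5, 3.0)

# chi atom quadruples: chi1 = N-CA-CB-XG, chi2 = CA-CB-XG-XD.
CHI_ATOMS: dict[str, dict[int, tuple[str, str, str, str]]] = {
    "ARG": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "ASN": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "OD1")},
    "ASP": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "OD1")},
    "CYS": {1: ("N", "CA", "CB", "SG")},
    "GLN": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "GLU": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "HIS": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "ND1")},
    "ILE": {1: ("N", "CA", "CB", "CG1"), 2: ("CA", "CB", "CG1", "CD1")},
    "LEU": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "LYS": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "MET": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "SD")},
    "PHE": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "PRO": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "SER": {1: ("N", "CA", "CB", "OG")},
    "THR": {1: ("N", "CA", "CB", "OG1")},
    "TRP": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "TYR": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "VAL": {1: ("N", "CA", "CB", "CG1")},
}

#: Residues whose chi2 runs over a chemically symmetric carboxylate; folded
#: to (-pi/2, pi/2] because OD1/OD2 are interchangeable.
SYMMETRIC_CHI2 = frozenset({"ASP"})


def wrap_angle(x):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    w = np.mod(-x + math.pi, TWO_PI)
    out = -(w - math.pi)
    return out if out.ndim else float(out)


def circular_distance(a, b):
    """Shortest angular distance |a - b| on the circle, in [0, pi]."""
    return np.abs(wrap_angle(np.asarray(a, float) - np.asarray(b, float)))


def fold_symmetric(x):
    """Fold an angle with two-fold chemical symmetry to (-pi/2, pi/2]."""
    x = np.asarray(x, dtype=float)
    w = np.mod(-x + math.pi / 2, math.pi)
    out = -(w - math.pi / 2)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Dihedral computation
# ---------------------------------------------------------------------------

def compute_dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points by the atan2 convention, in (-pi, pi].

    The convention is right-handed with the planar *anti* (trans)
    arrangement at pi and *syn* (cis) at 0.  Raises
    :class:`CollinearError` when three consecutive points are collinear.
    Accepts arrays with a trailing axis of length 3 for batch evaluation.
    """
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.any(np.linalg.norm(n1, axis=-1) < 1e-9) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-9
    ):
        raise CollinearError("three consecutive points are collinear")
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = (n1 * n2).sum(axis=-1)
    y = (np.cross(n1, n2) * b1u).sum(axis=-1)
    ang = np.arctan2(y, x)
    return wrap_angle(ang)


def chi_angles(
    structure: Structure,
    chain: str,
    resnum: int,
    chi_index: int = 1,
    icode: str = "",
) -> float:
    """Chi angle of one residue of a structure, in (-pi, pi].

    Gly/Ala (no chi) raise :class:`NoChiError`; missing side-chain atoms
    raise :class:`MissingAtomError` listing the absent names.  Asp chi2 is
    folded to (-pi/2, pi/2] for the OD1/OD2 carboxylate symmetry.
    """
    idx = structure.residue_indices(chain, resnum, icode)
    if idx.size == 0:
        raise KeyError(f"no residue {chain}:{resnum}{icode}")
    resname = str(structure.array.res_name[idx[0]])
    table = CHI_ATOMS.get(resname)
    if table is None or chi_index not in table:
        raise NoChiError(f"{resname} {chain}:{resnum} has no chi{chi_index}")
    quad = table[chi_index]
    positions = []
    missing = []
    for name in quad:
        i = structure.find_atom(chain, resnum, name, icode)
        if i is None:
            missing.append(name)
        else:
            positions.append(structure.coords[i])
    if missing:
        raise MissingAtomError(
            f"{resname} {chain}:{resnum} chi{chi_index} missing atoms: "
            + ", ".join(missing)
        )
    ang = compute_dihedral(*positions)
    if chi_index == 2 and resname in SYMMETRIC_CHI2:
        ang = fold_symmetric(ang)
    return float(ang)


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclass
class DihedralSeries:
    """Frames x (residue, chi) angle matrix in radians on (-pi, pi].

    ``data`` holds columns ``frame``, ``traj`` and one column per tracked
    dihedral (label format free, conventionally ``"F104:chi1"``).
    Identity-coded columns (amino-acid type 0/1 instead of an angle) are
    listed in ``identity_columns``.  Missing values are NaN.
    """

    data: pd.DataFrame
    identity_columns: frozenset[str] = frozenset()

    def __post_init__(self):
        for col in ("frame", "traj"):
            if col not in self.data.columns:
                raise ValueError(f"DihedralSeries requires a {col!r} column")
        self.identity_columns = frozenset(self.identity_columns)
        for col in self.labels:
            if col in self.identity_columns:
                continue
            vals = self.data[col].to_numpy(float)
            ok = np.isnan(vals) | ((vals > -math.pi - 1e-12) & (vals <= math.pi + 1e-12))
            if not ok.all():
                raise ValueError(f"column {col!r} has angles outside (-pi, pi]")

    @property
    def labels(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("frame", "traj")]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def angles(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy(float)

    def to_tsv(self, path: str | Path) -> None:
        header = "# identity_columns=" + ",".join(sorted(self.identity_columns))
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DihedralSeries":
        with open(path) as fh:
            first = fh.readline()
            identity: frozenset[str] = frozenset()
            if first.startswith("#"):
                tail = first.split("=", 1)[1].strip() if "=" in first else ""
                identity = frozenset(t for t in tail.split(",") if t)
            else:
                fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
        return cls(df, identity)

    @classmethod
    def concat(cls, parts: list["DihedralSeries"]) -> "DihedralSeries":
        ident = frozenset().union(*(p.identity_columns for p in parts))
        return cls(pd.concat([p.data for p in parts], ignore_index=True), ident)


@dataclass
class RotamerStateSeries:
    """Per-residue discrete state per frame (int codes; -1 = missing).

    ``centers`` maps each angle column to its tuple of peak centers
    (state code = index into the tuple); identity-coded columns map to
    ``None`` and keep their 0/1 amino-acid-type code.
    """

    data: pd.DataFrame
    centers: dict[str, tuple[float, ...] | None]

    @property
    def labels(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("frame", "traj")]

    def states(self, label: str) -> np.ndarray:
        return self.data[label].to_numpy(int)


def assign_states(
    series: DihedralSeries,
    peaks: tuple[float, ...] = DEFAULT_PEAKS,
    per_residue_peaks: dict[str, tuple[float, ...]] | None = None,
) -> RotamerStateSeries:
    """Assign each angle to the nearest peak center under circular distance.

    Circularly equidistant angles go to the lower-index center (deterministic
    tie-break).  Identity-coded columns pass through their 0/1 code; NaN
    frames become the missing marker -1.  Requires >= 2 distinct centers.
    """
    per_residue_peaks = per_residue_peaks or {}
    out = {"frame": series.data["frame"], "traj": series.data["traj"]}
    centers_map: dict[str, tuple[float, ...] | None] = {}
    for label in series.labels:
        if label in series.identity_columns:
            vals = series.data[label].to_numpy(float)
            states = np.where(np.isnan(vals), -1, vals).astype(int)
            centers_map[label] = None
        else:
            centers = tuple(per_residue_peaks.get(label, peaks))
            if len(set(np.round(wrap_angle(np.asarray(centers)), 12))) < 2:
                raise ValueError(f"need >= 2 distinct peak centers for {label!r}")
            vals = series.angles(label)
            dists = np.stack(
                [circular_distance(vals, c) for c in centers], axis=1
            )
            # np.argmin takes the first (lowest-index) minimum: the tie rule.
            states = np.argmin(np.round(dists, 12), axis=1)
            states = np.where(np.isnan(vals), -1, states)
            centers_map[label] = centers
        out[label] = states
    return RotamerStateSeries(pd.DataFrame(out), centers_map)


def state_distribution(states: RotamerStateSeries, label: str) -> dict[int, float]:
    """Relative frequencies of the observed states of one residue (sum to 1)."""
    vals = states.states(label)
    vals = vals[vals >= 0]
    if vals.size == 0:
        raise ValueError(f"no observed frames for {label!r}")
    uniq, counts = np.unique(vals, return_counts=True)
    freqs = counts / counts.sum()
    return {int(u): float(f) for u, f in zip(uniq, freqs)}


# ---------------------------------------------------------------------------
# Wrapped kernel density estimate (diagnostic, for distribution plots)
# ---------------------------------------------------------------------------

def vonmises_kde(
    angles: np.ndarray,
    kappa: float | None = None,
    grid_size: int = 360,
) -> tuple[np.ndarray, np.ndarray]:
    """Von Mises kernel density of circular data on a (-pi, pi] grid.

    When ``kappa`` is None the concentration is chosen by maximising the
    leave-one-out log-likelihood over a coarse grid -- adequate for the
    diagnostic plots this feeds; distributions themselves are assessed via
    discrete state frequencies, not the KDE.
    """
    angles = np.asarray(angles, float)
    angles = angles[~np.isnan(angles)]
    if angles.size == 0:
        raise ValueError("no angles to estimate")
    if kappa is None:
        candidates = np.array([2.0, 5.0, 10.0, 20.0, 50.0, 100.0])
        best, kappa = -np.inf, candidates[0]
        diff = angles[:, None] - angles[None, :]
        for k in candidates:
            kern = np.exp(k * np.cos(diff)) / (TWO_PI * np.i0(k))
            np.fill_diagonal(kern, 0.0)
            loo = kern.sum(axis=1) / max(angles.size - 1, 1)
            ll = np.log(np.maximum(loo, 1e-300)).sum()
            if ll > best:
                best, kappa = ll, float(k)
    grid = np.linspace(-math.pi, math.pi, grid_size, endpoint=False) + math.pi / grid_size
    dens = np.exp(kappa * np.cos(grid[:, None] - angles[None, :])).sum(axis=1)
    dens /= angles.size * TWO_PI * np.i0(kappa)
    return grid, dens


def plot_angle_distribution(
    series: DihedralSeries,
    label: str,
    peaks: tuple[float, ...] = DEFAULT_PEAKS,
    ax=None,
):
    """Wrapped-KDE plot of one residue's chi-angle distribution (diagnostic).

    Marks the rotamer peak centers; returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid, dens = vonmises_kde(series.angles(label))
    ax.plot(grid, dens)
    for c in peaks:
        ax.axvline(wrap_angle(c), ls="--", lw=0.8, color="grey")
    ax.set_xlabel("chi angle (rad)")
    ax.set_ylabel("density")
    ax.set_title(label)
    return ax


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------

def _nmi(table: np.ndarray) -> float:
    """Normalised mutual information (arithmetic-mean normalisation)."""
    n = table.sum()
    if n == 0:
        return 0.0
    pxy = table / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = (pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum()
    hx = -(px[px > 0] * np.log(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log(py[py > 0])).sum()
    denom = 0.5 * (hx + hy)
    return float(mi / denom) if denom > 0 else 0.0


def _cramers_v(table: np.ndarray) -> float:
    if min(table.shape) < 2:
        return 0.0
    return float(association(table, method="cramer", correction=False))


@dataclass
class StateCorrelationNetwork:
    """Pairwise association of per-residue discrete-state series.

    ``matrix`` is symmetric with unit diagonal, values in [0, 1].
    ``flagged`` lists residues whose pooled state series was constant
    (association with them defined as 0).
    """

    residues: list[str]
    matrix: pd.DataFrame
    edges: list[tuple[str, str, float]]
    method: str
    threshold: float
    flagged: list[str] = field(default_factory=list)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.residues)
        g.add_weighted_edges_from(self.edges)
        return g

    def to_edge_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue_a\tresidue_b\tassociation\n")
            for a, b, w in self.edges:
                fh.write(f"{a}\t{b}\t{w:.4f}\n")

    def to_matrix_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t", float_format="%.4f")


def correlation_network(
    states: RotamerStateSeries,
    method: str = "cramers_v",
    threshold: float = 0.3,
) -> StateCorrelationNetwork:
    """Pairwise association matrix of residue state series (pooled frames).

    Frames from multiple trajectories are pooled; an identity-coded residue
    (e.g. a mutation site whose 0/1 state varies only across trajectories)
    enters exactly like a rotamer state.  ``method`` is ``"cramers_v"``
    (default) or ``"nmi"``.  Residues with a constant pooled series are
    flagged and get association 0.  Edges with association strictly above
    ``threshold`` are listed, strongest first.
    """
    labels = states.labels
    if len(labels) < 2:
        raise ValueError("need at least two residues")
    measure = {"cramers_v": _cramers_v, "nmi": _nmi}.get(method)
    if measure is None:
        raise ValueError(f"unknown association method {method!r}")
    if len(states.data) < 10:
        raise ValueError("need at least 10 frames")

    flagged = [
        l for l in labels if np.unique(states.states(l)[states.states(l) >= 0]).size < 2
    ]
    mat = np.eye(len(labels))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a = states.states(labels[i])
            b = states.states(labels[j])
            ok = (a >= 0) & (b >= 0)
            a, b = a[ok], b[ok]
            if labels[i] in flagged or labels[j] in flagged or a.size == 0:
                v = 0.0
            else:
                table = pd.crosstab(a, b).to_numpy()
                v = measure(table)
            mat[i, j] = mat[j, i] = float(np.clip(v, 0.0, 1.0))
    matrix = pd.DataFrame(mat, index=labels, columns=labels)
    edges = [
        (labels[i], labels[j], float(mat[i, j]))
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if mat[i, j] > threshold
    ]
    edges.sort(key=lambda e: -e[2])
    return StateCorrelationNetwork(
        residues=labels,
        matrix=matrix,
        edges=edges,
        method=method,
        threshold=threshold,
        flagged=flagged,
    )
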