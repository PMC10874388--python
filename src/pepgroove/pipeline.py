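"""End-to-end orchestration: configuration, stage execution, reporting.

A :class:`RunConfig` collects every tunable of every stage with defaults
equal to the module defaults; :func:`run_pipeline` executes the requested
stages in dependency order, serialises the configuration into the output
directory, logs each operation with its parameters, and writes tab-separated
tables plus a JSON report.  All randomness flows from the single master
seed, so a rerun with an identical configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import fpfit, geometry, hrex, rotamers, structio

STAGE_ORDER = ("interface", "superpose", "dihedrals", "correlate", "hrex", "fp")

# Fixed numeric formatting: areas to 1 decimal, distances/RMSD to 3 decimals.
FMT_AREA = "%.1f"
FMT_DIST = "%.3f"


@dataclass
class RunConfig:
    """All pipeline parameters; defaults mirror the module defaults."""

    outdir: str = "pepgroove_run"
    seed: int = 0
    stages: tuple[str, ...] = ()
    interface: dict = field(default_factory=dict)
    superpose: dict = field(default_factory=dict)
    dihedrals: dict = field(default_factory=dict)
    correlate: dict = field(default_factory=dict)
    hrex: dict = field(default_factory=dict)
    fp: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        defaults = {
            "interface": {
                "complex": None, "ligand_chain": None, "cutoff": 5.0,
                "probe": geometry.DEFAULT_PROBE,
                "n_points": geometry.DEFAULT_SPHERE_POINTS,
                "hbond_dmax": geometry.HBOND_DMAX,
                "hbond_angle_min": geometry.HBOND_ANGLE_MIN,
                "salt_dmax": geometry.SALT_BRIDGE_DMAX,
                "include_waters": False,
            },
            "superpose": {"a": None, "b": None, "pairing": None},
            "dihedrals": {"series": None, "peaks": list(rotamers.DEFAULT_PEAKS)},
            "correlate": {
                "series": None, "method": "cramers_v", "threshold": 0.3,
                "peaks": list(rotamers.DEFAULT_PEAKS),
            },
            "hrex": {
                "replicas": 8, "t0": 300.0, "tmax": 430.0,
                "sweeps": 2000, "moves_per_sweep": 10, "exchange_interval": 10,
                "width": hrex.DEFAULT_PROPOSAL_WIDTH, "system": None,
            },
            "fp": {"binding": None, "competition": None,
                   "l50": None, "p0": None, "kd": None, "n_boot": 200},
        }
        for stage, base in defaults.items():
            merged = dict(base)
            merged.update(getattr(self, stage))
            setattr(self, stage, merged)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class AnalysisReport:
    """Per-stage outputs of one pipeline run; every number is traceable to
    one logged operation call."""

    config: RunConfig
    sections: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sections, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def system_from_dict(d: dict) -> hrex.ToyTorsionSystem:
    """Build a toy torsion system from a plain config mapping."""
    terms = [
        hrex.TorsionTerm(
            coord=int(t["coord"]), k=float(t["k"]),
            multiplicity=int(t.get("m", 1)), phase=float(t.get("phase", 0.0)),
            scalable=bool(t.get("scalable", False)),
        )
        for t in d.get("terms", [])
    ]
    couplings = [
        hrex.Coupling(i=int(c["i"]), j=int(c["j"]), jconst=float(c["jconst"]))
        for c in d.get("couplings", [])
    ]
    return hrex.ToyTorsionSystem(
        n_coords=int(d["n_coords"]), terms=terms, couplings=couplings,
        t0=float(d.get("t0", 300.0)),
    )


def _setup_logging(outdir: Path) -> logging.Logger:
    logger = logging.getLogger(f"pepgroove.run.{outdir}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(fh)
    logger.addHandler(logging.StreamHandler())
    logger.propagate = False
    return logger


def _preflight(config: RunConfig) -> None:
    """Fail on missing inputs before any computation starts."""
    needed = []
    if "interface" in config.stages:
        needed.append(config.interface["complex"])
    if "superpose" in config.stages:
        needed += [config.superpose["a"], config.superpose["b"]]
        if config.superpose["pairing"]:
            needed.append(config.superpose["pairing"])
    for stage in ("dihedrals", "correlate"):
        if stage in config.stages:
            needed.append(getattr(config, stage)["series"])
    if "fp" in config.stages:
        if config.fp["binding"]:
            needed.append(config.fp["binding"])
        if config.fp["competition"]:
            needed.append(config.fp["competition"])
    for p in needed:
        if p is None:
            raise FileNotFoundError("a required input path is unset in the config")
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the configured stages and write tables, log and report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _preflight(config)
    log = _setup_logging(outdir)
    config.to_yaml(outdir / "config.yaml")
    report = AnalysisReport(config=config)
    log.info("seed=%d stages=%s", config.seed, ",".join(config.stages) or "(none)")

    for stage in STAGE_ORDER:
        if stage in config.stages:
            _RUNNERS[stage](config, outdir, report, log)

    report.to_json(outdir / "report.json")
    return report


def _run_interface(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    p = config.interface
    s = structio.read_structure(p["complex"])
    ligand = structio.select(s, f"chain {p['ligand_chain']}")
    log.info("interface: complex=%s ligand_chain=%s cutoff=%.2f probe=%.2f n_points=%d",
             p["complex"], p["ligand_chain"], p["cutoff"], p["probe"], p["n_points"])
    contacts = geometry.contact_residues(
        s, ligand, cutoff=p["cutoff"], include_waters=p["include_waters"]
    )
    df = contacts.to_frame()
    if not df.empty:
        df["min_distance"] = df["min_distance"].map(lambda v: FMT_DIST % v)
    df.to_csv(outdir / "contacts.tsv", sep="\t", index=False)

    receptor = ligand.complement().intersect_mask(~s.water_mask)
    hbonds = geometry.detect_hbonds(
        s, ligand, receptor, dmax=p["hbond_dmax"], angle_min=p["hbond_angle_min"]
    )
    with open(outdir / "hbonds.tsv", "w") as fh:
        fh.write("donor\tacceptor\tdistance\tangle\n")
        for h in hbonds:
            d, a = h.donor, h.acceptor
            fh.write(
                f"{d.chain}:{d.resname}{d.resnum}:{d.name}\t"
                f"{a.chain}:{a.resname}{a.resnum}:{a.name}\t"
                f"{h.distance:.3f}\t{h.angle:.1f}\n"
            )
    bridges = geometry.detect_salt_bridges(s, ligand, receptor, dmax=p["salt_dmax"])
    with open(outdir / "salt_bridges.tsv", "w") as fh:
        fh.write("cation\tanion\tdistance\n")
        for b in bridges:
            fh.write(
                f"{b.cation[0][0]}:{b.cation[1]}{b.cation[0][1]}\t"
                f"{b.anion[0][0]}:{b.anion[1]}{b.anion[0][1]}\t{b.distance:.3f}\n"
            )
    buried = geometry.buried_interface(
        s, ligand, probe=p["probe"], n_points=p["n_points"],
        include_waters=p["include_waters"],
    )
    report.sections["interface"] = {
        "n_contacts": len(contacts.residues),
        "contact_residues": [
            f"{r.chain}:{r.resname}{r.resnum}" for r in contacts.residues
        ],
        "n_hbonds": len(hbonds),
        "n_salt_bridges": len(bridges),
        "buried_interface": round(buried.buried, 1),
        "dsasa_receptor": round(buried.dsasa_receptor, 1),
        "dsasa_ligand": round(buried.dsasa_ligand, 1),
    }
    log.info("interface: %d contacts, %d hbonds, %d salt bridges, buried=%s A^2",
             len(contacts.residues), len(hbonds), len(bridges),
             FMT_AREA % buried.buried)


def _run_superpose(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    p = config.superpose
    a = structio.read_structure(p["a"])
    b = structio.read_structure(p["b"])
    pairing = geometry.load_pairing(p["pairing"]) if p["pairing"] else None
    res = geometry.superpose_calpha(a, b, pairing)
    log.info("superpose: a=%s b=%s pairs=%d rmsd=%s",
             p["a"], p["b"], res.n_pairs, FMT_DIST % res.rmsd)
    report.sections["superpose"] = {
        "rmsd": round(res.rmsd, 3), "n_pairs": res.n_pairs,
    }


def _load_states(cfg: dict) -> rotamers.RotamerStateSeries:
    series = rotamers.DihedralSeries.from_tsv(cfg["series"])
    return rotamers.assign_states(series, peaks=tuple(cfg["peaks"]))


def _run_dihedrals(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    states = _load_states(config.dihedrals)
    dists = {}
    for label in states.labels:
        dist = rotamers.state_distribution(states, label)
        dists[label] = {str(k): round(v, 4) for k, v in dist.items()}
    with open(outdir / "state_distributions.tsv", "w") as fh:
        fh.write("residue\tstate\tfrequency\n")
        for label, d in dists.items():
            for k, v in sorted(d.items()):
                fh.write(f"{label}\t{k}\t{v:.4f}\n")
    report.sections["dihedrals"] = dists
    log.info("dihedrals: %d residues, peaks=%s",
             len(states.labels), config.dihedrals["peaks"])


def _run_correlate(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    p = config.correlate
    states = _load_states(p)
    net = rotamers.correlation_network(
        states, method=p["method"], threshold=p["threshold"]
    )
    net.to_edge_tsv(outdir / "network_edges.tsv")
    net.to_matrix_tsv(outdir / "network_matrix.tsv")
    report.sections["correlate"] = {
        "method": net.method,
        "threshold": net.threshold,
        "edges": [[a, b, round(w, 4)] for a, b, w in net.edges],
        "flagged_constant": net.flagged,
    }
    log.info("correlate: method=%s threshold=%.2f edges=%d",
             net.method, net.threshold, len(net.edges))


def _run_hrex(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    p = config.hrex
    if p["system"] is None:
        raise ValueError("hrex stage requires a system definition")
    system = system_from_dict(p["system"])
    ladder = hrex.build_ladder(int(p["replicas"]), float(p["t0"]), float(p["tmax"]))
    result = hrex.run_hrex(
        system, ladder, int(p["sweeps"]), int(p["moves_per_sweep"]),
        int(p["exchange_interval"]), seed=config.seed, width=float(p["width"]),
    )
    result.series(0).to_tsv(outdir / "hrex_replica1.tsv")
    with open(outdir / "hrex_exchange.tsv", "w") as fh:
        fh.write("pair\tattempts\taccepts\trate\n")
        for k in range(ladder.n - 1):
            rate = result.acceptance_rates[k]
            fh.write(f"{k}-{k+1}\t{result.attempts[k]}\t{result.accepts[k]}\t"
                     f"{0.0 if np.isnan(rate) else rate:.3f}\n")
    report.sections["hrex"] = {
        "scales": [round(s, 4) for s in ladder.scales],
        "acceptance_rates": [
            None if np.isnan(r) else round(float(r), 3)
            for r in result.acceptance_rates
        ],
        "round_trips": result.round_trips,
    }
    log.info("hrex: %d replicas, scales %.3f..%.3f, %d round trips",
             ladder.n, ladder.scales[0], ladder.scales[-1], result.round_trips)


def _run_fp(config: RunConfig, outdir: Path, report: AnalysisReport, log):
    p = config.fp
    section = {}
    if p["binding"]:
        data = fpfit.FPTitration.from_tsv(p["binding"])
        fit = fpfit.fit_binding(data, n_boot=int(p["n_boot"]), seed=config.seed)
        section["binding"] = {
            "kd_nM": round(fit.kd, 4), "a0": round(fit.a0, 4),
            "amax": round(fit.amax, 4),
            "kd_ci_nM": [round(v, 4) for v in fit.kd_ci],
            "unidentifiable": fit.unidentifiable,
        }
        log.info("fp binding: KD=%.4g nM", fit.kd)
    if p["competition"]:
        import pandas as pd

        df = pd.read_csv(p["competition"], sep="\t", comment="#")
        fit = fpfit.fit_competition(
            df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
            n_boot=int(p["n_boot"]), seed=config.seed,
        )
        section["competition"] = {
            "logec50": round(fit.logec50, 4),
            "ec50_nM": round(fit.ec50_nm, 4),
        }
        if all(p[k] is not None for k in ("l50", "p0", "kd")):
            ki = fpfit.ki_from_ec50(
                fit.ec50_nm, float(p["l50"]), float(p["p0"]), float(p["kd"])
            )
            section["ki_nM"] = round(ki.ki, 4)
            log.info("fp competition: EC50=%.4g nM Ki=%.4g nM", fit.ec50_nm, ki.ki)
    report.sections["fp"] = section
    with open(outdir / "fp_fits.tsv", "w") as fh:
        fh.write("quantity\tvalue\n")
        for group, vals in section.items():
            if isinstance(vals, dict):
                for k, v in vals.items():
                    fh.write(f"{group}.{k}\t{v}\n")
            else:
                fh.write(f"{group}\t{vals}\n")


_RUNNERS = {
    "interface": _run_interface,
    "superpose": _run_superpose,
    "dihedrals": _run_dihedrals,
    "correlate": _run_correlate,
    "hrex": _run_hrex,
    "fp": _run_fp,
}
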