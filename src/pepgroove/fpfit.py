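"""Fluorescence-polarization binding and competition fitting.

Direct binding uses the exact quadratic single-site isotherm

    y = A0 + (Amax - A0) * [(x + c + KD) - sqrt((x + c + KD)^2 - 4 x c)] / (2 c)

with x the titrated protein concentration (nM), c the fixed fluorescent
peptide concentration (nM) and KD the dissociation constant -- the
ligand-depletion form required when c is not negligible against KD.

Competition uses the one-site sigmoid

    y = A0 + (Amax - A0) / (1 + 10**(x - logEC50)),     x = log10 molar,

which is the internally consistent form of the printed model (a strict
as-printed mode, with the leading A_max that makes the low-concentration
plateau 2*Amax - A0, is provided for auditability).  The inhibition
constant follows from

    Ki = EC50 / (L50/KD + P0/KD + 1)

where L50 is the labelled-peptide concentration at 50% inhibition and P0
the free-protein concentration at 0% inhibition (both inputs, in nM).

Fitting is trust-region least squares with multi-start initialisation and
seeded residual-resampling bootstrap percentile intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError

LOG_KD_BOUNDS = (-3.0, 6.0)  # log10 nM admissible box for KD / EC50(nM)
DEFAULT_N_BOOT = 1000


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class FPTitration:
    """Direct-binding titration: protein concentrations x (nM), anisotropies y,
    fixed fluorescent-peptide concentration c (nM)."""

    x: np.ndarray
    y: np.ndarray
    c: float

    def __post_init__(self):
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if self.x.shape != self.y.shape or self.x.size < 4:
            raise ValueError("x and y must have equal length >= 4")
        if np.any(self.x < 0):
            raise ValueError("protein concentrations must be >= 0")
        if not self.c > 0:
            raise ValueError("fluorescent peptide concentration c must be > 0")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# units=nM\tc={self.c:g}\n")
            pd.DataFrame({"x_nM": self.x, "y": self.y}).to_csv(
                fh, sep="\t", index=False, float_format="%.6g"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FPTitration":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#") or "c=" not in header:
                raise ValueError("titration file must start with '# units=nM\tc=<value>'")
            c = float(header.split("c=")[1].split()[0])
            df = pd.read_csv(fh, sep="\t")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), c)


# ---------------------------------------------------------------------------
# Model curves
# ---------------------------------------------------------------------------

def binding_isotherm(x, c: float, kd: float, a0: float, amax: float):
    """Quadratic direct-binding isotherm; exact for any c > 0, x >= 0.

    Evaluated in the conjugate form ``bound = 2x / (s + sqrt(s^2 - 4xc))``
    with ``s = x + c + kd``, which avoids the subtractive cancellation of
    the printed radical when ``s^2 >> 4xc``.
    """
    x = np.asarray(x, float)
    if c <= 0:
        raise ValueError("c must be > 0")
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    s = x + c + kd
    disc = np.sqrt(np.maximum(s * s - 4.0 * x * c, 0.0))
    bound = np.where(s + disc > 0, 2.0 * x / (s + disc), 0.0)
    return a0 + (amax - a0) * bound


def competition_curve(x, a0: float, amax: float, logec50: float, strict: bool = False):
    """One-site competition sigmoid over x = log10 molar concentration.

    Default: ``y = A0 + (Amax - A0) / (1 + 10**(x - logEC50))`` with upper
    plateau Amax at low competitor and lower plateau A0 at high competitor.
    ``strict=True`` evaluates the as-printed variant with a leading Amax
    (whose low-x plateau is 2*Amax - A0).
    """
    x = np.asarray(x, float)
    frac = 1.0 / (1.0 + np.power(10.0, x - logec50))
    lead = amax if strict else a0
    return lead + (amax - a0) * frac


def ki_from_ec50(ec50: float, l50: float, p0: float, kd: float) -> "KiResult":
    """Inhibition constant Ki = EC50 / (L50/KD + P0/KD + 1); all in nM."""
    if kd == 0:
        raise ZeroDivisionError("KD must be non-zero")
    if ec50 <= 0 or kd < 0 or l50 < 0 or p0 < 0:
        raise ValueError("EC50, KD must be > 0 and L50, P0 >= 0")
    ki = ec50 / (l50 / kd + p0 / kd + 1.0)
    return KiResult(ki=ki, ec50=ec50, l50=l50, p0=p0, kd=kd)


@dataclass(frozen=True)
class KiResult:
    ki: float
    ec50: float
    l50: float
    p0: float
    kd: float


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------

@dataclass
class BindingFit:
    kd: float
    a0: float
    amax: float
    rss: float
    kd_ci: tuple[float, float]
    a0_ci: tuple[float, float]
    amax_ci: tuple[float, float]
    n_boot: int
    c: float
    n_points: int
    unidentifiable: bool = False
    warnings: list[str] = field(default_factory=list)

    def predict(self, x):
        return binding_isotherm(x, self.c, self.kd, self.a0, self.amax)

    def summary(self) -> str:
        lines = [
            "Direct-binding FP fit (quadratic isotherm)",
            f"  n = {self.n_points} points, c = {self.c:g} nM",
            f"  KD    = {self.kd:10.4g} nM   95% CI [{self.kd_ci[0]:.4g}, {self.kd_ci[1]:.4g}]",
            f"  A0    = {self.a0:10.4g}      95% CI [{self.a0_ci[0]:.4g}, {self.a0_ci[1]:.4g}]",
            f"  Amax  = {self.amax:10.4g}      95% CI [{self.amax_ci[0]:.4g}, {self.amax_ci[1]:.4g}]",
            f"  RSS   = {self.rss:10.4g}   (bootstrap n = {self.n_boot})",
        ]
        if self.unidentifiable:
            lines.append("  WARNING: KD unidentifiable (flat response)")
        lines += [f"  WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


@dataclass
class CompetitionFit:
    logec50: float  # log10 molar
    a0: float
    amax: float
    rss: float
    logec50_ci: tuple[float, float]
    n_boot: int
    n_points: int
    increasing_data: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def ec50_molar(self) -> float:
        return 10.0**self.logec50

    @property
    def ec50_nm(self) -> float:
        return self.ec50_molar * 1e9

    def predict(self, x_log10_molar):
        return competition_curve(x_log10_molar, self.a0, self.amax, self.logec50)

    def summary(self) -> str:
        lines = [
            "Competition FP fit (one-site sigmoid)",
            f"  n = {self.n_points} points",
            f"  logEC50 = {self.logec50:8.4f} (EC50 = {self.ec50_nm:.4g} nM)"
            f"   95% CI [{self.logec50_ci[0]:.4f}, {self.logec50_ci[1]:.4f}]",
            f"  A0 = {self.a0:.4g}, Amax = {self.amax:.4g}, RSS = {self.rss:.4g}",
        ]
        if self.increasing_data:
            lines.append("  WARNING: anisotropy increases with competitor (sign check)")
        lines += [f"  WARNING: {w}" for w in self.warnings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _multistart_least_squares(residual, starts, bounds) -> tuple[np.ndarray, float]:
    best_params, best_cost = None, np.inf
    errors = []
    for p0 in starts:
        try:
            res = least_squares(residual, p0, bounds=bounds, method="trf")
        except Exception as exc:  # pragma: no cover - defensive
            errors.append(str(exc))
            continue
        if res.success and res.cost < best_cost:
            best_cost = res.cost
            best_params = res.x
    if best_params is None:
        raise FitError(
            "no start converged; diagnostics: " + "; ".join(errors[:3] or ["none"])
        )
    return best_params, best_cost


def _percentile_ci(samples: np.ndarray) -> tuple[float, float]:
    return (float(np.percentile(samples, 2.5)), float(np.percentile(samples, 97.5)))


def fit_binding(
    data: FPTitration, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> BindingFit:
    """Least-squares fit of (KD, A0, Amax) with bootstrap percentile CIs.

    Multi-start over a data-driven KD grid (half-response interpolation plus
    log-spaced brackets); residual-resampling bootstrap (x is a designed
    variable, so pairs resampling would distort the design).  Deterministic
    for a fixed ``seed``.  A flat response is flagged as unidentifiable and
    its KD interval is widened to the admissible box.
    """
    x, y, c = data.x, data.y, data.c
    warnings: list[str] = []
    span = y.max() - y.min()
    mid = 0.5 * (y.max() + y.min())
    above = x[y >= mid]
    x_half = float(above.min()) if above.size and y[np.argmax(x)] > y[np.argmin(x)] else float(np.median(x))
    x_half = max(x_half, 1e-3)
    kd_starts = {x_half, x_half / 10, x_half * 10, float(np.sqrt(max(x.min(), 1e-3) * x.max()))}
    starts = [
        np.array([math.log10(k), y.min(), y.max()]) for k in sorted(kd_starts)
    ] + [
        np.array([math.log10(k), y.max(), y.min()]) for k in sorted(kd_starts)
    ]
    if not (np.any(x < x_half) and np.any(x > x_half)):
        warnings.append("design points do not span both sides of the inflection")

    def residual(p):
        return binding_isotherm(x, c, 10.0 ** p[0], p[1], p[2]) - y

    lo = [LOG_KD_BOUNDS[0], -np.inf, -np.inf]
    hi = [LOG_KD_BOUNDS[1], np.inf, np.inf]
    params, cost = _multistart_least_squares(residual, starts, (lo, hi))
    kd, a0, amax = 10.0 ** params[0], params[1], params[2]
    yhat = binding_isotherm(x, c, kd, a0, amax)
    resid = y - yhat
    rss = float((resid**2).sum())

    unidentifiable = abs(amax - a0) < 1e-9 or span < 1e-12
    if n_boot == 0:
        kd_ci = (
            (float(kd),) * 2 if not unidentifiable
            else (10.0 ** LOG_KD_BOUNDS[0], 10.0 ** LOG_KD_BOUNDS[1])
        )
        return BindingFit(
            kd=float(kd), a0=float(a0), amax=float(amax), rss=rss,
            kd_ci=kd_ci, a0_ci=(float(a0),) * 2, amax_ci=(float(amax),) * 2,
            n_boot=0, c=c, n_points=x.size,
            unidentifiable=unidentifiable, warnings=warnings,
        )
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 3))
    for b in range(n_boot):
        y_b = yhat + rng.choice(resid, size=resid.size, replace=True)

        def residual_b(p, y_b=y_b):
            return binding_isotherm(x, c, 10.0 ** p[0], p[1], p[2]) - y_b

        try:
            r = least_squares(residual_b, params, bounds=(lo, hi), method="trf")
            boots[b] = r.x
        except Exception:
            boots[b] = params
    kd_ci = tuple(10.0 ** np.array(_percentile_ci(boots[:, 0])))
    a0_ci = _percentile_ci(boots[:, 1])
    amax_ci = _percentile_ci(boots[:, 2])
    if unidentifiable:
        kd_ci = (10.0 ** LOG_KD_BOUNDS[0], 10.0 ** LOG_KD_BOUNDS[1])
    return BindingFit(
        kd=float(kd), a0=float(a0), amax=float(amax), rss=rss,
        kd_ci=kd_ci, a0_ci=a0_ci, amax_ci=amax_ci,
        n_boot=n_boot, c=c, n_points=x.size,
        unidentifiable=unidentifiable, warnings=warnings,
    )


def fit_competition(
    conc_molar,
    y,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> CompetitionFit:
    """Least-squares fit of (logEC50, A0, Amax) to a competition titration.

    Concentrations are supplied in molar and logged internally.  Warns when
    the design spans fewer than two decades; a monotone-increasing response
    (anisotropy rising with competitor) trips the sign check flag.
    """
    conc = np.asarray(conc_molar, float)
    y = np.asarray(y, float)
    if conc.shape != y.shape or conc.size < 4:
        raise ValueError("conc and y must have equal length >= 4")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")
    x = np.log10(conc)
    warnings = []
    if x.max() - x.min() < 2.0:
        warnings.append("concentration range spans fewer than two decades")
    slope = np.polyfit(x, y, 1)[0]
    increasing = bool(slope > 0)

    def residual(p):
        return competition_curve(x, p[1], p[2], p[0]) - y

    mid = 0.5 * (y.max() + y.min())
    order = np.argsort(x)
    crossing = x[order][np.argmin(np.abs(y[order] - mid))]
    starts = [
        np.array([crossing, y.min(), y.max()]),
        np.array([crossing - 1.0, y.min(), y.max()]),
        np.array([crossing + 1.0, y.min(), y.max()]),
        np.array([float(np.median(x)), y.min(), y.max()]),
    ]
    lo = [x.min() - 3.0, -np.inf, -np.inf]
    hi = [x.max() + 3.0, np.inf, np.inf]
    params, _ = _multistart_least_squares(residual, starts, (lo, hi))
    yhat = competition_curve(x, params[1], params[2], params[0])
    resid = y - yhat
    rss = float((resid**2).sum())

    if n_boot == 0:
        return CompetitionFit(
            logec50=float(params[0]), a0=float(params[1]), amax=float(params[2]),
            rss=rss, logec50_ci=(float(params[0]),) * 2,
            n_boot=0, n_points=conc.size,
            increasing_data=increasing, warnings=warnings,
        )
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        y_b = yhat + rng.choice(resid, size=resid.size, replace=True)

        def residual_b(p, y_b=y_b):
            return competition_curve(x, p[1], p[2], p[0]) - y_b

        try:
            r = least_squares(residual_b, params, bounds=(lo, hi), method="trf")
            boots[b] = r.x[0]
        except Exception:
            boots[b] = params[0]
    return CompetitionFit(
        logec50=float(params[0]), a0=float(params[1]), amax=float(params[2]),
        rss=rss, logec50_ci=_percentile_ci(boots),
        n_boot=n_boot, n_points=conc.size,
        increasing_data=increasing, warnings=warnings,
    )
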