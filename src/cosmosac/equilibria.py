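"""Phase-equilibrium calculations on top of the activity-coefficient engine.

Vapor--liquid equilibrium uses modified Raoult's law, y_i P = x_i gamma_i
P_i^sat, appropriate for the low/moderate pressures (< a few bar) the model
targets: the vapor phase is ideal and no Poynting correction is applied.
Liquid--liquid equilibrium uses the gamma--gamma (isoactivity) criterion
x_i^a gamma_i^a = x_i^b gamma_i^b, with tie lines located by a
Gibbs-energy-of-mixing tangent construction followed by a Newton polish.

Pure-compound vapor pressures come from Antoine correlations; coefficients
in other conventions (log10, mmHg, Celsius, ...) are converted once at load
time to the internal natural-log / kPa / K form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .core import MixtureState, ParameterSet, ln_gamma
from .exceptions import BracketError, SolverError, ValidationError

__all__ = [
    "VaporPressureModel",
    "BinaryVLEDataset",
    "TieLine",
    "psat",
    "bubble_pressure",
    "bubble_temperature",
    "vle_deviations",
    "lle_binary",
    "lle_temperature_sweep",
    "read_vle_dataset",
    "read_idac_table",
]

log = logging.getLogger(__name__)

_P_TO_KPA = {"kPa": 1.0, "Pa": 1e-3, "bar": 100.0, "mmHg": 0.1333223684, "atm": 101.325}


@dataclass
class VaporPressureModel:
    """Antoine vapor-pressure correlation, internally ln P[kPa] = A - B/(T[K] + C).

    Coefficients may be declared in another dialect (log base 10, pressure
    in mmHg/bar/Pa/atm, temperature in Celsius); they are converted to the
    internal convention at construction.  ``t_range`` is the validity range
    in K; out-of-range evaluation raises or warns per ``out_of_range``.
    """

    A: float
    B: float
    C: float
    name: str = ""
    log_base: str = "e"          # "e" or "10"
    p_unit: str = "kPa"
    t_unit: str = "K"
    t_range: tuple = (1.0, 1e4)
    out_of_range: str = "error"  # "error" | "warn" | "ignore"

    def __post_init__(self) -> None:
        if self.p_unit not in _P_TO_KPA:
            raise ValidationError(f"unknown pressure unit {self.p_unit!r}")
        A, B, C = float(self.A), float(self.B), float(self.C)
        if self.log_base == "10":
            A, B = A * np.log(10.0), B * np.log(10.0)
        elif self.log_base != "e":
            raise ValidationError(f"unknown log base {self.log_base!r}")
        if self.t_unit == "C":
            C -= 273.15
        elif self.t_unit != "K":
            raise ValidationError(f"unknown temperature unit {self.t_unit!r}")
        A += np.log(_P_TO_KPA[self.p_unit])
        self._A, self._B, self._C = A, B, C
        self.log_base, self.p_unit, self.t_unit = "e", "kPa", "K"


def psat(model: VaporPressureModel, T: float) -> float:
    """Saturation pressure in kPa at T (K)."""
    lo, hi = model.t_range
    if not (lo <= T <= hi):
        msg = f"T = {T} K outside validity range [{lo}, {hi}] of {model.name!r}"
        if model.out_of_range == "error":
            raise ValidationError(msg)
        if model.out_of_range == "warn":
            log.warning(msg)
    return float(np.exp(model._A - model._B / (T + model._C)))


@dataclass
class BinaryVLEDataset:
    """Experimental binary VLE points: liquid x1, vapor y1 and P (kPa) or T (K)."""

    mode: str                   # "isothermal" | "isobaric"
    fixed: float                # T (K) if isothermal, P (kPa) if isobaric
    x1: np.ndarray
    y1: np.ndarray
    values: np.ndarray          # P (kPa) if isothermal, T (K) if isobaric
    name: str = ""

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.y1 = np.asarray(self.y1, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in {"isothermal", "isobaric"}:
            raise ValidationError(f"unknown mode {self.mode!r}")
        if not (self.x1.size == self.y1.size == self.values.size) or self.x1.size < 1:
            raise ValidationError("x1, y1 and values must have equal length >= 1")
        if np.any((self.x1 < 0) | (self.x1 > 1) | (self.y1 < 0) | (self.y1 > 1)):
            raise ValidationError("compositions must lie in [0, 1]")


def bubble_pressure(
    x,
    T: float,
    profiles: Sequence,
    params: ParameterSet,
    psat_models: Sequence,
) -> tuple:
    """Bubble pressure and vapor composition by modified Raoult's law.

    P = sum_i x_i gamma_i P_i^sat;  y_i = x_i gamma_i P_i^sat / P.
    """
    x = np.asarray(x, dtype=float)
    gammas = np.exp(ln_gamma(MixtureState(profiles, x, T), params))
    ps = np.array([psat(m, T) for m in psat_models])
    partial = x * gammas * ps
    P = float(partial.sum())
    return P, partial / P


def bubble_temperature(
    x,
    P: float,
    profiles: Sequence,
    params: ParameterSet,
    psat_models: Sequence,
    t_bounds: tuple = None,
) -> tuple:
    """Bubble temperature at pressure P (kPa) by safeguarded root finding.

    Solves sum_i x_i gamma_i(T) psat_i(T) = P with Brent's method; the
    activity coefficients are re-evaluated at every iterate.  Raises
    :class:`BracketError` when the bracket does not contain a sign change.
    """
    if t_bounds is None:
        los, his = zip(*(m.t_range for m in psat_models))
        t_bounds = (max(los), min(his))
    t_lo, t_hi = t_bounds

    def f(T: float) -> float:
        return bubble_pressure(x, T, profiles, params, psat_models)[0] - P

    f_lo, f_hi = f(t_lo), f(t_hi)
    if f_lo * f_hi > 0:
        raise BracketError(
            f"P = {P} kPa not bracketed on [{t_lo}, {t_hi}] K "
            f"(P({t_lo}) = {f_lo + P:.6g}, P({t_hi}) = {f_hi + P:.6g})"
        )
    T = optimize.brentq(f, t_lo, t_hi, xtol=1e-10, rtol=8.9e-16)
    Pcalc, y = bubble_pressure(x, T, profiles, params, psat_models)
    return float(T), y


def vle_deviations(dataset: BinaryVLEDataset, p_model, y_model) -> tuple:
    """Average deviations of equilibrium pressure and vapor composition.

    Pressure deviation is relative, composition deviation absolute:

        dP% = (100/NP) sum |P_exp - P_mod| / P_exp
        dy% = (100/NP) sum |y_exp - y_mod|
    """
    p_model = np.asarray(p_model, dtype=float)
    y_model = np.asarray(y_model, dtype=float)
    if dataset.mode != "isothermal":
        raise ValidationError("pressure deviations require an isothermal dataset")
    p_exp, y_exp = dataset.values, dataset.y1
    if p_model.size != p_exp.size or y_model.size != y_exp.size:
        raise ValidationError("prediction length does not match dataset")
    if np.any(p_exp <= 0):
        raise ValidationError("experimental pressures must be positive")
    dp = 100.0 / p_exp.size * float(np.sum(np.abs(p_exp - p_model) / p_exp))
    dy = 100.0 / y_exp.size * float(np.sum(np.abs(y_exp - y_model)))
    return dp, dy


@dataclass
class TieLine:
    """A binary LLE tie line: coexisting liquid compositions at T."""

    T: float
    x1_alpha: float
    x1_beta: float
    residual: float


def _gibbs_mixing(x1: np.ndarray, gamma_model: Callable) -> np.ndarray:
    g = np.empty_like(x1)
    for i, x in enumerate(x1):
        lg1, lg2 = gamma_model(x)
        g[i] = x * (np.log(x) + lg1) + (1 - x) * (np.log(1 - x) + lg2)
    return g


def _lower_hull_gap(xs: np.ndarray, gs: np.ndarray):
    """Widest pair of non-adjacent grid points on the lower convex hull.

    Returns (x_left, x_right) bracketing a miscibility gap, or None when the
    scanned Gibbs energy of mixing is convex.
    """
    hull = [0]
    for i in range(1, xs.size):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (xs[b] - xs[a]) * (gs[i] - gs[a]) - (gs[b] - gs[a]) * (xs[i] - xs[a])
            if cross <= 0:  # hull[-1] lies above segment a->i
                hull.pop()
            else:
                break
        hull.append(i)
    best = None
    for a, b in zip(hull[:-1], hull[1:]):
        if b - a > 1 and (best is None or xs[b] - xs[a] > best[1] - best[0]):
            best = (xs[a], xs[b])
    return best


def lle_binary(
    T: float,
    gamma_model: Callable,
    n_scan: int = 201,
    tol: float = 1e-8,
    x0: tuple = None,
) -> TieLine | None:
    """Binary LLE tie line by the gamma--gamma (isoactivity) method.

    ``gamma_model(x1) -> (ln gamma1, ln gamma2)`` defines the liquid model at
    the (fixed) temperature of interest.  A dense Gibbs-energy scan plus
    convex-hull tangent construction provides the initial phase guesses
    (or ``x0`` when given, e.g. for temperature continuation); Newton on the
    2x2 isoactivity system x_i^a gamma_i^a = x_i^b gamma_i^b polishes them.
    Returns ``None`` when no miscibility gap exists on the scan.
    """
    if x0 is None:
        eps = 1e-6
        xs = np.linspace(eps, 1 - eps, n_scan)
        gap = _lower_hull_gap(xs, _gibbs_mixing(xs, gamma_model))
        if gap is None:
            return None
        x0 = gap

    def activities(x: float) -> np.ndarray:
        lg1, lg2 = gamma_model(x)
        return np.array([np.log(x) + lg1, np.log(1 - x) + lg2])

    def F(v: np.ndarray) -> np.ndarray:
        # solve in logit coordinates to keep compositions in (0, 1)
        xa, xb = 1 / (1 + np.exp(-v))
        d = activities(xa) - activities(xb)
        return d

    v0 = np.array([np.log(x0[0] / (1 - x0[0])), np.log(x0[1] / (1 - x0[1]))])
    sol = optimize.root(F, v0, method="hybr", tol=1e-14)
    xa, xb = 1 / (1 + np.exp(-sol.x))
    resid = float(
        np.max(np.abs(np.exp(activities(xa)) - np.exp(activities(xb))))
    )
    if xa > xb:
        xa, xb = xb, xa
    if abs(xb - xa) < 1e-4:
        return None  # solver collapsed onto the trivial solution
    if resid > tol:
        raise SolverError(
            f"isoactivity residual {resid:.3e} > {tol} at T = {T} K "
            f"(x1 = {xa:.6f}/{xb:.6f}; solver: {sol.message})"
        )
    return TieLine(T=float(T), x1_alpha=float(xa), x1_beta=float(xb), residual=resid)


def lle_temperature_sweep(
    T_grid,
    gamma_model_factory: Callable,
    n_scan: int = 201,
    tol: float = 1e-8,
) -> list:
    """Tie lines over a temperature grid with continuation.

    ``gamma_model_factory(T)`` must return the composition->ln gamma model at
    T.  Each solved tie line seeds the next temperature; when the previous
    seed fails, the full scan initialization is retried.
    """
    out = []
    prev = None
    for T in T_grid:
        model = gamma_model_factory(T)
        tie = None
        if prev is not None:
            try:
                tie = lle_binary(T, model, n_scan=n_scan, tol=tol,
                                 x0=(prev.x1_alpha, prev.x1_beta))
            except SolverError:
                tie = None
        if tie is None:
            tie = lle_binary(T, model, n_scan=n_scan, tol=tol)
        if tie is not None:
            out.append(tie)
        prev = tie
    return out


def cosmo_gamma_model(profiles: Sequence, params: ParameterSet, T: float) -> Callable:
    """Adapt a COSMO-SAC binary to the composition->ln gamma LLE contract."""

    def model(x1: float):
        lg = ln_gamma(MixtureState(profiles, [x1, 1 - x1], T), params)
        return float(lg[0]), float(lg[1])

    return model


# ---------------------------------------------------------------------------
# tabular dataset readers
# ---------------------------------------------------------------------------

def read_vle_dataset(path_or_buf, name: str = "") -> BinaryVLEDataset:
    """Read a delimited binary-VLE table.

    Required columns: ``x1``, ``y1`` and either ``P_kPa`` (isothermal, with a
    ``T_K`` column or header-equal values) or ``T_K`` (isobaric with
    ``P_kPa`` fixed).  Mode is inferred from which of P/T varies.
    """
    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    need = {"x1", "y1"}
    if not need <= set(df.columns):
        raise ValidationError(f"VLE table must contain columns {sorted(need)}")
    has_p = "P_kPa" in df.columns
    has_t = "T_K" in df.columns
    if not (has_p and has_t):
        raise ValidationError("VLE table needs both P_kPa and T_K columns")
    if df["T_K"].nunique() == 1:
        return BinaryVLEDataset(
            "isothermal", float(df["T_K"].iloc[0]),
            df["x1"].to_numpy(), df["y1"].to_numpy(), df["P_kPa"].to_numpy(),
            name=name,
        )
    if df["P_kPa"].nunique() == 1:
        return BinaryVLEDataset(
            "isobaric", float(df["P_kPa"].iloc[0]),
            df["x1"].to_numpy(), df["y1"].to_numpy(), df["T_K"].to_numpy(),
            name=name,
        )
    raise ValidationError("neither T_K nor P_kPa is constant: ambiguous dataset mode")


def read_idac_table(path_or_buf) -> pd.DataFrame:
    """Read a delimited IDAC table with columns solute, solvent, T_K, ln_gamma_inf."""
    df = pd.read_csv(path_or_buf, sep=None, engine="python", comment="#")
    need = {"solute", "solvent", "T_K", "ln_gamma_inf"}
    if not need <= set(df.columns):
        raise ValidationError(f"IDAC table must contain columns {sorted(need)}")
    if not np.all(np.isfinite(df["ln_gamma_inf"])):
        raise ValidationError("non-finite experimental ln_gamma_inf value")
    return df
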