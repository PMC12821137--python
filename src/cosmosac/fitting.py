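"""Estimation of the COSMO-SAC universal parameters from IDAC data.

The objective is the average absolute deviation (AAD) between predicted and
experimental ln of infinite-dilution activity coefficients,

    AAD = (1/NP) sum_i |ln gamma_i,mod^inf - ln gamma_i,exp^inf|,

minimized with the Nelder--Mead simplex method.  All free parameters are
positive and are optimized in log-space, which enforces positivity without
penalties.  The averaging radius ``r_avg`` enters through the sigma-profile
construction itself, so it is optimized indirectly: a grid scan in which all
other free parameters are re-estimated at each ``r_avg`` (the profiles being
rebuilt from the underlying COSMO geometries every time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import ParameterSet, idac
from .exceptions import FitError, ValidationError
from .sigma import SigmaGrid, build_profile

__all__ = [
    "IdacRecord",
    "IdacDataset",
    "FitResult",
    "aad",
    "r_squared",
    "predict_idac",
    "fit_parameters",
    "scan_r_avg",
]


def aad(ln_gamma_pred, ln_gamma_exp) -> float:
    """Average absolute deviation between predicted and experimental ln IDAC."""
    pred = np.asarray(ln_gamma_pred, dtype=float)
    exp = np.asarray(ln_gamma_exp, dtype=float)
    if pred.size != exp.size or pred.size < 1:
        raise ValidationError("prediction and experiment must have equal length >= 1")
    return float(np.mean(np.abs(pred - exp)))


def r_squared(ln_gamma_pred, ln_gamma_exp) -> float:
    """Squared Pearson correlation of predicted vs experimental ln IDAC."""
    pred = np.asarray(ln_gamma_pred, dtype=float)
    exp = np.asarray(ln_gamma_exp, dtype=float)
    if pred.size != exp.size or pred.size < 2:
        raise ValidationError("need at least two matched points")
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise ValidationError("R^2 undefined for zero-variance input")
    r, _ = stats.pearsonr(pred, exp)
    return float(r**2)


@dataclass(frozen=True)
class IdacRecord:
    solute: str
    solvent: str
    T: float
    ln_gamma_inf: float


@dataclass
class IdacDataset:
    """IDAC records plus the COSMO molecules they reference.

    Holding molecules (not prebuilt profiles) lets the fit rebuild
    sigma-profiles when ``r_avg`` changes.  ``split_hb`` should match the
    model variant being fitted (True for HB2).
    """

    records: Sequence
    molecules: Mapping
    grid: SigmaGrid = field(default_factory=SigmaGrid)
    split_hb: bool = False

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise ValidationError("dataset needs at least one record")
        for rec in self.records:
            if not math.isfinite(rec.ln_gamma_inf):
                raise ValidationError(f"non-finite ln_gamma_inf for {rec}")
            for name in (rec.solute, rec.solvent):
                if name not in self.molecules:
                    raise ValidationError(f"unresolvable profile id {name!r}")
        self._profile_cache: dict = {}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, molecules: Mapping, **kw) -> "IdacDataset":
        records = [
            IdacRecord(r.solute, r.solvent, float(r.T_K), float(r.ln_gamma_inf))
            for r in df.itertuples()
        ]
        return cls(records=records, molecules=molecules, **kw)

    @property
    def exp(self) -> np.ndarray:
        return np.array([r.ln_gamma_inf for r in self.records])

    def profiles(self, r_avg: float) -> Mapping:
        """Sigma-profiles of all referenced molecules at this r_avg (cached)."""
        key = (round(float(r_avg), 12), self.split_hb)
        if key not in self._profile_cache:
            self._profile_cache[key] = {
                name: build_profile(mol, r_avg, self.grid, split_hb=self.split_hb)
                for name, mol in self.molecules.items()
            }
        return self._profile_cache[key]


def predict_idac(dataset: IdacDataset, params: ParameterSet) -> np.ndarray:
    """Predicted ln gamma^inf for every dataset record under ``params``."""
    profiles = dataset.profiles(params.r_avg)
    cache: dict = {}
    out = np.empty(len(dataset.records))
    for i, rec in enumerate(dataset.records):
        out[i] = idac(
            profiles[rec.solute], profiles[rec.solvent], rec.T, params,
            _gamma_cache=cache,
        )
    return out


@dataclass
class FitResult:
    """Outcome of a parameter estimation."""

    params: ParameterSet
    aad: float
    r2: float
    iterations: int
    aad_initial: float
    scan_table: pd.DataFrame | None = None


# free-parameter handling ----------------------------------------------------

_SCALAR_FREE = ("f_pol", "r_eff", "sigma_hb", "r_avg")


def _pack(params: ParameterSet, free: Sequence) -> tuple:
    """Map the free parameters onto log-space coordinates."""
    names, theta = [], []
    for f in free:
        if f in _SCALAR_FREE:
            names.append(f)
            theta.append(math.log(getattr(params, f)))
        elif f == "c_hb":
            if isinstance(params.c_hb, Mapping):
                for key in params.c_hb:
                    names.append(f"c_hb:{key}")
                    theta.append(math.log(params.c_hb[key]))
            else:
                names.append("c_hb:scalar")
                theta.append(math.log(params.c_hb))
        else:
            raise FitError(f"unknown free parameter {f!r}")
    return names, np.array(theta)


def _unpack(params: ParameterSet, names: Sequence, theta: np.ndarray) -> ParameterSet:
    changes: dict = {}
    c_hb = dict(params.c_hb) if isinstance(params.c_hb, Mapping) else params.c_hb
    for name, t in zip(names, theta):
        val = math.exp(t)
        if name.startswith("c_hb:"):
            key = name.split(":", 1)[1]
            if key == "scalar":
                c_hb = val
            else:
                c_hb[key] = val
            changes["c_hb"] = c_hb
        else:
            changes[name] = val
    return params.replace(**changes)


def fit_parameters(
    dataset: IdacDataset,
    init: ParameterSet,
    free: Sequence,
    xatol: float = 1e-6,
    fatol: float = 1e-12,
    maxiter: int = 2000,
) -> FitResult:
    """Minimize the AAD objective over the named free parameters.

    ``free`` is a subset of {"f_pol", "r_eff", "sigma_hb", "c_hb", "r_avg"};
    for HB2 parameter sets "c_hb" frees every hydrogen-bond constant as one
    joint simplex.  Deterministic given inputs (Nelder--Mead has no
    randomness); convergence on simplex spread < ``xatol`` in log-space.
    """
    names, theta0 = _pack(init, free)
    if theta0.size == 0:
        raise FitError("no free parameters requested")

    from .exceptions import ConfigurationError, ValidationError as _VErr

    def objective(theta: np.ndarray) -> float:
        try:
            p = _unpack(init, names, theta)
        except ConfigurationError:
            return 1e10  # simplex stepped outside the parameter box
        try:
            return aad(predict_idac(dataset, p), dataset.exp)
        except (ConfigurationError, _VErr):
            return 1e10
        except Exception as exc:  # noqa: BLE001 - reported as fit failure
            raise FitError(f"objective evaluation failed at {p}: {exc}") from exc

    f0 = objective(theta0)
    res = optimize.minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxiter": maxiter},
    )
    theta_best, f_best = res.x, float(res.fun)
    if f_best > f0:  # Nelder--Mead never worsens the best vertex, but be safe
        theta_best, f_best = theta0, f0
    params_best = _unpack(init, names, theta_best)
    pred = predict_idac(dataset, params_best)
    r2 = r_squared(pred, dataset.exp) if np.ptp(dataset.exp) > 0 and len(pred) > 1 else float("nan")
    return FitResult(
        params=params_best,
        aad=f_best,
        r2=r2,
        iterations=int(res.nit),
        aad_initial=f0,
    )


def scan_r_avg(
    dataset: IdacDataset,
    init: ParameterSet,
    grid: Iterable,
    free: Sequence,
    **fit_kw,
) -> FitResult:
    """Indirect optimization of the averaging radius.

    For each grid value the sigma-profiles are rebuilt with that ``r_avg``
    and all other free parameters are re-estimated; the best row is
    returned together with the full (r_avg, AAD) scan table.  A failed
    nested fit is recorded (NaN AAD) and the scan continues.
    """
    grid = [float(g) for g in grid]
    if not grid or any(g <= 0 for g in grid):
        raise ValidationError("r_avg grid must be nonempty and positive")
    free_inner = [f for f in free if f != "r_avg"]
    rows, results = [], []
    for r in grid:
        start = init.replace(r_avg=r)
        try:
            if free_inner:
                res = fit_parameters(dataset, start, free_inner, **fit_kw)
            else:
                a = aad(predict_idac(dataset, start), dataset.exp)
                res = FitResult(start, a, float("nan"), 0, a)
            rows.append({"r_avg": r, "aad": res.aad})
            results.append(res)
        except FitError as exc:
            rows.append({"r_avg": r, "aad": float("nan"), "error": str(exc)})
            results.append(None)
    table = pd.DataFrame(rows)
    finite = table["aad"].dropna()
    if finite.empty:
        raise FitError("every nested fit in the r_avg scan failed")
    best_idx = int(finite.idxmin())
    best = results[best_idx]
    return FitResult(
        params=best.params,
        aad=best.aad,
        r2=best.r2,
        iterations=best.iterations,
        aad_initial=best.aad_initial,
        scan_table=table,
    )
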