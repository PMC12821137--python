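"""The COSMO-SAC activity-coefficient engine.

The model writes the liquid-phase activity coefficient of compound ``i`` as

    ln gamma_i = n_i sum_m p_i(sigma_m) [ln Gamma_S(sigma_m) - ln Gamma_i(sigma_m)]
                 + ln gamma_i^SG,

where ``p_i`` is the compound's normalized sigma-profile, ``n_i = A_i/a_eff``
its number of standard surface segments, ``Gamma_S``/``Gamma_i`` the segment
activity coefficients of the mixture and of the pure compound, and the last
term the Staverman--Guggenheim combinatorial contribution.  The segment
activity coefficients solve the self-consistency relation

    ln Gamma(sigma_m) = -ln sum_n p(sigma_n) Gamma(sigma_n)
                              exp(-DW(sigma_m, sigma_n) / RT)

with the segment-exchange energy

    DW = (alpha'/2) (sigma_m + sigma_n)^2
         + c_hb max(0, sigma_acc - sigma_hb) min(0, sigma_don + sigma_hb),

``sigma_acc = max(sigma_m, sigma_n)``, ``sigma_don = min(sigma_m, sigma_n)``
and ``alpha' = f_pol * 0.3 * a_eff^{3/2} / eps0``.

Two variants are provided.  ``cosmosac2002`` uses a single hydrogen-bond
constant applied to every segment pair.  ``hb2`` splits the sigma-profile
into hydrogen-bond donor/acceptor classes and looks up one constant per
donor--acceptor class pair (up to eight distinct constants); pairs that are
not a donor against an acceptor get no hydrogen-bond term.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import yaml

from .exceptions import ConfigurationError, ConvergenceError, ValidationError
from .sigma import (
    ACCEPTOR_LABELS,
    DONOR_LABELS,
    HB_INDEX,
    HB_LABELS,
    SigmaGrid,
    SigmaProfile,
)

__all__ = [
    "ParameterSet",
    "MixtureState",
    "SegmentGammaField",
    "available_presets",
    "misfit_alpha",
    "exchange_energy",
    "mixture_profile",
    "solve_segment_gammas",
    "staverman_guggenheim",
    "ln_gamma",
    "idac",
]

_HB_CONSTANT_NAMES = (
    "C_HB", "C_HB2", "C_HB3", "C_HB4", "C_HB5", "C_HB6", "C_HB7", "C_HB8",
)


def _load_config() -> dict:
    ref = importlib.resources.files("cosmosac.data").joinpath("parameters.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass
class ParameterSet:
    """Universal parameters plus fixed model constants.

    ``c_hb`` is a scalar (kcal mol^-1 A^4 e^-2) for the 2002 variant and a
    mapping of constant names (C_HB..C_HB8) for HB2; ``hb_pair_map`` assigns
    each donor-class/acceptor-class pair one of those names.  ``sigma_hb``
    is the hydrogen-bond cutoff in e/A^2.  The fixed constants (dielectric
    prefactor ``eps0``, gas constant, coordination number ``z`` and the
    volume/area normalizers of the combinatorial term) follow the 2002
    Lin--Sandler conventions and are fields so alternates can be tested.
    """

    variant: str = "cosmosac2002"
    f_pol: float = 1.0
    r_avg: float = 1.5
    r_eff: float = 1.2
    sigma_hb: float = 0.0084
    c_hb: object = 0.0
    hb_pair_map: Mapping | None = None
    hb_misfit: bool = True          # apply the misfit term to HB pairs too
    eps0: float = 2.395e-4          # e^2 mol kcal^-1 A^-1
    gas_constant: float = 1.98721e-3  # kcal mol^-1 K^-1
    z_coordination: float = 10.0
    r0_volume: float = 66.69        # A^3
    q0_area: float = 79.53          # A^2
    name: str = ""

    def __post_init__(self) -> None:
        if self.variant not in {"cosmosac2002", "hb2"}:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if not (0 < self.f_pol <= 1.5):
            raise ConfigurationError("f_pol must be in (0, 1.5]")
        for attr in ("r_avg", "r_eff", "sigma_hb"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be positive")
        if self.variant == "hb2":
            if not isinstance(self.c_hb, Mapping):
                raise ConfigurationError("hb2 variant needs a mapping of C_HB constants")
            if any(v <= 0 for v in self.c_hb.values()):
                raise ConfigurationError("all C_HB constants must be positive")
            if self.hb_pair_map is None:
                self.hb_pair_map = _load_config()["hb_pair_map"]
        else:
            if isinstance(self.c_hb, Mapping):
                raise ConfigurationError("cosmosac2002 variant takes a scalar c_hb")
            if self.c_hb < 0:
                raise ConfigurationError("c_hb must be non-negative")

    # -- derived quantities -------------------------------------------------
    @property
    def a_eff(self) -> float:
        """Standard segment area pi * r_eff^2 (A^2)."""
        return np.pi * self.r_eff**2

    @property
    def alpha_prime(self) -> float:
        """Misfit-energy prefactor f_pol * 0.3 * a_eff^{3/2} / eps0."""
        return self.f_pol * 0.3 * self.a_eff**1.5 / self.eps0

    def hb_constant(self, class_m: str, class_n: str) -> float:
        """Hydrogen-bond constant for a segment-class pair (0 if inactive)."""
        if self.variant == "cosmosac2002":
            return float(self.c_hb)
        for donor, acceptor in ((class_m, class_n), (class_n, class_m)):
            if donor in DONOR_LABELS and acceptor in ACCEPTOR_LABELS:
                name = self.hb_pair_map.get(donor, {}).get(acceptor)
                if name is None:
                    raise ConfigurationError(
                        f"no HB constant configured for pair ({donor}, {acceptor})"
                    )
                if name not in self.c_hb:
                    raise ConfigurationError(f"missing HB constant {name}")
                return float(self.c_hb[name])
        return 0.0

    def c_matrix(self) -> np.ndarray:
        """(8, 8) lookup of the HB constant by (class_don, class_acc) index."""
        m = np.zeros((len(HB_LABELS), len(HB_LABELS)))
        if self.variant == "cosmosac2002":
            m[:, :] = float(self.c_hb)
            return m
        for d in HB_LABELS:
            for a in HB_LABELS:
                if d in DONOR_LABELS and a in ACCEPTOR_LABELS:
                    m[HB_INDEX[d], HB_INDEX[a]] = self.hb_constant(d, a)
        return m

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ParameterSet":
        """Load a named preset from the shipped configuration.

        Presets cover both model variants at the three quantum-chemistry
        levels; ``overrides`` replace any field.
        """
        cfg = _load_config()
        key = cfg.get("aliases", {}).get(name, name)
        # case-insensitive match
        presets = cfg["presets"]
        if key not in presets:
            lower = {k.lower(): k for k in presets}
            lower.update({k.lower(): v for k, v in cfg.get("aliases", {}).items()})
            if name.lower() in lower:
                key = lower[name.lower()]
                key = cfg.get("aliases", {}).get(key, key)
            else:
                raise ConfigurationError(
                    f"unknown preset {name!r}; available: {sorted(presets)}"
                )
        p = presets[key]
        const = cfg["constants"]
        kwargs = dict(
            variant=p["variant"],
            f_pol=p["f_pol"],
            r_avg=p["r_avg"],
            r_eff=p["r_eff"],
            sigma_hb=p["sigma_hb"],
            c_hb=p["c_hb"],
            hb_pair_map=cfg["hb_pair_map"] if p["variant"] == "hb2" else None,
            eps0=const["eps0"],
            gas_constant=const["gas_constant"],
            z_coordination=const["z_coordination"],
            r0_volume=const["r0_volume"],
            q0_area=const["q0_area"],
            name=key,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def replace(self, **changes) -> "ParameterSet":
        return replace(self, **changes)


def available_presets() -> list:
    return sorted(_load_config()["presets"])


def misfit_alpha(params: ParameterSet) -> float:
    """The misfit prefactor alpha' (kcal mol^-1 A^4 e^-2)."""
    if params.r_eff <= 0:
        raise ConfigurationError("r_eff must be positive")
    return params.alpha_prime


def exchange_energy(
    sigma_m: float,
    sigma_n: float,
    class_m: str,
    class_n: str,
    params: ParameterSet,
) -> float:
    """Segment-exchange energy DW (kcal/mol) for one segment pair.

    Symmetric in (m, n).  The hydrogen-bond contribution is attractive and
    active only when the more positive density exceeds ``sigma_hb`` and the
    more negative density lies below ``-sigma_hb`` (and, for HB2, when the
    corresponding segment classes form a donor--acceptor pair).
    """
    s_acc = max(sigma_m, sigma_n)
    s_don = min(sigma_m, sigma_n)
    c = params.hb_constant(class_m, class_n)
    hb = c * max(0.0, s_acc - params.sigma_hb) * min(0.0, s_don + params.sigma_hb)
    misfit = 0.5 * params.alpha_prime * (sigma_m + sigma_n) ** 2
    if not params.hb_misfit and hb != 0.0:
        misfit = 0.0
    return misfit + hb


@dataclass
class MixtureState:
    """Compound sigma-profiles, mole fractions and temperature."""

    profiles: Sequence
    x: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.profiles) != self.x.size:
            raise ValidationError("one mole fraction per profile required")
        if np.any(self.x < 0):
            raise ValidationError("mole fractions must be non-negative")
        if abs(self.x.sum() - 1.0) > 1e-12:
            raise ValidationError(f"mole fractions sum to {self.x.sum():.15g}, not 1")
        if self.T <= 0:
            raise ValidationError("temperature must be positive")


@dataclass
class SegmentGammaField:
    """Converged ln Gamma per (HB class, sigma bin)."""

    grid: SigmaGrid
    classes: tuple
    ln_gamma: np.ndarray  # (n_classes, n_bins)
    residual: float
    iterations: int


def _check_grids(profiles) -> SigmaGrid:
    g0 = profiles[0].grid
    for p in profiles[1:]:
        g = p.grid
        if g.n_bins != g0.n_bins or not (
            np.isclose(g.sigma_min, g0.sigma_min) and np.isclose(g.sigma_max, g0.sigma_max)
        ):
            raise ValidationError("all compound profiles must share one sigma grid")
    return g0


def _union_classes(profiles) -> tuple:
    present = set()
    for p in profiles:
        present.update(p.classes)
    return tuple(c for c in HB_LABELS if c in present)


def _expand(profile: SigmaProfile, classes: tuple) -> np.ndarray:
    """Profile areas on a common class list (zero rows for absent classes)."""
    out = np.zeros((len(classes), profile.grid.n_bins))
    for i, c in enumerate(profile.classes):
        out[classes.index(c)] = profile.areas[i]
    return out


def mixture_profile(profiles: Sequence, x) -> SigmaProfile:
    """Area-weighted mixture sigma-profile p_S = sum_i x_i A_i p_i / sum_i x_i A_i."""
    x = np.asarray(x, dtype=float)
    grid = _check_grids(profiles)
    classes = _union_classes(profiles)
    areas = sum(xi * _expand(p, classes) for xi, p in zip(x, profiles))
    return SigmaProfile(
        grid=grid,
        classes=classes,
        areas=areas,
        total_area=float(sum(xi * p.total_area for xi, p in zip(x, profiles))),
        volume=float(sum(xi * p.volume for xi, p in zip(x, profiles))),
        name="mixture",
    )


def _exchange_matrix(sig_row, cls_row, sig_col, cls_col, params: ParameterSet):
    """Vectorized DW between two segment sets (rows x columns)."""
    sm = sig_row[:, None]
    sn = sig_col[None, :]
    s_acc = np.maximum(sm, sn)
    s_don = np.minimum(sm, sn)
    cmat = params.c_matrix()
    # class of the donor-side (more negative sigma) and acceptor-side segment
    row_is_don = sm <= sn
    cd = np.where(row_is_don, cls_row[:, None], cls_col[None, :])
    ca = np.where(row_is_don, cls_col[None, :], cls_row[:, None])
    c = cmat[cd, ca]
    hb = c * np.maximum(0.0, s_acc - params.sigma_hb) * np.minimum(0.0, s_don + params.sigma_hb)
    misfit = 0.5 * params.alpha_prime * (sm + sn) ** 2
    if not params.hb_misfit:
        misfit = np.where(hb != 0.0, 0.0, misfit)
    return misfit + hb


def solve_segment_gammas(
    profile: SigmaProfile,
    T: float,
    params: ParameterSet,
    tol: float = 1e-8,
    max_iter: int = 500,
    damping: float = 0.5,
) -> SegmentGammaField:
    """Solve the segment-activity self-consistency equation.

    Damped successive substitution on ln Gamma (mixing factor ``damping``)
    until max|ln Gamma_new - ln Gamma_old| < ``tol``.  The fixed point only
    couples populated (class, bin) entries; afterwards ln Gamma is evaluated
    once for every entry of the profile's (class, bin) lattice so that
    unpopulated bins still carry a defined value.
    """
    if T <= 0:
        raise ValidationError("temperature must be positive")
    p = profile.p_sigma  # (n_c, n_bins), sums to 1
    n_c, n_bins = p.shape
    centers = profile.grid.centers
    cls_idx_all = np.repeat(
        [HB_INDEX[c] for c in profile.classes], n_bins
    )
    sig_all = np.tile(centers, n_c)
    p_flat = p.ravel()
    pop = p_flat > 0
    if not np.any(pop):
        raise ValidationError("profile has no populated bins")
    sig_pop = sig_all[pop]
    cls_pop = cls_idx_all[pop]
    p_pop = p_flat[pop]

    RT = params.gas_constant * T
    W = _exchange_matrix(sig_pop, cls_pop, sig_pop, cls_pop, params)
    K = np.exp(-W / RT)  # (n_pop, n_pop)

    ln_g = np.zeros(p_pop.size)
    residual = np.inf
    history = []
    for it in range(1, max_iter + 1):
        ln_new = -np.log(K @ (p_pop * np.exp(ln_g)))
        residual = float(np.max(np.abs(ln_new - ln_g)))
        history.append(residual)
        if residual < tol:
            ln_g = ln_new
            break
        ln_g = (1.0 - damping) * ln_g + damping * ln_new
    else:
        raise ConvergenceError(
            f"segment-gamma iteration did not reach tol={tol} in {max_iter} "
            f"iterations (residual {residual:.3e})",
            residual_history=history,
        )

    # evaluate ln Gamma on the full (class, bin) lattice
    W_full = _exchange_matrix(sig_all, cls_idx_all, sig_pop, cls_pop, params)
    ln_full = -np.log(np.exp(-W_full / RT) @ (p_pop * np.exp(ln_g)))
    return SegmentGammaField(
        grid=profile.grid,
        classes=profile.classes,
        ln_gamma=ln_full.reshape(n_c, n_bins),
        residual=residual,
        iterations=it,
    )


def staverman_guggenheim(x, r, q, z: float = 10.0) -> np.ndarray:
    """Staverman--Guggenheim combinatorial ln gamma per compound.

    ln gamma_i^SG = ln(phi_i/x_i) + (z/2) q_i ln(theta_i/phi_i) + l_i
                    - (phi_i/x_i) sum_j x_j l_j,

    with phi, theta the volume and surface fractions, l_i = (z/2)(r_i - q_i)
    - (r_i - 1).  Written in ratio form (phi_i/x_i = r_i / sum x r), which is
    finite for x_i = 0 and therefore directly yields the infinite-dilution
    limit.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(r <= 0) or np.any(q <= 0):
        raise ValidationError("r and q must be positive")
    sxr = float(x @ r)
    sxq = float(x @ q)
    phi_over_x = r / sxr
    theta_over_phi = (q / sxq) / phi_over_x
    ell = (z / 2.0) * (r - q) - (r - 1.0)
    return (
        np.log(phi_over_x)
        + (z / 2.0) * q * np.log(theta_over_phi)
        + ell
        - phi_over_x * float(x @ ell)
    )


def _residual_ln_gamma(profile, gamma_mix, gamma_pure, params) -> float:
    """n_i sum_m p_i(sigma_m) [ln Gamma_S - ln Gamma_i] for one compound."""
    classes = gamma_mix.classes
    p_i = _expand(profile, classes)
    p_i = p_i / p_i.sum()
    pure = _expand_field(gamma_pure, classes)
    n_i = profile.total_area / params.a_eff
    return float(n_i * np.sum(p_i * (gamma_mix.ln_gamma - pure)))


def _expand_field(fieldobj: SegmentGammaField, classes: tuple) -> np.ndarray:
    out = np.zeros((len(classes), fieldobj.grid.n_bins))
    for i, c in enumerate(fieldobj.classes):
        out[classes.index(c)] = fieldobj.ln_gamma[i]
    return out


def ln_gamma(
    mixture: MixtureState,
    params: ParameterSet,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> np.ndarray:
    """Activity coefficients ln gamma_i for every compound of the mixture.

    The 2002 variant ignores HB classes (its single constant applies to all
    segment pairs); HB2 uses whatever classes the profiles carry, so HB2
    should be fed class-split profiles.
    """
    profiles = list(mixture.profiles)
    _check_grids(profiles)
    classes = _union_classes(profiles)
    mix = mixture_profile(profiles, mixture.x)
    # ensure the mixture field covers every class any compound populates
    if mix.classes != classes:
        mix = SigmaProfile(
            grid=mix.grid, classes=classes, areas=_expand(mix, classes),
            total_area=mix.total_area, volume=mix.volume, name=mix.name,
        )
    gamma_mix = solve_segment_gammas(mix, mixture.T, params, tol=tol, max_iter=max_iter)

    r = np.array([p.volume / params.r0_volume for p in profiles])
    q = np.array([p.total_area / params.q0_area for p in profiles])
    ln_sg = staverman_guggenheim(mixture.x, r, q, z=params.z_coordination)

    out = np.empty(len(profiles))
    for i, prof in enumerate(profiles):
        expanded = SigmaProfile(
            grid=prof.grid, classes=classes, areas=_expand(prof, classes),
            total_area=prof.total_area, volume=prof.volume, name=prof.name,
        )
        gamma_pure = solve_segment_gammas(
            expanded, mixture.T, params, tol=tol, max_iter=max_iter
        )
        out[i] = _residual_ln_gamma(prof, gamma_mix, gamma_pure, params) + ln_sg[i]
    return out


def idac(
    solute: SigmaProfile,
    solvent: SigmaProfile,
    T: float,
    params: ParameterSet,
    tol: float = 1e-8,
    max_iter: int = 500,
    _gamma_cache: dict | None = None,
) -> float:
    """ln gamma at infinite dilution of ``solute`` in ``solvent``.

    Evaluated in the analytic dilute limit: the mixture sigma-profile equals
    the pure solvent's, and the combinatorial part uses its x -> 0 limiting
    form.  ``_gamma_cache`` may map a key to a solved field to reuse pure-
    compound solves across many solute/solvent pairs at one temperature.
    """
    _check_grids([solute, solvent])
    classes = _union_classes([solute, solvent])

    def solved(profile):
        key = (profile.name, id(profile), classes, T)
        if _gamma_cache is not None and key in _gamma_cache:
            return _gamma_cache[key]
        expanded = SigmaProfile(
            grid=profile.grid, classes=classes, areas=_expand(profile, classes),
            total_area=profile.total_area, volume=profile.volume, name=profile.name,
        )
        fieldobj = solve_segment_gammas(expanded, T, params, tol=tol, max_iter=max_iter)
        if _gamma_cache is not None:
            _gamma_cache[key] = fieldobj
        return fieldobj

    gamma_solvent = solved(solvent)
    gamma_solute = solved(solute)
    residual = _residual_ln_gamma(solute, gamma_solvent, gamma_solute, params)

    r = np.array([solute.volume, solvent.volume]) / params.r0_volume
    q = np.array([solute.total_area, solvent.total_area]) / params.q0_area
    sg = staverman_guggenheim(
        np.array([0.0, 1.0]), r, q, z=params.z_coordination
    )[0]
    return residual + sg
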