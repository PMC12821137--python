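"""Sigma-profile construction.

A COSMO calculation yields an apparent surface-charge density ``sigma*`` on
every cavity segment.  COSMO-SAC consumes a histogram of surface area versus
charge density -- the sigma-profile.  Three steps produce it:

1. spatial averaging of the raw segment charges with an averaging radius
   ``r_avg`` (the Mullins modification of the Lin--Sandler model),
2. optional classification of every segment into a hydrogen-bond (HB)
   donor/acceptor class based on its nearest atom (needed by the HB2 model
   variant, which carries one interaction constant per donor--acceptor pair),
3. assignment of each segment's area to the sigma histogram by two-bin linear
   interpolation.

Units: positions in Angstrom (A), areas in A^2, charge densities in e/A^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .io import CosmoMolecule

__all__ = [
    "HB_LABELS",
    "DONOR_LABELS",
    "ACCEPTOR_LABELS",
    "SigmaGrid",
    "SigmaProfile",
    "average_charges",
    "classify_segments",
    "build_profile",
]

# Hydrogen-bond segment classes.  Order is the canonical index used by the
# interaction-constant lookup tables.
HB_LABELS = (
    "NONE",
    "OH_DONOR",
    "OH_ACCEPTOR",
    "NH_DONOR",
    "N_ACCEPTOR",
    "WATER_DONOR",
    "WATER_ACCEPTOR",
    "OTHER_ACCEPTOR",
)
HB_INDEX = {label: i for i, label in enumerate(HB_LABELS)}
DONOR_LABELS = frozenset({"OH_DONOR", "NH_DONOR", "WATER_DONOR"})
ACCEPTOR_LABELS = frozenset(
    {"OH_ACCEPTOR", "N_ACCEPTOR", "WATER_ACCEPTOR", "OTHER_ACCEPTOR"}
)

# Covalent radii (A) for the bond-detection distance criterion.
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform discretization of the sigma axis, symmetric about zero.

    The default 51-bin grid on [-0.025, 0.025] e/A^2 is the de-facto
    COSMO-SAC standard.  ``n_bins`` must be odd so sigma = 0 is a bin center.
    """

    n_bins: int = 51
    sigma_min: float = -0.025
    sigma_max: float = 0.025

    def __post_init__(self) -> None:
        if self.n_bins < 3 or self.n_bins % 2 == 0:
            raise ValidationError("n_bins must be an odd integer >= 3")
        if not np.isclose(self.sigma_min, -self.sigma_max):
            raise ValidationError("grid must be symmetric about sigma = 0")

    @property
    def spacing(self) -> float:
        return (self.sigma_max - self.sigma_min) / (self.n_bins - 1)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.sigma_min, self.sigma_max, self.n_bins)

    @classmethod
    def from_centers(cls, centers: np.ndarray, rtol: float = 1e-9) -> "SigmaGrid":
        centers = np.asarray(centers, dtype=float)
        diffs = np.diff(centers)
        if len(centers) < 3 or np.any(diffs <= 0):
            raise ValidationError("bin centers must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=rtol, atol=1e-15):
            raise ValidationError("bin centers must be uniformly spaced")
        return cls(len(centers), float(centers[0]), float(centers[-1]))


@dataclass
class SigmaProfile:
    """Binned surface-area distribution over charge density.

    ``areas`` has shape (n_classes, n_bins) in A^2; ``classes`` names each
    row.  An unsplit profile carries the single class ``"NONE"``.
    ``total_area`` and ``volume`` are the whole-molecule cavity values used
    for the combinatorial term and segment count.
    """

    grid: SigmaGrid
    classes: tuple
    areas: np.ndarray
    total_area: float
    volume: float
    name: str = ""
    extra_headers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas = np.atleast_2d(np.asarray(self.areas, dtype=float))
        self.classes = tuple(self.classes)
        if self.areas.shape != (len(self.classes), self.grid.n_bins):
            raise ValidationError(
                f"areas shape {self.areas.shape} does not match "
                f"({len(self.classes)}, {self.grid.n_bins})"
            )
        if np.any(self.areas < -1e-12):
            raise ValidationError("negative bin area")
        if self.total_area <= 0 or self.volume <= 0:
            raise ValidationError("total_area and volume must be positive")

    @property
    def segment_area(self) -> float:
        """Sum of binned segment areas (may differ slightly from total_area)."""
        return float(self.areas.sum())

    @property
    def p_sigma(self) -> np.ndarray:
        """Normalized probability p(sigma, class); sums to 1."""
        return self.areas / self.areas.sum()

    def collapse_classes(self) -> "SigmaProfile":
        """Sum all HB classes into a single unsplit profile."""
        return SigmaProfile(
            grid=self.grid,
            classes=("NONE",),
            areas=self.areas.sum(axis=0, keepdims=True),
            total_area=self.total_area,
            volume=self.volume,
            name=self.name,
            extra_headers=dict(self.extra_headers),
        )


def average_charges(mol: "CosmoMolecule", r_avg: float) -> np.ndarray:
    """Spatially average raw segment charge densities.

    Each segment's averaged density is a weighted mean over all segments,

        sigma_m = sum_n sigma*_n w_mn / sum_n w_mn,
        w_mn = [r_n^2 r_avg^2 / (r_n^2 + r_avg^2)] exp(-d_mn^2 / (r_n^2 + r_avg^2)),

    with r_n = sqrt(a_n / pi) the segment radius and d_mn the center
    distance.  The self term (d_mm = 0) is included.

    Parameters
    ----------
    mol : CosmoMolecule
    r_avg : float
        Averaging radius in A; must be positive.

    Returns
    -------
    ndarray of shape (n_segments,) -- averaged sigma in e/A^2.
    """
    if r_avg <= 0:
        raise ValidationError(f"r_avg must be positive, got {r_avg}")
    areas = mol.segment_areas
    if np.any(areas <= 0):
        raise ValidationError("all segment areas must be positive")
    rn2 = areas / np.pi                      # (n,)
    denom = rn2 + r_avg**2                   # (n,) -- depends on source segment n only
    d2 = cdist(mol.segment_positions, mol.segment_positions, "sqeuclidean")
    w = (rn2 * r_avg**2 / denom)[None, :] * np.exp(-d2 / denom[None, :])
    return (w @ mol.segment_sigmas_raw) / w.sum(axis=1)


def _bonded_pairs(elements, positions, scale: float = 1.3):
    """Adjacency by covalent-radius distance criterion: d < scale*(r_a + r_b)."""
    radii = []
    for el in elements:
        if el not in COVALENT_RADII:
            raise ValidationError(f"unknown element symbol: {el!r}")
        radii.append(COVALENT_RADII[el])
    radii = np.asarray(radii)
    d = cdist(positions, positions)
    cut = scale * (radii[:, None] + radii[None, :])
    np.fill_diagonal(d, np.inf)
    return d < cut


def classify_atoms(elements, positions) -> list:
    """Assign an HB class to every atom.

    Rules (nearest-neighbor chemistry, deliberately simple):

    * H bonded to a water O (an O whose bonded neighbors are exactly two H)
      -> WATER_DONOR; H bonded to any other O -> OH_DONOR; H bonded to N
      -> NH_DONOR; other H -> NONE.
    * water O -> WATER_ACCEPTOR; O with at least one H (hydroxyl)
      -> OH_ACCEPTOR; O with no H (ether, carbonyl) -> OTHER_ACCEPTOR.
    * N -> N_ACCEPTOR.  Everything else -> NONE.
    """
    elements = [str(e).capitalize() for e in elements]
    positions = np.asarray(positions, dtype=float)
    bonds = _bonded_pairs(elements, positions)
    n = len(elements)

    def is_water_o(i: int) -> bool:
        nbrs = [j for j in range(n) if bonds[i, j]]
        return elements[i] == "O" and len(nbrs) == 2 and all(
            elements[j] == "H" for j in nbrs
        )

    labels = []
    for i, el in enumerate(elements):
        nbrs = [j for j in range(n) if bonds[i, j]]
        if el == "H":
            nbr_els = [elements[j] for j in nbrs]
            if any(elements[j] == "O" and is_water_o(j) for j in nbrs):
                labels.append("WATER_DONOR")
            elif "O" in nbr_els:
                labels.append("OH_DONOR")
            elif "N" in nbr_els:
                labels.append("NH_DONOR")
            else:
                labels.append("NONE")
        elif el == "O":
            if is_water_o(i):
                labels.append("WATER_ACCEPTOR")
            elif any(elements[j] == "H" for j in nbrs):
                labels.append("OH_ACCEPTOR")
            else:
                labels.append("OTHER_ACCEPTOR")
        elif el == "N":
            labels.append("N_ACCEPTOR")
        else:
            labels.append("NONE")
    return labels


def classify_segments(mol: "CosmoMolecule") -> list:
    """HB class per segment: each segment inherits its nearest atom's class.

    Deterministic given the molecule; raises on unknown element symbols.
    """
    atom_labels = classify_atoms(mol.atom_elements, mol.atom_positions)
    d = cdist(mol.segment_positions, mol.atom_positions)
    nearest = d.argmin(axis=1)
    return [atom_labels[i] for i in nearest]


def _bin_areas(
    grid: SigmaGrid, sigmas: np.ndarray, areas: np.ndarray, clamp: bool, who: str
) -> np.ndarray:
    """Accumulate segment areas into bins by two-bin linear interpolation."""
    out = np.zeros(grid.n_bins)
    pos = (sigmas - grid.sigma_min) / grid.spacing
    if clamp:
        pos = np.clip(pos, 0.0, grid.n_bins - 1.0)
    else:
        bad = np.nonzero((pos < 0) | (pos > grid.n_bins - 1))[0]
        if bad.size:
            raise ValidationError(
                f"averaged sigma of segment {bad[0]} of {who} "
                f"({sigmas[bad[0]]:.6g} e/A^2) lies outside the grid "
                f"[{grid.sigma_min}, {grid.sigma_max}]"
            )
    lo = np.clip(np.floor(pos).astype(int), 0, grid.n_bins - 2)
    frac = pos - lo
    np.add.at(out, lo, areas * (1.0 - frac))
    np.add.at(out, lo + 1, areas * frac)
    return out


def build_profile(
    mol: "CosmoMolecule",
    r_avg: float,
    grid: SigmaGrid | None = None,
    split_hb: bool = False,
    clamp: bool = False,
) -> SigmaProfile:
    """Build the sigma-profile of a molecule.

    Averages the raw charges with ``r_avg``, optionally classifies the
    segments into HB classes, and bins each segment's area onto the grid by
    linear interpolation between the two bracketing bin centers (area is
    conserved exactly).

    Parameters
    ----------
    mol, r_avg : see :func:`average_charges`.
    grid : SigmaGrid, default the 51-bin standard grid.
    split_hb : build per-HB-class sub-profiles (required by the HB2 variant).
    clamp : assign out-of-grid sigma to the edge bins instead of raising.
    """
    grid = grid or SigmaGrid()
    sigmas = average_charges(mol, r_avg)
    areas = mol.segment_areas
    if split_hb:
        seg_labels = classify_segments(mol)
        present = [c for c in HB_LABELS if c in seg_labels]
        labels_arr = np.asarray(seg_labels)
        rows = []
        for c in present:
            mask = labels_arr == c
            rows.append(_bin_areas(grid, sigmas[mask], areas[mask], clamp, mol.name))
        classes, binned = tuple(present), np.vstack(rows)
    else:
        classes = ("NONE",)
        binned = _bin_areas(grid, sigmas, areas, clamp, mol.name)[None, :]
    return SigmaProfile(
        grid=grid,
        classes=classes,
        areas=binned,
        total_area=mol.total_area,
        volume=mol.volume,
        name=mol.name,
    )
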