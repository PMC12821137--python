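"""Synthetic COSMO-cavity fixtures.

Real sigma-profiles come from continuum-solvation quantum chemistry.  This
module generates physically plausible stand-ins without any quantum
chemistry: segments tile near-uniform Fibonacci lattices on atom-centered
spheres (points buried inside a neighboring atom's sphere are culled, so the
segments tile the union surface), and the raw charge density sigma* is a sum
of smooth angular Gaussian patches anchored to atoms -- negative lobes on
polar hydrogens, positive lobes on acceptor heteroatoms, mirroring the sign
convention of apparent screening charges.  The total surface charge is
shifted to an exact target (zero by default).

Everything is deterministic given the spec and its seed, so generated
``.cosmo`` files are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .io import CosmoMolecule, write_turbomole_cosmo

__all__ = [
    "CAVITY_RADII",
    "ChargePatch",
    "FixtureSpec",
    "generate_fixture",
    "library_specs",
    "fixture_library",
    "analytic_union_area",
]

# COSMO cavity radii (A), roughly 1.17x the van der Waals radii.
CAVITY_RADII = {
    "H": 1.30, "C": 2.00, "N": 1.83, "O": 1.72, "F": 1.72,
    "S": 2.16, "Cl": 2.05,
}


@dataclass(frozen=True)
class ChargePatch:
    """A smooth charge lobe on one atom's sphere.

    ``amplitude`` is the peak raw density in e/A^2; ``width`` the angular
    Gaussian width in radians; ``direction`` the lobe axis (defaults to
    pointing away from the rest of the molecule).
    """

    atom: int
    amplitude: float
    width: float = 1.0
    direction: tuple | None = None


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic COSMO molecule."""

    name: str
    atoms: tuple                       # ((element, (x, y, z)), ...)
    segments_per_atom: int = 220
    patches: tuple = ()
    seed: int = 0
    net_charge: float = 0.0

    def with_patches(self, patches) -> "FixtureSpec":
        return replace(self, patches=tuple(patches))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    m, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(m) < 0:
        m[:, 0] = -m[:, 0]
    return m


def _sphere_lens_volume(r1: float, r2: float, d: float) -> float:
    """Volume of the intersection of two spheres a distance d apart."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        rmin = min(r1, r2)
        return 4.0 / 3.0 * np.pi * rmin**3
    return (
        np.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def analytic_union_area(spec: FixtureSpec, n_reference: int = 20000) -> float:
    """Reference exposed area of the union of atom spheres.

    For a single atom this is the closed form 4 pi r^2.  For overlapping
    spheres the hidden caps themselves overlap, so the exposed area is
    evaluated by a converged fine surface lattice (``n_reference`` points
    per sphere, about 100x the generator's default resolution).
    """
    centers = np.array([p for _, p in spec.atoms], dtype=float)
    radii = np.array([CAVITY_RADII[e] for e, _ in spec.atoms])
    if len(radii) == 1:
        return float(4 * np.pi * radii[0] ** 2)
    total = 0.0
    for i in range(len(radii)):
        pts = centers[i] + radii[i] * _fibonacci_sphere(n_reference)
        keep = np.ones(len(pts), dtype=bool)
        for j in range(len(radii)):
            if j != i:
                keep &= np.linalg.norm(pts - centers[j], axis=1) > radii[j]
        total += 4 * np.pi * radii[i] ** 2 * keep.mean()
    return float(total)


def generate_fixture(spec: FixtureSpec) -> tuple:
    """Generate a synthetic molecule and its TURBOMOLE-dialect text.

    Returns ``(CosmoMolecule, cosmo_text)``.  Raises when an atom sphere is
    engulfed by another (no exposed surface) or an element has no cavity
    radius.
    """
    if not spec.atoms:
        raise ValidationError("fixture needs at least one atom")
    elements = [e for e, _ in spec.atoms]
    centers = np.array([p for _, p in spec.atoms], dtype=float)
    for e in elements:
        if e not in CAVITY_RADII:
            raise ValidationError(f"no cavity radius for element {e!r}")
    radii = np.array([CAVITY_RADII[e] for e in elements])
    n_at = len(elements)
    for i in range(n_at):
        for j in range(i + 1, n_at):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            if d + min(radii[i], radii[j]) <= max(radii[i], radii[j]):
                raise ValidationError(
                    f"sphere of atom {i + 1} and atom {j + 1} overlap beyond "
                    "tolerance (one sphere engulfs the other)"
                )

    rng = np.random.default_rng(spec.seed)
    centroid = centers.mean(axis=0)

    seg_atom, seg_pos, seg_area, seg_sigma = [], [], [], []
    for i in range(n_at):
        rot = _random_rotation(rng)
        pts = _fibonacci_sphere(spec.segments_per_atom) @ rot.T
        pos = centers[i] + radii[i] * pts
        keep = np.ones(len(pos), dtype=bool)
        for j in range(n_at):
            if j != i:
                keep &= np.linalg.norm(pos - centers[j], axis=1) > radii[j]
        pos = pos[keep]
        if pos.size == 0:
            continue
        area = 4 * np.pi * radii[i] ** 2 / spec.segments_per_atom
        sigma = np.zeros(len(pos))
        for patch in spec.patches:
            if patch.atom != i:
                continue
            if patch.direction is not None:
                axis = np.asarray(patch.direction, dtype=float)
            elif n_at > 1:
                rest = (centroid * n_at - centers[i]) / (n_at - 1)
                axis = centers[i] - rest
            else:
                axis = np.array([0.0, 0.0, 1.0])
            axis = axis / np.linalg.norm(axis)
            cosang = np.clip((pos - centers[i]) @ axis / radii[i], -1.0, 1.0)
            theta = np.arccos(cosang)
            sigma += patch.amplitude * np.exp(-((theta / patch.width) ** 2))
        seg_atom.extend([i + 1] * len(pos))
        seg_pos.append(pos)
        seg_area.extend([area] * len(pos))
        seg_sigma.append(sigma)

    if not seg_area:
        raise ValidationError("no exposed surface segments generated")
    seg_pos = np.vstack(seg_pos)
    seg_area = np.array(seg_area)
    seg_sigma = np.concatenate(seg_sigma)

    # shift sigma uniformly so the total charge hits the target exactly
    total_area = float(seg_area.sum())
    charge = float(seg_sigma @ seg_area)
    seg_sigma = seg_sigma + (spec.net_charge - charge) / total_area

    volume = float((4.0 / 3.0) * np.pi * np.sum(radii**3))
    for i in range(n_at):
        for j in range(i + 1, n_at):
            d = float(np.linalg.norm(centers[i] - centers[j]))
            volume -= _sphere_lens_volume(radii[i], radii[j], d)

    mol = CosmoMolecule(
        name=spec.name,
        atom_elements=elements,
        atom_positions=centers,
        segment_atom_index=np.array(seg_atom),
        segment_positions=seg_pos,
        segment_areas=seg_area,
        segment_charges=seg_sigma * seg_area,
        total_area=total_area,
        volume=volume,
        source_dialect="synthetic",
        stated_total_charge=spec.net_charge,
    )
    return mol, write_turbomole_cosmo(mol)


def library_specs(seed: int = 7) -> dict:
    """Specs for the five standard fixtures spanning the main HB chemistries:
    nonpolar, water (donor+acceptor), hydroxyl, carbonyl acceptor, amine."""

    def patch(atom, amp, width=0.9, direction=None):
        return ChargePatch(atom=atom, amplitude=amp, width=width, direction=direction)

    specs = {
        "alkane-like": FixtureSpec(
            name="alkane-like",
            atoms=(
                ("C", (0.0, 0.0, 0.0)),
                ("C", (1.54, 0.0, 0.0)),
                ("H", (-0.63, 0.89, 0.0)),
                ("H", (-0.63, -0.89, 0.0)),
                ("H", (2.17, 0.89, 0.0)),
                ("H", (2.17, -0.89, 0.0)),
            ),
            patches=(patch(0, 0.0018), patch(1, -0.0018)),
            seed=seed,
        ),
        "water-like": FixtureSpec(
            name="water-like",
            atoms=(
                ("O", (0.0, 0.0, 0.0)),
                ("H", (0.757, 0.586, 0.0)),
                ("H", (-0.757, 0.586, 0.0)),
            ),
            patches=(
                patch(0, 0.030, 1.0, direction=(0.0, -1.0, 0.0)),
                patch(1, -0.032, 1.1),
                patch(2, -0.032, 1.1),
            ),
            seed=seed + 1,
        ),
        "alcohol-like": FixtureSpec(
            name="alcohol-like",
            atoms=(
                ("C", (0.0, 0.0, 0.0)),
                ("C", (1.54, 0.0, 0.0)),
                ("O", (2.02, 1.35, 0.0)),
                ("H", (2.98, 1.38, 0.0)),
                ("H", (-0.55, 0.93, 0.0)),
                ("H", (-0.55, -0.93, 0.0)),
            ),
            patches=(
                patch(2, 0.028, 0.9, direction=(-0.3, 1.0, 0.0)),
                patch(3, -0.030, 1.1),
                patch(0, 0.002),
            ),
            seed=seed + 2,
        ),
        "ketone-like": FixtureSpec(
            name="ketone-like",
            atoms=(
                ("C", (0.0, 0.0, 0.0)),
                ("C", (1.54, 0.0, 0.0)),
                ("O", (2.15, 1.06, 0.0)),
                ("C", (2.32, -1.25, 0.0)),
            ),
            patches=(
                patch(2, 0.026, 0.9, direction=(0.5, 1.0, 0.0)),
                patch(1, 0.003),
                patch(0, -0.003),
            ),
            seed=seed + 3,
        ),
        "amine-like": FixtureSpec(
            name="amine-like",
            atoms=(
                ("N", (0.0, 0.0, 0.0)),
                ("H", (0.95, 0.35, 0.0)),
                ("H", (-0.95, 0.35, 0.0)),
                ("C", (0.0, -1.47, 0.0)),
            ),
            patches=(
                patch(0, 0.030, 1.0, direction=(0.0, 0.7, 0.7)),
                patch(1, -0.028, 1.1),
                patch(2, -0.028, 1.1),
            ),
            seed=seed + 4,
        ),
    }
    return specs


def fixture_library(seed: int = 7) -> dict:
    """Generate the named fixture molecules (idempotent for a given seed)."""
    return {name: generate_fixture(spec)[0] for name, spec in library_specs(seed).items()}
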