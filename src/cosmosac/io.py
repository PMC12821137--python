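"""Reading and writing COSMO solvation output and sigma-profile tables.

Two COSMO dialects are supported:

* the TURBOMOLE ``.cosmo`` layout (``$``-keyed sections; atomic and segment
  coordinates in Bohr, areas in A^2, charges in e), and
* the GAMESS-style layout used by the open LVPP sigma-profile database
  (keyword headers, coordinates in Angstrom).

Both parsers normalize to the same in-memory :class:`CosmoMolecule`
(positions in A, areas in A^2, charges in e).  Parsing is strict: structural
problems raise, unknown trailing sections are tolerated.

The sigma-profile table is a plain-text exchange format: ``#``-prefixed
header lines (name, total area, volume, HB classes) followed by one row per
bin with the sigma bin center (e/A^2) and the surface area (A^2) per class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exceptions import (
    CosmoParseError,
    ProfileFormatError,
    UnsupportedDialectError,
    ValidationError,
)
from .sigma import SigmaGrid, SigmaProfile

BOHR_TO_ANGSTROM = 0.52917721

__all__ = [
    "BOHR_TO_ANGSTROM",
    "SegmentRecord",
    "CosmoMolecule",
    "parse_turbomole_cosmo",
    "parse_gamess_cosmo",
    "write_turbomole_cosmo",
    "write_gamess_cosmo",
    "read_profile_table",
    "write_profile_table",
]


@dataclass(frozen=True)
class SegmentRecord:
    """One cavity segment: 1-based parent atom, position (A), area (A^2),
    screening charge (e) and raw charge density charge/area (e/A^2)."""

    atom_index: int
    position: tuple
    area: float
    charge: float
    sigma_raw: float


@dataclass
class CosmoMolecule:
    """Parsed COSMO cavity data for one molecule.

    Array-backed for efficiency; :attr:`segments` exposes per-segment
    records.  ``total_area``/``volume`` are the file-header cavity values
    (model code uses these); the segment-sum area is available separately
    and must agree with the header within 1%.
    """

    name: str
    atom_elements: list
    atom_positions: np.ndarray          # (n_atoms, 3) A
    segment_atom_index: np.ndarray      # (n_seg,) 1-based
    segment_positions: np.ndarray       # (n_seg, 3) A
    segment_areas: np.ndarray           # (n_seg,) A^2
    segment_charges: np.ndarray         # (n_seg,) e
    total_area: float                   # A^2, header value
    volume: float                       # A^3, header value
    source_dialect: str = "synthetic"
    stated_total_charge: float | None = None

    def __post_init__(self) -> None:
        self.atom_positions = np.asarray(self.atom_positions, dtype=float).reshape(-1, 3)
        self.segment_positions = np.asarray(self.segment_positions, dtype=float).reshape(-1, 3)
        self.segment_atom_index = np.asarray(self.segment_atom_index, dtype=int)
        self.segment_areas = np.asarray(self.segment_areas, dtype=float)
        self.segment_charges = np.asarray(self.segment_charges, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.atom_elements) == 0 or self.segment_areas.size == 0:
            raise ValidationError("molecule needs at least one atom and one segment")
        if np.any(self.segment_areas <= 0):
            i = int(np.argmin(self.segment_areas))
            raise ValidationError(
                f"segment {i} of {self.name!r} has non-positive area "
                f"{self.segment_areas[i]:.6g}"
            )
        if self.volume <= 0:
            raise ValidationError(f"volume of {self.name!r} must be positive")
        seg_sum = float(self.segment_areas.sum())
        if abs(seg_sum - self.total_area) > 0.01 * self.total_area:
            raise ValidationError(
                f"segment-area sum {seg_sum:.4f} disagrees with header total "
                f"area {self.total_area:.4f} by more than 1%"
            )
        if self.stated_total_charge is not None:
            q = float(self.segment_charges.sum())
            if abs(q - self.stated_total_charge) > 1e-6:
                raise ValidationError(
                    f"segment charges sum to {q:.3e} e but file states "
                    f"{self.stated_total_charge:.3e} e"
                )

    @property
    def segment_sigmas_raw(self) -> np.ndarray:
        """Raw charge density per segment, charge/area (e/A^2)."""
        return self.segment_charges / self.segment_areas

    @property
    def segment_area_sum(self) -> float:
        return float(self.segment_areas.sum())

    @property
    def segments(self) -> list:
        return [
            SegmentRecord(
                atom_index=int(self.segment_atom_index[i]),
                position=tuple(self.segment_positions[i]),
                area=float(self.segment_areas[i]),
                charge=float(self.segment_charges[i]),
                sigma_raw=float(self.segment_charges[i] / self.segment_areas[i]),
            )
            for i in range(self.segment_areas.size)
        ]


def _as_text(text) -> str:
    if hasattr(text, "read"):
        text = text.read()
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    return text


def _float(tok: str, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise CosmoParseError(f"non-numeric field {tok!r} at line {lineno}") from None


# ---------------------------------------------------------------------------
# TURBOMOLE dialect
# ---------------------------------------------------------------------------

def parse_turbomole_cosmo(text) -> CosmoMolecule:
    """Parse a TURBOMOLE ``.cosmo`` file.

    Requires the ``$cosmo`` header (area/volume), ``$coord_rad`` atomic
    coordinates and ``$segment_information`` blocks.  Atomic and segment
    coordinates are in Bohr and are converted to Angstrom; areas are read as
    A^2 and charges as e.
    """
    text = _as_text(text)
    lines = text.splitlines()
    sections: dict = {}
    current = None
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("$"):
            current = stripped.split()[0][1:].lower()
            sections[current] = []
        elif current is not None:
            sections[current].append((lineno, line))

    if not sections:
        raise CosmoParseError("no $-keyed sections found: not a TURBOMOLE COSMO file")
    if "segment_information" not in sections:
        raise CosmoParseError("missing $segment_information section")
    if "coord_rad" not in sections:
        raise CosmoParseError("missing $coord_rad section")
    if "cosmo" not in sections:
        raise CosmoParseError("missing $cosmo section (area/volume header)")

    name = "unknown"
    for _, line in sections.get("info", []):
        if line.strip():
            name = line.strip()
            break

    area = volume = None
    for lineno, line in sections["cosmo"]:
        m = re.match(r"\s*(area|volume)\s*=\s*([-\d.eEdD+]+)", line)
        if m:
            val = _float(m.group(2).replace("D", "e").replace("d", "e"), lineno)
            if m.group(1) == "area":
                area = val
            else:
                volume = val
    if area is None or volume is None:
        raise CosmoParseError("missing area/volume in $cosmo section")

    stated_charge = None
    for lineno, line in sections.get("screening_charge", []):
        m = re.match(r"\s*cosmo\s*=\s*([-\d.eE+]+)", line)
        if m:
            stated_charge = _float(m.group(1), lineno)

    elements, apos = [], []
    for lineno, line in sections["coord_rad"]:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        tok = s.split()
        if len(tok) < 5:
            raise CosmoParseError(f"short atom line at line {lineno}")
        x, y, z = (_float(t, lineno) for t in tok[1:4])
        elements.append(tok[4].capitalize())
        apos.append((x * BOHR_TO_ANGSTROM, y * BOHR_TO_ANGSTROM, z * BOHR_TO_ANGSTROM))

    sidx, spos, sarea, scharge = [], [], [], []
    for lineno, line in sections["segment_information"]:
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        tok = s.split()
        if len(tok) < 7:
            raise CosmoParseError(f"short segment line at line {lineno}")
        sidx.append(int(_float(tok[1], lineno)))
        x, y, z = (_float(t, lineno) for t in tok[2:5])
        spos.append((x * BOHR_TO_ANGSTROM, y * BOHR_TO_ANGSTROM, z * BOHR_TO_ANGSTROM))
        scharge.append(_float(tok[5], lineno))
        a = _float(tok[6], lineno)
        if a <= 0:
            raise ValidationError(f"non-positive segment area at line {lineno}")
        sarea.append(a)
    if not sarea:
        raise CosmoParseError("empty $segment_information section")

    return CosmoMolecule(
        name=name,
        atom_elements=elements,
        atom_positions=np.array(apos),
        segment_atom_index=np.array(sidx),
        segment_positions=np.array(spos),
        segment_areas=np.array(sarea),
        segment_charges=np.array(scharge),
        total_area=area,
        volume=volume,
        source_dialect="turbomole",
        stated_total_charge=stated_charge,
    )


def write_turbomole_cosmo(mol: CosmoMolecule) -> str:
    """Serialize a molecule in the TURBOMOLE ``.cosmo`` dialect."""
    out = ["$info", mol.name, "$cosmo"]
    out.append(f"  area   = {mol.total_area:.10f}       # [A**2]")
    out.append(f"  volume = {mol.volume:.10f}       # [A**3]")
    out.append("$screening_charge")
    out.append(f"  cosmo      = {mol.segment_charges.sum():.10f}")
    out.append("$coord_rad")
    out.append("#atom   x [a.u.]           y [a.u.]           z [a.u.]      element  radius [A]")
    for i, (el, p) in enumerate(zip(mol.atom_elements, mol.atom_positions), start=1):
        b = p / BOHR_TO_ANGSTROM
        out.append(
            f"{i:4d} {b[0]: .14e} {b[1]: .14e} {b[2]: .14e}  {el.lower():<2s}  1.72"
        )
    out.append("$segment_information")
    out.append("# n  atom        position (X, Y, Z) [a.u.]        charge [e]   area [A**2]  charge/area [e/A**2]  potential")
    for i in range(mol.segment_areas.size):
        b = mol.segment_positions[i] / BOHR_TO_ANGSTROM
        q, a = mol.segment_charges[i], mol.segment_areas[i]
        out.append(
            f"{i + 1:5d} {mol.segment_atom_index[i]:4d} "
            f"{b[0]: .14e} {b[1]: .14e} {b[2]: .14e} "
            f"{q: .14e} {a: .14e} {q / a: .14e}  0.0"
        )
    out.append("$end")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# GAMESS dialect (open LVPP sigma-profile database layout)
# ---------------------------------------------------------------------------

_GAMESS_HEADER = "COSMO SOLVATION RESULTS (GAMESS)"


def parse_gamess_cosmo(text) -> CosmoMolecule:
    """Parse COSMO output in the GAMESS dialect of the open sigma-profile
    database.  Coordinates are already in Angstrom; areas in A^2, charges
    in e.  TURBOMOLE-style input is rejected with an explicit error."""
    text = _as_text(text)
    if not text.strip():
        raise CosmoParseError("empty input stream")
    if "$segment_information" in text or "$cosmo" in text:
        raise UnsupportedDialectError(
            "input looks like a TURBOMOLE .cosmo file; use parse_turbomole_cosmo"
        )
    if _GAMESS_HEADER not in text:
        raise UnsupportedDialectError(
            "missing GAMESS COSMO header line; unrecognized dialect"
        )
    lines = text.splitlines()
    name = "unknown"
    area = volume = stated_charge = None
    elements, apos = [], []
    sidx, spos, sarea, scharge = [], [], [], []
    mode = None
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        m = re.match(r"MOLECULE NAME:\s*(.+)", s)
        if m:
            name = m.group(1).strip()
            continue
        m = re.match(r"TOTAL SURFACE AREA \(A\*\*2\)\s*=\s*(\S+)", s)
        if m:
            area = _float(m.group(1), lineno)
            continue
        m = re.match(r"CAVITY VOLUME \(A\*\*3\)\s*=\s*(\S+)", s)
        if m:
            volume = _float(m.group(1), lineno)
            continue
        m = re.match(r"TOTAL SCREENING CHARGE \(E\)\s*=\s*(\S+)", s)
        if m:
            stated_charge = _float(m.group(1), lineno)
            continue
        if s.startswith("ATOM COORDINATES"):
            mode = "atoms"
            continue
        if s.startswith("SEGMENT INFORMATION"):
            mode = "segments"
            continue
        if s.startswith("END COSMO"):
            mode = None
            continue
        if mode == "atoms":
            tok = s.split()
            if len(tok) < 4:
                raise CosmoParseError(f"short atom line at line {lineno}")
            elements.append(tok[0].capitalize())
            apos.append(tuple(_float(t, lineno) for t in tok[1:4]))
        elif mode == "segments":
            tok = s.split()
            if tok[0].upper() in {"IDX", "N"}:  # column header
                continue
            if len(tok) < 7:
                raise CosmoParseError(f"short segment line at line {lineno}")
            sidx.append(int(_float(tok[1], lineno)))
            spos.append(tuple(_float(t, lineno) for t in tok[2:5]))
            scharge.append(_float(tok[5], lineno))
            a = _float(tok[6], lineno)
            if a <= 0:
                raise ValidationError(f"non-positive segment area at line {lineno}")
            sarea.append(a)

    if not sarea:
        raise CosmoParseError("missing SEGMENT INFORMATION block")
    if area is None or volume is None:
        raise CosmoParseError("missing surface area / cavity volume header")
    return CosmoMolecule(
        name=name,
        atom_elements=elements,
        atom_positions=np.array(apos),
        segment_atom_index=np.array(sidx),
        segment_positions=np.array(spos),
        segment_areas=np.array(sarea),
        segment_charges=np.array(scharge),
        total_area=area,
        volume=volume,
        source_dialect="gamess",
        stated_total_charge=stated_charge,
    )


def write_gamess_cosmo(mol: CosmoMolecule) -> str:
    """Serialize a molecule in the GAMESS/LVPP dialect."""
    out = [
        _GAMESS_HEADER,
        f"MOLECULE NAME: {mol.name}",
        f"TOTAL SURFACE AREA (A**2) = {mol.total_area:.10f}",
        f"CAVITY VOLUME (A**3)      = {mol.volume:.10f}",
        f"TOTAL SCREENING CHARGE (E) = {mol.segment_charges.sum():.10f}",
        "ATOM COORDINATES (ANGSTROM)",
    ]
    for el, p in zip(mol.atom_elements, mol.atom_positions):
        out.append(f"  {el:<2s} {p[0]: .14e} {p[1]: .14e} {p[2]: .14e}")
    out.append(f"SEGMENT INFORMATION: NSEG = {mol.segment_areas.size}")
    out.append("  IDX  IATOM        X(A)          Y(A)          Z(A)        CHARGE(E)     AREA(A**2)")
    for i in range(mol.segment_areas.size):
        p = mol.segment_positions[i]
        out.append(
            f"{i + 1:5d} {mol.segment_atom_index[i]:5d} "
            f"{p[0]: .14e} {p[1]: .14e} {p[2]: .14e} "
            f"{mol.segment_charges[i]: .14e} {mol.segment_areas[i]: .14e}"
        )
    out.append("END COSMO")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Sigma-profile exchange table
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {"name", "total_area", "volume", "classes"}


def write_profile_table(profile: SigmaProfile) -> str:
    """Serialize a sigma-profile as a plain-text table (read/write identity
    holds to better than 1e-12)."""
    out = [
        f"# name: {profile.name}",
        f"# total_area: {profile.total_area:.17g}",
        f"# volume: {profile.volume:.17g}",
        f"# classes: {' '.join(profile.classes)}",
    ]
    for key, val in profile.extra_headers.items():
        out.append(f"# {key}: {val}")
    out.append("# columns: sigma [e/A^2], area [A^2] per class")
    centers = profile.grid.centers
    for k in range(profile.grid.n_bins):
        row = " ".join(f"{profile.areas[c, k]:.17g}" for c in range(len(profile.classes)))
        out.append(f"{centers[k]:.17g} {row}")
    return "\n".join(out) + "\n"


def read_profile_table(text) -> SigmaProfile:
    """Parse the sigma-profile exchange table written by
    :func:`write_profile_table`.  Unknown header keys are preserved in
    ``extra_headers``.  A non-uniform or non-increasing sigma column is a
    format error."""
    text = _as_text(text)
    headers: dict = {}
    extra: dict = {}
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            m = re.match(r"#\s*([\w ]+?)\s*:\s*(.*)", s)
            if m:
                key = m.group(1).strip()
                if key == "columns":
                    continue
                (headers if key in _KNOWN_KEYS else extra)[key] = m.group(2).strip()
            continue
        tok = s.split()
        try:
            rows.append([float(t) for t in tok])
        except ValueError:
            raise ProfileFormatError(f"non-numeric value at line {lineno}") from None
    if not rows:
        raise ProfileFormatError("no data rows in profile table")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ProfileFormatError("ragged rows in profile table")
    data = np.array(rows)
    try:
        grid = SigmaGrid.from_centers(data[:, 0])
    except ValidationError as exc:
        raise ProfileFormatError(str(exc)) from None
    classes = tuple(headers.get("classes", "NONE").split())
    if data.shape[1] - 1 != len(classes):
        raise ProfileFormatError(
            f"{data.shape[1] - 1} area columns but {len(classes)} declared classes"
        )
    for key in ("total_area", "volume"):
        if key not in headers:
            raise ProfileFormatError(f"missing required header {key!r}")
    return SigmaProfile(
        grid=grid,
        classes=classes,
        areas=data[:, 1:].T,
        total_area=float(headers["total_area"]),
        volume=float(headers["volume"]),
        name=headers.get("name", ""),
        extra_headers=extra,
    )
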