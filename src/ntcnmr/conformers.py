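"""NtC conformer class tables.

A dinucleotide step of a DNA backbone is described by nine torsion angles,
``(delta, chi)`` of the 5'-side nucleotide, the inter-nucleotide
``(epsilon, zeta, alpha, beta, gamma)`` run, and ``(delta, chi)`` of the
3'-side nucleotide.  An NtC (diNucleotide Conformer) class is a point in
that nine-dimensional torsion space together with class-specific NMR
parameters of the bridging phosphate: a ³¹P shielding constant ``sigma``
(ppm) and a three-bond ³J(P,H3') coupling ``j_coupling`` (Hz).  Classes may
additionally carry discretized geometric dependences of those parameters —
a 36x36 shielding surface over the flanking (alpha, zeta) torsions and a
36-point coupling curve over epsilon, both on the fixed 10-degree binning
used throughout this package.

The class inventory is data, not code: real class-defining tables are
loaded from CSV/TSV, and a synthetic table with the canonical BI/BII
members (BB00, BB01, BB04, BB07) is generated for testing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TORSION_NAMES",
    "N_BINS",
    "BIN_WIDTH",
    "TorsionVector",
    "NtCClass",
    "ClassTable",
    "load_class_table",
    "write_class_table",
    "synthetic_class_table",
]

#: Fixed component order of a step's torsion vector.  ``delta5``/``chi5``
#: belong to the 5' nucleotide, ``alpha3``..``chi3`` to the 3' nucleotide.
TORSION_NAMES: tuple[str, ...] = (
    "delta5",
    "chi5",
    "epsilon",
    "zeta",
    "alpha3",
    "beta3",
    "gamma3",
    "delta3",
    "chi3",
)

#: Number of 10-degree bins covering the full circle.
N_BINS = 36
BIN_WIDTH = 360.0 / N_BINS

FAMILIES = ("BI_family", "BII_family", "other")


def normalize_angle(a):
    """Map angles (scalar or array, degrees) onto [0, 360)."""
    return np.asarray(a, dtype=float) % 360.0


def torsion_bin(a) -> np.ndarray:
    """Index (0-based) of the half-open 10-degree bin containing each angle.

    Angles are normalized first, so 360 lands in bin 0 and 359.99 in bin 35.
    """
    k = np.floor_divide(normalize_angle(a), BIN_WIDTH).astype(int)
    return np.minimum(k, N_BINS - 1)


@dataclasses.dataclass(frozen=True)
class TorsionVector:
    """The nine backbone torsions of one dinucleotide step, degrees in [0, 360)."""

    delta5: float
    chi5: float
    epsilon: float
    zeta: float
    alpha3: float
    beta3: float
    gamma3: float
    delta3: float
    chi3: float

    def __post_init__(self) -> None:
        for name in TORSION_NAMES:
            v = float(getattr(self, name))
            if not np.isfinite(v):
                raise ValueError(f"torsion {name} is not finite: {v!r}")
            object.__setattr__(self, name, float(normalize_angle(v)))

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "TorsionVector":
        vals = list(values)
        if len(vals) != len(TORSION_NAMES):
            raise ValueError(
                f"expected {len(TORSION_NAMES)} torsions, got {len(vals)}"
            )
        return cls(*vals)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in TORSION_NAMES], dtype=float)


@dataclasses.dataclass
class NtCClass:
    """One NtC class: defining torsions plus phosphate NMR parameters.

    ``sigma_surface`` (36x36, ppm, axes alpha x zeta) and ``j_curve``
    (36, Hz, over epsilon) are optional discretized parameter dependences;
    when present, their value at the bin containing the class-defining
    torsion must reproduce the scalar parameter.
    """

    class_id: str
    defining_torsions: TorsionVector
    family: str
    sigma: float
    j_coupling: float
    sigma_surface: np.ndarray | None = None
    j_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"class {self.class_id}: family {self.family!r} not one of {FAMILIES}"
            )
        if self.sigma_surface is not None:
            self.sigma_surface = np.asarray(self.sigma_surface, dtype=float)
            if self.sigma_surface.shape != (N_BINS, N_BINS):
                raise ValueError(
                    f"class {self.class_id}: sigma_surface must be "
                    f"{N_BINS}x{N_BINS}, got {self.sigma_surface.shape}"
                )
        if self.j_curve is not None:
            self.j_curve = np.asarray(self.j_curve, dtype=float)
            if self.j_curve.shape != (N_BINS,):
                raise ValueError(
                    f"class {self.class_id}: j_curve must have {N_BINS} entries"
                )

    @property
    def center_bins(self) -> tuple[int, int, int]:
        """(alpha, zeta, epsilon) bin indices of the class-defining torsions."""
        t = self.defining_torsions
        return (
            int(torsion_bin(t.alpha3)),
            int(torsion_bin(t.zeta)),
            int(torsion_bin(t.epsilon)),
        )

    def validate(self, atol: float = 1e-9) -> None:
        ka, kz, ke = self.center_bins
        if self.sigma_surface is not None:
            v = self.sigma_surface[ka, kz]
            if abs(v - self.sigma) > atol:
                raise ValueError(
                    f"class {self.class_id}: sigma_surface at class center "
                    f"({v:.12g}) differs from sigma ({self.sigma:.12g})"
                )
        if self.j_curve is not None:
            v = self.j_curve[ke]
            if abs(v - self.j_coupling) > atol:
                raise ValueError(
                    f"class {self.class_id}: j_curve at class center "
                    f"({v:.12g}) differs from j_coupling ({self.j_coupling:.12g})"
                )


@dataclasses.dataclass
class ClassTable:
    """An ordered collection of NtC classes with unique identifiers."""

    classes: list[NtCClass]
    source: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("a class table needs at least 2 classes")
        seen: set[str] = set()
        dupes = []
        for c in self.classes:
            if c.class_id in seen:
                dupes.append(c.class_id)
            seen.add(c.class_id)
        if dupes:
            raise ValueError(f"duplicate class_id(s): {sorted(set(dupes))}")
        for c in self.classes:
            c.validate()

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return any(c.class_id == class_id for c in self.classes)

    def __getitem__(self, class_id: str) -> NtCClass:
        for c in self.classes:
            if c.class_id == class_id:
                return c
        raise KeyError(class_id)

    @property
    def ids(self) -> list[str]:
        return [c.class_id for c in self.classes]

    def sorted_by_id(self) -> list[NtCClass]:
        return sorted(self.classes, key=lambda c: c.class_id)

    def torsion_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Stack defining torsions into an (n_classes, 9) array."""
        ids = list(order) if order is not None else self.ids
        return np.vstack([self[i].defining_torsions.as_array() for i in ids])


# ---------------------------------------------------------------------------
# serialization

_SCALAR_COLUMNS = ["class_id", "family", *TORSION_NAMES, "sigma_ppm", "j_hz"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def load_class_table(path: str | Path, load_grids: bool = True) -> ClassTable:
    """Read a class-definition table from CSV/TSV.

    Expected header: ``class_id,family,delta5,chi5,epsilon,zeta,alpha3,
    beta3,gamma3,delta3,chi3,sigma_ppm,j_hz``.  Optional sidecar files
    ``<class_id>.sigma_grid.csv`` (36x36, no header) and
    ``<class_id>.j_curve.csv`` (36 rows) next to the table provide the
    parameter dependences.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in _SCALAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"class table {path} is missing column(s): {missing}")
    for col in (*TORSION_NAMES, "sigma_ppm", "j_hz"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"class table {path}: non-numeric {col} at row(s) {list(bad)}"
            )
    classes = []
    for _, row in df.iterrows():
        cid = str(row["class_id"])
        surface = curve = None
        if load_grids:
            grid_path = path.parent / f"{cid}.sigma_grid.csv"
            if grid_path.exists():
                surface = np.loadtxt(grid_path, delimiter=",")
            curve_path = path.parent / f"{cid}.j_curve.csv"
            if curve_path.exists():
                curve = np.loadtxt(curve_path, delimiter=",")
        classes.append(
            NtCClass(
                class_id=cid,
                defining_torsions=TorsionVector.from_iterable(
                    [float(row[n]) for n in TORSION_NAMES]
                ),
                family=str(row["family"]),
                sigma=float(row["sigma_ppm"]),
                j_coupling=float(row["j_hz"]),
                sigma_surface=surface,
                j_curve=curve,
            )
        )
    return ClassTable(classes=classes, source=str(path))


def write_class_table(table: ClassTable, path: str | Path) -> None:
    """Write a class table (and any grids as sidecar files) to CSV/TSV."""
    path = Path(path)
    rows = []
    for c in table:
        t = c.defining_torsions
        rows.append(
            {
                "class_id": c.class_id,
                "family": c.family,
                **{n: getattr(t, n) for n in TORSION_NAMES},
                "sigma_ppm": c.sigma,
                "j_hz": c.j_coupling,
            }
        )
    pd.DataFrame(rows, columns=_SCALAR_COLUMNS).to_csv(
        path, sep=_sep_for(path), index=False, float_format="%.12g"
    )
    for c in table:
        if c.sigma_surface is not None:
            np.savetxt(
                path.parent / f"{c.class_id}.sigma_grid.csv",
                c.sigma_surface,
                delimiter=",",
                fmt="%.12g",
            )
        if c.j_curve is not None:
            np.savetxt(
                path.parent / f"{c.class_id}.j_curve.csv",
                c.j_curve,
                delimiter=",",
                fmt="%.12g",
            )


# ---------------------------------------------------------------------------
# synthetic table

# B-DNA-like torsion centers (degrees) for the synthetic default table.
# BB00 is canonical BI (epsilon - zeta < 0), BB07 canonical BII
# (epsilon - zeta > 0); BB04 bridges the two along zeta.  Values are
# synthetic stand-ins chosen in the experimentally typical ranges, not a
# published class-definition set.
_SYNTHETIC_CENTERS: Mapping[str, tuple[str, tuple[float, ...]]] = {
    #              family        d5     chi5   eps    zeta   a3     b3     g3     d3     chi3
    "BB00": ("BI_family", (135.0, 250.0, 187.0, 262.0, 300.0, 176.0, 46.0, 135.0, 250.0)),
    "BB01": ("BI_family", (135.0, 250.0, 210.0, 285.0, 300.0, 240.0, 46.0, 135.0, 250.0)),
    "BB04": ("BII_family", (140.0, 255.0, 230.0, 180.0, 300.0, 176.0, 46.0, 140.0, 255.0)),
    "BB07": ("BII_family", (145.0, 260.0, 246.0, 174.0, 300.0, 110.0, 46.0, 145.0, 260.0)),
    "BA05": ("other", (85.0, 200.0, 190.0, 265.0, 300.0, 176.0, 46.0, 135.0, 250.0)),
    "AB01": ("other", (85.0, 200.0, 210.0, 290.0, 295.0, 176.0, 120.0, 145.0, 255.0)),
    "BA01": ("other", (140.0, 255.0, 230.0, 270.0, 300.0, 176.0, 46.0, 85.0, 200.0)),
    "OT01": ("other", (135.0, 250.0, 60.0, 80.0, 160.0, 280.0, 180.0, 85.0, 100.0)),
}

# Synthetic shieldings (ppm, relative scale around a B-DNA-like phosphate)
# and couplings (Hz).  The BI members sit near the canonical small-J,
# high-shielding corner; BII members have larger J and lower shielding.
_SYNTHETIC_PARAMS: Mapping[str, tuple[float, float]] = {
    "BB00": (280.0, 1.8),
    "BB01": (279.6, 2.4),
    "BB04": (279.2, 5.5),
    "BB07": (275.9, 9.5),
    "BA05": (279.8, 2.0),
    "AB01": (279.3, 2.8),
    "BA01": (278.6, 6.0),
    "OT01": (277.5, 4.0),
}


def synthetic_class_table(seed: int, with_dependences: bool = True) -> ClassTable:
    """Deterministically generate a small NtC table for testing.

    The table contains BB00/BB01 (BI family), BB04/BB07 (BII family) and
    four further classes, with centers separated by at least 40 degrees in
    at least one torsion.  A small seeded jitter (< 3 degrees) makes tables
    from different seeds distinguishable without eroding the separation.
    When ``with_dependences`` is true, each class also carries a smooth
    synthetic sigma_surface and Karplus-type j_curve anchored at the class
    scalars.
    """
    rng = np.random.default_rng(seed)
    classes = []
    for cid, (family, center) in _SYNTHETIC_CENTERS.items():
        jitter = rng.uniform(-3.0, 3.0, size=len(TORSION_NAMES))
        sigma, j = _SYNTHETIC_PARAMS[cid]
        classes.append(
            NtCClass(
                class_id=cid,
                defining_torsions=TorsionVector.from_iterable(
                    np.asarray(center) + jitter
                ),
                family=family,
                sigma=sigma + rng.uniform(-0.05, 0.05),
                j_coupling=j + rng.uniform(-0.05, 0.05),
            )
        )
    table = ClassTable(classes=classes, source=f"synthetic(seed={seed})")
    if with_dependences:
        from .synthetic import synthetic_dependences

        table = synthetic_dependences(table, seed=seed)
    return table
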