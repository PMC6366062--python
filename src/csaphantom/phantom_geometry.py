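"""Drilled resolution-phantom geometry: the ground truth for all measurements.

The phantom is a 10-cm-diameter, 2-cm-thick PMMA block with 110 holes drilled
perpendicular to its faces: 22 distinct diameters from 3.00 to 3.42 mm in
0.02-mm steps, five replicate holes per diameter, placed at random sites on a
regular grid.  Hole positions are nuisance parameters -- only the diameter
ladder enters the accuracy / precision / limit-of-detection analysis -- so
layouts are generated by seeded sampling of collision-free grid sites rather
than reproducing any particular drilling map.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DIAMETERS_MM",
    "N_DIAMETERS",
    "N_REPLICATES",
    "N_HOLES",
    "BLOCK_DIAMETER_MM",
    "BLOCK_THICKNESS_MM",
    "HoleSpec",
    "PhantomLayout",
    "LayoutInfeasibleError",
    "nominal_csa",
    "build_layout",
]

#: The drilled diameter ladder: 3.00 + 0.02 k mm, k = 0..21.
DIAMETERS_MM: tuple[float, ...] = tuple(round(3.00 + 0.02 * k, 2) for k in range(22))
N_DIAMETERS = 22
N_REPLICATES = 5
N_HOLES = N_DIAMETERS * N_REPLICATES  # 110
BLOCK_DIAMETER_MM = 100.0
BLOCK_THICKNESS_MM = 20.0


class LayoutInfeasibleError(RuntimeError):
    """Raised when 110 collision-free hole sites cannot be placed."""


def nominal_csa(diameter_mm: float) -> float:
    """Circular cross-sectional area pi*(d/2)**2 in mm^2 of a drilled hole.

    Parameters
    ----------
    diameter_mm : float
        Hole diameter in mm; must be strictly positive.
    """
    if not diameter_mm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_mm!r}")
    return math.pi * (diameter_mm / 2.0) ** 2


@dataclass(frozen=True)
class HoleSpec:
    """One drilled hole: nominal diameter, position, and replicate index."""

    diameter_mm: float
    center_xy_mm: tuple[float, float]
    replicate_index: int  # 1..5
    nominal_csa_mm2: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if math.isnan(self.nominal_csa_mm2):
            object.__setattr__(self, "nominal_csa_mm2", nominal_csa(self.diameter_mm))
        rel = abs(self.nominal_csa_mm2 - nominal_csa(self.diameter_mm))
        if rel > 1e-12 * nominal_csa(self.diameter_mm):
            raise ValueError("nominal_csa_mm2 inconsistent with diameter")


@dataclass(frozen=True)
class PhantomLayout:
    """Full drilling layout of the resolution phantom.

    ``holes`` are ordered by (diameter, replicate); the positional index of a
    hole in this tuple is its stable ``hole_id`` used throughout the package.
    """

    holes: tuple[HoleSpec, ...]
    min_spacing_mm: float
    seed: int
    block_diameter_mm: float = BLOCK_DIAMETER_MM
    block_thickness_mm: float = BLOCK_THICKNESS_MM
    margin_mm: float = 4.0

    @property
    def diameters(self) -> np.ndarray:
        """Sorted unique diameters present in the layout."""
        return np.unique([h.diameter_mm for h in self.holes])

    @property
    def max_diameter_mm(self) -> float:
        return max(h.diameter_mm for h in self.holes)

    def centers(self) -> np.ndarray:
        """(n, 2) array of hole centers in block coordinates (mm)."""
        return np.array([h.center_xy_mm for h in self.holes], dtype=float)

    def validate(self) -> None:
        """Check all layout invariants; raise ``ValueError`` on violation."""
        if len(self.holes) != N_HOLES:
            raise ValueError(f"expected {N_HOLES} holes, got {len(self.holes)}")
        diams = self.diameters
        if len(diams) != N_DIAMETERS:
            raise ValueError(f"expected {N_DIAMETERS} diameters, got {len(diams)}")
        ladder = 3.00 + 0.02 * np.arange(N_DIAMETERS)
        if np.max(np.abs(diams - ladder)) > 1e-12:
            raise ValueError("diameter ladder does not match 3.00 + 0.02 k")
        counts = pd.Series([h.diameter_mm for h in self.holes]).value_counts()
        if not (counts == N_REPLICATES).all():
            raise ValueError("every diameter must appear exactly 5 times")
        c = self.centers()
        radii = np.array([h.diameter_mm / 2.0 for h in self.holes])
        if np.any(
            np.hypot(c[:, 0], c[:, 1]) + radii + self.margin_mm
            > self.block_diameter_mm / 2.0 + 1e-9
        ):
            raise ValueError("hole extends beyond block margin")
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        if np.min(d2) < (self.min_spacing_mm - 1e-9) ** 2:
            raise ValueError("holes closer than min_spacing_mm")
        if self.min_spacing_mm <= self.max_diameter_mm:
            raise ValueError("min_spacing_mm must exceed the largest diameter")

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hole_id": np.arange(len(self.holes)),
                "diameter_mm": [h.diameter_mm for h in self.holes],
                "center_x_mm": [h.center_xy_mm[0] for h in self.holes],
                "center_y_mm": [h.center_xy_mm[1] for h in self.holes],
                "replicate_index": [h.replicate_index for h in self.holes],
            }
        )

    def to_csv(self, path) -> None:
        """Write the layout as CSV with a JSON header comment block."""
        header = {
            "block_diameter_mm": self.block_diameter_mm,
            "block_thickness_mm": self.block_thickness_mm,
            "min_spacing_mm": self.min_spacing_mm,
            "margin_mm": self.margin_mm,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "PhantomLayout":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise ValueError("missing JSON header line")
            header = json.loads(first[2:])
            df = pd.read_csv(io.StringIO(fh.read()))
        holes = tuple(
            HoleSpec(
                diameter_mm=float(r.diameter_mm),
                center_xy_mm=(float(r.center_x_mm), float(r.center_y_mm)),
                replicate_index=int(r.replicate_index),
            )
            for r in df.sort_values("hole_id").itertuples()
        )
        return cls(
            holes=holes,
            min_spacing_mm=float(header["min_spacing_mm"]),
            seed=int(header["seed"]),
            block_diameter_mm=float(header["block_diameter_mm"]),
            block_thickness_mm=float(header["block_thickness_mm"]),
            margin_mm=float(header.get("margin_mm", 4.0)),
        )


def build_layout(
    seed: int,
    min_spacing_mm: float = 6.0,
    margin_mm: float = 4.0,
    block_diameter_mm: float = BLOCK_DIAMETER_MM,
) -> PhantomLayout:
    """Generate a randomized, collision-free drilling layout.

    Sites live on a regular grid with pitch ``min_spacing_mm`` (so any two
    distinct sites automatically satisfy the spacing constraint) restricted to
    the disk where a hole of the largest diameter still fits inside the block
    with ``margin_mm`` clearance.  110 distinct sites are drawn with a seeded
    generator and the diameter ladder is assigned replicate by replicate.

    Raises
    ------
    LayoutInfeasibleError
        If the grid admits fewer than 110 sites ("layout infeasible").
    """
    if min_spacing_mm <= max(DIAMETERS_MM):
        raise ValueError("min_spacing_mm must exceed the largest hole diameter")
    r_max = max(DIAMETERS_MM) / 2.0
    usable = block_diameter_mm / 2.0 - margin_mm - r_max
    if usable <= 0:
        raise LayoutInfeasibleError("layout infeasible: margin exceeds block radius")
    pitch = min_spacing_mm
    n = int(math.floor(usable / pitch))
    axis = np.arange(-n, n + 1) * pitch
    gx, gy = np.meshgrid(axis, axis)
    keep = np.hypot(gx, gy) <= usable
    sites = np.column_stack([gx[keep], gy[keep]])
    if len(sites) < N_HOLES:
        raise LayoutInfeasibleError(
            f"layout infeasible: grid admits {len(sites)} sites, need {N_HOLES}"
        )
    rng = np.random.default_rng(seed)
    chosen = sites[rng.choice(len(sites), size=N_HOLES, replace=False)]
    holes = tuple(
        HoleSpec(
            diameter_mm=DIAMETERS_MM[k // N_REPLICATES],
            center_xy_mm=(float(chosen[k, 0]), float(chosen[k, 1])),
            replicate_index=k % N_REPLICATES + 1,
        )
        for k in range(N_HOLES)
    )
    layout = PhantomLayout(
        holes=holes,
        min_spacing_mm=min_spacing_mm,
        seed=seed,
        block_diameter_mm=block_diameter_mm,
        margin_mm=margin_mm,
    )
    layout.validate()
    return layout
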