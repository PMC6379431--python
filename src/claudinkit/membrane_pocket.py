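"""Membrane-frame estimation and cis-interaction pocket aperture.

The membrane normal is taken as the normalized mean of the four
transmembrane helix axes, each pre-oriented cytosolic→extracellular using
the topology of the bundle (in claudins TM1 and TM3 run in→out, TM2 and
TM4 out→in, so the axes of TM2/TM4 are flipped before averaging). The
pocket aperture is the extent of the cis-interaction pocket along that
normal: the upper rim (Phe146/Tyr147 on the extracellular edge of TM3, by
default) minus the lower rim (Glu158/Met159 on β5). Rim points are
side-chain heavy-atom centroids — robust at the 3.6–3.9 Å resolutions of
the claudin structures and symmetric across residue types, with a Cα
fallback for glycine. The width is signed (upper − lower) so a rim
inversion is detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateBundleError, MissingResidueError, ValidationError
from .helix_geometry import fit_axis
from .structure_io import StructureModel, select_calpha, sidechain_heavy_atoms

CLAUDIN_TM_RANGES: tuple[tuple[int, int], ...] = ((8, 27), (78, 98), (118, 149), (160, 182))
CLAUDIN_TM_TOPOLOGY: tuple[int, ...] = (1, -1, 1, -1)  # +1 = N→C runs in→out
DEFAULT_UPPER_RESIDUES: tuple[int, ...] = (146, 147)
DEFAULT_LOWER_RESIDUES: tuple[int, ...] = (158, 159)


@dataclass(frozen=True)
class MembraneFrame:
    """Unit membrane normal (cytosolic→extracellular) plus a reference offset."""

    normal: np.ndarray
    center_offset: float  # bundle centroid projected on the normal, Å


@dataclass(frozen=True)
class PocketAperture:
    upper_residues: tuple[int, ...]
    lower_residues: tuple[int, ...]
    upper_projection: float  # Å along the normal, relative to the bundle center
    lower_projection: float
    vertical_width: float  # = upper_projection − lower_projection (signed)
    per_residue_projections: dict[int, float]

    @property
    def abs_width(self) -> float:
        return abs(self.vertical_width)


def estimate_membrane_normal(
    model: StructureModel,
    tm_ranges: Sequence[tuple[int, int]] = CLAUDIN_TM_RANGES,
    chain: str | Sequence[str] = "A",
    topology: Sequence[int] = CLAUDIN_TM_TOPOLOGY,
) -> MembraneFrame:
    """Membrane normal from the mean of per-helix axis directions.

    ``chain`` may be a single chain id (all ranges on that chain) or one
    chain id per TM range (e.g. a synthetic bundle with one helix per
    chain). Each axis is multiplied by its topology sign (+1 in→out, −1
    out→in) before averaging so the mean points extracellular. A mean
    vector of norm < 0.5 means the helix directions nearly cancel and the
    bundle is degenerate.
    """
    if isinstance(chain, str):
        chains = [chain] * len(tm_ranges)
    else:
        chains = list(chain)
        if len(chains) != len(tm_ranges):
            raise ValidationError("need one chain per TM range (or one for all)")
    if len(topology) != len(tm_ranges):
        raise ValidationError("need one topology sign per TM range")
    directions = []
    all_coords = []
    for (lo, hi), ch, sign in zip(tm_ranges, chains, topology):
        trace = select_calpha(model, ch, (lo, hi))
        axis = fit_axis(trace.coords, (lo, hi))
        directions.append(float(np.sign(sign)) * axis.direction)
        all_coords.append(trace.coords)
    mean = np.mean(directions, axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < 0.5:
        raise DegenerateBundleError(
            f"mean helix direction has norm {norm:.3f} < 0.5; "
            "helix axes nearly cancel"
        )
    normal = mean / norm
    centroid = np.vstack(all_coords).mean(axis=0)
    return MembraneFrame(normal=normal, center_offset=float(centroid @ normal))


def pocket_vertical_width(
    model: StructureModel,
    frame: MembraneFrame,
    upper_residues: Sequence[int] = DEFAULT_UPPER_RESIDUES,
    lower_residues: Sequence[int] = DEFAULT_LOWER_RESIDUES,
    chain: str = "A",
) -> PocketAperture:
    """Signed pocket aperture along the membrane normal.

    Each rim point is the mean of its residues' side-chain heavy-atom
    centroids projected on the normal; width = upper − lower, so a bent
    TM3 that pushes the upper rim toward the bilayer narrows the width.
    """
    if not upper_residues or not lower_residues:
        raise ValidationError("upper and lower residue sets must be nonempty")
    projections: dict[int, float] = {}

    def rim_projection(residues: Sequence[int]) -> float:
        per_res = []
        missing = []
        for num in residues:
            atoms = sidechain_heavy_atoms(model, chain, num)
            if not atoms:
                missing.append(num)
                continue
            centroid = np.mean([a.position for a in atoms], axis=0)
            proj = float(centroid @ frame.normal) - frame.center_offset
            projections[num] = proj
            per_res.append(proj)
        if missing:
            raise MissingResidueError(
                f"chain {chain}: residues {missing} have no atoms for the pocket rim"
            )
        return float(np.mean(per_res))

    upper = rim_projection(upper_residues)
    lower = rim_projection(lower_residues)
    return PocketAperture(
        upper_residues=tuple(upper_residues),
        lower_residues=tuple(lower_residues),
        upper_projection=upper,
        lower_projection=lower,
        vertical_width=upper - lower,
        per_residue_projections=projections,
    )
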