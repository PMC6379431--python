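"""Least-squares superposition and per-residue displacement profiling.

Superposition is restricted to proper rotations (Kabsch with reflection
suppression). Core selection mirrors the "low-RMSD region" practice:
starting from the rigid transmembrane segments, residues whose deviation
exceeds a rejection threshold are iteratively dropped and the fit is
repeated until the core is stable. The converged transform is then applied
to the whole structure and per-residue Cα displacements are reported — on
a bent-vs-straight claudin pair this is the profile whose extracellular
maximum reaches several Å.

Correspondence between the two models is by identical author residue
number (same protein or point mutants); alignment-driven mapping is out of
scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import (
    EmptySelectionError,
    InsufficientPointsError,
    NonConvergenceError,
    ValidationError,
)
from .structure_io import StructureModel, select_calpha

_CORE_FLOOR_FRACTION = 0.2
_CORE_FLOOR_MIN = 3


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform p ↦ R p + t."""

    rotation: np.ndarray  # 3×3, det = +1
    translation: np.ndarray  # 3-vector, Å

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValidationError("rotation must be 3×3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValidationError("rotation is not orthogonal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValidationError("rotation is improper (det ≠ +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of Q onto P.

    Returns the transform minimizing RMSD(transform(Q), P) over proper
    rotations plus the achieved RMSD. Correspondence is by row. Reflections
    are suppressed by sign-correcting the smallest singular direction; for
    degenerate (collinear) inputs any minimizing proper rotation is
    accepted and the RMSD is still exact.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError("P and Q must be matching (n, 3) arrays")
    n = len(P)
    if n < 3:
        raise InsufficientPointsError(f"superposition needs ≥ 3 points, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = pc - R @ qc
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(Q) - P) ** 2, axis=1))))
    return transform, rmsd


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    core_residues: set[int]
    core_rmsd: float
    iterations: int
    rejected_residues: set[int]
    chain_map: dict[str, str]
    trace: list[tuple[int, int, float]] = field(default_factory=list)


def _paired_coords(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_map: Mapping[str, str],
    residues: Iterable[int],
) -> tuple[list[int], np.ndarray, np.ndarray]:
    """Cα pairs for the given residue numbers across all mapped chains.

    Residue numbers index positions within each mapped chain pair; a
    residue is used only where both chains have its Cα.
    """
    nums: list[int] = []
    pa: list[np.ndarray] = []
    pb: list[np.ndarray] = []
    wanted = sorted(set(residues))
    for ca_chain, cb_chain in chain_map.items():
        lookup_a = _ca_lookup(model_a, ca_chain, wanted)
        lookup_b = _ca_lookup(model_b, cb_chain, wanted)
        for num in wanted:
            if num in lookup_a and num in lookup_b:
                nums.append(num)
                pa.append(lookup_a[num])
                pb.append(lookup_b[num])
    return nums, np.asarray(pa, dtype=float), np.asarray(pb, dtype=float)


def _ca_lookup(model: StructureModel, chain: str, wanted: list[int]) -> dict[int, np.ndarray]:
    if not wanted:
        return {}
    try:
        trace = select_calpha(model, chain, (min(wanted), max(wanted)))
    except EmptySelectionError:
        return {}
    return dict(zip(trace.residue_numbers, trace.coords))


def normalize_chain_map(chain_map) -> dict[str, str]:
    if isinstance(chain_map, Mapping):
        return dict(chain_map)
    if isinstance(chain_map, (tuple, list)) and len(chain_map) == 2:
        return {chain_map[0]: chain_map[1]}
    raise ValidationError("chain_map must be a {chain_a: chain_b} mapping or a pair")


def core_superpose(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_map,
    initial_core: Iterable[int],
    reject_threshold: float = 2.0,
    max_iter: int = 20,
    adaptive: bool = False,
) -> SuperpositionResult:
    """Iterative low-RMSD-core superposition of model_b onto model_a.

    Fit Kabsch on the current core, compute per-residue Cα deviations, drop
    residues deviating by more than ``reject_threshold`` Å (or, in adaptive
    mode, more than 2× the current core RMSD), and repeat until the core is
    stable or ``max_iter`` is reached. If a rejection round would shrink
    the core below its floor (20% of the initial core, minimum 3), a
    :class:`NonConvergenceError` carrying the iteration trace is raised.
    """
    chain_map = normalize_chain_map(chain_map)
    initial = sorted(set(initial_core))
    nums, _, _ = _paired_coords(model_a, model_b, chain_map, initial)
    if len(nums) < 3:
        raise InsufficientPointsError(
            f"only {len(nums)} initial-core residues have Cα in both models"
        )
    floor = max(_CORE_FLOOR_MIN, math.ceil(_CORE_FLOOR_FRACTION * len(nums)))
    core = list(nums)
    trace: list[tuple[int, int, float]] = []
    transform = RigidTransform.identity()
    rmsd = float("inf")
    iterations = 0
    for iteration in range(1, max_iter + 1):
        iterations = iteration
        core_nums, pa, pb = _paired_coords(model_a, model_b, chain_map, core)
        transform, rmsd = kabsch(pa, pb)
        dev = np.linalg.norm(transform.apply(pb) - pa, axis=1)
        threshold = max(2.0 * rmsd, 1e-6) if adaptive else reject_threshold
        keep = [num for num, d in zip(core_nums, dev) if d <= threshold]
        trace.append((iteration, len(core_nums), rmsd))
        if len(keep) == len(core_nums):
            break
        if len(keep) < floor:
            raise NonConvergenceError(
                f"core shrank to {len(keep)} residues (floor {floor}) at "
                f"iteration {iteration}",
                trace=trace,
            )
        core = keep
    return SuperpositionResult(
        transform=transform,
        core_residues=set(core),
        core_rmsd=rmsd,
        iterations=iterations,
        rejected_residues=set(nums) - set(core),
        chain_map=chain_map,
        trace=trace,
    )


@dataclass
class DisplacementProfile:
    """Per-residue Cα displacement after applying a superposition transform."""

    displacements: dict[int, float]
    max_shift: tuple[int, float]  # (residue, Å)

    def max_over(self, residues: Iterable[int]) -> tuple[int, float]:
        """Maximum displacement restricted to a residue subset."""
        subset = {r: d for r, d in self.displacements.items() if r in set(residues)}
        if not subset:
            raise EmptySelectionError("no profiled residues in the requested subset")
        best = max(subset, key=subset.get)
        return best, subset[best]


def displacement_profile(
    model_a: StructureModel,
    model_b: StructureModel,
    result: SuperpositionResult,
    residues: Iterable[int],
) -> DisplacementProfile:
    """Per-residue |Cα_a − transform(Cα_b)| over the requested residues."""
    nums, pa, pb = _paired_coords(model_a, model_b, result.chain_map, residues)
    if not nums:
        raise EmptySelectionError("no residues present with Cα in both models")
    disp = np.linalg.norm(result.transform.apply(pb) - pa, axis=1)
    profile = {num: float(d) for num, d in zip(nums, disp)}
    best = max(profile, key=profile.get)
    return DisplacementProfile(displacements=profile, max_shift=(best, profile[best]))
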