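"""Synthetic coordinate generators with known ground truth.

Every geometric stage of the toolkit is tested against fixtures built here:
ideal α-helices (known axis), kinked helices (known bend angle and vertex),
rigid two-domain pairs (known core and known mobile-domain displacement),
helix bundles (known mean axis) and per-atom B-factor assignments (known
chain offsets). Generators are deterministic given a seed; changing only
the seed changes only the noise terms.

Default helix parameters are canonical α-helix values: 1.5 Å rise and 100°
twist per residue, 2.3 Å Cα radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import GenerationError, ValidationError
from .structure_io import AtomRecord, StructureModel

_CLASH_CUTOFF = 2.0  # Å; nonbonded Cα pairs closer than this are a clash


@dataclass(frozen=True)
class HelixSpec:
    """Geometry of a regular helical Cα curve."""

    n_residues: int
    rise_per_residue: float = 1.5
    twist_per_residue: float = 100.0
    radius: float = 2.3
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: float = 0.0  # degrees; azimuth of the first residue

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValidationError("n_residues must be ≥ 5")
        if self.rise_per_residue <= 0 or self.radius <= 0:
            raise ValidationError("rise and radius must be positive")
        norm = float(np.linalg.norm(self.axis_direction))
        if not np.isclose(norm, 1.0, atol=1e-6):
            raise ValidationError("axis_direction must be a unit vector")


@dataclass(frozen=True)
class KinkSpec:
    """A helix with a rigid kink of known angle at a known vertex residue."""

    helix: HelixSpec
    vertex_index: int  # 1-based residue position within the helix
    kink_angle: float  # degrees, [0, 180)
    kink_plane_azimuth: float = 0.0  # degrees, orientation of the bend plane

    def __post_init__(self) -> None:
        if not 1 < self.vertex_index < self.helix.n_residues:
            raise ValidationError(
                f"vertex_index {self.vertex_index} must lie strictly inside "
                f"1..{self.helix.n_residues}"
            )
        if not 0.0 <= self.kink_angle < 180.0:
            raise ValidationError("kink_angle must be in [0, 180)")


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return axis_angle_rotation(axis, 180.0)
    K = _skew(v)
    return np.eye(3) + K + K @ K / (1.0 + c)


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float)


def axis_angle_rotation(axis: Sequence[float], angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    k = np.asarray(axis, dtype=float)
    k = k / np.linalg.norm(k)
    th = np.deg2rad(angle_deg)
    K = _skew(k)
    return np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)


def _calpha_model(
    identifier: str, chain: str, numbers: Sequence[int], coords: np.ndarray, b: float = 20.0
) -> StructureModel:
    atoms = [
        AtomRecord(chain, int(num), "", "ALA", "CA", "", 1.0, b, pos, "C")
        for num, pos in zip(numbers, coords)
    ]
    return StructureModel(identifier, atoms)


def helix_curve(spec: HelixSpec) -> np.ndarray:
    """Cα positions of the ideal helix, residue i at parameter i-1."""
    i = np.arange(spec.n_residues)
    t = np.deg2rad(spec.twist_per_residue * i + spec.phase)
    local = np.column_stack(
        [
            spec.radius * np.cos(t),
            spec.radius * np.sin(t),
            spec.rise_per_residue * i,
        ]
    )
    R = _rotation_between(np.array([0.0, 0.0, 1.0]), np.asarray(spec.axis_direction, float))
    return local @ R.T + np.asarray(spec.origin, dtype=float)


def make_ideal_helix(spec: HelixSpec, chain: str = "A", start_residue: int = 1) -> StructureModel:
    """Cα-only model of a regular helix about the given axis, residues 1..n."""
    coords = helix_curve(spec)
    numbers = range(start_residue, start_residue + spec.n_residues)
    return _calpha_model("ideal-helix", chain, list(numbers), coords)


def make_kinked_helix(spec: KinkSpec, chain: str = "A") -> StructureModel:
    """Helix whose distal arm is rigidly rotated by ``kink_angle`` at the vertex.

    The proximal arm is the ideal helix; residues after the vertex are the
    ideal continuation rotated about an axis perpendicular to the helix axis
    through the vertex Cα (azimuth selects which perpendicular), so the
    vertex-anchored bend angle of the result equals ``kink_angle`` exactly
    by construction. The chain stays continuous at the vertex.
    """
    h = spec.helix
    coords = helix_curve(h)
    axis = np.asarray(h.axis_direction, dtype=float)
    # a unit vector perpendicular to the helix axis, rotated by the azimuth
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    perp = axis_angle_rotation(axis, spec.kink_plane_azimuth) @ perp
    R = axis_angle_rotation(perp, spec.kink_angle)
    pivot = coords[spec.vertex_index - 1]
    out = coords.copy()
    out[spec.vertex_index :] = (coords[spec.vertex_index :] - pivot) @ R.T + pivot
    d = np.linalg.norm(np.diff(out, axis=0), axis=1)
    if np.any(d > 4.2):
        raise GenerationError("chain break at the kink (consecutive Cα > 4.2 Å)")
    _check_self_intersection(out)
    return _calpha_model("kinked-helix", chain, list(range(1, h.n_residues + 1)), out)


def _check_self_intersection(coords: np.ndarray) -> None:
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    i, j = np.triu_indices(n, k=2)  # nonbonded: sequence separation ≥ 2
    if np.any(dist[i, j] < _CLASH_CUTOFF):
        raise GenerationError(
            f"self-intersection: nonbonded Cα pair closer than {_CLASH_CUTOFF} Å"
        )


@dataclass
class DomainPair:
    """Two copies of a core∪mobile structure with a known mobile displacement."""

    model_a: StructureModel
    model_b: StructureModel
    true_displacement: dict[int, float]  # residue → Å, noise-free ground truth
    core_residues: set[int]
    mobile_residues: set[int]


def make_domain_pair(
    core: StructureModel,
    mobile: StructureModel,
    rotation: np.ndarray | None = None,
    translation: Sequence[float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DomainPair:
    """Rigid two-domain pair: B's mobile domain is transformed, A's is not.

    ``core`` and ``mobile`` must share a chain id and no residue numbers.
    Isotropic Gaussian noise of sd ``noise_sd`` is added to every atom of B.
    The noise-free per-residue displacement of the mobile atoms is returned
    as the oracle for displacement profiling.
    """
    chains = set(a.chain_id for a in core.atoms) | set(a.chain_id for a in mobile.atoms)
    if len(chains) != 1:
        raise ValidationError("core and mobile must share a single chain id")
    core_res = {a.residue_number for a in core.atoms}
    mobile_res = {a.residue_number for a in mobile.atoms}
    if core_res & mobile_res:
        raise ValidationError(
            f"core and mobile share residue numbers {sorted(core_res & mobile_res)}"
        )
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-9) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-9
    ):
        raise ValidationError("rotation must be proper orthogonal")
    rng = np.random.default_rng(seed)
    atoms_a = list(core.atoms) + list(mobile.atoms)
    moved = {a.key: R @ a.position + t for a in mobile.atoms}
    truth: dict[int, float] = {}
    for a in mobile.atoms:
        if a.atom_name == "CA":
            truth[a.residue_number] = float(np.linalg.norm(moved[a.key] - a.position))
    atoms_b = []
    for a in atoms_a:
        pos = moved.get(a.key, a.position).copy()
        if noise_sd > 0:
            pos = pos + rng.normal(0.0, noise_sd, 3)
        atoms_b.append(
            AtomRecord(
                a.chain_id,
                a.residue_number,
                a.insertion_code,
                a.residue_name,
                a.atom_name,
                a.altloc,
                a.occupancy,
                a.b_factor,
                pos,
                a.element,
            )
        )
    model_a = StructureModel("domain-pair-a", atoms_a)
    model_b = StructureModel("domain-pair-b", atoms_b)
    return DomainPair(model_a, model_b, truth, core_res, mobile_res)


def make_helix_bundle(
    n_helices: int,
    tilt_angles: Sequence[float],
    spacing: float = 10.0,
    n_residues: int = 20,
    tilt_azimuth: float = 0.0,
) -> StructureModel:
    """Parallel-packed helix bundle, one chain per helix (A, B, C, ...).

    Each helix is tilted from z by its listed (signed) angle about a common
    azimuthal axis, so the analytic mean axis is known
    (:func:`bundle_mean_axis`). Helix origins sit on a circle of radius
    ``spacing`` in the xy plane.
    """
    if n_helices < 2:
        raise ValidationError("a bundle needs at least 2 helices")
    if len(tilt_angles) != n_helices:
        raise ValidationError("one tilt angle per helix required")
    tilt_axis = axis_angle_rotation((0, 0, 1), tilt_azimuth) @ np.array([1.0, 0.0, 0.0])
    atoms: list[AtomRecord] = []
    coords_per_chain = []
    for k in range(n_helices):
        direction = axis_angle_rotation(tilt_axis, tilt_angles[k]) @ np.array([0.0, 0.0, 1.0])
        phi = 2.0 * np.pi * k / n_helices
        origin = (spacing * np.cos(phi), spacing * np.sin(phi), 0.0)
        spec = HelixSpec(
            n_residues=n_residues,
            axis_direction=tuple(direction),
            origin=origin,
        )
        coords = helix_curve(spec)
        coords_per_chain.append(coords)
        chain = chr(ord("A") + k)
        for i, pos in enumerate(coords, start=1):
            atoms.append(AtomRecord(chain, i, "", "ALA", "CA", "", 1.0, 20.0, pos, "C"))
    for k in range(n_helices):
        for m in range(k + 1, n_helices):
            diff = coords_per_chain[k][:, None, :] - coords_per_chain[m][None, :, :]
            if np.min(np.linalg.norm(diff, axis=-1)) < _CLASH_CUTOFF:
                raise GenerationError(
                    f"helices {k} and {m} clash at spacing {spacing} Å"
                )
    return StructureModel("helix-bundle", atoms)


def bundle_mean_axis(tilt_angles: Sequence[float], tilt_azimuth: float = 0.0) -> np.ndarray:
    """Analytic mean direction of the bundle built by :func:`make_helix_bundle`."""
    tilt_axis = axis_angle_rotation((0, 0, 1), tilt_azimuth) @ np.array([1.0, 0.0, 0.0])
    dirs = [
        axis_angle_rotation(tilt_axis, t) @ np.array([0.0, 0.0, 1.0]) for t in tilt_angles
    ]
    mean = np.mean(dirs, axis=0)
    return mean / np.linalg.norm(mean)


def assign_bfactors(
    model: StructureModel,
    per_chain_offset: Mapping[str, float],
    gradient_along_z: float = 0.0,
    base: float = 20.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> StructureModel:
    """Copy of the model with B = base + chain offset + gradient·z + jitter.

    Gaussian jitter of sd ``jitter_sd`` is drawn with the given seed; B is
    clamped at 0.
    """
    for chain in per_chain_offset:
        if not model.has_chain(chain):
            raise ValidationError(f"chain {chain!r} not in model")
    rng = np.random.default_rng(seed)
    atoms = []
    for a in model.atoms:
        b = base + per_chain_offset.get(a.chain_id, 0.0) + gradient_along_z * a.position[2]
        if jitter_sd > 0:
            b += rng.normal(0.0, jitter_sd)
        atoms.append(a.with_b_factor(max(b, 0.0)))
    return StructureModel(model.identifier, atoms)
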