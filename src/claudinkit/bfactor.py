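"""Per-chain B-factor profiles and within-ASU chain comparison.

Crystallographic B-factors are used as a proxy for local flexibility: in
the claudin-3 crystals the asymmetric unit holds two copies of the
molecule (chains A and C), and comparing their B-factor profiles asks
whether one copy is systematically more mobile than the other. The
comparison is strictly within one asymmetric unit — no cross-crystal
normalization is attempted, and deposited isotropic B values are taken at
face value.

Backbone scope (N, CA, C, O) is the default: at ~4 Å resolution
side-chain disorder would dominate an all-atom average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptySelectionError, LookupError_, ValidationError
from .structure_io import StructureModel

_BACKBONE = frozenset({"N", "CA", "C", "O"})


@dataclass
class BfactorProfile:
    chain_id: str
    per_residue: dict[int, float]  # residue → mean B over the atom scope, Å²
    mean: float  # model-level mean over the profiled atoms
    sd: float


@dataclass
class ChainBfactorComparison:
    chain_a: str
    chain_b: str
    mean_delta: float  # mean of B(chain_b) − B(chain_a) over shared residues
    per_residue_delta: dict[int, float]
    fraction_b_higher: float  # ties count 0.5 each
    n_shared: int


def chain_bfactor_profile(
    model: StructureModel, chain: str, atom_scope: str = "backbone"
) -> BfactorProfile:
    """Per-residue mean B-factor of one chain.

    ``atom_scope`` is ``backbone`` (N, CA, C, O) or ``all`` (all heavy
    atoms). Waters and hydrogens are excluded; residues with no atoms in
    scope are omitted.
    """
    if atom_scope not in ("backbone", "all"):
        raise ValidationError(f"atom_scope must be 'backbone' or 'all', got {atom_scope!r}")
    if not model.has_chain(chain):
        raise LookupError_(f"chain {chain!r} not in {sorted(model.chains)}")
    per_residue: dict[int, float] = {}
    all_bs: list[float] = []
    for num in model.residue_numbers(chain):
        atoms = [
            a
            for a in model.residue_atoms(chain, num)
            if not a.is_water
            and not a.is_hydrogen
            and (atom_scope == "all" or a.atom_name in _BACKBONE)
        ]
        if not atoms:
            continue
        bs = [a.b_factor for a in atoms]
        per_residue[num] = float(np.mean(bs))
        all_bs.extend(bs)
    if not per_residue:
        raise EmptySelectionError(f"chain {chain}: no atoms in scope {atom_scope!r}")
    return BfactorProfile(
        chain_id=chain,
        per_residue=per_residue,
        mean=float(np.mean(all_bs)),
        sd=float(np.std(all_bs)),
    )


def compare_chains(
    model: StructureModel,
    chain_a: str,
    chain_b: str,
    region: tuple[int, int] | None = None,
    atom_scope: str = "backbone",
) -> ChainBfactorComparison:
    """B-factor difference profile between two chains of one model.

    delta = B(chain_b) − B(chain_a) per residue shared by both chains,
    optionally restricted to ``region``. Without a region, at least 10
    shared residues are required. ``fraction_b_higher`` counts exact ties
    as 0.5 each, so identical chains score exactly 0.5.
    """
    prof_a = chain_bfactor_profile(model, chain_a, atom_scope)
    prof_b = chain_bfactor_profile(model, chain_b, atom_scope)
    shared = sorted(set(prof_a.per_residue) & set(prof_b.per_residue))
    if region is not None:
        lo, hi = region
        shared = [n for n in shared if lo <= n <= hi]
        if not shared:
            raise EmptySelectionError(
                f"chains {chain_a}/{chain_b} share no residues in region {region}"
            )
    elif len(shared) < 10:
        raise ValidationError(
            f"chains {chain_a} and {chain_b} share only {len(shared)} residues (< 10)"
        )
    delta = {n: prof_b.per_residue[n] - prof_a.per_residue[n] for n in shared}
    values = np.array(list(delta.values()))
    higher = float(np.sum(values > 0) + 0.5 * np.sum(values == 0)) / len(values)
    return ChainBfactorComparison(
        chain_a=chain_a,
        chain_b=chain_b,
        mean_delta=float(values.mean()),
        per_residue_delta=delta,
        fraction_b_higher=higher,
        n_shared=len(shared),
    )
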