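"""End-to-end analysis orchestration and fixture generation.

`run_report` loads one to three structures named in an
:class:`AnalysisConfig`, measures per-structure quantities (per-chain and
mean TM3 bend angles, membrane frame, pocket aperture, within-ASU B-factor
comparison), and for every structure pair computes the low-RMSD-core
superposition, the per-residue displacement profile with its extracellular
maximum, the bend-angle difference and the pocket-width difference. The
result is a single JSON-serializable report; stages are isolated so that a
failure in one is recorded without discarding the others. Reports are
deterministic given config and seed (no timestamps).

Defaults are the claudin-3 profile: vertex 134, proximal arm 118–133,
distal arm 135–149, rigid TMD core segments 1–27 / 78–133 / 160–200 minus
the distal arm, ECD 28–77, pocket rims {146, 147} / {158, 159}.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np

from . import bfactor, binding, helix_geometry, membrane_pocket, superposition
from .errors import ClaudinkitError, ValidationError
from .structure_io import StructureModel, read_structure, write_pdb
from .synthetic import (
    HelixSpec,
    KinkSpec,
    assign_bfactors,
    bundle_mean_axis,
    make_domain_pair,
    make_helix_bundle,
    make_ideal_helix,
    make_kinked_helix,
)

SCHEMA_VERSION = "1"

DEFAULT_CORE_RANGES: tuple[tuple[int, int], ...] = ((1, 27), (78, 133), (160, 200))


@dataclass
class StructureEntry:
    path: str
    label: str
    chains: tuple[str, ...] = ("A", "C")


@dataclass
class AnalysisConfig:
    """Full configuration of one analysis run; serialized into the report."""

    structures: list[StructureEntry] = field(default_factory=list)
    vertex_residue: int = 134
    proximal_range: tuple[int, int] = (118, 133)
    distal_range: tuple[int, int] = (135, 149)
    initial_core_ranges: tuple[tuple[int, int], ...] = DEFAULT_CORE_RANGES
    reject_threshold: float = 2.0
    adaptive_core: bool = False
    tm_ranges: tuple[tuple[int, int], ...] = membrane_pocket.CLAUDIN_TM_RANGES
    tm_topology: tuple[int, ...] = membrane_pocket.CLAUDIN_TM_TOPOLOGY
    upper_residues: tuple[int, ...] = membrane_pocket.DEFAULT_UPPER_RESIDUES
    lower_residues: tuple[int, ...] = membrane_pocket.DEFAULT_LOWER_RESIDUES
    ecd_range: tuple[int, int] = (28, 77)
    bfactor_scope: str = "backbone"
    bfactor_chain_pair: tuple[str, str] = ("A", "C")
    binding_csv: str | None = None
    seed: int = 0

    def initial_core(self) -> set[int]:
        """Core residues: the rigid TMD segments minus the distal TM3 arm."""
        core: set[int] = set()
        for lo, hi in self.initial_core_ranges:
            core.update(range(lo, hi + 1))
        core -= set(range(self.distal_range[0], self.distal_range[1] + 1))
        return core

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        structures = [
            StructureEntry(
                path=s["path"], label=s["label"], chains=tuple(s.get("chains", ("A", "C")))
            )
            for s in raw.get("structures", [])
        ]
        kwargs = {k: v for k, v in raw.items() if k != "structures"}
        for key in (
            "proximal_range",
            "distal_range",
            "ecd_range",
            "bfactor_chain_pair",
            "upper_residues",
            "lower_residues",
            "tm_topology",
        ):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("initial_core_ranges", "tm_ranges"):
            if key in kwargs:
                kwargs[key] = tuple(tuple(r) for r in kwargs[key])
        return cls(structures=structures, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(report_section: dict, name: str, fn):
    """Run one stage; on failure record the error and keep going."""
    try:
        report_section[name] = fn()
        return True
    except ClaudinkitError as exc:
        report_section.setdefault("errors", {})[name] = str(exc)
        return False


def _bend_section(model: StructureModel, entry: StructureEntry, cfg: AnalysisConfig) -> dict:
    result = helix_geometry.mean_bend(
        model, entry.chains, cfg.proximal_range, cfg.vertex_residue, cfg.distal_range
    )
    return {
        "per_chain": {c: round(m.angle, 3) for c, m in result.per_chain.items()},
        "mean_angle": round(result.mean_angle, 3),
        "vertex_residue": cfg.vertex_residue,
    }


def _frame_and_pocket(model: StructureModel, entry: StructureEntry, cfg: AnalysisConfig) -> dict:
    chain = entry.chains[0]
    frame = membrane_pocket.estimate_membrane_normal(
        model, cfg.tm_ranges, chain, cfg.tm_topology
    )
    aperture = membrane_pocket.pocket_vertical_width(
        model, frame, cfg.upper_residues, cfg.lower_residues, chain
    )
    return {
        "chain": chain,
        "normal": [round(x, 6) for x in frame.normal],
        "upper_projection": round(aperture.upper_projection, 3),
        "lower_projection": round(aperture.lower_projection, 3),
        "vertical_width": round(aperture.vertical_width, 3),
        "abs_width": round(aperture.abs_width, 3),
        "per_residue_projections": {
            str(k): round(v, 3) for k, v in aperture.per_residue_projections.items()
        },
    }


def _bfactor_section(model: StructureModel, cfg: AnalysisConfig) -> dict:
    a, b = cfg.bfactor_chain_pair
    cmp_ = bfactor.compare_chains(model, a, b, atom_scope=cfg.bfactor_scope)
    return {
        "chain_a": a,
        "chain_b": b,
        "mean_delta": round(cmp_.mean_delta, 3),
        "fraction_b_higher": round(cmp_.fraction_b_higher, 4),
        "n_shared": cmp_.n_shared,
    }


def _pair_section(
    label_a: str,
    model_a: StructureModel,
    chains_a: Sequence[str],
    label_b: str,
    model_b: StructureModel,
    chains_b: Sequence[str],
    cfg: AnalysisConfig,
    bend_by_label: dict[str, float],
    width_by_label: dict[str, float],
) -> dict:
    section: dict[str, Any] = {}
    chain_map = {chains_a[0]: chains_b[0]}

    def superpose():
        result = superposition.core_superpose(
            model_a,
            model_b,
            chain_map,
            cfg.initial_core(),
            reject_threshold=cfg.reject_threshold,
            adaptive=cfg.adaptive_core,
        )
        section["_result"] = result
        return {
            "chain_map": chain_map,
            "core_rmsd": round(result.core_rmsd, 4),
            "iterations": result.iterations,
            "n_core": len(result.core_residues),
            "n_rejected": len(result.rejected_residues),
            "rotation": [[round(x, 8) for x in row] for row in result.transform.rotation],
            "translation": [round(x, 6) for x in result.transform.translation],
        }

    def profile():
        result = section.pop("_result")
        lo, hi = cfg.ecd_range
        prof = superposition.displacement_profile(
            model_a, model_b, result, range(lo, hi + 1)
        )
        res, shift = prof.max_shift
        return {
            "ecd_range": list(cfg.ecd_range),
            "per_residue": {str(k): round(v, 3) for k, v in prof.displacements.items()},
            "max_shift_residue": res,
            "max_shift": round(shift, 3),
        }

    ok = _stage(section, "superposition", superpose)
    if ok:
        _stage(section, "displacement", profile)
    section.pop("_result", None)
    if label_a in bend_by_label and label_b in bend_by_label:
        section["bend_difference"] = round(
            bend_by_label[label_a] - bend_by_label[label_b], 3
        )
    if label_a in width_by_label and label_b in width_by_label:
        section["pocket_width_difference"] = round(
            width_by_label[label_a] - width_by_label[label_b], 3
        )
    return section


def run_report(config: AnalysisConfig) -> dict:
    """Execute every applicable stage and assemble the JSON report.

    The report carries a ``status`` of ``ok`` or ``partial``; partial means
    at least one stage recorded an error (the CLI maps this to exit 2).
    """
    report: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "structures": {},
        "pairs": {},
    }
    models: dict[str, tuple[StructureModel, StructureEntry]] = {}
    bend_by_label: dict[str, float] = {}
    width_by_label: dict[str, float] = {}
    for entry in config.structures:
        section: dict[str, Any] = {}
        report["structures"][entry.label] = section
        try:
            model = read_structure(entry.path)
        except ClaudinkitError as exc:
            section.setdefault("errors", {})["load"] = str(exc)
            continue
        models[entry.label] = (model, entry)
        if _stage(section, "bend", lambda m=model, e=entry: _bend_section(m, e, config)):
            bend_by_label[entry.label] = section["bend"]["mean_angle"]
        if _stage(
            section, "pocket", lambda m=model, e=entry: _frame_and_pocket(m, e, config)
        ):
            width_by_label[entry.label] = section["pocket"]["vertical_width"]
        _stage(section, "bfactor", lambda m=model: _bfactor_section(m, config))
    labels = [e.label for e in config.structures if e.label in models]
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            la, lb = labels[i], labels[j]
            ma, ea = models[la]
            mb, eb = models[lb]
            report["pairs"][f"{la}__vs__{lb}"] = _pair_section(
                la, ma, ea.chains, lb, mb, eb.chains, config, bend_by_label, width_by_label
            )
    if config.binding_csv:
        _stage(report, "binding", lambda: _binding_section(config))
    report["status"] = "partial" if _has_errors(report) else "ok"
    return report


def _binding_section(cfg: AnalysisConfig) -> dict:
    conc, bound, unbound = binding.read_binding_csv(cfg.binding_csv)
    fractions = binding.normalize_peaks(bound, unbound, saturating_index=-1)
    series = binding.BindingSeries(conc, fractions, saturating_index=-1)
    fit = binding.fit_one_site(series)
    return {
        "kd_uM": round(fit.kd, 6),
        "rss": round(fit.rss, 8),
        "converged": fit.converged,
        "n_points": len(conc),
    }


def _has_errors(node) -> bool:
    if isinstance(node, dict):
        return any(k == "errors" and v for k, v in node.items()) or any(
            _has_errors(v) for v in node.values()
        )
    return False


# ---------------------------------------------------------------------------
# Fixture generation


def make_fixtures(kind: str, parameters: dict | None, seed: int, out_dir: str | Path) -> dict:
    """Write synthetic fixtures plus a sidecar truth JSON; returns the truth.

    Kinds: ``kinked_pair`` (bent + straight helices of known angles),
    ``domain_pair`` (rigid core + translated mobile domain), ``bundle``
    (four-helix bundle of known mean axis), ``binding`` (titration CSV of
    known Kd). Outputs are byte-identical for identical seed and
    parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = dict(parameters or {})
    builders = {
        "kinked_pair": _fixture_kinked_pair,
        "domain_pair": _fixture_domain_pair,
        "bundle": _fixture_bundle,
        "binding": _fixture_binding,
    }
    if kind not in builders:
        raise ValidationError(f"unknown fixture kind {kind!r}; choose from {sorted(builders)}")
    truth = builders[kind](params, seed, out)
    truth["kind"] = kind
    truth["seed"] = seed
    (out / f"{kind}_truth.json").write_text(json.dumps(truth, sort_keys=True, indent=2))
    return truth


def _fixture_kinked_pair(params: dict, seed: int, out: Path) -> dict:
    theta_a = float(params.get("theta_a", 25.0))
    theta_b = float(params.get("theta_b", 17.0))
    n = int(params.get("n_residues", 37))
    vertex = int(params.get("vertex_index", 19))
    azimuth = float(params.get("kink_plane_azimuth", 0.0))
    files = {}
    for name, theta in (("bent", theta_a), ("straight", theta_b)):
        spec = KinkSpec(
            helix=HelixSpec(n_residues=n),
            vertex_index=vertex,
            kink_angle=theta,
            kink_plane_azimuth=azimuth,
        )
        model = make_kinked_helix(spec, chain="A")
        path = out / f"kinked_{name}.pdb"
        write_pdb(model, path)
        files[name] = path.name
    return {
        "files": files,
        "theta_a": theta_a,
        "theta_b": theta_b,
        "n_residues": n,
        "vertex_index": vertex,
        "proximal_range": [1, vertex - 1],
        "distal_range": [vertex + 1, n],
    }


def _fixture_domain_pair(params: dict, seed: int, out: Path) -> dict:
    shift = float(params.get("translation", 5.0))
    noise_sd = float(params.get("noise_sd", 0.0))
    n_core = int(params.get("n_core", 30))
    n_mobile = int(params.get("n_mobile", 20))
    core = make_ideal_helix(HelixSpec(n_residues=n_core), chain="A")
    mobile = make_ideal_helix(
        HelixSpec(n_residues=n_mobile, origin=(12.0, 0.0, 0.0)),
        chain="A",
        start_residue=n_core + 11,
    )
    pair = make_domain_pair(
        core, mobile, translation=(shift, 0.0, 0.0), noise_sd=noise_sd, seed=seed
    )
    write_pdb(pair.model_a, out / "domain_a.pdb")
    write_pdb(pair.model_b, out / "domain_b.pdb")
    return {
        "files": {"a": "domain_a.pdb", "b": "domain_b.pdb"},
        "translation": shift,
        "noise_sd": noise_sd,
        "core_residues": sorted(pair.core_residues),
        "mobile_residues": sorted(pair.mobile_residues),
        "true_displacement": {str(k): round(v, 6) for k, v in pair.true_displacement.items()},
    }


def _fixture_bundle(params: dict, seed: int, out: Path) -> dict:
    tilts = [float(t) for t in params.get("tilt_angles", (10.0, -10.0, 10.0, -10.0))]
    spacing = float(params.get("spacing", 10.0))
    model = make_helix_bundle(len(tilts), tilts, spacing=spacing)
    if params.get("bfactor_offsets"):
        model = assign_bfactors(
            model,
            {str(k): float(v) for k, v in params["bfactor_offsets"].items()},
            seed=seed,
        )
    write_pdb(model, out / "bundle.pdb")
    return {
        "files": {"bundle": "bundle.pdb"},
        "tilt_angles": tilts,
        "spacing": spacing,
        "mean_axis": [round(x, 9) for x in bundle_mean_axis(tilts)],
    }


def _fixture_binding(params: dict, seed: int, out: Path) -> dict:
    kd = float(params.get("kd", 0.05))
    noise_sd = float(params.get("noise_sd", 0.0))
    conc = [float(c) for c in params.get(
        "concentrations", (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0)
    )]
    series = binding.simulate_binding(kd, conc, noise_sd=noise_sd, seed=seed)
    total = 100.0  # arbitrary chromatogram scale
    lines = ["concentration_uM,bound_height,unbound_height"]
    for c, f in zip(series.ligand_concentrations, series.fraction_bound):
        lines.append(f"{c:.6g},{f * total:.6f},{(1.0 - f) * total:.6f}")
    (out / "binding.csv").write_text("\n".join(lines) + "\n")
    return {
        "files": {"binding": "binding.csv"},
        "kd": kd,
        "noise_sd": noise_sd,
        "concentrations": conc,
    }


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
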