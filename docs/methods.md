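# Methods

This note documents the models, estimators and numerical choices behind
claudinkit, what the synthetic generators do and do not emulate, and the
known limitations of each stage.

## Coordinate model

Structures are read through gemmi (PDB and mmCIF) into a flat atom list
indexed by author chain id and author residue number — the numbering in
which claudin residues (Pro134, Phe146, Glu158, …) are always cited. Only
the first model block is used; hydrogens and waters never enter geometry.
Altloc selection takes the highest-occupancy conformer, breaking ties
toward the lexicographically first altloc, so selections are deterministic.
Insertion codes are carried through I/O but rejected inside geometry
ranges, since claudin numbering has none; a structure that did contain them
there would need renumbering before analysis. Gaps (e.g. the disordered
region around residues 66–70 in the wild-type claudin-3 crystal) are
reported by every selection, and an arm or range is usable only while at
least 80% of its residues retain a Cα.

## Helix-axis estimation

The bend angle relies on the direction of an axis fitted to a short
(~15-residue) helical arm, and the estimator matters more than it first
appears. The naive choice — the principal eigenvector of the centered Cα
covariance — is biased whenever the arm spans a non-integer number of
helical turns: the uncancelled first-harmonic wobble couples into the
eigenvector, tilting it by up to ~2.3° for 12–18-residue arms (a helix of
100°/residue twist cancels exactly only at multiples of 18 residues). That
bias alone would exceed the accuracy this analysis needs.

`fit_axis` therefore proceeds in three stages, each initializing the next:

1. **PCA** of the centered points — coarse direction;
2. **cylinder fit** — Levenberg–Marquardt on (direction, center)
   minimizing the *variance of radial distances* to the axis line. Unlike
   PCA (which minimizes total perpendicular spread) this objective is
   exactly zero at the true axis of an ideal helix of any length;
3. **full helix-model fit** — least squares of the eight-parameter helical
   curve (direction 2, center 2, phase, radius, twist, rise) against all
   coordinates. Both twist signs are tried because the apparent twist
   handedness depends on the viewing direction along the axis and LM cannot
   cross between the two basins; the lower-cost solution wins.

For ideal helices the recovered axis is exact to numerical precision in
any orientation. Under 0.3 Å isotropic Cα noise the resulting bend-angle
error for two 18-residue arms is ~0.6° (median) and stays within 2° for
>95% of seeds. Degenerate input (exactly collinear points) short-circuits
to the PCA line with zero residual. The fitted direction is always
oriented from the first to the last residue (N→C), and `rms_residual` is
the RMS perpendicular distance of the points to the final axis line
(≈ the 2.3 Å Cα radius for a real helix — it measures helicity, not error).

## Bend angle

`bend_angle` takes the vertex residue and two arm ranges explicitly — kink
*detection* is deliberately out of scope — and reports
`arccos(d̂_prox · d̂_dist)` in degrees with both axes oriented N→C, i.e. the
unsigned deviation from collinearity. A perfectly straight helix scores
≈ 0°, so the nonzero angle of a "straight" claudin TM3 reflects real
non-ideality and differences of mean angles are meaningful. The vertex
belongs to neither arm, so the bent residue itself cannot bias either
axis. The claudin-3 defaults (config-exposed) are vertex 134, proximal arm
118–133 (the membrane-embedded end of TM3), distal arm 135–149 (the
extracellular "thumb" segment). `mean_bend` averages chains arithmetically
— in these crystals the asymmetric unit holds two copies (chains A and C),
and the per-chain values are retained beside the mean.

## Superposition and displacement profiles

`kabsch` is the standard SVD solution restricted to proper rotations: the
sign of the smallest singular direction is corrected, so mirror-image
inputs fit with a genuine rotation rather than a reflection. For collinear
degenerate input any minimizing proper rotation is accepted; the RMSD is
still exact.

`core_superpose` iterates: fit on the current core → compute per-residue
Cα deviations → drop residues above the rejection threshold → refit, until
stable or `max_iter`. The default threshold is a fixed 2.0 Å — ordinary
"low-RMSD core" practice — with an adaptive alternative (2× current core
RMSD) selectable in config. Rejected residues are never readmitted, which
keeps the iteration monotone; consequently the converged core can be a
strict subset of the truly rigid region, which is harmless for the
transform (the fit is already exact on the subset) and is reported
explicitly. If rejection would shrink the core below 20% of its initial
size (floor 3), a non-convergence error carrying the iteration trace is
raised instead of returning a meaningless transform.

The initial core for claudin pairs defaults to the rigid transmembrane
segments 1–27, 78–133 and 160–200 minus the distal TM3 arm, i.e. the
region expected to be conformation-independent. Correspondence between
models is by identical author residue number (point mutants of one
protein); cross-subtype mapping through an alignment is out of scope.
Displacement profiles are Cα-only; side-chain positions at 3.6–3.9 Å
resolution are too poorly determined to profile.

## Membrane frame and pocket aperture

No membrane is present in a crystal structure, so "perpendicular to the
membrane plane" must be estimated from the protein itself. The normal is
the normalized mean of the four TM helix axis directions, each
pre-multiplied by its topology sign (claudin default +1, −1, +1, −1 for
TM1–TM4: TM1/TM3 run cytosol→extracellular N→C, TM2/TM4 the reverse), so
the mean points extracellular. A mean-vector norm below 0.5 (axes nearly
cancelling — wrong topology signs or a broken selection) raises a
degenerate-bundle error rather than returning an arbitrary direction. The
default TM ranges (8–27, 78–98, 118–149, 160–182) are engineering choices
exposed in config; helix boundaries are not sharply defined at these
resolutions, and the mean direction is insensitive to a few residues
either way.

The pocket aperture projects side-chain heavy-atom centroids of the upper
rim ({146, 147}) and lower rim ({158, 159}) onto the normal and reports
width = upper − lower, signed so that rim inversion is detectable (the
absolute value is also reported). Side-chain centroids — not Cβ, not ring
tips — are used because they are robust at moderate resolution and
comparable across residue types; glycine falls back to Cα. Projections are
referenced to the TM-bundle centroid, which cancels in the width. The
width is invariant under global rigid motion when the frame is recomputed
from the moved model, and on hinge-constructed fixtures it decreases
monotonically with the kink angle — the geometric mechanism by which a
bent TM3 narrows the pocket.

## B-factor comparison

Per-residue means over backbone atoms (N, CA, C, O) by default; an
all-heavy-atom scope exists but at ~4 Å resolution side-chain disorder
dominates it. The chain comparison reports mean Δ = B(chain_b) −
B(chain_a) over shared residues (≥ 10 required unless an explicit region
is given), the per-residue Δ map, and the fraction of residues where
chain_b is higher with exact ties counted 0.5 each (identical chains score
exactly 0.5). Comparisons are meaningful only within one asymmetric unit:
no attempt is made to normalize B-factors across crystals or resolutions,
and deposited isotropic values are taken at face value.

## Binding model

Raw fraction bound at each ligand concentration is
bound/(bound + unbound) peak height; the literal bound/unbound ratio is
available behind `mode="ratio"` since assay descriptions are ambiguous
between the two. The series is rescaled so the saturating concentration
reads 1.0 and clipped to [0, 1]. The one-site law `f(L) = Bmax·L/(Kd+L)`
is fitted by least squares on the untransformed fractions (no Scatchard
linearization), parametrized in log10 Kd and multistarted over nine
log-spaced initial values spanning 0.01–100× the concentration range. In
normalized mode Bmax is fixed at 1.

One consequence of the saturation anchor is worth knowing: if the top
concentration is only, say, 95% saturating, rescaling it to 1.0 distorts
the curve and a fixed-Bmax fit absorbs the distortion as a slightly
smaller Kd (~13% at Kd = 0.05 μM with a 1 μM top point). The free-Bmax
mode (`fix_bmax=False`) removes this bias and is the recommended
sensitivity check. Data that never cross the transition (all fractions
above 0.8 or all below 0.2 at nonzero ligand) raise an
unidentifiable-curve error instead of returning an unconstrained Kd.
`compare_affinity` bootstraps the Kd ratio by resampling residuals
(default 500 seeded draws) and refitting both curves, reporting the point
ratio with a percentile interval.

## Synthetic generators

The generators construct the ground truth that every stage is tested
against: Cα-only ideal helices (rise 1.5 Å, twist 100°, radius 2.3 Å —
canonical α-helix values, all exposed), kinked helices whose distal arm is
rigidly rotated by a known angle about an in-plane axis through the vertex
Cα (so the constructed bend equals the nominal angle exactly, and the
vertex belongs to neither arm, matching the measurement convention),
rigid two-domain pairs with a known transform applied to the mobile
domain, parallel-packed helix bundles with analytically known mean axis,
and B-factor assignments B = base + chain offset + z-gradient + seeded
Gaussian jitter, clamped at zero. Generation errors (chain breaks > 4.2 Å,
nonbonded Cα pairs < 2.0 Å, clashing bundles) are raised rather than
silently producing unphysical fixtures. All randomness flows through
explicit seeds; changing only the seed changes only noise terms.

What they deliberately do not emulate: side chains and rotamers (pocket
rim measurements on synthetic fixtures exercise the Cα fallback path),
correlated or anisotropic displacement noise, sequence-dependent helix
irregularity (π-bulges, 3₁₀ segments), crystal packing, and solvent. A
passing recovery test therefore demonstrates the estimator, not the
behaviour of real electron-density-derived coordinates; the
deposited-structure test in the acceptance suite covers that end, when
local copies of the crystal structures are supplied.

Default fixture dimensions were chosen once as realistic stand-ins for the
claudin geometry: 37-residue kinked helices with the vertex at residue 19
give two 18-residue arms, matching the length scale of the TM3 arms; the
domain pair uses a 30-residue core and a 20-residue mobile segment offset
by 12 Å, the scale of the extracellular domain relative to the TMD; the
study-condition angles (25°/17°), shift (5 Å), B-factor offset (20 Å²) and
Kd (0.05 μM, with a 10× weaker comparator) are the conditions the analyses
are expected to resolve.

## Pipeline and report

`run_report` validates and echoes the full config into the report
(provenance), runs each stage in isolation — a failing stage records its
error string and the rest continue — and emits one JSON document per run:
per-structure bend/pocket/B-factor sections, per-pair
superposition/displacement/difference sections, and an optional binding
section from a titration CSV. Reports contain no timestamps and are
byte-identical given the same config and seed. The CLI maps full success
to exit 0, partial stage failure to exit 2, and config errors to exit 1.

## Known limitations

- Kink position is an input, not an inference; scanning for the vertex is
  out of scope.
- Arm and TM ranges are declared defaults, not structurally derived; the
  bend angle varies by a degree or two under reasonable alternative arm
  choices, which is why printed-angle comparisons carry ±3° tolerances.
- The membrane frame is a protein-internal estimate; it can differ by a
  few degrees from an implicit-membrane placement.
- Multi-chain superposition maps share one residue-number namespace per
  chain pair; profiling across several chain pairs simultaneously would
  collide on residue keys (single-pair use, as in the claudin analysis, is
  unaffected).
- B-factor comparisons ignore TLS/ADP decomposition and refinement
  provenance.
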