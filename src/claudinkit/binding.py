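"""One-site saturation binding: peak normalization, fitting, simulation.

Models the FSEC-based binding assay: a fluorescent claudin is titrated
with ligand (here GST-C-CPE over 0–1 μM), the chromatogram shows a bound
and an unbound peak, and the fraction bound at each concentration is
computed from the two peak heights. Because the receptor is fully
saturated at the top concentration, the fraction there anchors the maximum
(Bmax ≡ 1 in normalized mode), and the one-site law

    f(L) = Bmax · L / (Kd + L)

is fitted by nonlinear least squares on the untransformed fractions (no
Scatchard linearization), multistarted over log-spaced initial Kd values.

The raw fraction is bound/(bound + unbound) by default; the literal
bound/unbound ratio is available via ``mode="ratio"`` since assay
write-ups are ambiguous on this point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import UnidentifiableCurveError, ValidationError


@dataclass
class BindingSeries:
    """Ligand titration: concentrations (μM, strictly increasing) and fractions."""

    ligand_concentrations: np.ndarray
    fraction_bound: np.ndarray
    saturating_index: int = -1

    def __post_init__(self) -> None:
        conc = np.asarray(self.ligand_concentrations, dtype=float)
        frac = np.asarray(self.fraction_bound, dtype=float)
        if conc.shape != frac.shape or conc.ndim != 1:
            raise ValidationError("concentrations and fractions must match in length")
        if len(conc) < 4:
            raise ValidationError("a binding series needs ≥ 4 points")
        if np.any(conc < 0) or np.any(np.diff(conc) <= 0):
            raise ValidationError("concentrations must be nonnegative, strictly increasing")
        if np.any(frac < -1e-9) or np.any(frac > 1 + 1e-9):
            raise ValidationError("fractions must lie in [0, 1]")
        self.ligand_concentrations = conc
        self.fraction_bound = np.clip(frac, 0.0, 1.0)
        self.saturating_index = int(range(len(conc))[self.saturating_index])


@dataclass
class BindingFit:
    kd: float  # μM
    bmax: float
    rss: float
    converged: bool
    series: BindingSeries = field(repr=False)
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, concentrations) -> np.ndarray:
        L = np.asarray(concentrations, dtype=float)
        return self.bmax * L / (self.kd + L)


def normalize_peaks(
    bound_heights: Sequence[float],
    unbound_heights: Sequence[float],
    saturating_index: int = -1,
    mode: str = "fraction",
) -> BindingSeries | np.ndarray:
    """Fractions bound from chromatogram peak heights.

    Raw fraction_i = bound_i / (bound_i + unbound_i) (``mode="fraction"``)
    or bound_i / unbound_i (``mode="ratio"``); the series is rescaled so
    the saturating point equals 1.0 and clipped to [0, 1]. Returns the
    fractions as an array; build a :class:`BindingSeries` by pairing with
    the concentrations.
    """
    bound = np.asarray(bound_heights, dtype=float)
    unbound = np.asarray(unbound_heights, dtype=float)
    if bound.shape != unbound.shape or bound.ndim != 1:
        raise ValidationError("bound and unbound height lists must match in length")
    if np.any(bound < 0) or np.any(unbound < 0):
        raise ValidationError("peak heights must be nonnegative")
    if mode == "fraction":
        total = bound + unbound
        if np.any(total <= 0):
            raise ValidationError("zero total peak height at some concentration")
        raw = bound / total
    elif mode == "ratio":
        if np.any(unbound <= 0):
            raise ValidationError("zero unbound peak height in ratio mode")
        raw = bound / unbound
    else:
        raise ValidationError(f"mode must be 'fraction' or 'ratio', got {mode!r}")
    anchor = raw[saturating_index]
    if anchor <= 0:
        raise ValidationError("saturating point has zero raw fraction; cannot rescale")
    return np.clip(raw / anchor, 0.0, 1.0)


def fit_one_site(series: BindingSeries, fix_bmax: bool = True) -> BindingFit:
    """Least-squares one-site fit, multistarted over log-spaced initial Kd.

    In normalized mode (default) Bmax is fixed at 1 because the saturating
    point anchors the maximum; ``fix_bmax=False`` frees it for sensitivity
    checks. Data with no points bracketing the transition (all fractions
    above 0.8, or all below 0.2) do not constrain Kd and raise
    :class:`UnidentifiableCurveError`.
    """
    L = series.ligand_concentrations
    y = series.fraction_bound
    positive = L[L > 0]
    if len(positive) == 0:
        raise ValidationError("all concentrations are zero")
    informative = y[L > 0]
    if informative.min() > 0.8 or informative.max() < 0.2:
        raise UnidentifiableCurveError(
            "no data bracketing the binding transition; Kd is not constrained"
        )

    def residuals(theta):
        kd = 10.0 ** theta[0]
        bmax = theta[1] if len(theta) > 1 else 1.0
        return bmax * L / (kd + L) - y

    starts = np.log10(np.geomspace(positive.min() / 100.0, positive.max() * 100.0, 9))
    best = None
    for s in starts:
        x0 = [s] if fix_bmax else [s, max(y.max(), 0.1)]
        try:
            sol = least_squares(residuals, x0, method="lm", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return BindingFit(np.nan, 1.0, np.inf, False, series)
    kd = float(10.0 ** best.x[0])
    bmax = float(best.x[1]) if not fix_bmax else 1.0
    fitted = bmax * L / (kd + L)
    res = y - fitted
    return BindingFit(
        kd=kd,
        bmax=bmax,
        rss=float(np.sum(res**2)),
        converged=bool(best.success and np.isfinite(kd) and kd > 0),
        series=series,
        fitted=fitted,
        residuals=res,
    )


def simulate_binding(
    kd: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> BindingSeries:
    """Series drawn from the one-site law with Gaussian noise, clipped to [0, 1]."""
    if kd <= 0:
        raise ValidationError("kd must be positive")
    L = np.asarray(concentrations, dtype=float)
    f = L / (kd + L)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, f.shape)
    return BindingSeries(L, np.clip(f, 0.0, 1.0), saturating_index=-1)


@dataclass
class AffinityRatio:
    ratio: float  # kd_b / kd_a
    ci_low: float
    ci_high: float
    n_boot: int


def compare_affinity(
    fit_a: BindingFit,
    fit_b: BindingFit,
    n_boot: int = 500,
    seed: int = 0,
    ci: float = 0.95,
) -> AffinityRatio:
    """Kd ratio kd_b/kd_a with a residual-resampling bootstrap interval.

    A ratio above 1 means the second ligand/receptor pair binds more
    weakly. Both fits must have converged.
    """
    if not (fit_a.converged and fit_b.converged):
        raise ValidationError("both fits must have converged")
    if n_boot < 2:
        raise ValidationError("n_boot must be ≥ 2")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        kds = []
        for fit in (fit_a, fit_b):
            y_star = fit.fitted + rng.choice(fit.residuals, size=len(fit.residuals))
            series = BindingSeries(
                fit.series.ligand_concentrations,
                np.clip(y_star, 0.0, 1.0),
                fit.series.saturating_index,
            )
            try:
                kds.append(fit_one_site(series, fix_bmax=fit.bmax == 1.0).kd)
            except UnidentifiableCurveError:
                kds.append(fit.kd)
        ratios[i] = kds[1] / kds[0]
    alpha = (1.0 - ci) / 2.0
    return AffinityRatio(
        ratio=float(fit_b.kd / fit_a.kd),
        ci_low=float(np.quantile(ratios, alpha)),
        ci_high=float(np.quantile(ratios, 1.0 - alpha)),
        n_boot=n_boot,
    )


def read_binding_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a titration table: columns concentration_uM, bound_height, unbound_height."""
    df = pd.read_csv(path)
    required = {"concentration_uM", "bound_height", "unbound_height"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: need columns {sorted(required)}")
    df = df.sort_values("concentration_uM")
    return (
        df["concentration_uM"].to_numpy(float),
        df["bound_height"].to_numpy(float),
        df["unbound_height"].to_numpy(float),
    )
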