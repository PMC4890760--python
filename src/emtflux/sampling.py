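"""Uniform sampling of the steady-state flux space and comparison stats.

The feasible set of a model is the polytope ``{v : S v = 0, l <= v <= u}``.
Since signalling models carry no natural objective (there is no biomass to
maximise), the flux state of a context model is characterised by sampling
this polytope uniformly and summarising per-reaction marginals.

The sampler is artificially-centred hit-and-run (ACHR): directions are
drawn as differences between a randomly chosen stored point and the
running centre, which adapts the proposal to elongated polytopes; warm-up
points come from flux-variability analysis (FVA), so every extreme of
each reaction's flux range seeds the chain.  Directions live in the null
space of S by construction (differences of feasible points) and are
re-projected each step to keep ``||S v||`` at rounding level.

Comparison between an epithelial and a mesenchymal sample set uses the
per-reaction mean-flux fold change ``(mean_M + eps) / (mean_E + eps)``
(eps guards zero-flux reactions) and its log2; a fold > 1 means higher
flux in the mesenchymal context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model import StoichiometricModel

__all__ = [
    "FluxSampleSet",
    "DensityCurve",
    "InfeasibleModelError",
    "sample_fluxes",
    "mean_flux",
    "compare",
    "density_estimate",
    "pathway_report",
    "flux_variability",
]

DEFAULT_N_SAMPLES = 5000
DEFAULT_THINNING = 100
STEADY_STATE_TOL = 1e-6
_EPS_FOLD = 1e-6


class InfeasibleModelError(RuntimeError):
    """The model's polytope is empty: no flux vector satisfies the bounds."""


@dataclass
class FluxSampleSet:
    """A matrix of sampled steady-state flux vectors (n_samples x r)."""

    samples: np.ndarray
    reaction_ids: list[str]
    seed: int | None = None
    method: str = "achr"
    model_metadata: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean(self) -> pd.Series:
        return pd.Series(self.samples.mean(axis=0), index=self.reaction_ids)

    def span(self, definition: str = "mean") -> pd.Series:
        """Per-reaction flux summary: ``"mean"`` (average flux, the default
        convention here) or ``"width"`` (max - min of the samples)."""
        if definition == "mean":
            return self.mean()
        if definition == "width":
            return pd.Series(
                self.samples.max(axis=0) - self.samples.min(axis=0),
                index=self.reaction_ids,
            )
        raise ValueError(f"unknown span definition {definition!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.reaction_ids)


def _polytope(model: StoichiometricModel):
    S = model.S
    lb = model.lower_bounds.astype(float)
    ub = model.upper_bounds.astype(float)
    return S, lb, ub


def _check_feasible(S, lb, ub) -> np.ndarray:
    res = linprog(
        c=np.zeros(S.shape[1]),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleModelError(
            "no steady-state flux vector satisfies the bounds (LP status "
            f"{res.status}: {res.message})"
        )
    return res.x


def flux_variability(model: StoichiometricModel) -> pd.DataFrame:
    """Min/max achievable flux per reaction (FVA) under the model bounds."""
    S, lb, ub = _polytope(model)
    _check_feasible(S, lb, ub)
    rows = []
    for j in range(S.shape[1]):
        c = np.zeros(S.shape[1])
        c[j] = 1.0
        lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
        hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs")
        rows.append((lo.x[j], hi.x[j]))
    return pd.DataFrame(rows, columns=["minimum", "maximum"], index=model.reaction_ids)


def _fva_warmup(S, lb, ub) -> np.ndarray:
    """One optimal vertex per reaction per direction (2r warm-up points)."""
    r = S.shape[1]
    points = []
    for j in range(r):
        c = np.zeros(r)
        c[j] = 1.0
        for sign in (1.0, -1.0):
            res = linprog(
                sign * c,
                A_eq=S,
                b_eq=np.zeros(S.shape[0]),
                bounds=list(zip(lb, ub)),
                method="highs",
            )
            if res.status == 0:
                points.append(res.x)
    return np.asarray(points)


def sample_fluxes(
    model: StoichiometricModel,
    n_samples: int = DEFAULT_N_SAMPLES,
    seed: int | None = None,
    thinning: int = DEFAULT_THINNING,
) -> FluxSampleSet:
    """Sample the steady-state flux polytope with ACHR.

    Deterministic for a given ``seed``; every returned row satisfies
    ``||S v||_inf <= 1e-6`` and the bound constraints.  ``thinning`` is the
    number of hit-and-run steps between stored samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if thinning < 1:
        raise ValueError("thinning must be >= 1")
    S, lb, ub = _polytope(model)
    m, r = S.shape
    _check_feasible(S, lb, ub)

    rng = np.random.default_rng(seed)
    N = null_space(S)  # orthonormal basis of the flux null space
    if N.size == 0:
        # fully determined system: the polytope is a single point
        x = _check_feasible(S, lb, ub)
        samples = np.tile(x, (n_samples, 1))
        return FluxSampleSet(samples, list(model.reaction_ids), seed, "achr")

    project = N @ N.T  # orthogonal projector onto null(S)

    warmup = _fva_warmup(S, lb, ub)
    # pull warm-up points slightly towards their centroid so the chain
    # starts strictly inside the polytope where it has positive width
    centroid = warmup.mean(axis=0)
    warmup = centroid + 0.99 * (warmup - centroid)

    pool = list(warmup)
    center = warmup.mean(axis=0)
    x = center.copy()
    n_pool = len(pool)

    samples = np.empty((n_samples, r))
    stored = 0
    bound_tol = 1e-9
    while stored < n_samples:
        for _ in range(thinning):
            d = pool[rng.integers(len(pool))] - center
            d = project @ d
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                continue
            d /= norm
            # line limits within the box, along a null-space direction
            with np.errstate(divide="ignore", invalid="ignore"):
                to_upper = np.where(np.abs(d) > 1e-11, (ub - x) / d, np.inf)
                to_lower = np.where(np.abs(d) > 1e-11, (lb - x) / d, -np.inf)
            alpha_hi = min(
                np.min(np.where(d > 1e-11, to_upper, np.inf)),
                np.min(np.where(d < -1e-11, to_lower, np.inf)),
            )
            alpha_lo = max(
                np.max(np.where(d > 1e-11, to_lower, -np.inf)),
                np.max(np.where(d < -1e-11, to_upper, -np.inf)),
            )
            if not np.isfinite(alpha_hi) or not np.isfinite(alpha_lo) or alpha_hi <= alpha_lo:
                continue
            alpha = rng.uniform(alpha_lo, alpha_hi)
            x = x + alpha * d
            np.clip(x, lb - bound_tol, ub + bound_tol, out=x)
        x = project @ x  # remove rounding drift off the null space
        samples[stored] = np.clip(x, lb, ub)
        # running centre over warm-up and stored points (artificial centring)
        n_pool += 1
        center += (x - center) / n_pool
        pool.append(x.copy())
        if len(pool) > 200:
            pool.pop(0)
        stored += 1

    return FluxSampleSet(samples, list(model.reaction_ids), seed, "achr")


def mean_flux(samples: FluxSampleSet | np.ndarray) -> np.ndarray | pd.Series:
    """Arithmetic mean flux per reaction (column means)."""
    if isinstance(samples, FluxSampleSet):
        return samples.mean()
    arr = np.asarray(samples)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a non-empty 2-D sample matrix")
    return arr.mean(axis=0)


def compare(
    set_E: FluxSampleSet,
    set_M: FluxSampleSet,
    epsilon: float = _EPS_FOLD,
    span: str = "mean",
) -> pd.DataFrame:
    """Per-reaction comparison of two sample sets.

    Returns a frame indexed by reaction id with the mean flux in each
    context, the fold change ``(mean_M + eps) / (mean_E + eps)``, its log2
    (negative = higher flux in the epithelial context), and the span ratio
    ``span_M / span_E`` under the configured span definition.
    """
    if set_E.reaction_ids != set_M.reaction_ids:
        raise ValueError("sample sets cover different reaction sets")
    mean_E = set_E.mean()
    mean_M = set_M.mean()
    fold = (mean_M + epsilon) / (mean_E + epsilon)
    span_E = set_E.span(span)
    span_M = set_M.span(span)
    span_ratio = (span_M + epsilon) / (span_E + epsilon)
    return pd.DataFrame(
        {
            "mean_E": mean_E,
            "mean_M": mean_M,
            "fold": fold,
            "log2_fold": np.log2(fold),
            "span_E": span_E,
            "span_M": span_M,
            "span_ratio": span_ratio,
        }
    )


@dataclass
class DensityCurve:
    """A kernel density estimate of one reaction's sampled flux."""

    grid: np.ndarray
    density: np.ndarray
    mode: float
    degenerate: bool = False


def density_estimate(
    samples: FluxSampleSet, reaction_id: str, gridsize: int = 512
) -> DensityCurve:
    """Gaussian-kernel density (Silverman bandwidth) of one flux marginal.

    A zero-variance column is reported as a degenerate spike at its value
    rather than an error.  The curve integrates to 1 (trapezoid rule) to
    within 1e-3 on its grid; the mode is the grid point of maximum
    density ("most probable flux").
    """
    if samples.n_samples < 30:
        raise ValueError("need at least 30 samples for a density estimate")
    j = samples.reaction_ids.index(reaction_id)
    col = samples.samples[:, j]
    if np.ptp(col) < 1e-12:
        value = float(col[0])
        return DensityCurve(
            grid=np.array([value]), density=np.array([np.inf]), mode=value, degenerate=True
        )
    from scipy.stats import gaussian_kde

    kde = gaussian_kde(col, bw_method="silverman")
    pad = 3.0 * kde.factor * col.std(ddof=1)
    grid = np.linspace(col.min() - pad, col.max() + pad, gridsize)
    density = kde(grid)
    return DensityCurve(grid=grid, density=density, mode=float(grid[np.argmax(density)]))


def pathway_report(
    comparison: pd.DataFrame,
    pathway_sets: dict[str, list[str]],
    exclude_exchange_ids: set[str] | None = None,
    aggregate: str = "geometric",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate fold changes per pathway.

    Returns ``(summary, heatmap)``: one row per pathway with its aggregate
    fold (geometric mean of per-reaction folds by default, arithmetic by
    flag) and reaction count, and a reaction-by-pathway matrix of log2
    folds ready for a heat map.  Exchange reactions can be excluded by id.
    """
    if aggregate not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    drop = exclude_exchange_ids or set()
    rows = []
    heat: dict[str, pd.Series] = {}
    for pathway, rids in pathway_sets.items():
        if not rids:
            raise ValueError(f"pathway {pathway!r} has an empty reaction set")
        missing = [rid for rid in rids if rid not in comparison.index]
        if missing:
            raise KeyError(f"pathway {pathway!r} references unknown reactions {missing}")
        use = [rid for rid in rids if rid not in drop]
        folds = comparison.loc[use, "fold"]
        if aggregate == "geometric":
            agg = float(np.exp(np.log(folds).mean()))
        else:
            agg = float(folds.mean())
        rows.append(
            {
                "pathway": pathway,
                "aggregate_fold": agg,
                "log2_aggregate_fold": np.log2(agg),
                "n_reactions": len(use),
            }
        )
        heat[pathway] = comparison.loc[use, "log2_fold"]
    summary = pd.DataFrame(rows).set_index("pathway")
    heatmap = pd.DataFrame(heat)
    return summary, heatmap
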