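"""Accumulated local effects (ALE) curves and effect sizes.

An ALE curve for a factor is built from local prediction differences inside
quantile bins of that factor: for every row in a bin, predict with the
factor pushed to the bin's upper and lower edge, average the differences
per bin, accumulate across bins, and centre so the curve's sample-weighted
mean is zero.  Unlike partial-dependence curves, ALE stays unbiased when
features are correlated — which they strongly are in this cohort.

The effect size of a factor is the range (max minus min) of its ALE curve
over the middle 95% of the factor's sample, in response units (watts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bart import SumOfTreesPosterior, predict

__all__ = ["ALECurve", "EffectSize", "compute_ale", "ale_uncertainty", "effect_size"]


@dataclass
class ALECurve:
    """Centered accumulated local effect of one factor (response units)."""

    factor: str
    edges: np.ndarray  # strictly increasing bin edges, length K+1
    effect: np.ndarray  # centered accumulated effect at each edge
    counts: np.ndarray  # rows per bin, length K
    lo: np.ndarray | None = None  # pointwise interval bounds, if computed
    hi: np.ndarray | None = None
    draw_curves: np.ndarray | None = field(default=None, repr=False)

    def interpolate(self, x) -> np.ndarray:
        """Piecewise-linear curve value at arbitrary factor values."""
        return np.interp(np.asarray(x, dtype=float), self.edges, self.effect)

    def plot(self, factor_values=None, ax=None):
        """Plot the curve (with band if present) and a rug of the sample.

        Requires matplotlib; returns the axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.axhline(0.0, color="0.8", lw=0.8)
        if self.lo is not None:
            ax.fill_between(self.edges, self.lo, self.hi, alpha=0.25, lw=0)
        ax.plot(self.edges, self.effect, lw=1.5)
        if factor_values is not None:
            vals = np.asarray(pd.Series(factor_values).dropna(), dtype=float)
            ax.plot(vals, np.full(vals.size, ax.get_ylim()[0]), "|",
                    color="k", ms=4, alpha=0.25)
        ax.set_xlabel(self.factor)
        ax.set_ylabel("average change in metabolic power (W)")
        return ax

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: factor, edge, effect, lo, hi, n (per upper edge)."""
        k = len(self.counts)
        return pd.DataFrame(
            {
                "factor": self.factor,
                "edge": self.edges,
                "effect": self.effect,
                "lo": self.lo if self.lo is not None else np.nan,
                "hi": self.hi if self.hi is not None else np.nan,
                "n": np.concatenate(([0], self.counts)).astype(int)[: k + 1],
            }
        )


@dataclass
class EffectSize:
    """Range of the ALE curve over the factor's middle-95% window."""

    factor: str
    window: tuple[float, float]  # [P2.5, P97.5] of the factor's sample
    effect_range: float  # max - min of the curve on the window (W)
    lo: float | None = None  # interval bounds over posterior draws
    hi: float | None = None


def _quantile_edges(x: np.ndarray, bins: int) -> np.ndarray:
    qs = np.linspace(0.0, 1.0, bins + 1)
    edges = np.quantile(x, qs)
    edges = np.unique(edges)  # merge duplicate quantiles on discrete data
    if edges.size < 2:
        raise ValueError("factor is (near-)constant; no ALE bins available")
    return edges


def _bin_index(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # bin k covers (edges[k], edges[k+1]]; lowest values fall in bin 0
    idx = np.searchsorted(edges, x, side="left") - 1
    return np.clip(idx, 0, edges.size - 2)


def _accumulate(
    diffs: np.ndarray, bin_idx: np.ndarray, n_bins: int, x: np.ndarray, edges: np.ndarray
):
    """Mean local difference per bin -> cumulative sum -> sample-centered curve."""
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.bincount(bin_idx, weights=diffs, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    curve = np.concatenate(([0.0], np.cumsum(means)))
    curve = curve - np.interp(x, edges, curve).mean()
    return curve, counts


def compute_ale(
    predict_fn,
    data: pd.DataFrame,
    factor: str,
    bins: int = 40,
) -> ALECurve:
    """First-order ALE curve of ``factor`` under ``predict_fn``.

    ``predict_fn`` maps a predictor table to a prediction vector.  Rows
    missing the factor are excluded; missingness in other columns is the
    model's business.  ``bins`` quantile bins (reduced when the factor has
    few distinct values).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if factor not in data.columns:
        raise KeyError(f"factor {factor!r} not in data")
    if not pd.api.types.is_numeric_dtype(data[factor]):
        raise TypeError(f"factor {factor!r} is not numeric")
    rows = data[data[factor].notna()].reset_index(drop=True)
    x = rows[factor].to_numpy(dtype=float)
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError(f"factor {factor!r} is constant")
    edges = _quantile_edges(x, min(bins, n_distinct - 1))
    k = edges.size - 1
    bin_idx = _bin_index(x, edges)

    low = rows.copy()
    high = rows.copy()
    low[factor] = edges[bin_idx]
    high[factor] = edges[bin_idx + 1]
    diffs = np.asarray(predict_fn(high)) - np.asarray(predict_fn(low))
    curve, counts = _accumulate(diffs, bin_idx, k, x, edges)
    return ALECurve(factor=factor, edges=edges, effect=curve, counts=counts)


def ale_uncertainty(
    model: SumOfTreesPosterior,
    data: pd.DataFrame,
    factor: str,
    bins: int = 40,
    level: float = 0.95,
    max_draws: int | None = 200,
) -> ALECurve:
    """ALE curve with pointwise posterior intervals.

    Default mode propagates the sum-of-trees posterior: one ALE curve per
    posterior draw, with the pointwise ``level`` interval across draws.  The
    returned curve's point estimate is the posterior-mean curve.  For a
    nonparametric bootstrap (refitting the model on resampled rows) see
    :func:`ale_bootstrap`.
    """
    rows = data[data[factor].notna()].reset_index(drop=True)
    x = rows[factor].to_numpy(dtype=float)
    n_distinct = np.unique(x).size
    if n_distinct < 2:
        raise ValueError(f"factor {factor!r} is constant")
    edges = _quantile_edges(x, min(bins, n_distinct - 1))
    k = edges.size - 1
    bin_idx = _bin_index(x, edges)

    low = rows.copy()
    high = rows.copy()
    low[factor] = edges[bin_idx]
    high[factor] = edges[bin_idx + 1]
    _, d_hi = predict(model, high, return_draws=True, max_draws=max_draws)
    _, d_lo = predict(model, low, return_draws=True, max_draws=max_draws)
    n_draws = d_hi.shape[0]
    if n_draws < 20:
        raise ValueError(
            f"only {n_draws} posterior draws; run a longer chain (>= 20 needed) "
            "for interval estimates"
        )
    curves = np.empty((n_draws, k + 1))
    counts = np.bincount(bin_idx, minlength=k).astype(float)
    for d in range(n_draws):
        curves[d], _ = _accumulate(d_hi[d] - d_lo[d], bin_idx, k, x, edges)
    a = (1.0 - level) / 2.0
    return ALECurve(
        factor=factor,
        edges=edges,
        effect=curves.mean(axis=0),
        counts=counts,
        lo=np.quantile(curves, a, axis=0),
        hi=np.quantile(curves, 1.0 - a, axis=0),
        draw_curves=curves,
    )


def ale_bootstrap(
    fit_fn,
    data: pd.DataFrame,
    response: str,
    factor: str,
    bins: int = 40,
    level: float = 0.95,
    n_boot: int = 50,
    seed: int = 0,
) -> ALECurve:
    """Bootstrap ALE band: resample rows, refit, recompute the curve.

    ``fit_fn(predictors, response_values)`` must return a fitted model with
    a matching ``predict``-style callable via :func:`gaitcausal.bart.predict`.
    Expensive (``n_boot`` refits); the posterior-draw band from
    :func:`ale_uncertainty` is the default elsewhere.
    """
    rng = np.random.default_rng(seed)
    base = compute_ale(
        lambda rows: predict(fit_fn(data.drop(columns=[response]), data[response]), rows),
        data.drop(columns=[response]),
        factor,
        bins,
    )
    curves = np.empty((n_boot, base.edges.size))
    for b in range(n_boot):
        samp = data.sample(n=len(data), replace=True, random_state=int(rng.integers(2**31)))
        samp = samp.reset_index(drop=True)
        model = fit_fn(samp.drop(columns=[response]), samp[response])
        c = compute_ale(
            lambda rows: predict(model, rows),
            samp.drop(columns=[response]),
            factor,
            bins,
        )
        curves[b] = np.interp(base.edges, c.edges, c.effect)
    a = (1.0 - level) / 2.0
    base.lo = np.quantile(curves, a, axis=0)
    base.hi = np.quantile(curves, 1.0 - a, axis=0)
    return base


def effect_size(curve: ALECurve, factor_values) -> EffectSize:
    """Effect size: curve range over the factor's middle-95% sample window.

    The (interpolated) curve is restricted to factor values between the
    2.5th and 97.5th sample percentiles; the effect is max minus min there.
    Adding a constant to the curve leaves the result unchanged.
    """
    vals = np.asarray(pd.Series(factor_values).dropna(), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 factor values")
    lo_w, hi_w = np.quantile(vals, [0.025, 0.975])
    if hi_w <= lo_w:
        raise ValueError(
            f"middle-95% window of {curve.factor!r} collapses "
            f"(near-constant factor)"
        )
    inside = (curve.edges >= lo_w) & (curve.edges <= hi_w)
    pts = np.concatenate(
        ([curve.interpolate(lo_w)], curve.effect[inside], [curve.interpolate(hi_w)])
    )
    rng_eff = float(pts.max() - pts.min())

    lo = hi = None
    if curve.draw_curves is not None:
        draw_ranges = []
        for d in range(curve.draw_curves.shape[0]):
            dpts = np.concatenate(
                (
                    [np.interp(lo_w, curve.edges, curve.draw_curves[d])],
                    curve.draw_curves[d][inside],
                    [np.interp(hi_w, curve.edges, curve.draw_curves[d])],
                )
            )
            draw_ranges.append(dpts.max() - dpts.min())
        lo, hi = (float(v) for v in np.quantile(draw_ranges, [0.025, 0.975]))
    return EffectSize(
        factor=curve.factor, window=(float(lo_w), float(hi_w)), effect_range=rng_eff,
        lo=lo, hi=hi,
    )
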