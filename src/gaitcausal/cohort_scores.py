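"""Clinical summary scores and unit conversions for the gait cohort.

Item-level ordinal exams (Ashworth spasticity 1-5, Kendall strength 1-5,
selective motor control 0-2; six muscle groups, both sides) are reduced to
one summary score per domain with polychoric principal component analysis:
pairwise polychoric correlations between items, eigendecomposition, and the
first component applied to centred/scaled item codes.  Plain PCA on ordinal
codes is biased, hence the polychoric step.

Also here: oxygen-uptake -> net metabolic power conversion (20.1 J per mL
O2) and z-normalisation of factor columns for effect analysis, with the
spasticity axis flipped so that, as for every other factor, more positive
means less impaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "J_PER_ML_O2",
    "DOMAIN_SCALES",
    "MUSCLE_GROUPS",
    "SIDES",
    "ScoreModel",
    "polychoric_correlation",
    "polychoric_matrix",
    "summary_score",
    "net_metabolic_power",
    "zscore_factors",
    "inverse_zscore",
    "read_cohort",
    "read_exams",
    "exam_items_wide",
]

#: Energetic equivalent of oxygen: joules released per mL O2 consumed.
J_PER_ML_O2 = 20.1

#: Rating scale (inclusive integer bounds) per exam domain.
DOMAIN_SCALES = {"spasticity": (1, 5), "strength": (1, 5), "smc": (0, 2)}

MUSCLE_GROUPS = (
    "hip_flexors",
    "hip_adductors",
    "rectus_femoris",
    "hamstrings",
    "plantarflexors",
    "tibialis_posterior",
)
SIDES = ("L", "R")

#: Factors entering the z-scored effect analysis.  Sign -1 flips the axis so
#: that a more positive normalized value means less severe impairment.
FACTOR_SIGNS = {
    "GDI": 1.0,
    "DMC": 1.0,
    "SMC": 1.0,
    "Spasticity": -1.0,
    "Strength": 1.0,
    "Speed": 1.0,
    "Age": 1.0,
    "Height": 1.0,
    "Mass": 1.0,
}


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

def _thresholds(margin: np.ndarray, label: str) -> np.ndarray:
    """Interior normal thresholds from one ordinal margin (counts)."""
    total = margin.sum()
    if total <= 0 or (margin > 0).sum() < 2:
        raise ValueError(
            f"item {label!r}: margin concentrated in one category; "
            "polychoric thresholds are undefined"
        )
    cum = np.cumsum(margin)[:-1] / total
    return stats.norm.ppf(cum)


def _bvn_cdf_grid(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """F(a_i, b_j) for a standard bivariate normal, thresholds incl. +/-inf."""
    av = np.concatenate(([-np.inf], a, [np.inf]))
    bv = np.concatenate(([-np.inf], b, [np.inf]))
    grid = np.zeros((av.size, bv.size))
    # boundary rows/columns follow from the marginals
    grid[-1, :] = stats.norm.cdf(bv)
    grid[:, -1] = stats.norm.cdf(av)
    finite_a = av[1:-1]
    finite_b = bv[1:-1]
    if finite_a.size and finite_b.size:
        pts = np.column_stack(
            [np.repeat(finite_a, finite_b.size), np.tile(finite_b, finite_a.size)]
        )
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        grid[1:-1, 1:-1] = mvn.cdf(pts).reshape(finite_a.size, finite_b.size)
    return grid


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    f = _bvn_cdf_grid(a, b, rho)
    p = f[1:, 1:] - f[:-1, 1:] - f[1:, :-1] + f[:-1, :-1]
    return np.clip(p, 1e-12, None)


def polychoric_correlation(
    counts: np.ndarray, labels: tuple[str, str] = ("item1", "item2")
) -> float:
    """Two-step polychoric correlation from a two-way contingency table.

    Thresholds come from the inverse standard-normal of the cumulative
    marginal proportions; the correlation then maximizes the bivariate
    normal cell-probability log-likelihood.  The estimate is clipped to
    ``[-0.999, 0.999]``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    a = _thresholds(counts.sum(axis=1), labels[0])
    b = _thresholds(counts.sum(axis=0), labels[1])

    def nll(rho: float) -> float:
        return -float(np.sum(counts * np.log(_cell_probs(a, b, rho))))

    res = optimize.minimize_scalar(
        nll, bounds=(-0.999, 0.999), method="bounded", options={"xatol": 1e-5}
    )
    return float(np.clip(res.x, -0.999, 0.999))


def _contingency(x: pd.Series, y: pd.Series, levels_x, levels_y) -> np.ndarray:
    tab = pd.crosstab(
        pd.Categorical(x, categories=levels_x),
        pd.Categorical(y, categories=levels_y),
        dropna=False,
    ).to_numpy(dtype=float)
    # drop empty outer categories so margins stay informative
    tab = tab[tab.sum(axis=1) > 0][:, tab.sum(axis=0) > 0]
    return tab


def nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Repair a symmetric pseudo-correlation matrix to PSD with unit diagonal.

    Eigenvalues are clipped at zero and the result rescaled back to a
    correlation matrix.
    """
    c = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals.min() >= 0:
        return c
    vals = np.clip(vals, 0.0, None)
    c = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# exam tables and summary scores
# ---------------------------------------------------------------------------

def exam_items_wide(exams: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Pivot a long exam table to one column per muscle-side item.

    ``exams`` columns: child, domain, muscle, side, rating.  Returns a frame
    indexed by child with 12 columns named ``muscle.side``, missing ratings
    as NaN.  Column order is canonical (muscle group, then side) so scores
    do not depend on input row order.
    """
    if domain not in DOMAIN_SCALES:
        raise ValueError(f"unknown exam domain {domain!r}")
    sub = exams[exams["domain"] == domain]
    wide = sub.pivot_table(
        index="child", columns=["muscle", "side"], values="rating", aggfunc="first"
    )
    cols = [(m, s) for m in MUSCLE_GROUPS for s in SIDES]
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cols))
    wide.columns = [f"{m}.{s}" for m, s in cols]
    lo, hi = DOMAIN_SCALES[domain]
    bad = (wide < lo) | (wide > hi)
    if bad.any().any():
        raise ValueError(f"{domain} ratings outside the {lo}-{hi} scale")
    return wide


def polychoric_matrix(items: pd.DataFrame, domain: str | None = None) -> pd.DataFrame:
    """Pairwise-complete polychoric correlation matrix over item columns.

    Accepts either the wide item frame from :func:`exam_items_wide` or a
    long exam table plus ``domain``.  The raw pairwise matrix is repaired to
    the nearest positive semidefinite correlation matrix by eigenvalue
    clipping.
    """
    if domain is not None:
        items = exam_items_wide(items, domain)
    cols = list(items.columns)
    for c in cols:
        if items[c].dropna().nunique() < 2:
            raise ValueError(f"item {c!r} is constant; polychoric PCA is degenerate")
    k = len(cols)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            pair = items[[cols[i], cols[j]]].dropna()
            if len(pair) < 2:
                raise ValueError(f"items {cols[i]!r}, {cols[j]!r}: no complete pairs")
            levels_i = sorted(items[cols[i]].dropna().unique())
            levels_j = sorted(items[cols[j]].dropna().unique())
            tab = _contingency(pair[cols[i]], pair[cols[j]], levels_i, levels_j)
            corr[i, j] = corr[j, i] = polychoric_correlation(tab, (cols[i], cols[j]))
    return pd.DataFrame(nearest_psd(corr), index=cols, columns=cols)


@dataclass
class ScoreModel:
    """First polychoric principal component of one exam domain."""

    domain: str
    items: list[str]
    correlation: pd.DataFrame
    loadings: pd.Series  # unit-norm, oriented
    variance_explained: float
    item_means: pd.Series = field(repr=False, default=None)
    item_sds: pd.Series = field(repr=False, default=None)

    def raw_scores(self, wide: pd.DataFrame) -> pd.Series:
        """Unstandardized component scores; NaN for incomplete children."""
        z = (wide[self.items] - self.item_means) / self.item_sds
        scores = z @ self.loadings
        scores[wide[self.items].isna().any(axis=1)] = np.nan
        return scores


def fit_score_model(exams: pd.DataFrame, domain: str) -> ScoreModel:
    """Fit the polychoric-PCA score model for one exam domain."""
    wide = exam_items_wide(exams, domain)
    corr = polychoric_matrix(wide)
    vals, vecs = np.linalg.eigh(corr.to_numpy())
    first = vecs[:, -1]
    first = first / np.linalg.norm(first)
    loadings = pd.Series(first, index=corr.index)
    explained = float(vals[-1] / vals.sum())

    item_means = wide.mean()
    item_sds = wide.std(ddof=1)
    if (item_sds <= 0).any():
        bad = list(item_sds.index[item_sds <= 0])
        raise ValueError(f"constant item(s) {bad}; cannot scale")
    model = ScoreModel(
        domain=domain,
        items=list(corr.index),
        correlation=corr,
        loadings=loadings,
        variance_explained=explained,
        item_means=item_means,
        item_sds=item_sds,
    )
    # orient: score must correlate positively with the mean item rating, so
    # a higher spasticity score means more spastic, higher strength stronger
    raw = model.raw_scores(wide)
    mean_rating = wide.mean(axis=1)
    ok = raw.notna() & mean_rating.notna()
    if ok.sum() >= 2:
        r = np.corrcoef(raw[ok], mean_rating[ok])[0, 1]
        if r < 0:
            model.loadings = -model.loadings
    return model


def summary_score(
    exams: pd.DataFrame, domain: str, model: ScoreModel | None = None
) -> tuple[pd.Series, ScoreModel]:
    """Per-child summary score for one domain (complete cases only).

    Scores are the first polychoric principal component applied to
    centred/scaled item codes, standardized to mean 0 / SD 1 over the scored
    children.  Children missing any of the 12 items receive NaN.
    """
    if model is None:
        model = fit_score_model(exams, domain)
    wide = exam_items_wide(exams, domain)
    raw = model.raw_scores(wide)
    scored = raw.dropna()
    if len(scored) < 2:
        raise ValueError(f"fewer than two complete cases for domain {domain!r}")
    std = (raw - scored.mean()) / scored.std(ddof=1)
    std.name = domain
    return std, model


# ---------------------------------------------------------------------------
# metabolic power and normalisation
# ---------------------------------------------------------------------------

def net_metabolic_power(vo2_walk, vo2_rest):
    """Net metabolic power (W) from walking and resting O2 uptake (mL O2/s).

    ``20.1 * (vo2_walk - vo2_rest)``.  A resting rate above the walking rate
    yields a negative power, which is returned (with a logged warning)
    rather than silently dropped.
    """
    walk = np.asarray(vo2_walk, dtype=float)
    rest = np.asarray(vo2_rest, dtype=float)
    if (walk < 0).any() or (rest < 0).any():
        raise ValueError("oxygen uptake rates must be non-negative")
    power = J_PER_ML_O2 * (walk - rest)
    if (power < 0).any():
        logger.warning(
            "%d record(s) with resting VO2 above walking VO2: negative net power",
            int((power < 0).sum()),
        )
    if np.isscalar(vo2_walk) and np.isscalar(vo2_rest):
        return float(power)
    return power


def zscore_factors(
    cohort: pd.DataFrame, factors: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, dict[str, float]]]:
    """Z-normalize factor columns, missing-aware, with orientation flips.

    Each factor is centred and scaled by its sample mean/SD.  Columns with a
    sign of -1 in :data:`FACTOR_SIGNS` (spasticity) are flipped afterwards
    so a more positive normalized value always means a lesser severity of
    impairment.  Returns the transformed frame and per-factor metadata
    ``{mean, sd, sign}`` where ``sd`` is one standard deviation in original
    units.
    """
    if factors is None:
        factors = [c for c in FACTOR_SIGNS if c in cohort.columns]
    out = cohort.copy()
    meta: dict[str, dict[str, float]] = {}
    for col in factors:
        vals = cohort[col].astype(float)
        if vals.notna().sum() < 2:
            raise ValueError(f"column {col!r}: fewer than 2 non-missing values")
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            raise ValueError(f"column {col!r} has zero variance")
        sign = FACTOR_SIGNS.get(col, 1.0)
        out[col] = sign * (vals - mu) / sd
        meta[col] = {"mean": mu, "sd": sd, "sign": sign}
    return out, meta


def inverse_zscore(
    normalized: pd.DataFrame, meta: dict[str, dict[str, float]]
) -> pd.DataFrame:
    """Invert :func:`zscore_factors` using its metadata."""
    out = normalized.copy()
    for col, m in meta.items():
        out[col] = normalized[col] * m["sd"] / m["sign"] + m["mean"]
    return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

#: Logical cohort columns.  Readers map file columns onto these names.
COHORT_COLUMNS = [
    "child",
    "Age",
    "Sex",
    "Height",
    "Mass",
    "Speed",
    "GDI",
    "DMC",
    "SMC",
    "Spasticity",
    "Strength",
    "MetPower",
    "GMFCS",
]


def read_cohort(
    path, column_map: dict[str, str] | None = None, sheet: int | str = 0
) -> pd.DataFrame:
    """Read a per-child cohort table from CSV or XLSX.

    ``column_map`` maps logical names (:data:`COHORT_COLUMNS`) to the file's
    column headers; logical names already present in the file need no entry.
    Unknown file columns are carried through untouched.
    """
    p = str(path)
    if p.lower().endswith((".xlsx", ".xls")):
        df = pd.read_excel(p, sheet_name=sheet)
    else:
        df = pd.read_csv(p)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped column(s) not in file: {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    if "Sex" in df.columns and df["Sex"].dtype == object:
        df["Sex"] = (
            df["Sex"].str.strip().str.lower().map({"m": 1, "male": 1, "f": 0, "female": 0})
        )
    return df


def read_exams(path) -> pd.DataFrame:
    """Read a long-format item-level exam table (child, domain, muscle, side, rating)."""
    df = pd.read_csv(path)
    required = {"child", "domain", "muscle", "side", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exam table missing column(s): {sorted(missing)}")
    bad = set(df["domain"].unique()) - set(DOMAIN_SCALES)
    if bad:
        raise ValueError(f"unknown exam domain(s): {sorted(bad)}")
    return df
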