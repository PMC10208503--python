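"""Bayesian additive regression trees (sum-of-trees MCMC), from scratch.

The regression function is a sum of ``m`` small binary decision trees, each
kept weak by a regularizing prior, fitted by backfitting Gibbs sampling:

* response rescaled to ``[-0.5, 0.5]``;
* tree-structure prior: a node at depth ``d`` is non-terminal with
  probability ``alpha * (1 + d) ** -beta``;
* leaf-value prior ``N(0, sigma_mu^2)`` with ``sigma_mu = 0.5 / (k sqrt(m))``;
* error variance prior: scaled inverse chi-squared ``nu * lambda / chi2_nu``
  with ``lambda`` solved so that a data-based sigma estimate sits at the
  prior's ``q`` quantile;
* per-iteration Metropolis-Hastings grow / prune / change proposals on each
  tree against its partial residual, then conjugate Gibbs draws of the leaf
  values and of ``sigma^2``.

Missing predictor values are handled natively (missingness incorporated in
attributes): every split carries a flag sending missing values left or
right, sampled along with the split, so missingness itself can carry
signal.  A fixed seed makes the whole posterior reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BARTConfig",
    "SumOfTreesPosterior",
    "FitMetrics",
    "fit",
    "predict",
    "cv_select",
    "fit_metrics",
]


@dataclass(frozen=True)
class BARTConfig:
    """Hyperparameters of the sum-of-trees sampler.

    Defaults are the study's selected set: 50 trees, leaf-prior scale
    ``k = 5`` (strong shrinkage), error-variance prior ``nu = 3`` with the
    data-based sigma estimate at the ``q = 0.99`` prior quantile, and
    native missing-data handling on.
    """

    num_trees: int = 50
    k: float = 5.0
    nu: float = 3.0
    q: float = 0.99
    alpha: float = 0.95
    beta: float = 2.0
    n_burn: int = 1000
    n_draws: int = 1000
    keep_every: int = 1
    seed: int = 42
    use_missing_data: bool = True
    min_leaf: int = 5
    # proposal mix over grow / prune / change
    p_grow: float = 0.28
    p_prune: float = 0.28

    def __post_init__(self) -> None:
        if self.num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        if self.k <= 0 or self.nu <= 0 or not (0 < self.q < 1):
            raise ValueError("require k > 0, nu > 0, q in (0, 1)")
        if not (0 < self.alpha < 1) or self.beta < 0:
            raise ValueError("require alpha in (0, 1), beta >= 0")
        if self.n_draws < 1 or self.n_burn < 0 or self.keep_every < 1:
            raise ValueError("invalid chain lengths")
        if self.p_grow + self.p_prune >= 1:
            raise ValueError("p_grow + p_prune must leave room for change moves")


@dataclass
class FitMetrics:
    """In- or out-of-sample fit of posterior-mean predictions."""

    r_squared: float
    rmse: float


class _Node:
    __slots__ = ("leaf", "var", "split", "miss_left", "left", "right", "rows", "depth")

    def __init__(self, rows: np.ndarray, depth: int):
        self.leaf = True
        self.var = -1
        self.split = 0.0
        self.miss_left = True
        self.left: _Node | None = None
        self.right: _Node | None = None
        self.rows = rows
        self.depth = depth


def _leaves(node: _Node, out: list[_Node]) -> list[_Node]:
    if node.leaf:
        out.append(node)
    else:
        _leaves(node.left, out)
        _leaves(node.right, out)
    return out


def _prunable(node: _Node, out: list[_Node]) -> list[_Node]:
    """Internal nodes whose children are both leaves."""
    if not node.leaf:
        if node.left.leaf and node.right.leaf:
            out.append(node)
        else:
            _prunable(node.left, out)
            _prunable(node.right, out)
    return out


def _compact(node: _Node, mus: dict[int, float]):
    """Serialize a training tree to nested tuples (leaves carry their mu)."""
    if node.leaf:
        return (0, mus[id(node)])
    return (
        1,
        node.var,
        node.split,
        node.miss_left,
        _compact(node.left, mus),
        _compact(node.right, mus),
    )


def _eval_tree(tree, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if tree[0] == 0:
        out[idx] = tree[1]
        return
    _, var, split, miss_left, left, right = tree
    col = X[idx, var]
    isnan = np.isnan(col)
    with np.errstate(invalid="ignore"):
        goleft = (col <= split) | (isnan if miss_left else np.zeros_like(isnan))
    _eval_tree(left, X, idx[goleft], out)
    _eval_tree(right, X, idx[~goleft], out)


@dataclass
class SumOfTreesPosterior:
    """Posterior draws of the sum-of-trees model.

    ``forests[d]`` is a tuple of compact trees for draw ``d``; ``sigma[d]``
    the corresponding noise SD in response units.  ``center``/``scale`` undo
    the internal response rescaling.
    """

    config: BARTConfig
    columns: list[str]
    forests: list[tuple]
    sigma: np.ndarray
    center: float
    scale: float
    train_missing: bool

    @property
    def n_draws(self) -> int:
        return len(self.forests)

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "config": asdict(self.config),
                "columns": self.columns,
                "center": self.center,
                "scale": self.scale,
                "train_missing": self.train_missing,
                "sigma": self.sigma.tolist(),
                "forests": self.forests,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SumOfTreesPosterior":
        d = json.loads(text)

        def detuple(t):
            return (0, t[1]) if t[0] == 0 else (1, t[1], t[2], t[3], detuple(t[4]), detuple(t[5]))

        return cls(
            config=BARTConfig(**d["config"]),
            columns=list(d["columns"]),
            forests=[tuple(detuple(t) for t in f) for f in d["forests"]],
            sigma=np.asarray(d["sigma"], dtype=float),
            center=float(d["center"]),
            scale=float(d["scale"]),
            train_missing=bool(d["train_missing"]),
        )


def _as_matrix(predictors: pd.DataFrame | np.ndarray, columns: list[str] | None):
    if isinstance(predictors, pd.DataFrame):
        df = predictors
        if columns is not None:
            missing = [c for c in columns if c not in df.columns]
            if missing:
                raise KeyError(f"prediction table lacks training column(s): {missing}")
            df = df[columns]
        # one-hot any non-numeric (categorical) columns
        out_cols: list[str] = []
        mats: list[np.ndarray] = []
        for c in df.columns:
            col = df[c]
            if pd.api.types.is_numeric_dtype(col):
                out_cols.append(str(c))
                mats.append(col.to_numpy(dtype=float))
            else:
                cats = sorted(col.dropna().unique())
                for cat in cats:
                    out_cols.append(f"{c}={cat}")
                    mats.append((col == cat).astype(float).where(col.notna()).to_numpy(dtype=float))
        return np.column_stack(mats), out_cols
    X = np.asarray(predictors, dtype=float)
    if X.ndim != 2:
        raise ValueError("predictors must be 2-dimensional")
    names = [f"x{i}" for i in range(X.shape[1])] if columns is None else list(columns)
    return X, names


class _Sampler:
    """Backfitting Gibbs sampler over one forest."""

    def __init__(self, X: np.ndarray, y_s: np.ndarray, cfg: BARTConfig, rng, lam: float,
                 prior_only: bool = False):
        self.X = X
        self.y = y_s
        self.cfg = cfg
        self.rng = rng
        self.lam = lam
        self.prior_only = prior_only
        n, p = X.shape
        self.n, self.p = n, p
        self.sigma_mu = 0.5 / (cfg.k * math.sqrt(cfg.num_trees))
        self.has_nan = [bool(np.isnan(X[:, j]).any()) for j in range(p)]
        all_rows = np.arange(n)
        self.roots = [_Node(all_rows, 0) for _ in range(cfg.num_trees)]
        self.fits = np.zeros((cfg.num_trees, n))
        self.fit_total = np.zeros(n)
        self.mus: list[dict[int, float]] = [
            {id(r): 0.0} for r in self.roots
        ]

    # -- structural helpers --------------------------------------------------
    def _p_split(self, depth: int) -> float:
        return self.cfg.alpha * (1.0 + depth) ** (-self.cfg.beta)

    def _draw_rule(self, node: _Node):
        """Uniform (variable, split value, missing-direction) for a node, or None."""
        rng = self.rng
        rows = node.rows
        usable = []
        for j in rng.permutation(self.p):
            col = self.X[rows, j]
            vals = np.unique(col[~np.isnan(col)])
            if vals.size >= 2:
                usable.append((int(j), vals))
                break  # sample variable uniformly by permutation, take first usable
        if not usable:
            return None
        j, vals = usable[0]
        split = float(vals[rng.integers(vals.size - 1)])
        miss_left = bool(rng.integers(2)) if self.has_nan[j] else True
        return j, split, miss_left

    def _partition(self, rows: np.ndarray, j: int, split: float, miss_left: bool):
        col = self.X[rows, j]
        isnan = np.isnan(col)
        with np.errstate(invalid="ignore"):
            goleft = (col <= split) | (isnan if miss_left else np.zeros_like(isnan))
        return rows[goleft], rows[~goleft]

    def _leaf_loglik(self, s: float, nl: int, sigma2: float) -> float:
        sm2 = self.sigma_mu**2
        if self.prior_only:
            return 0.0
        v = sigma2 + nl * sm2
        return 0.5 * math.log(sigma2 / v) + sm2 * s * s / (2.0 * sigma2 * v)

    # -- MH moves -------------------------------------------------------------
    def _step_tree(self, t: int, resid: np.ndarray, sigma2: float) -> None:
        cfg, rng = self.cfg, self.rng
        root = self.roots[t]
        stump = root.leaf
        if stump:
            move, p_move_fwd = "grow", 1.0
        else:
            u = rng.random()
            if u < cfg.p_grow:
                move, p_move_fwd = "grow", cfg.p_grow
            elif u < cfg.p_grow + cfg.p_prune:
                move, p_move_fwd = "prune", cfg.p_prune
            else:
                move = "change"

        if move == "grow":
            leaves = _leaves(root, [])
            growable = [lf for lf in leaves if lf.rows.size >= 2 * cfg.min_leaf]
            if not growable:
                return
            node = growable[rng.integers(len(growable))]
            rule = self._draw_rule(node)
            if rule is None:
                return
            j, split, miss_left = rule
            lrows, rrows = self._partition(node.rows, j, split, miss_left)
            if lrows.size < cfg.min_leaf or rrows.size < cfg.min_leaf:
                return
            d = node.depth
            ps_d, ps_d1 = self._p_split(d), self._p_split(d + 1)
            log_prior = math.log(ps_d) + 2 * math.log(1 - ps_d1) - math.log(1 - ps_d)
            ll_old = self._leaf_loglik(resid[node.rows].sum(), node.rows.size, sigma2)
            ll_new = self._leaf_loglik(resid[lrows].sum(), lrows.size, sigma2) + \
                self._leaf_loglik(resid[rrows].sum(), rrows.size, sigma2)
            # reverse move: prune on the grown tree; growing `node` makes it
            # prunable but may stop its parent from being prunable
            w_after = self._count_prunable_after_grow(root, node)
            log_trans = math.log(cfg.p_prune / p_move_fwd) + math.log(len(growable) / w_after)
            if math.log(rng.random() + 1e-300) < log_trans + log_prior + (ll_new - ll_old):
                node.leaf = False
                node.var, node.split, node.miss_left = j, split, miss_left
                node.left = _Node(lrows, d + 1)
                node.right = _Node(rrows, d + 1)

        elif move == "prune":
            prunable = _prunable(root, [])
            if not prunable:
                return
            node = prunable[rng.integers(len(prunable))]
            d = node.depth
            ps_d, ps_d1 = self._p_split(d), self._p_split(d + 1)
            log_prior = math.log(1 - ps_d) - math.log(ps_d) - 2 * math.log(1 - ps_d1)
            ll_old = self._leaf_loglik(resid[node.left.rows].sum(), node.left.rows.size, sigma2) + \
                self._leaf_loglik(resid[node.right.rows].sum(), node.right.rows.size, sigma2)
            ll_new = self._leaf_loglik(resid[node.rows].sum(), node.rows.size, sigma2)
            # reverse move: grow on the pruned tree
            will_be_stump = node is root
            p_move_rev = 1.0 if will_be_stump else cfg.p_grow
            growable_after = self._count_growable_after_prune(root, node)
            log_trans = math.log(p_move_rev / cfg.p_prune) + \
                math.log(len(prunable) / max(growable_after, 1))
            if math.log(rng.random() + 1e-300) < log_trans + log_prior + (ll_new - ll_old):
                node.leaf = True
                node.left = node.right = None
                node.var = -1

        else:  # change: re-draw the rule of a prunable (singly internal) node
            prunable = _prunable(root, [])
            if not prunable:
                return
            node = prunable[rng.integers(len(prunable))]
            rule = self._draw_rule(node)
            if rule is None:
                return
            j, split, miss_left = rule
            lrows, rrows = self._partition(node.rows, j, split, miss_left)
            if lrows.size < cfg.min_leaf or rrows.size < cfg.min_leaf:
                return
            ll_old = self._leaf_loglik(resid[node.left.rows].sum(), node.left.rows.size, sigma2) + \
                self._leaf_loglik(resid[node.right.rows].sum(), node.right.rows.size, sigma2)
            ll_new = self._leaf_loglik(resid[lrows].sum(), lrows.size, sigma2) + \
                self._leaf_loglik(resid[rrows].sum(), rrows.size, sigma2)
            if math.log(rng.random() + 1e-300) < ll_new - ll_old:
                node.var, node.split, node.miss_left = j, split, miss_left
                node.left.rows, node.right.rows = lrows, rrows

    def _count_prunable_after_grow(self, root: _Node, grown: _Node) -> int:
        count = len(_prunable(root, []))
        # grown leaf becomes a prunable node (+1); if its sibling subtree makes
        # the parent currently prunable, the parent stops being prunable (-1)
        parent = self._find_parent(root, grown)
        if parent is not None and parent.left.leaf and parent.right.leaf:
            return count  # parent was prunable, now isn't: +1 - 1
        return count + 1

    def _count_growable_after_prune(self, root: _Node, pruned: _Node) -> int:
        leaves = _leaves(root, [])
        count = sum(
            1
            for lf in leaves
            if lf.rows.size >= 2 * self.cfg.min_leaf
            and lf is not pruned.left
            and lf is not pruned.right
        )
        if pruned.rows.size >= 2 * self.cfg.min_leaf:
            count += 1
        return count

    def _find_parent(self, node: _Node, target: _Node) -> _Node | None:
        if node.leaf:
            return None
        if node.left is target or node.right is target:
            return node
        return self._find_parent(node.left, target) or self._find_parent(node.right, target)

    # -- Gibbs sweeps ----------------------------------------------------------
    def _draw_leaves(self, t: int, resid: np.ndarray, sigma2: float) -> None:
        rng = self.rng
        sm2 = self.sigma_mu**2
        root = self.roots[t]
        new_fit = np.empty(self.n)
        mus: dict[int, float] = {}
        for leaf in _leaves(root, []):
            nl = leaf.rows.size
            if self.prior_only:
                mu = rng.normal(0.0, self.sigma_mu)
            else:
                s = resid[leaf.rows].sum()
                post_var = 1.0 / (1.0 / sm2 + nl / sigma2)
                mu = post_var * s / sigma2 + math.sqrt(post_var) * rng.normal()
            mus[id(leaf)] = mu
            new_fit[leaf.rows] = mu
        self.mus[t] = mus
        self.fit_total += new_fit - self.fits[t]
        self.fits[t] = new_fit

    def run(self):
        cfg = self.cfg
        rng = self.rng
        n = self.n
        sigma2 = float(self.lam) if self.lam > 0 else 1e-12
        forests: list[tuple] = []
        sigmas: list[float] = []
        total = cfg.n_burn + cfg.n_draws * cfg.keep_every
        for it in range(total):
            for t in range(cfg.num_trees):
                resid = self.y - self.fit_total + self.fits[t]
                self._step_tree(t, resid, sigma2)
                self._draw_leaves(t, resid, sigma2)
            e = self.y - self.fit_total
            sigma2 = (cfg.nu * self.lam + float(e @ e)) / rng.chisquare(cfg.nu + n)
            sigma2 = max(sigma2, 1e-18)
            if it >= cfg.n_burn and (it - cfg.n_burn) % cfg.keep_every == 0:
                forests.append(
                    tuple(_compact(r, self.mus[t]) for t, r in enumerate(self.roots))
                )
                sigmas.append(math.sqrt(sigma2))
        return forests, np.asarray(sigmas)


def _sigma_guess(X: np.ndarray, y_s: np.ndarray) -> float:
    """Least-squares residual SD on complete cases, response-SD fallback."""
    n, p = X.shape
    sd_y = float(np.std(y_s, ddof=1)) if n > 1 else 0.0
    complete = ~np.isnan(X).any(axis=1)
    if complete.sum() > p + 2:
        Xc = np.column_stack([np.ones(int(complete.sum())), X[complete]])
        coef, *_ = np.linalg.lstsq(Xc, y_s[complete], rcond=None)
        resid = y_s[complete] - Xc @ coef
        dof = complete.sum() - (p + 1)
        est = math.sqrt(float(resid @ resid) / max(dof, 1))
        if est > 0:
            return est
    return max(sd_y, 1e-6)


def fit(
    predictors: pd.DataFrame | np.ndarray,
    response,
    config: BARTConfig | None = None,
    _prior_only: bool = False,
) -> SumOfTreesPosterior:
    """Fit the sum-of-trees posterior by backfitting MCMC.

    ``predictors`` may contain missing values only when
    ``config.use_missing_data`` is set; the response must be complete.
    """
    cfg = config or BARTConfig()
    X, columns = _as_matrix(predictors, None)
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or len(y) != X.shape[0]:
        raise ValueError("response must be a vector matching the predictor rows")
    if np.isnan(y).any():
        raise ValueError("response contains missing values")
    if len(y) < 20:
        raise ValueError("need at least 20 rows to fit")
    nan_cols = [c for c, j in zip(columns, range(X.shape[1])) if np.isnan(X[:, j]).all()]
    if nan_cols:
        raise ValueError(f"all-missing predictor column(s): {nan_cols}")
    has_nan = bool(np.isnan(X).any())
    if has_nan and not cfg.use_missing_data:
        raise ValueError("predictors contain missing values but use_missing_data=False")

    ymin, ymax = float(y.min()), float(y.max())
    center = (ymin + ymax) / 2.0
    scale = ymax - ymin
    if scale == 0:
        scale = 1.0
    y_s = (y - center) / scale

    rng = np.random.default_rng(cfg.seed)
    sigma_hat = _sigma_guess(X, y_s)
    lam = sigma_hat**2 * stats.chi2.ppf(1.0 - cfg.q, cfg.nu) / cfg.nu

    sampler = _Sampler(X, y_s, cfg, rng, lam, prior_only=_prior_only)
    forests, sigmas = sampler.run()
    return SumOfTreesPosterior(
        config=cfg,
        columns=columns,
        forests=forests,
        sigma=sigmas * scale,
        center=center,
        scale=scale,
        train_missing=has_nan,
    )


def predict(
    model: SumOfTreesPosterior,
    rows: pd.DataFrame | np.ndarray,
    return_draws: bool = False,
    max_draws: int | None = None,
):
    """Posterior-mean prediction per row, in response units.

    With ``return_draws`` the full draws-by-rows matrix is returned as well.
    ``max_draws`` evaluates an evenly thinned subset of the posterior.
    """
    X, _ = _as_matrix(rows, model.columns if isinstance(rows, pd.DataFrame) else None)
    if X.shape[1] != len(model.columns):
        raise ValueError(
            f"expected {len(model.columns)} predictor column(s), got {X.shape[1]}"
        )
    if np.isnan(X).any() and not (model.config.use_missing_data and model.train_missing):
        raise ValueError(
            "prediction rows contain missing values but the model was not "
            "trained with missing data"
        )
    n = X.shape[0]
    idx_all = np.arange(n)
    forests = model.forests
    if max_draws is not None and max_draws < len(forests):
        sel = np.linspace(0, len(forests) - 1, max_draws).round().astype(int)
        forests = [forests[i] for i in sel]
    draws = np.zeros((len(forests), n))
    scratch = np.empty(n)
    for d, forest in enumerate(forests):
        acc = np.zeros(n)
        for tree in forest:
            _eval_tree(tree, X, idx_all, scratch)
            acc += scratch
        draws[d] = acc
    draws = model.center + model.scale * draws
    mean = draws.mean(axis=0)
    if return_draws:
        return mean, draws
    return mean


def fit_metrics(
    model: SumOfTreesPosterior,
    predictors,
    response,
    max_draws: int | None = None,
) -> FitMetrics:
    """Pseudo-R^2 and RMSE of posterior-mean predictions.

    In-sample when called with the training data; pass held-out rows for an
    out-of-sample assessment.
    """
    y = np.asarray(response, dtype=float)
    if np.std(y) == 0:
        raise ValueError("zero-variance response: R^2 undefined")
    yhat = predict(model, predictors, max_draws=max_draws)
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return FitMetrics(r_squared=1.0 - sse / sst, rmse=math.sqrt(sse / len(y)))


def cv_select(
    predictors: pd.DataFrame | np.ndarray,
    response,
    grid: list[BARTConfig],
    folds: int = 5,
    seed: int = 0,
) -> tuple[BARTConfig, pd.DataFrame]:
    """K-fold cross-validated RMSE per config; returns the winner.

    Ties break toward fewer trees, then smaller ``k``.  Fold assignment is a
    seeded permutation shared across configs.
    """
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n // folds < 10:
        raise ValueError("each fold must contain at least 10 rows")
    X = predictors.reset_index(drop=True) if isinstance(predictors, pd.DataFrame) \
        else np.asarray(predictors, dtype=float)
    perm = np.random.default_rng(seed).permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f in range(folds):
        fold_of[perm[f::folds]] = f

    records = []
    for ci, cfg in enumerate(grid):
        sq_err = np.zeros(folds)
        for f in range(folds):
            test = fold_of == f
            Xtr = X.loc[~test] if isinstance(X, pd.DataFrame) else X[~test]
            Xte = X.loc[test] if isinstance(X, pd.DataFrame) else X[test]
            m = fit(Xtr, y[~test], cfg)
            pred = predict(m, Xte)
            sq_err[f] = float(np.mean((y[test] - pred) ** 2))
        rmse = math.sqrt(float(sq_err.mean()))
        records.append({"config_index": ci, "num_trees": cfg.num_trees,
                        "k": cfg.k, "nu": cfg.nu, "q": cfg.q, "cv_rmse": rmse})
    table = pd.DataFrame(records)
    order = table.sort_values(["cv_rmse", "num_trees", "k"]).index
    best = grid[int(table.loc[order[0], "config_index"])]
    return best, table


def default_cv_grid(base: BARTConfig | None = None) -> list[BARTConfig]:
    """The conventional search grid: k x (nu, q) x num_trees."""
    base = base or BARTConfig()
    grid = []
    for m in (50, 200):
        for k in (2.0, 3.0, 5.0):
            for nu, q in ((3.0, 0.9), (3.0, 0.99), (10.0, 0.75)):
                grid.append(replace(base, num_trees=m, k=k, nu=nu, q=q))
    return grid
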