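"""Stochastic gradient-boosted regression trees for niche modeling.

A from-scratch implementation of the boosting workflow used for species
distribution modeling: shallow least-squares regression trees fit
stagewise to the negative gradient of a Bernoulli (presence-absence) or
Laplace (abundance) loss, with shrinkage, bagging, k-fold
cross-validated selection of the number of trees, backward model
simplification, relative-influence accounting and partial-dependence
response curves.

Conventions follow the ecology BRT literature: slow learning rates,
tree complexity given as interaction depth (maximum terminal nodes
minus one), a 50% bag fraction, and tree counts selected where the mean
held-out deviance across folds is minimal.

The split search and tree routing are numba-compiled; everything is
bit-reproducible given (data, config, seed) — fold assignment, bagging
draws and tie-breaks (lowest variable index, then lowest split value)
are all deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from numba import njit

_EPS_NEWTON = 1e-4     # clamp on the Bernoulli Newton denominator
_TIE_EPS = 1e-12       # strict-improvement margin for split tie-breaks


@dataclasses.dataclass
class BRTConfig:
    """Hyperparameters of one boosted-tree fit.

    tree_complexity is the interaction depth: trees carry at most
    ``tree_complexity + 1`` terminal nodes, grown best-first.
    ``tree_block`` trees are added between cross-validation
    checkpoints; growth stops once the mean held-out deviance has not
    improved for ``patience_blocks`` checkpoints (or at ``max_trees``).
    """

    loss: str = "bernoulli"           # bernoulli | laplace
    learning_rate: float = 0.005
    tree_complexity: int = 5
    bag_fraction: float = 0.5
    n_folds: int = 10
    tree_block: int = 50
    max_trees: int = 10_000
    min_obs_leaf: int = 10
    patience_blocks: int = 5
    seed: int = 0

    def validate(self) -> "BRTConfig":
        if self.loss not in ("bernoulli", "laplace"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if not 0 < self.learning_rate < 1:
            raise ValueError("learning_rate must be in (0, 1)")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if self.tree_complexity < 1 or self.n_folds < 2 or self.tree_block < 1:
            raise ValueError("bad tree_complexity / n_folds / tree_block")
        return self


@dataclasses.dataclass
class _Tree:
    """One regression tree in flat-array form.

    ``var[i] < 0`` marks node i terminal with prediction ``value[i]``;
    otherwise rows with ``x[var[i]] <= threshold[i]`` go to
    ``left[i]``, the rest to ``right[i]``.
    """

    var: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(X.shape[0])
        _route(X, self.var, self.threshold, self.left, self.right, self.value, out)
        return out

    def to_dict(self) -> dict:
        return {k: getattr(self, k).tolist()
                for k in ("var", "threshold", "left", "right", "value")}

    @classmethod
    def from_dict(cls, d: dict) -> "_Tree":
        return cls(np.asarray(d["var"], dtype=np.int64),
                   np.asarray(d["threshold"], dtype=np.float64),
                   np.asarray(d["left"], dtype=np.int64),
                   np.asarray(d["right"], dtype=np.int64),
                   np.asarray(d["value"], dtype=np.float64))


@njit(cache=True)
def _route(X, var, thr, left, right, value, out):  # pragma: no cover - numba
    for i in range(X.shape[0]):
        node = 0
        while var[node] >= 0:
            if X[i, var[node]] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]


@njit(cache=True)
def _best_split(X, z, idx, min_obs):  # pragma: no cover - numba
    """Best least-squares split of the rows ``idx`` of X on residual z.

    Returns (var, threshold, improvement); var = -1 when no valid split
    exists.  Ties resolve to the lowest variable index, then the lowest
    threshold (ascending scan with strict improvement).
    """
    n = idx.shape[0]
    p = X.shape[1]
    best_imp = 0.0
    best_var = -1
    best_thr = 0.0
    if n < 2 * min_obs:
        return best_var, best_thr, best_imp
    x = np.empty(n)
    zz = np.empty(n)
    for j in range(p):
        for t in range(n):
            x[t] = X[idx[t], j]
            zz[t] = z[idx[t]]
        order = np.argsort(x, kind="mergesort")
        total = 0.0
        for t in range(n):
            total += zz[t]
        base = total * total / n
        left_sum = 0.0
        for t in range(n - 1):
            o = order[t]
            left_sum += zz[o]
            nl = t + 1
            nr = n - nl
            if nl < min_obs or nr < min_obs:
                continue
            if x[o] == x[order[t + 1]]:
                continue
            right_sum = total - left_sum
            imp = left_sum * left_sum / nl + right_sum * right_sum / nr - base
            if imp > best_imp + _TIE_EPS:
                best_imp = imp
                best_var = j
                best_thr = 0.5 * (x[o] + x[order[t + 1]])
    return best_var, best_thr, best_imp


def _grow_tree(X, z, bag, max_leaves, min_obs):
    """Best-first least-squares tree on the bagged rows.

    Returns (tree arrays sans terminal values, per-leaf bag membership,
    list of (var, improvement) for the splits made).
    """
    var = [-1]
    thr = [0.0]
    left = [-1]
    right = [-1]
    members = {0: bag}
    cand = {}
    v, t, imp = _best_split(X, z, bag, min_obs)
    if v >= 0:
        cand[0] = (imp, v, t)
    splits = []
    n_leaves = 1
    while n_leaves < max_leaves and cand:
        node = max(cand, key=lambda k: (cand[k][0], -k))
        imp, v, t = cand.pop(node)
        idx = members.pop(node)
        go_left = X[idx, v] <= t
        li, ri = idx[go_left], idx[~go_left]
        var[node] = v
        thr[node] = t
        nl, nr = len(var), len(var) + 1
        left[node], right[node] = nl, nr
        for child, cidx in ((nl, li), (nr, ri)):
            var.append(-1)
            thr.append(0.0)
            left.append(-1)
            right.append(-1)
            members[child] = cidx
            cv, ct, cimp = _best_split(X, z, cidx, min_obs)
            if cv >= 0:
                cand[child] = (cimp, cv, ct)
        splits.append((v, imp))
        n_leaves += 1
    tree = _Tree(np.asarray(var, dtype=np.int64),
                 np.asarray(thr, dtype=np.float64),
                 np.asarray(left, dtype=np.int64),
                 np.asarray(right, dtype=np.int64),
                 np.zeros(len(var)))
    return tree, members, splits


def _sigmoid(f: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(f, -500, 500)))


def bernoulli_deviance(y: np.ndarray, f: np.ndarray) -> float:
    """Mean binomial deviance of margins f, -2*(y*f - log(1+e^f))."""
    return float(np.mean(-2.0 * (y * f - np.logaddexp(0.0, f))))


def laplace_deviance(y: np.ndarray, f: np.ndarray) -> float:
    """Mean absolute deviation (the Laplace working deviance)."""
    return float(np.mean(np.abs(y - f)))


class _Booster:
    """Stagewise fitter over a fixed training set, with optional tracked
    extra rows (the held-out fold) whose margins are updated per tree."""

    def __init__(self, X, y, cfg: BRTConfig, rng: np.random.Generator,
                 X_track=None):
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.cfg = cfg
        self.rng = rng
        self.trees: list[_Tree] = []
        self.influence = np.zeros(X.shape[1])
        if cfg.loss == "bernoulli":
            pbar = float(np.clip(self.y.mean(), 1e-8, 1 - 1e-8))
            self.init = float(np.log(pbar / (1.0 - pbar)))
        else:
            self.init = float(np.median(self.y))
        self.f = np.full(len(self.y), self.init)
        self.X_track = (np.ascontiguousarray(X_track, dtype=np.float64)
                        if X_track is not None else None)
        self.f_track = (np.full(len(X_track), self.init)
                        if X_track is not None else None)
        self.n_bag = max(2 * cfg.min_obs_leaf,
                         int(round(cfg.bag_fraction * len(self.y))))
        self.n_bag = min(self.n_bag, len(self.y))

    def grow(self, n_new: int) -> None:
        cfg = self.cfg
        max_leaves = cfg.tree_complexity + 1
        for _ in range(n_new):
            bag = self.rng.permutation(len(self.y))[: self.n_bag]
            if cfg.loss == "bernoulli":
                p = _sigmoid(self.f)
                z = self.y - p
            else:
                z = np.sign(self.y - self.f)
            tree, members, splits = _grow_tree(
                self.X, z, bag, max_leaves, cfg.min_obs_leaf)
            for leaf, idx in members.items():
                if len(idx) == 0:
                    continue
                if cfg.loss == "bernoulli":
                    num = z[idx].sum()
                    den = (p[idx] * (1.0 - p[idx])).sum()
                    gamma = num / max(den, _EPS_NEWTON)
                else:
                    gamma = float(np.median(self.y[idx] - self.f[idx]))
                tree.value[leaf] = gamma
            for v, imp in splits:
                self.influence[v] += imp
            lr = cfg.learning_rate
            self.f += lr * tree.predict(self.X)
            if self.X_track is not None:
                self.f_track += lr * tree.predict(self.X_track)
            tree.value *= lr          # store shrunken terminal values
            self.trees.append(tree)

    def deviance(self) -> float:
        fn = bernoulli_deviance if self.cfg.loss == "bernoulli" else laplace_deviance
        return fn(self.y, self.f)

    def track_deviance(self, y_track) -> float:
        fn = bernoulli_deviance if self.cfg.loss == "bernoulli" else laplace_deviance
        return fn(np.asarray(y_track, dtype=np.float64), self.f_track)


@dataclasses.dataclass
class BRTModel:
    """A fitted boosted-tree ensemble plus its CV diagnostics."""

    config: BRTConfig
    feature_names: list[str]
    init: float
    trees: list[_Tree]
    influence_raw: np.ndarray          # accumulated squared improvements
    n_trees: int
    cv_profile: pd.DataFrame           # n_trees x (mean/sd held-out deviance)
    cv_heldout: pd.Series | None       # held-out link predictions at n_trees
    train_index: pd.Index
    train_deviance: np.ndarray         # full-train deviance per stage
    n_excluded: int = 0
    flags: list[str] = dataclasses.field(default_factory=list)

    # -- prediction ---------------------------------------------------

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        return np.ascontiguousarray(X, dtype=np.float64)

    def predict_link(self, X) -> np.ndarray:
        """Additive prediction on the link scale (logit for Bernoulli,
        response scale for Laplace)."""
        Xm = self._matrix(X)
        f = np.full(Xm.shape[0], self.init)
        for tree in self.trees[: self.n_trees]:
            f += tree.predict(Xm)
        return f

    def predict(self, X) -> np.ndarray:
        """Probability (Bernoulli) or abundance (Laplace) prediction."""
        f = self.predict_link(X)
        return _sigmoid(f) if self.config.loss == "bernoulli" else f

    # -- serialization ------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({
            "schema": "diatom-ntrans-brt/1",
            "config": dataclasses.asdict(self.config),
            "feature_names": self.feature_names,
            "init": self.init,
            "n_trees": self.n_trees,
            "influence_raw": self.influence_raw.tolist(),
            "trees": [t.to_dict() for t in self.trees[: self.n_trees]],
        })

    @classmethod
    def from_json(cls, text: str) -> "BRTModel":
        d = json.loads(text)
        return cls(config=BRTConfig(**d["config"]),
                   feature_names=d["feature_names"], init=d["init"],
                   trees=[_Tree.from_dict(t) for t in d["trees"]],
                   influence_raw=np.asarray(d["influence_raw"]),
                   n_trees=d["n_trees"], cv_profile=pd.DataFrame(),
                   cv_heldout=None, train_index=pd.Index([]),
                   train_deviance=np.empty(0))


def _fold_assignment(y: np.ndarray, cfg: BRTConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..k-1; stratified by class for Bernoulli."""
    n = len(y)
    folds = np.empty(n, dtype=np.int64)
    if cfg.loss == "bernoulli":
        for cls in (0.0, 1.0):
            where = np.flatnonzero(y == cls)
            perm = rng.permutation(len(where))
            folds[where[perm]] = np.arange(len(where)) % cfg.n_folds
    else:
        perm = rng.permutation(n)
        folds[perm] = np.arange(n) % cfg.n_folds
    return folds


def fit_brt(X, y, cfg: BRTConfig) -> BRTModel:
    """Fit a BRT with cross-validated selection of the number of trees.

    ``X`` is a DataFrame of predictors (rows with missing predictor
    values are excluded and counted), ``y`` the response aligned on the
    same index — binary in {0, 1} for the Bernoulli loss, real for
    Laplace.  Trees are added in blocks; after each block the held-out
    deviance of every fold is recorded, and the selected tree count
    minimizes the mean across folds.  The returned model is refit on
    all rows at that tree count.
    """
    cfg.validate()
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    keep = ~X.isna().any(axis=1) & y.notna()
    n_excluded = int((~keep).sum())
    X, y = X.loc[keep], y.loc[keep]
    feature_names = [str(c) for c in X.columns]
    Xm = X.to_numpy(dtype=float)
    ym = y.to_numpy(dtype=float)
    flags: list[str] = []

    if cfg.loss == "bernoulli" and not set(np.unique(ym)) <= {0.0, 1.0}:
        raise ValueError("bernoulli loss needs a binary 0/1 response")
    if np.ptp(ym) == 0:
        flags.append("constant_response")
        warnings.warn("constant response: returning an intercept-only model")
        init = (float(np.log(np.clip(ym.mean(), 1e-8, 1 - 1e-8)
                             / (1 - np.clip(ym.mean(), 1e-8, 1 - 1e-8))))
                if cfg.loss == "bernoulli" else float(np.median(ym)))
        return BRTModel(cfg, feature_names, init, [], np.zeros(Xm.shape[1]), 0,
                        pd.DataFrame(columns=["n_trees", "mean_dev", "sd_dev"]),
                        None, X.index, np.empty(0), n_excluded, flags)
    if len(ym) < 2 * cfg.n_folds:
        raise ValueError("need at least 2*n_folds observations")

    root = np.random.SeedSequence(cfg.seed)
    ss_folds, ss_cv, ss_final = root.spawn(3)
    folds = _fold_assignment(ym, cfg, np.random.default_rng(ss_folds))

    # --- cross-validation over tree counts, in blocks -----------------
    fold_rngs = [np.random.default_rng(s) for s in ss_cv.spawn(cfg.n_folds)]
    boosters = []
    val_sets = []
    for kf in range(cfg.n_folds):
        tr = folds != kf
        va = ~tr
        boosters.append(_Booster(Xm[tr], ym[tr], cfg, fold_rngs[kf],
                                 X_track=Xm[va]))
        val_sets.append((np.flatnonzero(va), ym[va]))

    checkpoints: list[int] = []
    fold_dev: list[np.ndarray] = []
    heldout_at: list[np.ndarray] = []
    n_now = 0
    best_ck = -1
    while n_now < cfg.max_trees:
        block = min(cfg.tree_block, cfg.max_trees - n_now)
        devs = np.empty(cfg.n_folds)
        ho = np.empty(len(ym))
        for kf, booster in enumerate(boosters):
            booster.grow(block)
            devs[kf] = booster.track_deviance(val_sets[kf][1])
            ho[val_sets[kf][0]] = booster.f_track
        n_now += block
        checkpoints.append(n_now)
        fold_dev.append(devs)
        heldout_at.append(ho)
        means = [d.mean() for d in fold_dev]
        best_ck = int(np.argmin(means))
        if len(fold_dev) - 1 - best_ck >= cfg.patience_blocks:
            break

    means = np.array([d.mean() for d in fold_dev])
    sds = np.array([d.std(ddof=1) for d in fold_dev])
    best_ck = int(np.argmin(means))
    n_trees = checkpoints[best_ck]
    if best_ck == 0:
        flags.append("learning_rate_too_high")
        warnings.warn("held-out deviance already rising after one block; "
                      "consider a lower learning rate")
    cv_profile = pd.DataFrame(
        {"n_trees": checkpoints, "mean_dev": means, "sd_dev": sds})
    cv_heldout = pd.Series(heldout_at[best_ck], index=X.index,
                           name="cv_link_prediction")

    # --- final refit on all data at the selected tree count -----------
    final = _Booster(Xm, ym, cfg, np.random.default_rng(ss_final))
    train_dev = np.empty(n_trees)
    for i in range(n_trees):
        final.grow(1)
        train_dev[i] = final.deviance()

    return BRTModel(cfg, feature_names, final.init, final.trees,
                    final.influence, n_trees, cv_profile, cv_heldout,
                    X.index, train_dev, n_excluded, flags)


def relative_influence(model: BRTModel) -> pd.Series:
    """Per-variable relative influence, scaled to sum to 100.

    Each split's squared-error improvement is credited to its split
    variable and accumulated over all trees of the ensemble; totals are
    rescaled to percentages.  A model with no splits reports all zeros.
    """
    tot = model.influence_raw
    s = tot.sum()
    if s <= 0:
        out = pd.Series(np.zeros(len(model.feature_names)),
                        index=model.feature_names, name="relative_influence")
        out.attrs["no_splits"] = True
        return out
    out = pd.Series(100.0 * tot / s, index=model.feature_names,
                    name="relative_influence")
    out.attrs["no_splits"] = False
    return out.sort_values(ascending=False)


def partial_dependence(
    model: BRTModel, X, variable: str, grid: np.ndarray | None = None,
    n_grid: int = 50, scale: str = "link",
) -> pd.Series:
    """Univariate response curve by the clamped-average construction.

    For each grid value g the variable's column is set to g in every
    training row and the model predictions are averaged.  Returned on
    the link scale by default; ``scale='response'`` applies the inverse
    link (probability for Bernoulli).
    """
    if isinstance(X, pd.DataFrame):
        Xm = X[model.feature_names].to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
    j = model.feature_names.index(variable)
    if grid is None:
        lo, hi = np.nanmin(Xm[:, j]), np.nanmax(Xm[:, j])
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    out = np.empty(len(grid))
    work = Xm.copy()
    for i, g in enumerate(grid):
        work[:, j] = g
        f = model.predict_link(work)
        if scale == "response" and model.config.loss == "bernoulli":
            f = _sigmoid(f)
        out[i] = f.mean()
    return pd.Series(out, index=pd.Index(grid, name=variable),
                     name=f"pd_{variable}_{scale}")


def simplify(model: BRTModel, X: pd.DataFrame, y, cfg: BRTConfig | None = None
             ) -> tuple[BRTModel, list[str]]:
    """Backward predictor elimination under the one-standard-error rule.

    Iteratively drops the predictor with the lowest relative influence
    and refits; drops continue while the reduced model's minimum mean
    CV deviance stays within one standard error (across folds) of the
    full model's.  Returns the reduced model and the dropped sequence.
    """
    cfg = cfg or model.config
    base_row = model.cv_profile.loc[model.cv_profile["mean_dev"].idxmin()]
    budget = base_row["mean_dev"] + base_row["sd_dev"] / np.sqrt(cfg.n_folds)
    current = model
    kept = list(model.feature_names)
    dropped: list[str] = []
    while len(kept) > 1:
        infl = relative_influence(current)
        worst = infl.index[-1]
        trial_feats = [f for f in kept if f != worst]
        trial = fit_brt(X[trial_feats], y, cfg)
        trial_dev = trial.cv_profile["mean_dev"].min()
        if trial_dev <= budget:
            current, kept = trial, trial_feats
            dropped.append(worst)
        else:
            break
    return current, dropped


def cv_auc(y: np.ndarray, score: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney rank statistic (ties at 1/2)."""
    y = np.asarray(y, dtype=float)
    score = np.asarray(score, dtype=float)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        return np.nan
    from scipy.stats import rankdata
    r = rankdata(score)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def evaluate(model: BRTModel, X, y) -> dict:
    """Validation metrics with the field's conventional pass criteria.

    Bernoulli: cross-validated AUC of the held-out fold predictions,
    flagged as passing above 0.7.  Laplace: observed responses are
    binned into quartiles (classes 1-4) and the Pearson correlation
    between quartile class and prediction is reported, flagged at
    p < 0.05 and |r| > 0.35.  If (X, y) match the training rows the
    stored cross-validated predictions are used; otherwise predictions
    are made directly on X (apparent, not cross-validated — noted in
    the output).
    """
    from scipy import stats as sps
    y = np.asarray(pd.Series(y), dtype=float)
    if (model.cv_heldout is not None and len(y) == len(model.cv_heldout)):
        score = model.cv_heldout.to_numpy()
        cross_validated = True
    else:
        score = model.predict_link(X)
        cross_validated = False
    out: dict = {"cross_validated": cross_validated}
    if model.config.loss == "bernoulli":
        auc = cv_auc(y, score)
        out.update(auc=auc, passes=bool(auc > 0.7) if auc == auc else False)
    else:
        q = np.quantile(y, [0.25, 0.5, 0.75])
        cls = np.digitize(y, q, right=True) + 1       # quartile class 1..4
        if np.ptp(cls) == 0 or np.ptp(score) == 0:
            out.update(r=np.nan, p=np.nan, passes=False)
        else:
            r, p = sps.pearsonr(cls.astype(float), score)
            out.update(r=float(r), p=float(p),
                       passes=bool(p < 0.05 and abs(r) > 0.35))
        out["quartile_classes"] = cls
    return out
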