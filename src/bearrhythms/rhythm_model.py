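"""Multinomial models of rhythm-class probabilities.

The response is the per-window rhythm class (ultradian / diel / infradian
/ arrhythmic).  Candidate models combine categorical, linear and smooth
predictor terms with group effects for bear identity and season, and are
fitted by penalized maximum likelihood:

* smooth terms use a low-rank spline basis whose quadratic penalty has the
  linear function in its null space, so heavy smoothing shrinks a smooth
  back to a straight line;
* group indicators carry a ridge penalty, the classical analogue of a
  flat-prior random intercept at its posterior mode;
* model comparison uses grouped K-fold cross-validated expected log
  pointwise predictive density (elpd) and, for near-ties, stacking of the
  held-out predictive distributions on the simplex.

The log-likelihood is averaged over observations and penalties are not
rescaled with n, so duplicating every row leaves estimates unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize

DEFAULT_LAMBDA_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_N_BASIS = 8
DEFAULT_GROUP_RIDGE = 1.0
GRAD_TOL = 1e-6
MAX_NEWTON_ITER = 200
# coefficient norm beyond which the optimum is effectively on the boundary
# (separation / empty class); logits of that size are numerically 0 or 1
SEPARATION_NORM = 50.0


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class Term:
    """One predictor term: categorical, linear, or smooth (optionally
    interacted with a categorical via ``by``, one smooth per level)."""

    predictor: str
    form: str  # "categorical" | "linear" | "smooth"
    by: str | None = None

    def __post_init__(self):
        if self.form not in ("categorical", "linear", "smooth"):
            raise ValueError(f"unknown term form {self.form!r}")
        if self.by is not None and self.form != "smooth":
            raise ValueError("'by' interactions are defined for smooth terms only")

    @property
    def label(self) -> str:
        if self.form == "smooth":
            return f"s({self.predictor})" + (f"*{self.by}" if self.by else "")
        return self.predictor


@dataclass(frozen=True)
class ModelSpec:
    """A named candidate model: response terms plus grouping factors."""

    name: str
    terms: tuple[Term, ...] = ()
    groups: tuple[str, ...] = ()
    n_basis: int = DEFAULT_N_BASIS

    def required_columns(self) -> list[str]:
        cols = []
        for t in self.terms:
            cols.append(t.predictor)
            if t.by:
                cols.append(t.by)
        cols.extend(self.groups)
        return cols


def candidate_models(
    state: str, groups: tuple[str, ...] = ("bear_id", "season")
) -> list[ModelSpec]:
    """The a-priori candidate sets for the hibernation and active states.

    Hibernation: 15 models over body mass, age class, sex, status, snow
    depth, day length, ambient temperature and den attributes.  Active: 13
    models over the same intrinsic predictors plus day length, its
    direction and their interaction.
    """

    def s(p, by=None):
        return Term(p, "smooth", by)

    def cat(p):
        return Term(p, "categorical")

    def lin(p):
        return Term(p, "linear")

    if state == "hibernation":
        sets: list[tuple[str, tuple[Term, ...]]] = [
            ("null", ()),
            ("s(body_mass)", (s("body_mass"),)),
            ("age_class", (cat("age_class"),)),
            ("sex", (cat("sex"),)),
            ("status", (cat("status"),)),
            ("s(snow_depth)", (s("snow_depth"),)),
            ("s(day_length)", (s("day_length"),)),
            ("s(ambient_temp)", (s("ambient_temp"),)),
            ("s(open_area)", (s("open_area"),)),
            ("den_type", (cat("den_type"),)),
            ("s(open_area)+s(snow_depth)", (s("open_area"), s("snow_depth"))),
            ("den_type+s(snow_depth)", (cat("den_type"), s("snow_depth"))),
            (
                "s(open_area)+s(snow_depth)+status",
                (s("open_area"), s("snow_depth"), cat("status")),
            ),
            (
                "den_type+s(snow_depth)+status",
                (cat("den_type"), s("snow_depth"), cat("status")),
            ),
            (
                "den_type+s(snow_depth)+s(open_area)",
                (cat("den_type"), s("snow_depth"), s("open_area")),
            ),
        ]
    elif state == "active":
        sets = [
            ("null", ()),
            ("s(body_mass)", (s("body_mass"),)),
            ("age_class", (cat("age_class"),)),
            ("sex", (cat("sex"),)),
            ("status", (cat("status"),)),
            ("day_length_direction", (cat("day_length_direction"),)),
            ("s(day_length)", (s("day_length"),)),
            ("s(ambient_temp)", (s("ambient_temp"),)),
            ("snow_depth", (lin("snow_depth"),)),
            ("s(day_length)+status", (s("day_length"), cat("status"))),
            ("s(ambient_temp)+status", (s("ambient_temp"), cat("status"))),
            (
                "s(day_length)*direction",
                (s("day_length", by="day_length_direction"),),
            ),
            (
                "s(day_length)*direction+status",
                (s("day_length", by="day_length_direction"), cat("status")),
            ),
        ]
    else:
        raise ValueError("state must be 'hibernation' or 'active'")
    return [ModelSpec(name, terms, groups) for name, terms in sets]


# ---------------------------------------------------------------------------
# spline basis


def spline_basis(
    x: np.ndarray, n_basis: int = DEFAULT_N_BASIS, penalty_order: int = 2, degree: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Uniform B-spline basis with a difference penalty (P-spline).

    Knots are equally spaced (extended beyond the data range), so sequences
    of coefficients with vanishing ``penalty_order``-th difference lie in
    the penalty null space and reproduce polynomials of degree
    ``penalty_order - 1`` in x exactly: with the default second-order
    penalty, infinite smoothing recovers a straight line.

    Returns (basis matrix n x n_basis, penalty matrix, knot vector).
    """
    x = np.asarray(x, dtype=float)
    if n_basis <= degree:
        raise ValueError("n_basis must exceed the spline degree")
    xmin, xmax = x.min(), x.max()
    if xmax <= xmin:
        raise ValueError("constant x: cannot build a spline basis")
    h = (xmax - xmin) / (n_basis - degree)
    knots = xmin + h * np.arange(-degree, n_basis + 1)
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    D = np.diff(np.eye(n_basis), n=penalty_order, axis=0)
    S = D.T @ D
    return B, S, knots


def _eval_basis(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    lo, hi = knots[degree], knots[-degree - 1]
    x = np.asarray(x, dtype=float)
    if (x < lo).any() or (x > hi).any():
        warnings.warn("covariate outside training range; clipped for spline evaluation", stacklevel=2)
        x = np.clip(x, lo, hi)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def _sum_to_zero(B: np.ndarray, S: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Absorb the sum-to-zero identifiability constraint (column 1'B beta = 0)."""
    c = B.sum(axis=0)[:, None]
    Q, _ = np.linalg.qr(c, mode="complete")
    Z = Q[:, 1:]
    return B @ Z, Z.T @ S @ Z, Z


# ---------------------------------------------------------------------------
# design construction

@dataclass
class _Block:
    kind: str  # "intercept" | "linear" | "categorical" | "smooth" | "group"
    columns: slice
    term: Term | None = None
    levels: list | None = None
    knots: np.ndarray | None = None
    constraint: np.ndarray | None = None
    penalty: np.ndarray | None = None
    by_level: object = None


class Design:
    """Training-frozen design: builds X for new data, tracks penalties."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.blocks: list[_Block] = []
        self.column_names: list[str] = []
        pos = 0

        def add(kind, width, names, **kw):
            nonlocal pos
            self.blocks.append(_Block(kind=kind, columns=slice(pos, pos + width), **kw))
            self.column_names.extend(names)
            pos += width

        add("intercept", 1, ["(Intercept)"])
        for term in spec.terms:
            if term.form == "linear":
                add("linear", 1, [term.predictor], term=term)
            elif term.form == "categorical":
                levels = sorted(data[term.predictor].dropna().unique().tolist())
                add(
                    "categorical",
                    len(levels) - 1,
                    [f"{term.predictor}[{l}]" for l in levels[1:]],
                    term=term,
                    levels=levels,
                )
            else:  # smooth
                x = data[term.predictor].to_numpy(dtype=float)
                B, S, knots = spline_basis(x, spec.n_basis)
                Bc, Sc, Z = _sum_to_zero(B, S)
                if term.by is None:
                    add(
                        "smooth",
                        Bc.shape[1],
                        [f"s({term.predictor}).{j}" for j in range(Bc.shape[1])],
                        term=term,
                        knots=knots,
                        constraint=Z,
                        penalty=Sc,
                    )
                else:
                    by_levels = sorted(data[term.by].dropna().unique().tolist())
                    add(
                        "categorical",
                        len(by_levels) - 1,
                        [f"{term.by}[{l}]" for l in by_levels[1:]],
                        term=Term(term.by, "categorical"),
                        levels=by_levels,
                    )
                    for lev in by_levels:
                        add(
                            "smooth",
                            Bc.shape[1],
                            [f"s({term.predictor}):{term.by}[{lev}].{j}" for j in range(Bc.shape[1])],
                            term=term,
                            knots=knots,
                            constraint=Z,
                            penalty=Sc,
                            by_level=lev,
                        )
        for g in spec.groups:
            levels = sorted(data[g].dropna().unique().tolist())
            add(
                "group",
                len(levels),
                [f"{g}[{l}]" for l in levels],
                term=Term(g, "categorical"),
                levels=levels,
            )
        self.n_columns = pos

    def matrix(self, data: pd.DataFrame, training: bool = False) -> np.ndarray:
        n = len(data)
        X = np.zeros((n, self.n_columns))
        for blk in self.blocks:
            cols = blk.columns
            if blk.kind == "intercept":
                X[:, cols] = 1.0
            elif blk.kind == "linear":
                X[:, cols.start] = data[blk.term.predictor].to_numpy(dtype=float)
            elif blk.kind == "categorical":
                vals = data[blk.term.predictor]
                unseen = set(vals.dropna().unique()) - set(blk.levels)
                if unseen:
                    raise ValueError(
                        f"unseen level(s) {sorted(map(str, unseen))} for "
                        f"categorical predictor {blk.term.predictor!r}"
                    )
                for j, lev in enumerate(blk.levels[1:]):
                    X[:, cols.start + j] = (vals == lev).to_numpy(dtype=float)
            elif blk.kind == "smooth":
                x = data[blk.term.predictor].to_numpy(dtype=float)
                B = _eval_basis(x, blk.knots) @ blk.constraint
                if blk.by_level is not None:
                    B = B * (data[blk.term.by] == blk.by_level).to_numpy(dtype=float)[:, None]
                X[:, cols] = B
            elif blk.kind == "group":
                vals = data[blk.term.predictor]
                # unseen group levels get zero indicators: a new bear or
                # season is predicted at the population level
                for j, lev in enumerate(blk.levels):
                    X[:, cols.start + j] = (vals == lev).to_numpy(dtype=float)
        return X

    def penalties(self, lam: float, group_ridge: float) -> np.ndarray:
        """Full (p x p) penalty matrix applied to each contrast vector."""
        P = np.zeros((self.n_columns, self.n_columns))
        for blk in self.blocks:
            if blk.kind == "smooth":
                P[blk.columns, blk.columns] += lam * blk.penalty
            elif blk.kind == "group":
                idx = np.arange(blk.columns.start, blk.columns.stop)
                P[idx, idx] += group_ridge
        return P

    @property
    def has_smooth(self) -> bool:
        return any(b.kind == "smooth" for b in self.blocks)


# ---------------------------------------------------------------------------
# penalized multinomial fit


def _softmax_probs(eta: np.ndarray) -> np.ndarray:
    """Probabilities from non-reference logits (reference logit = 0)."""
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class RhythmProbabilityModel:
    """A fitted penalized multinomial model of rhythm-class probabilities."""

    spec: ModelSpec
    classes: list
    reference: object
    design: Design
    coef: np.ndarray  # (p, K-1), contrasts vs. the reference class
    lambda_: float
    group_ridge: float
    loglik: float  # in-sample, unpenalized
    hessian: np.ndarray  # of the mean penalized objective, at the optimum
    converged: bool
    separation: bool
    cv_elpd: float | None = None
    cv_elpd_se: float | None = None

    @property
    def nonref_classes(self) -> list:
        return [c for c in self.classes if c != self.reference]

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        return self.design.matrix(data) @ self.coef

    def predict_probs(self, data: pd.DataFrame) -> pd.DataFrame:
        """Per-class probabilities (columns ordered as ``self.classes``)."""
        probs = _softmax_probs(self.linear_predictor(data))
        # internal column order is [reference, *nonref]; re-map to classes
        internal = [self.reference] + self.nonref_classes
        cols = {c: probs[:, internal.index(c)] for c in self.classes}
        return pd.DataFrame(cols, index=data.index)

    def covariance(self) -> np.ndarray:
        """Asymptotic covariance of vec(coef) from the observed information."""
        n = self._n_obs
        return np.linalg.inv(self.hessian * n)

    def se(self) -> np.ndarray:
        """Standard errors, shaped like ``coef``."""
        se = np.sqrt(np.diag(self.covariance()))
        return se.reshape(self.coef.shape, order="F")

    _n_obs: int = 0


def _fit_core(
    X: np.ndarray,
    y_idx: np.ndarray,
    K: int,
    P: np.ndarray,
    coef0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, np.ndarray, bool, bool]:
    """Newton optimization of the penalized mean negative log-likelihood.

    Returns (coef (p, K-1), loglik, hessian, converged, separation).
    """
    n, p = X.shape
    Km1 = K - 1
    B = np.zeros((p, Km1)) if coef0 is None else coef0.copy()
    Y = np.zeros((n, Km1))
    for k in range(Km1):
        Y[:, k] = y_idx == (k + 1)  # index 0 is the reference

    def objective(Bm):
        probs = _softmax_probs(X @ Bm)
        ll = np.log(probs[np.arange(n), y_idx].clip(1e-300)).mean()
        pen = 0.5 * sum(Bm[:, k] @ P @ Bm[:, k] for k in range(Km1))
        return -ll + pen, probs

    def gradient(Bm, probs):
        G = X.T @ (probs[:, 1:] - Y) / n + P @ Bm
        return G

    def hessian(Bm, probs):
        Pm = probs[:, 1:]
        W = np.einsum("na,nb->nab", Pm, -Pm)
        W[:, np.arange(Km1), np.arange(Km1)] += Pm
        H = np.einsum("nab,ni,nj->aibj", W, X, X) / n
        H = H.reshape(Km1 * p, Km1 * p)
        for k in range(Km1):
            H[k * p : (k + 1) * p, k * p : (k + 1) * p] += P
        return H

    f, probs = objective(B)
    separation = False
    # iterate well past the documented 1e-6 criterion so closed-form cases
    # (intercept-only frequencies) come out exact to machine precision
    inner_tol = 1e-11
    for _ in range(MAX_NEWTON_ITER):
        G = gradient(B, probs)
        if np.linalg.norm(G) < inner_tol:
            break
        H = hessian(B, probs)
        g = G.reshape(-1, order="F")
        ridge = 0.0
        while True:
            try:
                step = np.linalg.solve(H + ridge * np.eye(H.shape[0]), g)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10, 1e-10)
        step = step.reshape(p, Km1, order="F")
        # backtracking line search on the objective
        alpha = 1.0
        for _ in range(40):
            Bn = B - alpha * step
            fn, probs_n = objective(Bn)
            if fn <= f:
                break
            alpha *= 0.5
        stalled = f - fn < 1e-15
        B, f, probs = Bn, fn, probs_n
        if np.linalg.norm(B) > SEPARATION_NORM:
            separation = True
            warnings.warn(
                "coefficient norm diverging: (quasi-)separation or an empty "
                "class; estimates are on the boundary",
                stacklevel=3,
            )
            break
        if stalled:
            break
    G = gradient(B, probs)
    converged = np.linalg.norm(G) < GRAD_TOL
    if not converged and not separation:
        raise ConvergenceError(
            f"Newton failed: |grad| = {np.linalg.norm(G):.3g} after "
            f"{MAX_NEWTON_ITER} iterations"
        )
    ll = float(np.log(_softmax_probs(X @ B)[np.arange(n), y_idx].clip(1e-300)).sum())
    H = hessian(B, probs)
    return B, ll, H, converged, separation


def fit_multinomial(
    spec: ModelSpec,
    data: pd.DataFrame,
    response: str = "rhythm_class",
    reference: object | None = None,
    lam: float | None = None,
    group_ridge: float = DEFAULT_GROUP_RIDGE,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    select_folds: int = 5,
    seed: int = 0,
) -> RhythmProbabilityModel:
    """Fit a penalized multinomial logistic model.

    Rows with missing required columns are dropped.  The reference class
    defaults to 'diel' when present (the most frequent class overall),
    otherwise to the most frequent class in ``data``.  When the spec has
    smooth terms and ``lam`` is None, the smoothing parameter is chosen
    from ``lambda_grid`` by internal cross-validated elpd.
    """
    cols = [response] + spec.required_columns()
    d = data.dropna(subset=[c for c in cols if c in data.columns]).reset_index(drop=True)
    if len(d) == 0:
        raise ValueError("no complete rows")
    classes = sorted(d[response].unique().tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 observed classes")
    if reference is None:
        reference = "diel" if "diel" in classes else d[response].mode().iloc[0]
    ordered = [reference] + [c for c in classes if c != reference]
    y_idx = d[response].map({c: i for i, c in enumerate(ordered)}).to_numpy()

    design = Design(spec, d)
    X = design.matrix(d, training=True)

    if lam is None and design.has_smooth:
        lam = _select_lambda(
            spec, d, response, ordered, y_idx, design, X, group_ridge, lambda_grid, select_folds, seed
        )
    elif lam is None:
        lam = 0.0

    P = design.penalties(lam, group_ridge)
    coef, ll, H, converged, separation = _fit_core(X, y_idx, len(ordered), P)
    model = RhythmProbabilityModel(
        spec=spec,
        classes=classes,
        reference=reference,
        design=design,
        coef=coef,
        lambda_=lam,
        group_ridge=group_ridge,
        loglik=ll,
        hessian=H,
        converged=converged,
        separation=separation,
    )
    model._n_obs = len(d)
    return model


def _select_lambda(
    spec, d, response, ordered, y_idx, design, X, group_ridge, grid, n_folds, seed
) -> float:
    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, len(d))
    K = len(ordered)
    best_lam, best_score = grid[0], -np.inf
    for lam in grid:
        P = design.penalties(lam, group_ridge)
        score = 0.0
        ok = True
        for f in range(n_folds):
            tr, te = fold != f, fold == f
            if te.sum() == 0 or len(np.unique(y_idx[tr])) < 2:
                continue
            try:
                coef, *_ = _fit_core(X[tr], y_idx[tr], K, P)
            except ConvergenceError:
                ok = False
                break
            probs = _softmax_probs(X[te] @ coef)
            score += float(np.log(probs[np.arange(te.sum()), y_idx[te]].clip(1e-300)).sum())
        if ok and score > best_score:
            best_lam, best_score = lam, score
    return best_lam


def predict_probs(model: RhythmProbabilityModel, new_data: pd.DataFrame) -> pd.DataFrame:
    """Per-class probability vectors for new covariate rows (sum to 1)."""
    return model.predict_probs(new_data)


# ---------------------------------------------------------------------------
# cross-validation and stacking


@dataclass
class CVResult:
    """Grouped K-fold cross-validated predictive density of one model."""

    spec_name: str
    elpd: float
    se: float
    pointwise: np.ndarray  # held-out log predictive density per observation
    prob_observed: np.ndarray  # held-out probability of the observed class


def _make_folds(d: pd.DataFrame, n_folds: int, grouping: str | None, response: str, seed: int) -> np.ndarray:
    n = len(d)
    rng = np.random.default_rng(seed)
    fold = np.zeros(n, dtype=int)
    if grouping is not None and grouping in d.columns:
        groups = sorted(d[grouping].unique().tolist(), key=str)
        rng.shuffle(groups)
        # balance fold sizes: assign each group to the currently smallest fold
        sizes = np.zeros(n_folds, dtype=int)
        for g in groups:
            mask = (d[grouping] == g).to_numpy()
            f = int(np.argmin(sizes))
            fold[mask] = f
            sizes[f] += int(mask.sum())
    else:
        # stratified by class: shuffle within class, deal round-robin
        for cls in sorted(d[response].unique().tolist(), key=str):
            idx = np.flatnonzero((d[response] == cls).to_numpy())
            rng.shuffle(idx)
            fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def cv_elpd(
    spec: ModelSpec,
    data: pd.DataFrame,
    n_folds: int = 10,
    grouping: str | None = "bear_id",
    response: str = "rhythm_class",
    reference: object | None = None,
    lam: float | None = None,
    group_ridge: float = DEFAULT_GROUP_RIDGE,
    seed: int = 0,
) -> CVResult:
    """Cross-validated elpd: sum over held-out observations of the log
    predicted probability of the observed class.

    Folds keep all windows of one bear together when ``grouping`` is a
    column of ``data`` (approximating leave-one-group-out), otherwise they
    are stratified by class.  A fold whose training part lacks a class is
    fitted anyway (the model pays for it on the held-out side) with a
    warning.  SE is the usual sqrt(n x var) of the pointwise values.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    cols = [response] + spec.required_columns()
    d = data.dropna(subset=[c for c in cols if c in data.columns]).reset_index(drop=True)
    classes = sorted(d[response].unique().tolist())
    if reference is None:
        reference = "diel" if "diel" in classes else d[response].mode().iloc[0]
    fold = _make_folds(d, n_folds, grouping, response, seed)

    pointwise = np.full(len(d), np.nan)
    prob_obs = np.full(len(d), np.nan)
    for f in range(n_folds):
        te = fold == f
        tr = ~te
        if te.sum() == 0:
            continue
        train = d[tr]
        if set(train[response].unique()) != set(classes):
            warnings.warn(
                f"fold {f}: training part lacks a class; held-out density "
                "for it comes from the fitted model alone",
                stacklevel=2,
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_multinomial(
                spec, train, response=response, reference=reference, lam=lam,
                group_ridge=group_ridge, seed=seed,
            )
        probs = m.predict_probs(d[te])
        obs = d.loc[te, response].to_numpy()
        p = np.array(
            [probs.iloc[i].get(c, 1e-300) for i, c in enumerate(obs)]
        ).clip(1e-300)
        prob_obs[te] = p
        pointwise[te] = np.log(p)
    elpd = float(np.nansum(pointwise))
    n = int(np.isfinite(pointwise).sum())
    se = float(np.sqrt(n * np.nanvar(pointwise)))
    return CVResult(spec.name, elpd, se, pointwise, prob_obs)


@dataclass
class StackingResult:
    """Simplex weights maximizing the combined held-out log density."""

    model_names: list[str]
    weights: np.ndarray
    elpd_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def stacking_weights(prob_matrix: np.ndarray, model_names: list[str] | None = None) -> StackingResult:
    """Stack M models from their held-out predictive probabilities.

    ``prob_matrix`` has shape (n_obs, M): column m holds model m's held-out
    probability of each observation's observed class.  The weights solve

        max_w  sum_i log( sum_m w_m p_mi ),   w on the simplex,

    a concave problem solved deterministically from the uniform start.
    Models with identical predictive columns share their weight equally.
    """
    P = np.atleast_2d(np.asarray(prob_matrix, dtype=float))
    n, M = P.shape
    if model_names is None:
        model_names = [f"model_{m}" for m in range(M)]
    if M == 1:
        return StackingResult(list(model_names), np.array([1.0]))

    # collapse duplicate columns so ties are resolved symmetrically
    groups: list[list[int]] = []
    for m in range(M):
        for grp in groups:
            if np.allclose(P[:, m], P[:, grp[0]], rtol=0, atol=1e-12):
                grp.append(m)
                break
        else:
            groups.append([m])
    Pu = P[:, [g[0] for g in groups]]
    Mu = Pu.shape[1]
    if Mu == 1:
        w = np.zeros(M)
        for m in groups[0]:
            w[m] = 1.0 / len(groups[0])
        return StackingResult(list(model_names), w)

    def neg(w):
        mix = Pu @ w
        return -np.log(mix.clip(1e-300)).mean()

    def grad(w):
        mix = (Pu @ w).clip(1e-300)
        return -(Pu / mix[:, None]).mean(axis=0)

    w0 = np.full(Mu, 1.0 / Mu)
    res = minimize(
        neg,
        w0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * Mu,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 500, "ftol": 1e-12},
    )
    wu = np.clip(res.x, 0.0, None)
    wu /= wu.sum()
    w = np.zeros(M)
    for grp, wg in zip(groups, wu):
        for m in grp:
            w[m] = wg / len(grp)
    return StackingResult(list(model_names), w)


def compare_models(
    specs: list[ModelSpec],
    data: pd.DataFrame,
    elpd_window: float = 4.0,
    **cv_kwargs,
) -> tuple[pd.DataFrame, StackingResult]:
    """Rank candidate models by cv-elpd and stack the near-ties.

    Models within ``elpd_window`` of the best are stacked; the rest get
    weight 0.  Returns (elpd table sorted best-first, stacking result).
    """
    results = [cv_elpd(s, data, **cv_kwargs) for s in specs]
    best = max(r.elpd for r in results)
    table = pd.DataFrame(
        {
            "model": [r.spec_name for r in results],
            "elpd": [r.elpd for r in results],
            "se": [r.se for r in results],
            "elpd_diff": [r.elpd - best for r in results],
        }
    ).sort_values("elpd", ascending=False, ignore_index=True)

    contenders = [i for i, r in enumerate(results) if best - r.elpd < elpd_window]
    P = np.column_stack([results[i].prob_observed for i in contenders])
    mask = np.isfinite(P).all(axis=1)
    sub = stacking_weights(P[mask], [results[i].spec_name for i in contenders])
    weights = np.zeros(len(specs))
    for j, i in enumerate(contenders):
        weights[i] = sub.weights[j]
    stack = StackingResult([r.spec_name for r in results], weights, table)
    return table, stack
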