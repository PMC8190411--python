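"""Reduced rank regression (RRR) dietary-pattern extraction.

RRR finds successive linear combinations of predictors (factors) that
maximize the explained variation in a small set of response variables. Here
the predictors X are z-standardized usual intakes of the 34 food groups and
the responses Y are z-standardized (energy-adjusted) Zn and PUFA intakes.

Identity-metric formulation: with X (n x p) and Y (n x m) column-centered,

    Yhat = X (X'X)^+ X' Y          (least-squares fit of Y on X)
    Yhat' Yhat v_k = lambda_k v_k  (response weights, ||v_k|| = 1)
    t_k = Y v_k                    (response score)
    a_k = (X'X)^+ X' Y v_k         (predictor weights)
    f_k = X a_k = Yhat v_k         (factor score, the projection of t_k)

Factor scores of distinct factors are exactly orthogonal, so per-response
explained variation (squared Pearson correlation of Y_j with f_k)
accumulates additively over factors. The sign of each factor is fixed so
that its correlation with the first response column (Zn by convention) is
non-negative, with ties resolved on the second response.

Factor loadings are, by default, Pearson correlations between each
predictor column and the factor score; a predictor-projection variant
(X'f / f'f, the loading type some PLS software reports) is available.

The simplified pattern score keeps only food groups with |loading| >= 0.20
(boundary included) and sums their z-standardized intakes signed by the
loading direction; per-person scores are then ranked into quintiles
(1 = low adherence, 5 = high adherence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "RRRModel",
    "SimplifiedPattern",
    "standardize_columns",
    "fit_rrr",
    "factor_loadings",
    "explained_variation",
    "simplify_pattern",
    "assign_quintiles",
]

LOADING_THRESHOLD = 0.20
_EIG_TOL = 1e-12


def standardize_columns(data: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """z-standardize columns (sample SD, n-1 denominator).

    Constant columns are dropped with a warning and recorded in the returned
    params under ``dropped``. Raises if every column is constant.
    """
    if len(data) < 2:
        raise ValueError("need n >= 2 to standardize")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    constant = sd.index[sd == 0.0].tolist()
    if len(constant) == len(data.columns):
        raise ValueError("all columns are constant")
    if constant:
        warnings.warn(f"dropping constant columns: {constant}", stacklevel=2)
    keep = [c for c in data.columns if c not in constant]
    z = (data[keep] - mean[keep]) / sd[keep]
    params = {"mean": mean[keep], "sd": sd[keep], "dropped": constant}
    return z, params


def _corr_with_factor(z_cols: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Pearson correlation of each (already centered) column with vector f."""
    fc = f - f.mean()
    cc = z_cols - z_cols.mean(axis=0)
    denom = np.sqrt((cc**2).sum(axis=0) * (fc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, cc.T @ fc / denom, 0.0)


@dataclass
class RRRModel:
    """A fitted reduced-rank-regression pattern model."""

    predictor_weights: pd.DataFrame  # p x K
    response_weights: pd.DataFrame  # m x K, unit columns
    factor_scores: pd.DataFrame  # n x K
    response_scores: pd.DataFrame  # n x K
    loadings: pd.DataFrame  # p x K
    eigenvalues: np.ndarray  # K, descending
    explained: pd.DataFrame  # K x (m + 2): per-response, overall, cumulative
    predictor_names: list[str]
    response_names: list[str]
    zero_rank_factors: list[int] = field(default_factory=list)
    loading_kind: str = "correlation"

    @property
    def n_factors(self) -> int:
        return self.factor_scores.shape[1]

    def to_csvs(self, outdir) -> None:
        """Serialize weights, loadings and explained-variation tables."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.predictor_weights.to_csv(outdir / "predictor_weights.csv")
        self.response_weights.to_csv(outdir / "response_weights.csv")
        self.loadings.to_csv(outdir / "loadings.csv")
        self.explained.to_csv(outdir / "explained_variation.csv")


def fit_rrr(
    X: pd.DataFrame,
    Y: pd.DataFrame,
    n_factors: int = 2,
    loading_kind: str = "correlation",
) -> RRRModel:
    """Fit reduced rank regression of standardized Y on standardized X.

    ``n_factors`` must not exceed the number of responses. A pseudo-inverse
    of X'X is used throughout, so collinear food groups are tolerated (a
    rank report is emitted as a warning). Factors whose eigenvalue is
    numerically zero are returned flagged in ``zero_rank_factors``.
    """
    Xv = np.asarray(X, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    n, p = Xv.shape
    m = Yv.shape[1]
    if n_factors > m:
        raise ValueError(f"n_factors={n_factors} exceeds number of responses ({m})")
    if n < 3:
        raise ValueError("need n >= 3")
    if Yv.shape[0] != n:
        raise ValueError("X and Y row mismatch")

    xtx = Xv.T @ Xv
    rank = np.linalg.matrix_rank(xtx)
    if rank < p:
        warnings.warn(f"predictor matrix is rank deficient ({rank} < {p}); pseudo-inverse used", stacklevel=2)
    B = linalg.pinvh(xtx) @ Xv.T @ Yv  # p x m coefficient matrix
    Yhat = Xv @ B
    S = Yhat.T @ Yhat
    evals, evecs = linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)[:n_factors]
    V = evecs[:, order][:, :n_factors]

    A = B @ V  # predictor weights a_k
    F = Xv @ A  # factor scores
    T = Yv @ V  # response scores

    # sign convention: corr(f_k, first response) >= 0, tie -> second response
    for k in range(n_factors):
        c0 = _corr_with_factor(Yv[:, [0]], F[:, k])[0]
        flip = c0 < 0
        if c0 == 0 and m > 1:
            flip = _corr_with_factor(Yv[:, [1]], F[:, k])[0] < 0
        if flip:
            V[:, k] *= -1
            A[:, k] *= -1
            F[:, k] *= -1
            T[:, k] *= -1

    zero_rank = [k for k in range(n_factors) if evals[k] <= _EIG_TOL * max(evals[0], 1.0)]

    fac_names = [f"factor{k + 1}" for k in range(n_factors)]
    pred_names = list(X.columns)
    resp_names = list(Y.columns)
    idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(n)

    model = RRRModel(
        predictor_weights=pd.DataFrame(A, index=pred_names, columns=fac_names),
        response_weights=pd.DataFrame(V, index=resp_names, columns=fac_names),
        factor_scores=pd.DataFrame(F, index=idx, columns=fac_names),
        response_scores=pd.DataFrame(T, index=idx, columns=fac_names),
        loadings=pd.DataFrame(np.zeros((p, n_factors)), index=pred_names, columns=fac_names),
        eigenvalues=evals,
        explained=pd.DataFrame(),
        predictor_names=pred_names,
        response_names=resp_names,
        zero_rank_factors=zero_rank,
        loading_kind=loading_kind,
    )
    model.loadings = factor_loadings(model, X, kind=loading_kind)
    model.explained = explained_variation(model, Y)
    return model


def factor_loadings(model: RRRModel, X: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """Loadings of each predictor on each factor.

    ``kind="correlation"`` (default): Pearson correlation between the
    standardized predictor and the factor score. ``kind="projection"``:
    X'f / f'f, the predictor-projection loading some PLS implementations
    report.
    """
    kind = kind or model.loading_kind
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[1] != len(model.predictor_names):
        raise ValueError("X column mismatch with fitted model")
    F = model.factor_scores.to_numpy()
    if Xv.shape[0] != F.shape[0]:
        raise ValueError("X row mismatch with fitted model")
    if kind == "correlation":
        L = np.column_stack([_corr_with_factor(Xv, F[:, k]) for k in range(F.shape[1])])
    elif kind == "projection":
        L = np.column_stack(
            [Xv.T @ F[:, k] / (F[:, k] @ F[:, k]) if F[:, k] @ F[:, k] > 0 else np.zeros(Xv.shape[1]) for k in range(F.shape[1])]
        )
    else:
        raise ValueError("kind must be 'correlation' or 'projection'")
    return pd.DataFrame(L, index=model.predictor_names, columns=model.factor_scores.columns)


def explained_variation(model: RRRModel, Y: pd.DataFrame) -> pd.DataFrame:
    """Explained-variation table, K rows.

    Per factor k and response j, the squared Pearson correlation between Y_j
    and the factor score f_k; ``overall`` is the mean over responses and
    ``cumulative_overall`` its running sum (valid because factor scores are
    mutually orthogonal).
    """
    Yv = np.asarray(Y, dtype=float)
    if Yv.shape[1] != len(model.response_names):
        raise ValueError("Y column mismatch with fitted model")
    F = model.factor_scores.to_numpy()
    if Yv.shape[0] != F.shape[0]:
        raise ValueError("Y row mismatch with fitted model")
    rows = []
    for k in range(F.shape[1]):
        r2 = _corr_with_factor(Yv, F[:, k]) ** 2
        rows.append(list(r2) + [float(r2.mean())])
    cols = [f"explained_{name}" for name in model.response_names] + ["overall"]
    tbl = pd.DataFrame(rows, index=model.factor_scores.columns, columns=cols)
    tbl["cumulative_overall"] = tbl["overall"].cumsum()
    return tbl


def grid_search_max_explained(X, Y, coarse_steps: int = 40, refine_rounds: int = 2) -> float:
    """Brute-force maximum of the factor-1 objective over unit weight vectors.

    Evaluates the mean (over responses) squared Pearson correlation between
    each response column and X @ a on a dense spherical grid of unit
    predictor-weight vectors a, with local grid refinement around the best
    point. Supports p in {2, 3, 4}. This is a validation utility: it never
    uses the eigen solution, so it serves as an independent check that
    :func:`fit_rrr`'s first factor attains the maximal explained response
    variation.
    """
    Xv = np.asarray(X, dtype=float)
    Yv = np.asarray(Y, dtype=float)
    p = Xv.shape[1]
    if p not in (2, 3, 4):
        raise ValueError("grid search supports 2 <= p <= 4")
    Yc = Yv - Yv.mean(axis=0)
    y_ss = (Yc**2).sum(axis=0)

    def objective(angles: list[np.ndarray]) -> tuple[float, tuple[float, ...]]:
        mesh = np.meshgrid(*angles, indexing="ij")
        flat = [m.ravel() for m in mesh]
        a = np.empty((p, flat[0].size))
        sin_prod = np.ones_like(flat[0])
        for i in range(p - 1):
            a[i] = sin_prod * np.cos(flat[i])
            sin_prod = sin_prod * np.sin(flat[i])
        a[p - 1] = sin_prod
        best_val, best_angles = -1.0, None
        for start in range(0, a.shape[1], 20000):
            block = a[:, start : start + 20000]
            F = Xv @ block
            Fc = F - F.mean(axis=0)
            f_ss = (Fc**2).sum(axis=0)
            num = (Yc.T @ Fc) ** 2  # m x chunk
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = np.where(f_ss > 0, num / (y_ss[:, None] * f_ss[None, :]), 0.0)
            vals = r2.mean(axis=0)
            j = int(np.argmax(vals))
            if vals[j] > best_val:
                best_val = float(vals[j])
                best_angles = tuple(flat[i][start + j] for i in range(p - 1))
        return best_val, best_angles

    # half-sphere suffices: the objective is sign-invariant in a
    grids = [np.linspace(0.0, np.pi, coarse_steps, endpoint=False) for _ in range(p - 1)]
    best_val, center = objective(grids)
    width = np.pi / coarse_steps
    for _ in range(refine_rounds):
        grids = [np.linspace(c - width, c + width, 21) for c in center]
        val, center = objective(grids)
        best_val = max(best_val, val)
        width = 2 * width / 20
    return best_val


@dataclass
class SimplifiedPattern:
    """A simplified dietary pattern: signed high-loading groups and scores."""

    factor_index: int
    contributing_groups: list[tuple[str, int, float]]  # (group_id, sign, loading)
    score: pd.Series
    quintile: pd.Series | None

    @property
    def signs(self) -> dict[str, int]:
        return {g: s for g, s, _ in self.contributing_groups}


def simplify_pattern(
    model: RRRModel,
    X: pd.DataFrame,
    factor: int = 1,
    threshold: float = LOADING_THRESHOLD,
) -> SimplifiedPattern:
    """Simplified score for a factor (1-based index).

    Contributing groups have |loading| >= threshold (boundary included);
    the score sums z-standardized intakes with the loading's sign. Raises if
    no group qualifies.
    """
    if not 1 <= factor <= model.n_factors:
        raise ValueError(f"model has no factor {factor}")
    load = model.loadings.iloc[:, factor - 1]
    contrib = [(g, 1 if load[g] >= 0 else -1, float(load[g])) for g in load.index if abs(load[g]) >= threshold]
    if not contrib:
        raise ValueError("empty simplified pattern: no loading reaches the threshold")
    score = pd.Series(0.0, index=X.index)
    for g, s, _ in contrib:
        score = score + s * X[g]
    score.name = f"simplified_factor{factor}"
    quintile = assign_quintiles(score) if len(score) >= 5 else None
    return SimplifiedPattern(factor_index=factor, contributing_groups=contrib, score=score, quintile=quintile)


def assign_quintiles(score) -> pd.Series:
    """Rank-based quintiles 1..5 of a score vector.

    Group sizes differ by at most one; ties are broken by stable input
    order; quintile 1 holds the lowest scores (low adherence), 5 the
    highest.
    """
    s = pd.Series(score)
    n = len(s)
    if n < 5:
        raise ValueError("need n >= 5 for quintiles")
    order = np.argsort(s.to_numpy(), kind="stable")
    sizes = [n // 5 + (1 if i < n % 5 else 0) for i in range(5)]
    labels = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = q
        start += size
    return pd.Series(labels, index=s.index, name="quintile")
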