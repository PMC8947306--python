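"""Canonical correlation analysis for paired stacked TDS matrices.

Given zero-centered observation matrices ``X`` (N x p, e.g. primary-sensory
dominance proportions) and ``Y`` (N x q, multi-sensory), CCA finds paired
linear combinations

    u_j = X a_j,    v_j = Y b_j,    j = 1 .. r = min(p, q),

chosen to maximize ``corr(u_j, v_j)`` subject to each ``u_j`` (and ``v_j``)
being uncorrelated with the earlier variates of its own set.  The solver
whitens the two within-set covariances with their inverse symmetric square
roots and takes the singular value decomposition of the whitened
cross-covariance; the singular values are the canonical correlations
``rho_1 >= ... >= rho_r``.

The number of meaningful dimensions is decided with sequential
Pillai-Bartlett trace tests, and each dimension's share of a set's sample
variance is summarized by the variance-extracted convention: the mean, over
the set's variables, of the squared correlation between the variable and
the set's own canonical variate.

Coefficients are scaled so the training variates have unit sample variance,
and the sign of each pair is fixed by making the largest-magnitude
coefficient of ``a_j`` positive (signs are otherwise arbitrary in CCA).

.. warning::
   When the rows are stacked bootstrap instants of smooth curves they are
   not independent samples; the sequential tests treat them as if they were,
   which inflates significance.  Interpret the dimension count accordingly
   (see the methods note).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bootstrap import StackedSampleMatrix

__all__ = [
    "CCAModel",
    "DimensionTestTable",
    "ContributionTable",
    "CanonicalSeries",
    "fit_cca",
    "canonical_series",
    "contribution_proportions",
    "pillai_dimension_tests",
    "select_num_variables",
    "coefficient_table",
    "permutation_pillai_pvalue",
    "model_to_dict",
    "write_model",
]


@dataclass(eq=False)
class CCAModel:
    """Fitted canonical correlation model.

    ``coeff_x`` is r x p with row ``j`` holding ``a_j`` (likewise
    ``coeff_y``); ``correlations`` holds ``rho_1 >= ... >= rho_r``.
    """

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    correlations: np.ndarray
    n_samples: int
    attributes_x: tuple[str, ...]
    attributes_y: tuple[str, ...]
    variate_scale: str = "unit-variance"
    ridge_x: float = 0.0
    ridge_y: float = 0.0

    @property
    def r(self) -> int:
        return int(self.correlations.size)

    @property
    def p(self) -> int:
        return int(self.coeff_x.shape[1])

    @property
    def q(self) -> int:
        return int(self.coeff_y.shape[1])


@dataclass(eq=False)
class DimensionTestTable:
    """Sequential Pillai-Bartlett tests, one row per dimension ``j``.

    Row ``j`` tests the null that dimensions ``j .. r`` all have zero
    population canonical correlation; ``pillai_trace[j]`` is
    ``sum_{i>=j} rho_i^2``.
    """

    pillai_trace: np.ndarray
    f_value: np.ndarray
    df1: np.ndarray
    df2: np.ndarray
    p_value: np.ndarray
    alpha: float
    n_selected: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pillai_trace": self.pillai_trace,
                "f_value": self.f_value,
                "df1": self.df1,
                "df2": self.df2,
                "p_value": self.p_value,
            },
            index=pd.RangeIndex(1, len(self.pillai_trace) + 1, name="dimension"),
        )


@dataclass(eq=False)
class ContributionTable:
    """Per-dimension contribution of the canonical variates to each set's
    sample variance (variance-extracted convention)."""

    contributions_x: np.ndarray
    contributions_y: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.contributions_x, "y": self.contributions_y},
            index=pd.RangeIndex(
                1, len(self.contributions_x) + 1, name="dimension"
            ),
        )


@dataclass(eq=False)
class CanonicalSeries:
    """Canonical variate time series ``u_j(t)``, ``v_j(t)`` on a grid."""

    instants: np.ndarray
    u: np.ndarray  # len(instants) x r
    v: np.ndarray


def _as_centered(data) -> np.ndarray:
    """Accept a StackedSampleMatrix or a plain array; return centered values."""
    if isinstance(data, StackedSampleMatrix):
        return data.values
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr - arr.mean(axis=0)


def _attribute_names(data, n: int, prefix: str) -> tuple[str, ...]:
    if isinstance(data, StackedSampleMatrix):
        return tuple(data.attributes)
    return tuple(f"{prefix}{i + 1}" for i in range(n))


def _inv_sqrt_psd(
    cov: np.ndarray, ridge_eps: float, label: str
) -> tuple[np.ndarray, float]:
    """Inverse symmetric square root of a covariance, with a tiny documented
    ridge added when the matrix is numerically rank deficient."""
    eigval, eigvec = np.linalg.eigh(cov)
    ridge = 0.0
    tol = max(eigval.max(), 0.0) * 1e-10
    if eigval.min() <= tol:
        ridge = ridge_eps * np.trace(cov) / cov.shape[0]
        warnings.warn(
            f"{label} within-set covariance is rank deficient; "
            f"applying ridge {ridge:.3e}",
            stacklevel=3,
        )
        eigval = eigval + ridge
        if eigval.min() <= 0:
            raise np.linalg.LinAlgError(
                f"{label} covariance not positive definite even after ridge"
            )
    return (eigvec * (1.0 / np.sqrt(eigval))) @ eigvec.T, ridge


def fit_cca(X, Y, ridge_eps: float = 1e-8) -> CCAModel:
    """Fit CCA on centered matrices (plain arrays are centered defensively).

    The contract is the maximization property: ``corr(u_j, v_j)``
    is maximal subject to orthogonality with earlier variates of the same
    set.  Within-set rank deficiency triggers a warning and a ridge of
    magnitude ``ridge_eps * trace / k``; a matrix that stays singular after
    the ridge raises :class:`numpy.linalg.LinAlgError`.
    """
    x = _as_centered(X)
    y = _as_centered(Y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = x.shape
    q = y.shape[1]
    if n < 2:
        raise ValueError("need at least two samples")
    if n <= p + q:
        warnings.warn(
            f"N={n} <= p+q={p + q}: canonical correlations will overfit",
            stacklevel=2,
        )
    sxx = x.T @ x / (n - 1)
    syy = y.T @ y / (n - 1)
    sxy = x.T @ y / (n - 1)
    kx, ridge_x = _inv_sqrt_psd(sxx, ridge_eps, "X")
    ky, ridge_y = _inv_sqrt_psd(syy, ridge_eps, "Y")
    u_w, sv, vt_w = np.linalg.svd(kx @ sxy @ ky)
    r = min(p, q)
    coeff_x = (kx @ u_w[:, :r]).T
    coeff_y = (ky @ vt_w[:r].T).T
    # deterministic sign: largest-|.| coefficient of a_j made positive
    for j in range(r):
        i = int(np.argmax(np.abs(coeff_x[j])))
        if coeff_x[j, i] < 0:
            coeff_x[j] *= -1
            coeff_y[j] *= -1
    return CCAModel(
        coeff_x=coeff_x,
        coeff_y=coeff_y,
        correlations=np.clip(sv[:r], 0.0, 1.0),
        n_samples=n,
        attributes_x=_attribute_names(X, p, "x"),
        attributes_y=_attribute_names(Y, q, "y"),
        ridge_x=ridge_x,
        ridge_y=ridge_y,
    )


def canonical_series(
    model: CCAModel,
    curves_x: np.ndarray,
    curves_y: np.ndarray,
    instants: np.ndarray | None = None,
    attributes_x: tuple[str, ...] | None = None,
    attributes_y: tuple[str, ...] | None = None,
) -> CanonicalSeries:
    """Evaluate ``u_j(t)`` and ``v_j(t)`` on centered curve matrices.

    ``curves_x``/``curves_y`` are instants x p (resp. q) matrices, already
    centered with the column means of the training stack.  If attribute
    names are supplied they must match the model's training order.
    """
    cx = np.asarray(curves_x, dtype=float)
    cy = np.asarray(curves_y, dtype=float)
    if attributes_x is not None and tuple(attributes_x) != model.attributes_x:
        raise ValueError("attribute order of curves_x does not match the model")
    if attributes_y is not None and tuple(attributes_y) != model.attributes_y:
        raise ValueError("attribute order of curves_y does not match the model")
    if cx.shape[1] != model.p or cy.shape[1] != model.q:
        raise ValueError("curve matrices do not match the model's p and q")
    if cx.shape[0] != cy.shape[0]:
        raise ValueError("curve matrices must share the instants")
    if instants is None:
        instants = np.arange(cx.shape[0], dtype=float)
    return CanonicalSeries(
        instants=np.asarray(instants, dtype=float),
        u=cx @ model.coeff_x.T,
        v=cy @ model.coeff_y.T,
    )


def contribution_proportions(model: CCAModel, X, Y) -> ContributionTable:
    """Variance-extracted contribution of each dimension to each set.

    The contribution of dimension ``j`` to a set is the mean over that
    set's variables of the squared sample correlation between the variable
    and the set's own canonical variate ``j``.  For a full-rank set with as
    many variables as dimensions the contributions sum to 1.
    """
    x = _as_centered(X)
    y = _as_centered(Y)
    out = []
    for data, coeff in ((x, model.coeff_x), (y, model.coeff_y)):
        sd = data.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column in the input matrix")
        variates = data @ coeff.T
        vsd = variates.std(axis=0, ddof=1)
        corr = (data.T @ variates) / (data.shape[0] - 1) / np.outer(sd, vsd)
        out.append((corr**2).mean(axis=0))
    return ContributionTable(contributions_x=out[0], contributions_y=out[1])


def pillai_dimension_tests(
    model: CCAModel,
    n_samples: int | None = None,
    alpha: float = 0.05,
) -> DimensionTestTable:
    """Sequential Pillai-Bartlett trace tests for the number of dimensions.

    For each ``j`` the statistic is ``V_j = sum_{i=j}^{r} rho_i^2``, tested
    with the standard asymptotic Pillai F approximation on the residual
    problem of ``p - j + 1`` and ``q - j + 1`` variables and ``N - j + 1``
    samples.  ``n_selected`` counts the leading dimensions significant at
    ``alpha``, stopping at the first failure.
    """
    n = int(n_samples if n_samples is not None else model.n_samples)
    p, q, r = model.p, model.q, model.r
    if n <= p + q:
        raise ValueError("need N > p + q for the F approximation")
    rho2 = model.correlations**2
    traces = np.empty(r)
    fvals = np.empty(r)
    df1s = np.empty(r)
    df2s = np.empty(r)
    pvals = np.empty(r)
    for j in range(1, r + 1):
        v = float(rho2[j - 1 :].sum())
        pj = p - j + 1
        qj = q - j + 1
        nj = n - j + 1
        s = min(pj, qj)
        m = (abs(pj - qj) - 1) / 2.0
        nn = (nj - pj - qj - 2) / 2.0
        df1 = s * (2 * m + s + 1)
        df2 = s * (2 * nn + s + 1)
        denom = s - v
        if denom <= 0:
            f = np.inf
        else:
            f = (df2 / df1) * (v / denom)
        traces[j - 1] = v
        fvals[j - 1] = f
        df1s[j - 1] = df1
        df2s[j - 1] = df2
        pvals[j - 1] = 0.0 if np.isinf(f) else float(stats.f.sf(f, df1, df2))
    n_selected = 0
    for pv in pvals:
        if pv < alpha:
            n_selected += 1
        else:
            break
    return DimensionTestTable(
        pillai_trace=traces,
        f_value=fvals,
        df1=df1s,
        df2=df2s,
        p_value=pvals,
        alpha=alpha,
        n_selected=n_selected,
    )


def select_num_variables(table: DimensionTestTable, alpha: float | None = None) -> int:
    """Leading dimensions with ``p < alpha``; stop at the first failure."""
    a = table.alpha if alpha is None else alpha
    count = 0
    for pv in table.p_value:
        if pv < a:
            count += 1
        else:
            break
    return count


def coefficient_table(
    model: CCAModel, which: str = "x", scale: str = "unit-variance"
) -> pd.DataFrame:
    """Coefficients as attributes x dimensions.

    ``scale="unit-variance"`` returns the fitted coefficients (training
    variates have unit variance); ``scale="sum-abs-100"`` rescales each
    dimension so the absolute coefficients sum to 100, for comparing
    patterns rather than magnitudes.
    """
    if which not in ("x", "y"):
        raise ValueError("which must be 'x' or 'y'")
    coeff = model.coeff_x if which == "x" else model.coeff_y
    names = model.attributes_x if which == "x" else model.attributes_y
    mat = coeff.T.copy()  # attributes x dimensions
    if scale == "sum-abs-100":
        mat = 100.0 * mat / np.abs(mat).sum(axis=0, keepdims=True)
    elif scale != "unit-variance":
        raise ValueError("scale must be 'unit-variance' or 'sum-abs-100'")
    return pd.DataFrame(
        mat,
        index=list(names),
        columns=[f"dim{j + 1}" for j in range(mat.shape[1])],
    )


def permutation_pillai_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p-value for the first-dimension Pillai trace.

    Row-shuffles ``y`` and recomputes ``sum rho_i^2``; valid for
    independently sampled rows.  Uses the add-one estimator
    ``(1 + #{perm >= observed}) / (1 + n_permutations)``.
    """
    x = _as_centered(x)
    y = _as_centered(y)
    rng = np.random.default_rng(seed)

    def trace(yy: np.ndarray) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_cca(x, yy)
        return float((model.correlations**2).sum())

    observed = trace(y)
    exceed = 0
    for _ in range(n_permutations):
        exceed += trace(y[rng.permutation(y.shape[0])]) >= observed
    return (1 + exceed) / (1 + n_permutations)


def model_to_dict(
    model: CCAModel,
    tests: DimensionTestTable | None = None,
    contributions: ContributionTable | None = None,
) -> dict:
    """JSON-ready dictionary of a fitted model and its companion tables."""
    out = {
        "attributes_x": list(model.attributes_x),
        "attributes_y": list(model.attributes_y),
        "coeff_x": model.coeff_x.tolist(),
        "coeff_y": model.coeff_y.tolist(),
        "correlations": model.correlations.tolist(),
        "n_samples": model.n_samples,
        "variate_scale": model.variate_scale,
        "ridge_x": model.ridge_x,
        "ridge_y": model.ridge_y,
    }
    if tests is not None:
        out["pillai_tests"] = {
            "pillai_trace": tests.pillai_trace.tolist(),
            "f_value": tests.f_value.tolist(),
            "df1": tests.df1.tolist(),
            "df2": tests.df2.tolist(),
            "p_value": tests.p_value.tolist(),
            "alpha": tests.alpha,
            "n_selected": tests.n_selected,
        }
    if contributions is not None:
        out["contributions"] = {
            "x": contributions.contributions_x.tolist(),
            "y": contributions.contributions_y.tolist(),
        }
    return out


def write_model(path, model: CCAModel, tests=None, contributions=None) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model, tests, contributions), fh, indent=2)
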