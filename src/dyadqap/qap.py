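"""Single-network MRQAP with double-semipartialing permutation inference.

Dyadic observations are non-independent: every actor appears in 2(n−1)
ordered dyads, so ordinary-least-squares *standard errors* are invalid
even though the OLS point estimates remain interpretable.  The quadratic
assignment procedure (QAP) builds a permutation null that respects actor
exchangeability: matrices are permuted by relabelling actors, i.e. the
same permutation is applied jointly to rows and columns.

For multiple regression we use the double-semipartialing (DSP) variant:
the focal predictor is residualized on all other predictors, the residual
*matrix* is permuted by random actor relabellings, and the focal
coefficient is re-estimated against each permuted residual matrix.  This
isolates the focal test from collinearity among predictors.  P-values
follow the exact-test convention (1 + exceedances) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg

from .network_data import DyadicMatrix, ValidationError, offdiag_indices

__all__ = [
    "PermutationPlan",
    "QapTermResult",
    "QapModelResult",
    "OlsFit",
    "ols_dyadic",
    "permute_square",
    "dsp_test",
]


@dataclass(frozen=True)
class PermutationPlan:
    """How the permutation null is drawn.

    ``blocks`` partitions actor indices; permutations are drawn
    independently within each block (a single block for one network).
    """

    n_perm: int = 10_000
    seed: int = 0
    blocks: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")


@dataclass(frozen=True)
class QapTermResult:
    term: str
    estimate: float
    standardized_estimate: float | None
    p_two_tailed: float
    p_one_tailed: float | None = None
    hypothesized_sign: int = 0      # +1, -1 or 0 (nondirectional)
    is_intercept: bool = False

    @property
    def p(self) -> float:
        """The p-value at the term's assigned tail."""
        return self.p_one_tailed if self.hypothesized_sign else self.p_two_tailed


@dataclass(frozen=True)
class QapModelResult:
    terms: tuple[QapTermResult, ...]
    intercept: float
    r2: float
    r2_adj: float
    model_p: float
    n_dyads: int
    n_dropped: int
    plan: PermutationPlan

    def term(self, name: str) -> QapTermResult:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    @property
    def free_terms(self) -> tuple[QapTermResult, ...]:
        """Terms eligible for model selection (non-intercept)."""
        return tuple(t for t in self.terms if not t.is_intercept)


# ---------------------------------------------------------------------------
# OLS on dyad vectors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OlsFit:
    intercept: float
    estimates: dict[str, float]
    standardized_estimates: dict[str, float]
    r2: float
    r2_adj: float


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns if X is rank deficient."""
    _, _, pivots = linalg.qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in pivots[rank:] if i < len(names))
        raise ValidationError(
            f"design matrix is rank deficient; collinear terms: {bad}"
        )


def ols_dyadic(y: np.ndarray, X: "np.ndarray | object") -> OlsFit:
    """Least squares on vectorized dyads.

    ``X`` may be a pandas DataFrame (column names become term names) or a
    2-D array.  An intercept is always added.  Standardized estimates are
    the coefficients of the z-scored regression, b·sd(x)/sd(y).
    adjusted R² = 1 − (1 − R²)(N − 1)/(N − k − 1).
    """
    if hasattr(X, "columns"):
        names = [str(c) for c in X.columns]
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        if Xv.ndim == 1:
            Xv = Xv[:, None]
        names = [f"x{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y, dtype=float)
    N, k = Xv.shape
    if N <= k + 1:
        raise ValidationError(f"too few dyads ({N}) for {k} predictors")
    sds = Xv.std(axis=0, ddof=1)
    if (sds == 0).any():
        const = [names[i] for i in np.nonzero(sds == 0)[0]]
        raise ValidationError(f"constant predictor(s): {const}")
    D = np.column_stack([np.ones(N), Xv])
    _check_rank(D, ["(intercept)"] + list(names))
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (N - 1) / (N - k - 1)
    sy = y.std(ddof=1)
    return OlsFit(
        intercept=float(beta[0]),
        estimates={nm: float(b) for nm, b in zip(names, beta[1:])},
        standardized_estimates={
            nm: float(b * sx / sy) for nm, b, sx in zip(names, beta[1:], sds)
        },
        r2=r2,
        r2_adj=r2_adj,
    )


def permute_square(M: DyadicMatrix, pi: Sequence[int]) -> DyadicMatrix:
    """Relabel actors of a square matrix: M'(i, j) = M(pi(i), pi(j)).

    The joint row/column permutation preserves the dyadic structure (and
    the masked diagonal), which is what makes QAP nulls respect actor
    exchangeability.
    """
    return M.permute(pi)


# ---------------------------------------------------------------------------
# Batched permutation internals (shared with the multigroup module)
# ---------------------------------------------------------------------------

def draw_permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) array of random actor permutations.  Identity draws are
    kept, not redrawn."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def gather_permuted(
    V: np.ndarray, perms: np.ndarray, rows: np.ndarray, cols: np.ndarray
) -> np.ndarray:
    """Values of the permuted matrix at fixed cell positions.

    Returns a (n_perm, len(rows)) array whose (p, t) entry is
    V[perms[p, rows[t]], perms[p, cols[t]]] — i.e. cell (rows[t], cols[t])
    of the matrix relabelled by permutation p.
    """
    return V[perms[:, rows], perms[:, cols]]


def _residualize(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Residual of v (vector or stack of row vectors) on span(Q), Q orthonormal."""
    if v.ndim == 1:
        return v - Q @ (Q.T @ v)
    return v - (v @ Q) @ Q.T


def _exceedance_p(null: np.ndarray, obs: float) -> float:
    return float((1 + int((null >= obs).sum())) / (null.size + 1))


def term_pvalues(
    null_b: np.ndarray, b_obs: float, sign: int
) -> tuple[float, float | None]:
    """Two-tailed and (if directional) one-tailed permutation p-values."""
    p_two = _exceedance_p(np.abs(null_b), abs(b_obs))
    p_one = None
    if sign:
        p_one = _exceedance_p(sign * null_b, sign * b_obs)
    return p_two, p_one


def r2_null(Qfull: np.ndarray, Yp: np.ndarray) -> np.ndarray:
    """R² of each permuted outcome row of Yp regressed on the fixed design
    whose orthonormal column basis (including the intercept) is Qfull."""
    fitted_ss = ((Yp @ Qfull) ** 2).sum(axis=1)
    N = Yp.shape[1]
    mean_ss = N * Yp.mean(axis=1) ** 2
    tot = (Yp**2).sum(axis=1)
    denom = tot - mean_ss
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = (fitted_ss - mean_ss) / denom
    return np.where(denom > 0, r2, 0.0)


# ---------------------------------------------------------------------------
# The DSP test
# ---------------------------------------------------------------------------

def dsp_test(
    Y: DyadicMatrix,
    predictors: Mapping[str, DyadicMatrix],
    plan: PermutationPlan | None = None,
    hypotheses: Mapping[str, int] | None = None,
) -> QapModelResult:
    """Multiple regression of a dyadic outcome with DSP permutation tests.

    For each focal predictor X_k:

    1. residualize X_k on the remaining predictors (plus intercept) over
       the observed dyad rows and reshape the residuals to a matrix E_k;
    2. for each permutation draw, relabel E_k's actors and re-estimate the
       focal coefficient of Y on {other predictors, permuted E_k};
    3. compare the observed coefficient to this null distribution.

    The model-level p compares the observed R² to R² under whole-matrix
    relabellings of Y (classical QAP-Y), using the same permutation
    stream.  Point estimates are the plain OLS estimates and do not depend
    on the permutations.

    Dyads with any missing value are dropped listwise; residual matrices
    carry 0 (the residual mean) in unobserved cells so permutations stay
    well defined, and inference uses only the observed rows.
    """
    if not predictors:
        raise ValidationError("at least one predictor required")
    plan = plan or PermutationPlan()
    hypotheses = dict(hypotheses or {})
    names = list(predictors)
    for M in predictors.values():
        if M.actors != Y.actors:
            raise ValidationError("predictor actor order differs from outcome")
    n = Y.n
    rows, cols = offdiag_indices(n)
    yv = Y.values[rows, cols]
    Xcols = {nm: predictors[nm].values[rows, cols] for nm in names}
    obs = ~np.isnan(yv)
    for v in Xcols.values():
        obs &= ~np.isnan(v)
    n_dropped = int((~obs).sum())
    N = int(obs.sum())
    y = yv[obs]
    X = np.column_stack([Xcols[nm][obs] for nm in names])

    import pandas as pd

    fit = ols_dyadic(y, pd.DataFrame(X, columns=names))

    rng = np.random.default_rng(plan.seed)
    perms = draw_permutations(n, plan.n_perm, rng)
    orows, ocols = rows[obs], cols[obs]

    # full-design basis for the model-level R² null
    Dfull = np.column_stack([np.ones(N), X])
    Qfull, _ = np.linalg.qr(Dfull)
    Ymat = Y.values.copy()
    miss = np.isnan(Ymat)
    np.fill_diagonal(miss, False)
    Ymat[np.isnan(Ymat)] = y.mean()      # placeholder for permuting only
    Yp = gather_permuted(Ymat, perms, orows, ocols)
    model_p = _exceedance_p(r2_null(Qfull, Yp), fit.r2)

    results = []
    for k, nm in enumerate(names):
        others = [names[j] for j in range(len(names)) if j != k]
        Z = np.column_stack([np.ones(N)] + [Xcols[o][obs] for o in others])
        Qz, _ = np.linalg.qr(Z)
        e = _residualize(X[:, k], Qz)
        E = np.zeros((n, n))
        E[orows, ocols] = e
        Ep = gather_permuted(E, perms, orows, ocols)
        Et = _residualize(Ep, Qz)
        yt = _residualize(y, Qz)
        denom = (Et**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_b = np.where(denom > 0, (Et @ yt) / denom, 0.0)
        sign = int(hypotheses.get(nm, 0))
        p_two, p_one = term_pvalues(null_b, fit.estimates[nm], sign)
        results.append(
            QapTermResult(
                term=nm,
                estimate=fit.estimates[nm],
                standardized_estimate=fit.standardized_estimates[nm],
                p_two_tailed=p_two,
                p_one_tailed=p_one,
                hypothesized_sign=sign,
            )
        )

    return QapModelResult(
        terms=tuple(results),
        intercept=fit.intercept,
        r2=fit.r2,
        r2_adj=fit.r2_adj,
        model_p=model_p,
        n_dyads=N,
        n_dropped=n_dropped,
        plan=plan,
    )
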