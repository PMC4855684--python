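"""Pooled multigroup MRQAP with class fixed effects.

Several classroom networks are analysed jointly: dyad rows from all
groups are stacked, each class gets its own fixed-effect intercept (one
reference intercept plus per-class offsets), slopes are pooled, and
group-level moderation is tested with interaction predictors built by
multiplying a dyadic predictor by the group's scalar code (e.g. year
group 0/1 or 0/1/2, so a single slope captures linear-in-age change).

Inference respects the nesting of actors in classes: the null is built
from permutations drawn *independently within each group*, applied
jointly to the rows and columns of that group's dependent matrix while
the predictors and intercept dummies stay fixed (block-restricted QAP-Y).
A double-semipartialing variant restricted within blocks is available for
sensitivity analysis.  This family of restricted permutation tests tends
to be conservative (it may overestimate standard errors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .network_data import DyadicMatrix, GroupData, ValidationError, offdiag_indices
from .qap import (
    PermutationPlan,
    QapModelResult,
    QapTermResult,
    _check_rank,
    _exceedance_p,
    _residualize,
    draw_permutations,
    gather_permuted,
    r2_null,
    term_pvalues,
)

__all__ = ["MultiGroupDesign", "build_interaction_matrix", "build_design", "mg_fit"]


def build_interaction_matrix(X: DyadicMatrix, group_code: int) -> DyadicMatrix:
    """Multiply every off-diagonal cell by the group's scalar code.

    With codes 0/1 the interaction column vanishes in the reference group
    and equals the predictor in the other; with codes 0/1/2 the slope on
    the interaction captures linear change across year groups.
    """
    return DyadicMatrix(
        list(X.actors), X.values * float(group_code), kind="generic"
    )


def interaction_name(predictor: str) -> str:
    return f"{predictor}:group"


@dataclass
class MultiGroupDesign:
    """Stacked dyad design over several groups.

    Row order is group-by-group, each group's dyads in the fixed
    row-major order, listwise-complete rows only.
    """

    groups: list[GroupData]
    predictor_names: list[str]
    interaction_names: list[str]
    column_names: list[str]          # design columns incl. intercept/dummies
    D: np.ndarray                    # (N, k) design matrix
    y: np.ndarray                    # (N,)
    group_slices: list[slice]        # pooled-row slice per group
    group_cells: list[tuple[np.ndarray, np.ndarray]]   # observed (rows, cols)
    n_dropped: int
    reference_group: str

    @property
    def n_rows(self) -> int:
        return self.D.shape[0]


def build_design(
    groups: Sequence[GroupData],
    predictors: Sequence[str],
    interactions: Sequence[str] = (),
) -> MultiGroupDesign:
    """Assemble the pooled fixed-effects design.

    Columns: intercept (reference = first group), one 0/1 dummy per
    remaining group, the pooled predictors, then one interaction column
    per requested predictor (predictor value × group code of the row's
    group).  Rows with any missing value are dropped listwise.
    """
    groups = list(groups)
    if not groups:
        raise ValidationError("no groups")
    for g in groups:
        if g.n < 3:
            raise ValidationError(f"group {g.group_id}: need at least 3 actors")
        for nm in predictors:
            if nm not in g.predictors:
                raise ValidationError(f"group {g.group_id}: missing predictor {nm!r}")
    for nm in interactions:
        if nm not in predictors:
            raise ValidationError(
                f"interaction requested for {nm!r}, which is not in the model"
            )
    ids = [g.group_id for g in groups]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate group ids")

    ref = groups[0].group_id
    blocks_y, blocks_X, cells, slices = [], [], [], []
    n_dropped = 0
    start = 0
    inames = [interaction_name(nm) for nm in interactions]
    for g in groups:
        n = g.n
        rows, cols = offdiag_indices(n)
        yv = g.Y.values[rows, cols]
        cols_data = {nm: g.predictors[nm].values[rows, cols] for nm in predictors}
        for nm in interactions:
            cols_data[interaction_name(nm)] = cols_data[nm] * float(g.group_code)
        obs = ~np.isnan(yv)
        for v in cols_data.values():
            obs &= ~np.isnan(v)
        n_dropped += int((~obs).sum())
        N_g = int(obs.sum())
        blocks_y.append(yv[obs])
        xs = [cols_data[nm][obs] for nm in list(predictors) + inames]
        blocks_X.append(np.column_stack(xs) if xs else np.empty((N_g, 0)))
        cells.append((rows[obs], cols[obs]))
        slices.append(slice(start, start + N_g))
        start += N_g

    N = start
    y = np.concatenate(blocks_y)
    Xp = np.vstack(blocks_X)
    dummy_names = [f"intercept[{g.group_id}]" for g in groups[1:]]
    dummies = np.zeros((N, len(groups) - 1))
    for j, sl in enumerate(slices[1:]):
        dummies[sl, j] = 1.0
    D = np.column_stack([np.ones(N), dummies, Xp])
    names = [f"intercept[{ref}]"] + dummy_names + list(predictors) + inames
    return MultiGroupDesign(
        groups=groups,
        predictor_names=list(predictors),
        interaction_names=inames,
        column_names=names,
        D=D,
        y=y,
        group_slices=slices,
        group_cells=cells,
        n_dropped=n_dropped,
        reference_group=ref,
    )


def _filled_y_matrices(design: MultiGroupDesign) -> list[np.ndarray]:
    out = []
    for g, sl in zip(design.groups, design.group_slices):
        V = g.Y.values.copy()
        V[np.isnan(V)] = design.y[sl].mean() if sl.stop > sl.start else 0.0
        out.append(V)
    return out


def mg_fit(
    groups: Sequence[GroupData],
    predictors: Sequence[str],
    interactions: Sequence[str] = (),
    plan: PermutationPlan | None = None,
    hypotheses: Mapping[str, int] | None = None,
    method: str = "qap_y",
) -> QapModelResult:
    """Fit the pooled multigroup model and test terms by block-restricted
    permutation.

    Point estimates come from least squares on the stacked design.  Under
    ``method="qap_y"`` (default) each permutation draw relabels the actors
    of every group's dependent matrix independently and refits the whole
    model; under ``method="dsp"`` the focal predictor's residual matrix is
    relabelled within blocks instead.  Intercept terms and the model-level
    R² are always tested against the QAP-Y null.  Standardized
    coefficients are not reported for multigroup models (the pooled
    outcome variance mixes between- and within-class variation).
    """
    if method not in ("qap_y", "dsp"):
        raise ValidationError(f"unknown method {method!r}")
    plan = plan or PermutationPlan()
    hypotheses = dict(hypotheses or {})
    design = build_design(groups, predictors, interactions)
    D, y, names = design.D, design.y, design.column_names
    N, k = D.shape
    if N <= k:
        raise ValidationError(f"too few dyads ({N}) for {k} design columns")
    _check_rank(D, names)
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 0.0
    n_free = k - 1
    r2_adj = 1.0 - (1.0 - r2) * (N - 1) / (N - n_free - 1)

    rng = np.random.default_rng(plan.seed)
    perms_per_group = [
        draw_permutations(g.n, plan.n_perm, rng) for g in design.groups
    ]

    # block-permuted outcomes (always needed: intercept tests and model p)
    Yp = np.empty((plan.n_perm, N))
    for V, perms, sl, (orows, ocols) in zip(
        _filled_y_matrices(design), perms_per_group,
        design.group_slices, design.group_cells,
    ):
        Yp[:, sl] = gather_permuted(V, perms, orows, ocols)
    Qfull, _ = np.linalg.qr(D)
    model_p = _exceedance_p(r2_null(Qfull, Yp), r2)
    B_y = np.linalg.pinv(D) @ Yp.T          # (k, n_perm) QAP-Y coefficient nulls

    n_icpt = 1 + len(design.groups) - 1
    results: list[QapTermResult] = []
    for j, nm in enumerate(names):
        is_icpt = j < n_icpt
        if is_icpt or method == "qap_y":
            null_b = B_y[j]
        else:
            # DSP within blocks: permute the focal residual matrix
            others = [i for i in range(k) if i != j]
            Qz, _ = np.linalg.qr(D[:, others])
            e = _residualize(D[:, j], Qz)
            Ep = np.empty((plan.n_perm, N))
            for g, perms, sl, (orows, ocols) in zip(
                design.groups, perms_per_group,
                design.group_slices, design.group_cells,
            ):
                E = np.zeros((g.n, g.n))
                E[orows, ocols] = e[sl]
                Ep[:, sl] = gather_permuted(E, perms, orows, ocols)
            Et = _residualize(Ep, Qz)
            yt = _residualize(y, Qz)
            denom = (Et**2).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                null_b = np.where(denom > 0, (Et @ yt) / denom, 0.0)
        sign = 0 if is_icpt else int(hypotheses.get(nm, 0))
        p_two, p_one = term_pvalues(null_b, float(beta[j]), sign)
        results.append(
            QapTermResult(
                term=nm,
                estimate=float(beta[j]),
                standardized_estimate=None,
                p_two_tailed=p_two,
                p_one_tailed=p_one,
                hypothesized_sign=sign,
                is_intercept=is_icpt,
            )
        )

    return QapModelResult(
        terms=tuple(results),
        intercept=float(beta[0]),
        r2=r2,
        r2_adj=r2_adj,
        model_p=model_p,
        n_dyads=N,
        n_dropped=design.n_dropped,
        plan=plan,
    )
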