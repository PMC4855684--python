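"""Valued-network density comparison via the vertex bootstrap.

The mean off-diagonal value of a valued sociomatrix (its *valued density*)
summarises a whole network, but its dyad observations are not independent:
every actor appears in 2(n−1) cells.  Standard errors are therefore
estimated by resampling *actors* with replacement (the vertex bootstrap of
Snijders & Borgatti) rather than cells, and two networks are compared with
an unpooled two-sample t statistic whose degrees of freedom follow the
dyad-count convention df = n₁(n₁−1) + n₂(n₂−1) − 2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_data import DyadicMatrix, ValidationError

__all__ = [
    "BootstrapDensity",
    "DensityComparison",
    "valued_density",
    "vertex_bootstrap",
    "compare_densities",
    "pairwise_density_tests",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapDensity:
    network_id: str
    observed_density: float
    bootstrap_se: float
    n_boot: int
    seed: int
    replicate_mean: float = float("nan")


@dataclass(frozen=True)
class DensityComparison:
    network_a: str
    network_b: str
    density_a: float
    density_b: float
    se_a: float
    se_b: float
    t: float
    df: int
    p_two_tailed: float
    alpha_adjusted: float | None = None

    @property
    def significant(self) -> bool:
        alpha = 0.05 if self.alpha_adjusted is None else self.alpha_adjusted
        return self.p_two_tailed < alpha


def valued_density(M: DyadicMatrix) -> float:
    """Mean of the off-diagonal cells; missing cells are excluded."""
    v = M.offdiag_values()
    n_missing = int(np.isnan(v).sum())
    if n_missing == v.size:
        raise ValidationError("all off-diagonal cells missing")
    if n_missing:
        log.info("valued_density: excluding %d missing cells", n_missing)
    return float(np.nanmean(v))


def vertex_bootstrap(
    M: DyadicMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    network_id: str | None = None,
) -> BootstrapDensity:
    """Bootstrap SE of the valued density by resampling actors.

    Each replicate draws n actors with replacement.  The cell for a
    resampled pair (a, b) mapping back to original actors (i, j) is
    M(i, j) when i ≠ j; when the same original actor fills both slots
    (a diagonal collision) the cell is drawn uniformly from that actor's
    own off-diagonal row and column values, so replicate matrices stay
    fully valued.  The SE is the standard deviation of the replicate
    densities.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be at least 2")
    n = M.n
    if n < 3:
        raise ValidationError("vertex bootstrap needs at least 3 actors")
    rng = np.random.default_rng(seed)
    V = M.values

    # pool of each actor's own off-diagonal row+column values, for collisions
    pools = []
    for i in range(n):
        pool = np.concatenate([np.delete(V[i, :], i), np.delete(V[:, i], i)])
        pool = pool[~np.isnan(pool)]
        pools.append(pool)

    densities = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        R = V[np.ix_(idx, idx)]
        # off-diagonal positions whose two slots hit the same original actor
        same = idx[:, None] == idx[None, :]
        np.fill_diagonal(same, False)
        for a, c in zip(*np.nonzero(same)):
            pool = pools[idx[a]]
            if pool.size:
                R[a, c] = rng.choice(pool)
        r, c = np.nonzero(~np.eye(n, dtype=bool))
        densities[b] = np.nanmean(R[r, c])
    return BootstrapDensity(
        network_id=network_id or "network",
        observed_density=valued_density(M),
        bootstrap_se=float(np.std(densities, ddof=1)),
        n_boot=n_boot,
        seed=seed,
        replicate_mean=float(densities.mean()),
    )


def dyad_df(n1: int, n2: int) -> int:
    """Degrees of freedom for a two-network comparison: the pooled number
    of tie variables minus 2 (e.g. n₁=23, n₂=19 → 846)."""
    return n1 * (n1 - 1) + n2 * (n2 - 1) - 2


def compare_densities(
    A: DyadicMatrix,
    B: DyadicMatrix,
    n_boot: int = 1000,
    seed: int = 0,
    ids: tuple[str, str] = ("A", "B"),
    alpha_adjusted: float | None = None,
) -> DensityComparison:
    """Two-sample t test on valued densities with vertex-bootstrap SEs.

    t = (d_A − d_B) / sqrt(SE_A² + SE_B²); the variances are unpooled
    because each SE is already network-specific.  Degenerate case: two
    constant networks with equal densities give t = 0, p = 1; unequal
    constant networks have no sampling variability and raise.
    """
    ss = np.random.SeedSequence(seed).spawn(2)
    ba = vertex_bootstrap(A, n_boot, int(ss[0].generate_state(1)[0] % 2**31), ids[0])
    bb = vertex_bootstrap(B, n_boot, int(ss[1].generate_state(1)[0] % 2**31), ids[1])
    se2 = ba.bootstrap_se**2 + bb.bootstrap_se**2
    diff = ba.observed_density - bb.observed_density
    df = dyad_df(A.n, B.n)
    if se2 == 0.0:
        if diff == 0.0:
            t, p = 0.0, 1.0
        else:
            raise ValidationError(
                "both bootstrap SEs are zero with unequal densities"
            )
    else:
        t = diff / np.sqrt(se2)
        p = 2.0 * stats.t.sf(abs(t), df)
    return DensityComparison(
        network_a=ids[0],
        network_b=ids[1],
        density_a=ba.observed_density,
        density_b=bb.observed_density,
        se_a=ba.bootstrap_se,
        se_b=bb.bootstrap_se,
        t=float(t),
        df=df,
        p_two_tailed=float(p),
        alpha_adjusted=alpha_adjusted,
    )


def pairwise_density_tests(
    networks: list[tuple[str, DyadicMatrix]],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[DensityComparison]:
    """All C(k, 2) pairwise density comparisons with Bonferroni-adjusted
    alpha = alpha / C(k, 2)."""
    ids = [nid for nid, _ in networks]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate network ids")
    if len(networks) < 2:
        raise ValidationError("need at least 2 networks")
    pairs = list(itertools.combinations(range(len(networks)), 2))
    alpha_adj = alpha / len(pairs)
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    out = []
    for (i, j), child in zip(pairs, children):
        ida, A = networks[i]
        idb, B = networks[j]
        out.append(
            compare_densities(
                A,
                B,
                n_boot=n_boot,
                seed=int(child.generate_state(1)[0] % 2**31),
                ids=(ida, idb),
                alpha_adjusted=alpha_adj,
            )
        )
    return out
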