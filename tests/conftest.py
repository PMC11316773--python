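import numpy as np
import pandas as pd
import pytest

from blapipe import simdata
from blapipe.markersel import ClusterProfile, ExpressionMatrix


@pytest.fixture(scope="session")
def social_arena():
    return simdata.social_arena()


@pytest.fixture(scope="session")
def feeding_arena():
    return simdata.feeding_arena()


@pytest.fixture(scope="session")
def short_traj(social_arena):
    return simdata.gen_trajectory(social_arena, 600, 1.5, seed=101)


@pytest.fixture(scope="session")
def profiles5():
    return simdata.random_profiles(5, seed=11)


@pytest.fixture(scope="session")
def small_expr(profiles5):
    expr, truth = simdata.gen_expression(profiles5, 25, seed=12)
    return expr, truth


@pytest.fixture()
def toy_expr():
    """Two clusters x three genes with hand-checkable counts."""
    counts = np.array(
        [
            # cluster A cells
            [3.0, 5.0, 0.0],
            [0.0, 5.0, 0.0],
            [2.0, 5.0, 0.0],
            # cluster B cells
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
            [1.0, 0.0, 1.0],
        ]
    )
    cells = [f"c{i}" for i in range(6)]
    return ExpressionMatrix(
        counts=counts,
        cell_ids=cells,
        gene_ids=["gA", "gB", "gC"],
        labels=pd.Series(["A"] * 3 + ["B"] * 3, index=cells),
    )


def brute_force_auc(in_values, out_values) -> float:
    """Pairwise win/tie count oracle for the one-vs-rest AUROC."""
    wins = ties = 0
    for a in in_values:
        for b in out_values:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(in_values) * len(out_values))


def brute_force_bh(pvalues, q) -> np.ndarray:
    """Literal step-up enumeration: reject p(i) for i <= k*,
    k* = max{i : p(i) <= i q / m}."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k_star = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def pearson(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac**2).sum() * (bc**2).sum())
    return float((ac * bc).sum() / denom) if denom > 0 else np.nan
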