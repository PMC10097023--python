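"""Random-forest screening of genus-level longevity discriminators.

The forest follows the regression-mode convention of the classic R
implementation even though the outcome is a binary group label: labels are
coded 0/1 and each tree is a depth-limited regression tree grown on a
bootstrap sample with mtry feature subsampling. Two importances fall out of
this design:

* permutation importance — the mean increase in out-of-bag squared error
  when one genus column is shuffled (the "%IncMSE" panel), and
* impurity importance — the total variance-impurity decrease a genus earns
  across all splits ("IncNodePurity").

sklearn's RandomForest classes do not expose per-tree out-of-bag indices
publicly, so the bootstrap loop lives here (seeded, deterministic) while the
trees themselves are sklearn ``DecisionTreeRegressor`` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor


@dataclass
class ImportanceReport:
    table: pd.DataFrame      # genus, perm_importance, impurity_importance, ranks
    n_trees: int
    max_depth: int
    seed: int


def rf_importances(
    features: pd.DataFrame,
    labels,
    n_trees: int = 500,
    max_depth: int = 7,
    seed: int = 0,
    max_features: float = 1.0 / 3.0,
) -> ImportanceReport:
    """Train the forest and compute both importance measures.

    features: samples x genera (relative abundances); labels: binary group
    membership, any two-level coding. ``max_features`` is the mtry fraction
    (regression default one third).
    """
    x = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"labels must have exactly 2 classes, got {len(classes)}")
    y01 = (y == classes[1]).astype(float)
    if min((y01 == 0).sum(), (y01 == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    n, p = x.shape
    mtry = max(1, int(round(max_features * p)))

    rng = np.random.default_rng(seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=n_trees)

    perm_imp = np.zeros(p)
    perm_counts = np.zeros(p)
    impurity_imp = np.zeros(p)
    oob_warned = False

    for t in range(n_trees):
        t_rng = np.random.default_rng(tree_seeds[t])
        boot = t_rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        tree = DecisionTreeRegressor(
            max_depth=max_depth,
            max_features=mtry,
            random_state=int(tree_seeds[t] % (2**31)),
        )
        tree.fit(x[boot], y01[boot])
        impurity_imp += tree.tree_.compute_feature_importances(normalize=False)

        if len(oob) == 0:
            oob_warned = True
            continue
        x_oob = x[oob]
        y_oob = y01[oob]
        base_mse = np.mean((tree.predict(x_oob) - y_oob) ** 2)
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        for j in used:
            x_perm = x_oob.copy()
            x_perm[:, j] = t_rng.permutation(x_perm[:, j])
            mse_perm = np.mean((tree.predict(x_perm) - y_oob) ** 2)
            perm_imp[j] += mse_perm - base_mse
        perm_counts += 1

    if oob_warned:
        warnings.warn("some trees had no out-of-bag samples")
    perm_counts = np.maximum(perm_counts, 1)
    perm_imp /= perm_counts
    impurity_imp /= n_trees

    table = pd.DataFrame(
        {
            "genus": features.columns,
            "perm_importance": perm_imp,
            "impurity_importance": impurity_imp,
        }
    )
    table["rank_perm"] = (
        table["perm_importance"].rank(ascending=False, method="first").astype(int)
    )
    table["rank_imp"] = (
        table["impurity_importance"].rank(ascending=False, method="first").astype(int)
    )
    return ImportanceReport(
        table=table, n_trees=n_trees, max_depth=max_depth, seed=seed
    )


def top_k(report: ImportanceReport, k: int = 10,
          measure: str = "perm") -> list[str]:
    """Top-k genera by one measure; ties by the other measure, then name."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if measure not in ("perm", "impurity"):
        raise ValueError(f"unknown measure {measure!r}")
    primary = f"{'perm' if measure == 'perm' else 'impurity'}_importance"
    secondary = f"{'impurity' if measure == 'perm' else 'perm'}_importance"
    ordered = report.table.sort_values(
        [primary, secondary, "genus"], ascending=[False, False, True],
        kind="stable",
    )
    return ordered["genus"].head(k).tolist()


def core_intersection(hub_genera: list[str], top_perm: list[str],
                      top_imp: list[str]) -> list[str]:
    """Genera in both importance top-k lists AND among the network hubs,
    reported in hub-ranking order."""
    if not (hub_genera and top_perm and top_imp):
        raise ValueError("all three genus lists must be non-empty")
    both = set(top_perm) & set(top_imp)
    core = [g for g in hub_genera if g in both]
    if not core:
        warnings.warn("empty core intersection")
    return core
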