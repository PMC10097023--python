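"""Probiotic strain characterisation arithmetic and PCA composite scoring.

Three indicators summarise a candidate strain: survival through simulated
gastrointestinal transit, self-aggregation capacity, and cell-surface
hydrophobicity (all percentages). After per-indicator z-standardisation the
Kaiser-Meyer-Olkin statistic gates whether a PCA-based composite score is
sensible (> 0.6 conventionally); principal components are then retained up
to a cumulative explained-variance threshold (default 90%), and each strain
receives the explained-variance-weighted component score

    F_sum = sum_c (v_c / M) * sum_i loading_{i,c} * X_i

with v_c the component's explained-variance fraction, M their cumulative
sum over the retained components, loading_{i,c} = eigenvector * sqrt(root),
and X_i the standardized indicator values. Strains are ranked by F_sum
descending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INDICATORS = ("gi_survival", "self_aggregation", "hydrophobicity")


# ---------------------------------------------------------------------------
# assay arithmetic

def gi_survival_rate(viable_before: float, viable_after: float) -> float:
    """Percent survival through simulated gastric + intestinal juice."""
    if viable_before <= 0:
        raise ValueError("viable count before transit must be positive")
    if viable_after < 0:
        raise ValueError("viable count after transit cannot be negative")
    return 100.0 * viable_after / viable_before


def self_aggregation(a0: float, a5: float) -> float:
    """Self-aggregation percentage (1 - A5/A0) x 100 from OD600 readings
    at 0 h and 5 h of standing."""
    if a0 <= 0:
        raise ValueError("initial absorbance A0 must be positive")
    if a5 < 0:
        raise ValueError("absorbance A5 cannot be negative")
    return (1.0 - a5 / a0) * 100.0


def hydrophobicity(a0: float, a1: float) -> float:
    """Xylene-adhesion percentage (1 - A1/A0) x 100 from aqueous-phase
    OD600 before and after two-phase partitioning."""
    if a0 <= 0:
        raise ValueError("initial absorbance A0 must be positive")
    if a1 < 0:
        raise ValueError("aqueous-phase absorbance A1 cannot be negative")
    return (1.0 - a1 / a0) * 100.0


# ---------------------------------------------------------------------------
# composite scoring

def standardize(table: pd.DataFrame, columns=INDICATORS) -> pd.DataFrame:
    """Per-indicator z-scores (ddof=1); constant columns are an error."""
    x = table[list(columns)].astype(float)
    sd = x.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant indicator column(s): {bad}")
    return (x - x.mean()) / sd


def kmo(table: pd.DataFrame, columns=INDICATORS) -> float:
    """Kaiser-Meyer-Olkin sampling-adequacy statistic.

    KMO = sum r_ij^2 / (sum r_ij^2 + sum u_ij^2) over i != j, where u_ij are
    partial correlations obtained from the inverse correlation matrix.
    """
    x = table[list(columns)].astype(float).to_numpy()
    if x.shape[0] < 3:
        raise ValueError("need at least 3 strains")
    if x.shape[1] < 2:
        raise ValueError("need at least 2 indicators")
    r = np.corrcoef(x, rowvar=False)
    try:
        s = np.linalg.inv(r)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    if np.linalg.cond(r) > 1e12:
        raise ValueError("singular correlation matrix")
    d = np.sqrt(np.diag(s))
    partial = -s / np.outer(d, d)
    off = ~np.eye(r.shape[0], dtype=bool)
    r2 = (r[off] ** 2).sum()
    u2 = (partial[off] ** 2).sum()
    return float(r2 / (r2 + u2))


@dataclass
class PcaScore:
    """Eigenstructure of the indicator correlation matrix plus strain scores.

    characteristic_roots: all eigenvalues, descending (they sum to the number
    of indicators); loadings: indicators x retained components, each column
    an eigenvector scaled by sqrt(root) so its squared entries sum to the
    root; explained_variance: root / n_indicators; cumulative: their sum M
    over retained components.
    """

    characteristic_roots: np.ndarray
    explained_variance: np.ndarray        # retained components
    cumulative: float
    loadings: pd.DataFrame                # indicators x retained components
    scores: pd.DataFrame | None = None    # strain, F_sum, rank

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def pca_components(table: pd.DataFrame, cum_threshold: float = 0.90,
                   columns=INDICATORS) -> PcaScore:
    """Eigen-decompose the indicator correlation matrix and retain the
    smallest set of leading components reaching ``cum_threshold`` cumulative
    explained variance.

    Eigenvector signs are fixed by making each component's largest-magnitude
    loading positive.
    """
    cols = list(columns)
    if table.shape[0] < len(cols):
        raise ValueError("need at least as many strains as indicators")
    xs = standardize(table, cols)
    r = np.corrcoef(xs.to_numpy(), rowvar=False)
    roots, vecs = np.linalg.eigh(r)
    order = np.argsort(roots)[::-1]
    roots = np.clip(roots[order], 0.0, None)
    vecs = vecs[:, order]
    explained = roots / len(cols)
    cum = np.cumsum(explained)
    m = int(np.searchsorted(cum, cum_threshold - 1e-12) + 1)
    m = min(m, len(cols))

    loadings = vecs[:, :m] * np.sqrt(roots[:m])
    for c in range(m):
        imax = np.argmax(np.abs(loadings[:, c]))
        if loadings[imax, c] < 0:
            loadings[:, c] = -loadings[:, c]
    load_df = pd.DataFrame(
        loadings, index=cols,
        columns=[f"PC{c + 1}" for c in range(m)],
    )
    return PcaScore(
        characteristic_roots=roots,
        explained_variance=explained[:m],
        cumulative=float(cum[m - 1]),
        loadings=load_df,
    )


def composite_score(pca: PcaScore, table: pd.DataFrame,
                    columns=INDICATORS,
                    score_coefficients: bool = False) -> PcaScore:
    """Explained-variance-weighted composite strain score and ranking.

    F_sum = sum_c (v_c / M) sum_i w_ic X_i with w the loadings as-is, or
    loadings / sqrt(root) ("score coefficients") when ``score_coefficients``
    is set. Ties in F_sum break by strain id.
    """
    cols = list(columns)
    if list(pca.loadings.index) != cols:
        raise ValueError("loading matrix does not match indicator columns")
    xs = standardize(table, cols).to_numpy()
    w = pca.loadings.to_numpy().copy()
    if score_coefficients:
        w = w / np.sqrt(pca.characteristic_roots[: pca.n_components])
    weights = pca.explained_variance / pca.cumulative
    f_sum = (xs @ w) @ weights
    scores = pd.DataFrame({"F_sum": f_sum}, index=table.index)
    if "source" in table.columns:
        scores.insert(0, "source", table["source"])
    # stable sort: ties in F_sum break by strain id (ascending)
    scores = scores.sort_index().sort_values(
        "F_sum", ascending=False, kind="mergesort"
    )
    scores["rank"] = np.arange(1, len(scores) + 1)
    pca.scores = scores
    return pca


def score_strains(table: pd.DataFrame, cum_threshold: float = 0.90,
                  kmo_gate: float = 0.6) -> tuple[PcaScore, float]:
    """KMO gate + PCA + composite ranking in one call.

    Returns the populated PcaScore and the KMO value; emits a warning (never
    an error) when KMO fails the conventional 0.6 adequacy gate.
    """
    import warnings

    k = kmo(table)
    if k <= kmo_gate:
        warnings.warn(
            f"KMO = {k:.3f} <= {kmo_gate}: composite PCA score may be "
            "inadequate for these indicators"
        )
    pca = pca_components(table, cum_threshold=cum_threshold)
    return composite_score(pca, table), k
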