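"""Weighted co-abundance network construction and module detection.

The workflow mirrors the weighted gene co-expression methodology transplanted
to OTU tables: robust-dispersion (MAD) pre-filtering, soft-threshold power
selection against a scale-free topology criterion, correlation-power
adjacency, topological overlap (TOM), average-linkage clustering of the TOM
dissimilarity, dynamic dendrogram cutting into modules (minimum size,
split-sensitivity, grey = unassigned), eigengene summarisation, closely
correlated module merging, and module-trait / membership statistics.

The dynamic cut implemented here is a hybrid variant: branches qualify as
modules when they are large enough and separate from their surroundings by a
height gap scaled by the split sensitivity; remaining elements are then
assigned to the nearest module core by average TOM dissimilarity when they
are no farther than the module's own spread. This keeps the two published
knobs (minimum module size, sensitivity 0-4) and the grey convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

# Fixed colour vocabulary so module names are reproducible run to run;
# assigned in decreasing module-size order.
MODULE_COLOURS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna3",
    "yellowgreen", "skyblue3", "plum1", "orangered4", "mediumpurple3",
    "lightsteelblue1", "lightcyan1", "ivory", "floralwhite", "darkorange2",
    "brown4", "bisque4", "darkslateblue", "plum2", "thistle2", "thistle1",
    "salmon4", "palevioletred3", "navajowhite2", "maroon", "lightpink4",
    "lavenderblush3", "honeydew1", "darkseagreen4", "coral1",
)

GREY = "grey"


@dataclass
class NetworkConfig:
    """Knobs of the network stage; defaults follow the standard methodology."""

    correlation: str = "pearson"          # or "spearman"
    network_type: str = "unsigned"        # or "signed"
    power_grid: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
    rsq_target: float = 0.85
    min_module_size: int = 25
    deep_split: int = 3
    merge_cut: float = 0.25
    mad_keep_fraction: float = 0.5
    transform: str = "log1p_relative"     # or "hellinger", "none"

    def validate(self) -> None:
        if not 0 < self.merge_cut < 1:
            raise ValueError("merge_cut must be in (0, 1)")
        if not 0 < self.mad_keep_fraction <= 1:
            raise ValueError("mad_keep_fraction must be in (0, 1]")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ValueError("deep_split must be an integer 0-4")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network type {self.network_type!r}")


@dataclass
class SoftThresholdReport:
    table: pd.DataFrame          # power, signed_r2, mean_connectivity
    chosen_power: float


@dataclass
class ModulePartition:
    """OTU -> module colour assignment plus eigengene summaries."""

    labels: pd.Series                     # index: otu id, value: colour
    eigengenes: pd.DataFrame              # samples x module colours
    variance_explained: pd.Series         # per module colour

    @property
    def module_names(self) -> list[str]:
        return [c for c in self.eigengenes.columns]

    def members(self, module: str) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class ModuleTraitResult:
    module_trait: pd.DataFrame   # module, trait, r, p
    gs: pd.DataFrame             # otu x trait correlations (gene significance)
    mm: pd.Series                # otu -> correlation with own module eigengene
    mm_gs: pd.DataFrame          # module, trait, r, p of MM vs GS over members

    def significant_modules(self, trait: str, alpha: float = 0.05) -> pd.DataFrame:
        sub = self.module_trait[self.module_trait["trait"] == trait]
        return sub[sub["p"] < alpha].sort_values("p")


# ---------------------------------------------------------------------------
# preprocessing

def transform_counts(counts: pd.DataFrame, transform: str) -> pd.DataFrame:
    """Map raw counts onto the scale correlations are computed on."""
    if transform == "none":
        return counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad[:5]}")
    rel = counts.div(totals, axis=0)
    if transform == "log1p_relative":
        # scale to per-10k before log1p so small fractions are not flattened
        return np.log1p(rel * 1e4)
    if transform == "hellinger":
        return np.sqrt(rel)
    raise ValueError(f"unknown transform {transform!r}")


def mad_filter(matrix: pd.DataFrame, keep_fraction: float) -> pd.DataFrame:
    """Keep the top ``keep_fraction`` of columns by median absolute deviation.

    Ranking is by MAD descending with ties resolved by original column order;
    the retained columns keep their original relative order.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    n_keep = int(np.floor(matrix.shape[1] * keep_fraction + 1e-9))
    if n_keep < 1:
        raise ValueError("keep_fraction retains no columns")
    order = np.argsort(-mad, kind="stable")[:n_keep]
    return matrix.iloc[:, np.sort(order)]


# ---------------------------------------------------------------------------
# adjacency / TOM

def _correlation_matrix(matrix: pd.DataFrame, method: str) -> np.ndarray:
    x = matrix.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = matrix.columns[sd == 0].tolist()
        raise ValueError(f"zero-variance OTU(s): {bad[:5]} (pre-filter them)")
    if method == "spearman":
        x = np.apply_along_axis(stats.rankdata, 0, x)
    r = np.corrcoef(x, rowvar=False)
    return np.clip(r, -1.0, 1.0)


def adjacency(matrix: pd.DataFrame, beta: float,
              network_type: str = "unsigned",
              correlation: str = "pearson") -> pd.DataFrame:
    """Soft-thresholded adjacency A_ij = |r_ij|^beta (unsigned) or
    ((1 + r_ij)/2)^beta (signed); unit diagonal."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = _correlation_matrix(matrix, correlation)
    if network_type == "unsigned":
        a = np.abs(r) ** beta
    elif network_type == "signed":
        a = ((1.0 + r) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.columns, columns=matrix.columns)


def connectivity(adj: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=0) - np.diag(a)
    return pd.Series(k, index=adj.index, name="k")


def scale_free_fit(k, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index.

    Bins connectivity into equal-width bins, regresses log10(frequency) on
    log10(mean connectivity) over non-empty bins, and returns R^2 with the
    sign flipped when the slope is positive (a rising degree distribution is
    the opposite of scale-free).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        raise ValueError("need at least n_bins positive connectivity values")
    if np.allclose(k, k[0]):
        raise ValueError("scale-free fit undefined for constant connectivity")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    log_k, log_p = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        if mean_k <= 0:
            continue
        log_k.append(np.log10(mean_k))
        log_p.append(np.log10(sel.sum() / k.size))
    if len(log_k) < 3:
        raise ValueError("too few occupied bins for a regression")
    fit = stats.linregress(log_k, log_p)
    return float(-np.sign(fit.slope) * fit.rvalue**2)


def pick_soft_threshold(matrix: pd.DataFrame,
                        config: NetworkConfig | None = None) -> SoftThresholdReport:
    """Evaluate the power grid and choose the soft threshold.

    Chosen power is the smallest grid power whose signed fit reaches
    ``rsq_target``; if none does, the power with the best signed fit.
    """
    config = config or NetworkConfig()
    config.validate()
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 OTUs")
    r = _correlation_matrix(matrix, config.correlation)
    rows = []
    for beta in config.power_grid:
        if config.network_type == "unsigned":
            a = np.abs(r) ** beta
        else:
            a = ((1.0 + r) / 2.0) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=0)
        try:
            r2 = scale_free_fit(k)
        except ValueError:
            r2 = np.nan
        rows.append({"power": beta, "signed_r2": r2,
                     "mean_connectivity": float(k.mean())})
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= config.rsq_target]
    if len(ok):
        chosen = float(ok["power"].iloc[0])
    else:
        chosen = float(table.loc[table["signed_r2"].idxmax(), "power"])
    return SoftThresholdReport(table=table, chosen_power=chosen)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    L_ij = sum_{u != i,j} a_iu a_uj and k_i the connectivity; TOM_ii = 1.
    """
    a = adj.to_numpy(dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=0)
    l = a0 @ a0  # L_ij = sum_u a_iu a_uj with u != i,j (diagonal zeroed)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    tom = (l + a0) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# module detection

# deep_split 0 (conservative) .. 4 (aggressive): minimum core-to-join height
# gap as a fraction of the dendrogram height range
_SPLIT_GAP = (0.33, 0.20, 0.12, 0.065, 0.03)

# a branch holding more than this share of all leaves is the background
# blob / root region, never a module
_MAX_BRANCH_FRACTION = 0.5


def _dynamic_cut(diss: np.ndarray, min_module_size: int,
                 deep_split: int) -> np.ndarray:
    """Label OTUs with module numbers 1..m (0 = unassigned).

    Branch qualification: an internal dendrogram node is a candidate module
    when (a) it has >= min_module_size leaves but no more than half of all
    leaves, and (b) the height gap between the assembly of its *core* (the
    height at which its first min_module_size members have merged) and the
    merge into its parent is at least a deep_split-dependent fraction of the
    dendrogram height range. Measuring the gap from the core rather than the
    branch tip keeps gradually accreting branches (a module absorbing its
    weakly-loaded members one by one) detectable. Among nested candidates the
    deepest win; remaining elements are then adopted by the closest module
    (average dissimilarity) when they sit within the module's own spread.
    """
    n = diss.shape[0]
    if n < min_module_size:
        warnings.warn("fewer OTUs than min_module_size; everything is grey")
        return np.zeros(n, dtype=int)
    z = linkage(squareform(diss, checks=False), method="average")
    heights = z[:, 2]
    h_range = heights.max() - heights.min()
    if h_range <= 0:
        return np.zeros(n, dtype=int)
    gap_min = _SPLIT_GAP[deep_split] * h_range

    n_nodes = 2 * n - 1
    parent_height = np.full(n_nodes, np.nan)
    size = np.ones(n_nodes, dtype=int)
    # core_top[node]: height of the merge that first brought the branch to
    # min_module_size members (inf while still smaller)
    core_top = np.full(n_nodes, np.inf)
    for i in range(n - 1):
        left, right = int(z[i, 0]), int(z[i, 1])
        node = n + i
        size[node] = size[left] + size[right]
        parent_height[left] = heights[i]
        parent_height[right] = heights[i]
        if size[node] >= min_module_size:
            # inherits the earliest core among children; heights[i] when this
            # very merge is what completed the core
            core_top[node] = min(core_top[left], core_top[right], heights[i])

    max_size = max(min_module_size, int(_MAX_BRANCH_FRACTION * n))
    candidate = np.zeros(n_nodes, dtype=bool)
    for i in range(n - 1):
        node = n + i
        if not min_module_size <= size[node] <= max_size:
            continue
        ph = parent_height[node]
        if np.isnan(ph):          # root detaches from nothing
            continue
        if ph - core_top[node] >= gap_min:
            candidate[node] = True

    # deepest candidates: drop any candidate with a candidate descendant
    has_cand_desc = np.zeros(n_nodes, dtype=bool)
    for i in range(n - 1):        # children have smaller node ids: bottom-up
        node = n + i
        left, right = int(z[i, 0]), int(z[i, 1])
        has_cand_desc[node] = (
            candidate[left] or candidate[right]
            or has_cand_desc[left] or has_cand_desc[right]
        )
    selected = [node for node in range(n, n_nodes)
                if candidate[node] and not has_cand_desc[node]]

    labels = np.zeros(n, dtype=int)
    for m, node in enumerate(sorted(selected), start=1):
        stack = [node]
        while stack:
            cur = stack.pop()
            if cur < n:
                labels[cur] = m
            else:
                stack.append(int(z[cur - n, 0]))
                stack.append(int(z[cur - n, 1]))

    labels = _adopt_borderline(diss, labels)
    return labels


def _adopt_borderline(diss: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Assign grey elements to the nearest module if within its spread."""
    modules = np.unique(labels[labels > 0])
    if len(modules) == 0:
        return labels
    grey = np.flatnonzero(labels == 0)
    if len(grey) == 0:
        return labels
    out = labels.copy()
    spreads, members = {}, {}
    for m in modules:
        idx = np.flatnonzero(labels == m)
        members[m] = idx
        sub = diss[np.ix_(idx, idx)]
        # spread: the farthest member's average distance to the rest
        avg = (sub.sum(axis=1)) / (len(idx) - 1)
        spreads[m] = avg.max()
    for g in grey:
        best_m, best_d = 0, np.inf
        for m in modules:
            d = diss[g, members[m]].mean()
            if d < best_d:
                best_m, best_d = m, d
        if best_d <= spreads[best_m]:
            out[g] = best_m
    return out


def _colour_names(labels: np.ndarray, otu_ids) -> pd.Series:
    """Map numeric module labels to colour names by decreasing size
    (ties by first-member position); 0 stays grey."""
    modules = np.unique(labels[labels > 0])
    stats_ = []
    for m in modules:
        idx = np.flatnonzero(labels == m)
        stats_.append((len(idx), -idx[0], m))
    stats_.sort(reverse=True)
    mapping = {}
    for rank, (_, _, m) in enumerate(stats_):
        if rank < len(MODULE_COLOURS):
            mapping[m] = MODULE_COLOURS[rank]
        else:
            mapping[m] = f"module{rank + 1}"
    names = [GREY if l == 0 else mapping[l] for l in labels]
    return pd.Series(names, index=otu_ids, name="module")


def module_eigengene(matrix: pd.DataFrame, member_otus) -> tuple[pd.Series, float]:
    """First principal component of the standardized member submatrix.

    Returned as a unit-variance sample vector, sign-oriented so it correlates
    non-negatively with the mean member profile (falling back to a positive
    loading on the first member when the mean profile is degenerate).
    variance_explained is the leading eigenvalue share.
    """
    member_otus = list(member_otus)
    if len(member_otus) < 2:
        raise ValueError("a module eigengene needs at least 2 members")
    x = matrix[member_otus].to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance member profile")
    xs = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    pc = u[:, 0] * s[0]
    if pc.std() == 0:
        raise ValueError("degenerate eigengene")
    eig = pc / pc.std()
    var_explained = float(s[0] ** 2 / (s**2).sum())
    mean_profile = xs.mean(axis=1)
    if mean_profile.std() > 1e-12:
        orient = np.corrcoef(eig, mean_profile)[0, 1]
    else:
        orient = np.corrcoef(eig, xs[:, 0])[0, 1]
    if orient < 0:
        eig = -eig
    return pd.Series(eig, index=matrix.index), var_explained


def _partition_from_labels(matrix: pd.DataFrame,
                           labels: pd.Series) -> ModulePartition:
    modules = [m for m in labels.unique() if m != GREY]
    # order columns by module size desc then name for stable output
    modules.sort(key=lambda m: (-(labels == m).sum(), m))
    eigs, var = {}, {}
    for m in modules:
        members = labels.index[labels == m]
        eigs[m], var[m] = module_eigengene(matrix, members)
    eigengenes = pd.DataFrame(eigs, index=matrix.index)
    return ModulePartition(labels=labels,
                           eigengenes=eigengenes,
                           variance_explained=pd.Series(var, dtype=float))


def detect_modules(matrix: pd.DataFrame, diss_tom: pd.DataFrame,
                   config: NetworkConfig | None = None) -> ModulePartition:
    """Dynamic-cut the TOM dendrogram into colour-labelled modules."""
    config = config or NetworkConfig()
    config.validate()
    d = diss_tom.to_numpy(dtype=float)
    labels_num = _dynamic_cut(d, config.min_module_size, config.deep_split)
    labels = _colour_names(labels_num, diss_tom.index)
    return _partition_from_labels(matrix, labels)


def merge_modules(partition: ModulePartition, matrix: pd.DataFrame,
                  merge_cut: float = 0.25) -> ModulePartition:
    """Merge modules whose eigengenes are closer than ``merge_cut``
    (dissimilarity 1 - cor, average linkage), iterating until stable."""
    labels = partition.labels.copy()
    for _ in range(20):
        modules = [m for m in labels.unique() if m != GREY]
        if len(modules) < 2:
            break
        part = _partition_from_labels(matrix, labels)
        modules = part.module_names
        e = part.eigengenes[modules].to_numpy()
        diss = 1.0 - np.corrcoef(e, rowvar=False)
        np.fill_diagonal(diss, 0.0)
        diss = np.clip((diss + diss.T) / 2, 0.0, 2.0)
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=merge_cut, criterion="distance")
        if len(np.unique(groups)) == len(modules):
            break
        # merge: every group keeps the colour of its largest member module
        sizes = labels.value_counts()
        new_map = {}
        for gid in np.unique(groups):
            group_modules = [modules[i] for i in np.flatnonzero(groups == gid)]
            keep = max(group_modules, key=lambda m: (sizes[m], m))
            for m in group_modules:
                new_map[m] = keep
        labels = labels.map(lambda m: new_map.get(m, m))
    return _partition_from_labels(matrix, labels)


# ---------------------------------------------------------------------------
# module-trait statistics

def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation from the t distribution."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _cross_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between two matrices (n x p, n x q)."""
    az = (a - a.mean(axis=0)) / a.std(axis=0)
    bz = (b - b.mean(axis=0)) / b.std(axis=0)
    return np.clip(az.T @ bz / a.shape[0], -1.0, 1.0)


def module_trait(matrix: pd.DataFrame, partition: ModulePartition,
                 traits: pd.DataFrame) -> ModuleTraitResult:
    """Eigengene-trait correlations plus per-OTU GS and MM statistics.

    Traits must be numeric (binary coded 0/1). p-values come from the
    two-sided t approximation with n - 2 degrees of freedom; no multiple-
    testing correction is applied by default (a BH-adjusted column is
    included for inspection).
    """
    traits = traits.loc[matrix.index]
    tvals = traits.to_numpy(dtype=float)
    if (tvals.std(axis=0) == 0).any():
        bad = traits.columns[tvals.std(axis=0) == 0].tolist()
        raise ValueError(f"constant trait(s): {bad}")
    n = matrix.shape[0]
    modules = partition.module_names
    e = partition.eigengenes[modules].to_numpy()

    r_mt = _cross_corr(e, tvals)
    p_mt = correlation_p(r_mt, n)
    rows = []
    for i, m in enumerate(modules):
        for j, t in enumerate(traits.columns):
            rows.append({"module": m, "trait": t,
                         "r": float(r_mt[i, j]), "p": float(p_mt[i, j])})
    mt = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    mt["p_bh"] = _benjamini_hochberg(mt["p"].to_numpy())

    x = matrix.to_numpy(dtype=float)
    gs_r = _cross_corr(x, tvals)
    gs = pd.DataFrame(gs_r, index=matrix.columns, columns=traits.columns)

    mm = pd.Series(np.nan, index=matrix.columns, name="MM")
    for i, m in enumerate(modules):
        members = partition.labels.index[partition.labels == m]
        cols = [matrix.columns.get_loc(o) for o in members]
        mm_r = _cross_corr(x[:, cols], e[:, [i]])[:, 0]
        mm.iloc[cols] = mm_r

    mmgs_rows = []
    for m in modules:
        members = partition.labels.index[partition.labels == m]
        if len(members) < 3:
            continue
        for t in traits.columns:
            a = np.abs(mm.loc[members].to_numpy())
            b = np.abs(gs.loc[members, t].to_numpy())
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            mmgs_rows.append({"module": m, "trait": t, "r": r,
                              "p": float(correlation_p(r, len(members)))})
    mm_gs = pd.DataFrame(mmgs_rows, columns=["module", "trait", "r", "p"])
    return ModuleTraitResult(module_trait=mt, gs=gs, mm=mm, mm_gs=mm_gs)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj
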