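"""Weighted co-expression network analysis, from scratch.

Implements the standard unsigned-WGCNA chain on an FPKM matrix:
low-expression prefilter, MAD top-N variance filter, soft-threshold
selection by scale-free topology fit, |cor|^beta adjacency, topological
overlap (TOM), average-linkage module detection with a static tree cut,
module eigengenes, eigengene-similarity merging, kME membership,
module-trait correlation, hypergeometric term enrichment and thresholded
edge-list export.

Correlations are computed on log2(FPKM + 1).  The static tree cut (in
place of the dynamic hybrid cut) is a documented simplification; module
minimum size and eigengene merging honour the usual parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .types import CalncError

log = logging.getLogger(__name__)

#: conventional module color sequence; grey is reserved for unassigned
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)
GREY = "grey"


@dataclass
class NetworkConfig:
    sample_frac: float = 0.9
    expr_cutoff: float = 1.0      # FPKM
    mad_top_n: int = 10_000
    r2_cutoff: float = 0.85
    beta_max: int = 30
    min_module_size: int = 30
    merge_cut_height: float = 0.25
    max_block_size: int = 10_000
    kme_cutoff: float = 0.9
    network_type: str = "unsigned"
    edge_weight_threshold: float = 0.2
    cut_height: Optional[float] = None   # None = 0.99 of the max merge height

    def __post_init__(self) -> None:
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if self.beta_max < 1:
            raise ValueError("beta_max must be >= 1")
        if not (0 < self.sample_frac <= 1):
            raise ValueError("sample_frac must lie in (0, 1]")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def prefilter(values: pd.DataFrame, expr_cutoff: float = 1.0,
              sample_frac: float = 0.9) -> pd.DataFrame:
    """Drop genes whose FPKM falls below ``expr_cutoff`` in at least
    ``sample_frac`` of the samples (i.e. keep genes expressed above the
    cutoff in more than 1 - sample_frac of samples)."""
    low = (values < expr_cutoff).mean(axis=1) >= sample_frac
    out = values.loc[~low]
    if out.empty:
        raise CalncError(
            "prefilter removed every gene; lower expr_cutoff or sample_frac"
        )
    return out


def mad_topn(values: pd.DataFrame, n: int) -> pd.DataFrame:
    """Keep the n rows with the largest median absolute deviation; ties
    broken by transcript id (lexicographic)."""
    mad = stats.median_abs_deviation(values.to_numpy(), axis=1, scale=1.0)
    if n >= len(values):
        if n > len(values):
            log.warning("mad_topn: n=%d >= %d rows; keeping all", n, len(values))
        return values
    order = sorted(range(len(values)), key=lambda i: (-mad[i], values.index[i]))
    keep = sorted(order[:n], key=lambda i: i)   # preserve row order
    return values.iloc[keep]


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    x = values.to_numpy()
    sd = x.std(axis=1)
    if (sd < 1e-12).any():
        bad = list(values.index[sd < 1e-12][:5])
        raise CalncError(f"constant genes break correlation (e.g. {bad})")
    c = np.corrcoef(x)
    c = np.clip(c, -1.0, 1.0)
    return pd.DataFrame(c, index=values.index, columns=values.index)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: float,
              network_type: str = "unsigned") -> np.ndarray:
    """Unsigned: |cor|^beta.  Signed: ((1 + cor)/2)^beta."""
    c = np.asarray(cor, dtype=float)
    if network_type == "unsigned":
        a = np.abs(c) ** beta
    elif network_type == "signed":
        a = ((1.0 + c) / 2.0) ** beta
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Bins k into ``n_bins`` equal-width bins, regresses log10 frequency
    on log10 mean connectivity over occupied bins, and returns
    (r_squared, slope).  Degenerate inputs give (0, 0).
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2), float(slope)


def pick_soft_threshold(
    values: pd.DataFrame,
    r2_cutoff: float = 0.85,
    beta_max: int = 30,
    network_type: str = "unsigned",
    beta_grid: Optional[Sequence[int]] = None,
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose connectivity distribution fits a scale-free
    topology (R^2 >= cutoff with negative slope); ``beta_max`` with a
    warning when none qualifies.  ``values`` are expression rows
    (genes x samples); the fit table reports R^2, slope and mean k per
    beta."""
    if len(values) < 3:
        raise CalncError("need >= 3 genes to pick a soft threshold")
    cor = correlation_matrix(values).to_numpy()
    if beta_grid is None:
        beta_grid = range(1, beta_max + 1)
    rows = []
    chosen = None
    for beta in beta_grid:
        a = adjacency(cor, beta, network_type)
        k = a.sum(axis=0) - 1.0
        r2, slope = scale_free_fit(k)
        rows.append({"beta": beta, "r2": r2, "slope": slope, "mean_k": float(k.mean())})
        if chosen is None and r2 >= r2_cutoff and slope < 0:
            chosen = int(beta)
    fit = pd.DataFrame(rows)
    if chosen is None:
        chosen = int(beta_max)
        log.warning(
            "no beta reached scale-free R^2 >= %.2f; falling back to beta_max=%d",
            r2_cutoff, beta_max,
        )
    return chosen, fit


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij)
    with l_ij = sum_u a_iu a_uj over u != i,j; unit diagonal."""
    a = np.asarray(adj, dtype=float)
    if not np.allclose(a, a.T, atol=1e-12):
        raise CalncError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0                      # includes no i/j self terms once diag is 0
    k = a0.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a0) / (kmin + 1.0 - a0)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def _linkage_from_dissim(d: np.ndarray):
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return average(squareform(d, checks=False))


def detect_modules(
    tom: np.ndarray,
    gene_ids: Sequence[str],
    min_module_size: int = 30,
    cut_height: Optional[float] = None,
) -> pd.Series:
    """Average-linkage clustering on 1 - TOM with a static cut.

    By default the cut height is placed in the middle of the largest gap
    among merge heights in the upper half of the dendrogram: genuinely
    co-expressed blocks finish merging well below the heights at which
    unstructured genes attach, and the widest gap separates the two
    regimes at any soft-threshold power.  An explicit ``cut_height``
    overrides this.  Clusters below ``min_module_size`` are relabelled
    grey; surviving clusters get conventional color names by decreasing
    size.
    """
    n = len(gene_ids)
    if n < min_module_size:
        log.warning("only %d genes (< min module size %d): all grey", n, min_module_size)
        return pd.Series([GREY] * n, index=list(gene_ids))
    link = _linkage_from_dissim(1.0 - np.asarray(tom, dtype=float))
    if cut_height is None:
        cut_height = _largest_gap_cut(link[:, 2])
    raw = fcluster(link, t=cut_height, criterion="distance")
    return _label_by_size(raw, gene_ids, min_module_size)


def _largest_gap_cut(merge_heights: np.ndarray) -> float:
    """Midpoint of the widest gap among sorted merge heights at or above
    their median; falls back to 0.99 of the maximum for tiny trees."""
    h = np.sort(np.asarray(merge_heights, dtype=float))
    upper = h[h >= np.median(h)]
    if upper.size < 3:
        return 0.99 * h.max()
    gaps = np.diff(upper)
    i = int(np.argmax(gaps))
    return float((upper[i] + upper[i + 1]) / 2.0)


def _label_by_size(raw_labels: np.ndarray, gene_ids: Sequence[str],
                   min_module_size: int) -> pd.Series:
    sizes = pd.Series(raw_labels).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    keep.sort(key=lambda c: (-sizes[c], c))
    mapping = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(keep)}
    labels = [mapping.get(c, GREY) for c in raw_labels]
    return pd.Series(labels, index=list(gene_ids))


def module_eigengene(values: pd.DataFrame, members: Sequence[str]) -> tuple[np.ndarray, float]:
    """First principal component over samples of the member-standardized
    expression; unit norm, sign aligned with the mean member profile.
    Returns (eigengene, variance_explained)."""
    members = list(members)
    if not members:
        raise CalncError("module_eigengene needs >= 1 member")
    x = values.loc[members].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        dropped = [m for m, s in zip(members, sd) if s == 0]
        log.warning("dropping %d constant members before PCA", len(dropped))
        x = x[sd > 0]
        if x.shape[0] == 0:
            raise CalncError("all module members constant")
    x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eig = vt[0]
    ve = float(s[0] ** 2 / (s**2).sum())
    mean_profile = x.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig / np.linalg.norm(eig), ve


def eigengene_table(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Eigengenes of all non-grey modules: samples x modules."""
    out = {}
    for mod in sorted(set(labels) - {GREY}):
        eig, _ = module_eigengene(values, list(labels.index[labels == mod]))
        out[mod] = eig
    return pd.DataFrame(out, index=values.columns)


def merge_modules(
    values: pd.DataFrame,
    labels: pd.Series,
    merge_cut_height: float = 0.25,
) -> pd.Series:
    """Merge modules whose eigengenes cluster (average linkage on
    1 - cor) below ``merge_cut_height``; iterate until stable."""
    labels = labels.copy()
    while True:
        mods = sorted(set(labels) - {GREY})
        if len(mods) < 2:
            return labels
        eigs = eigengene_table(values, labels)
        cor = np.corrcoef(eigs.to_numpy().T)
        d = 1.0 - np.clip(cor, -1.0, 1.0)
        link = _linkage_from_dissim(d)
        raw = fcluster(link, t=merge_cut_height, criterion="distance")
        if len(set(raw)) == len(mods):
            return labels
        sizes = labels.value_counts()
        for cluster in set(raw):
            group = [m for m, c in zip(mods, raw) if c == cluster]
            if len(group) > 1:
                target = max(group, key=lambda m: (sizes.get(m, 0), m))
                labels[labels.isin(group)] = target


def kme(values: pd.DataFrame, eigengene: np.ndarray) -> pd.Series:
    """Module membership: Pearson correlation of each gene with the
    module eigengene."""
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    e = np.asarray(eigengene, dtype=float)
    ec = e - e.mean()
    denom = np.sqrt((xc**2).sum(axis=1)) * np.sqrt((ec**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ ec) / denom
    return pd.Series(np.clip(r, -1, 1), index=values.index)


def kme_filter(values: pd.DataFrame, members: Sequence[str], eigengene: np.ndarray,
               kme_cutoff: float = 0.9) -> list[str]:
    """Retain members with |kME| >= cutoff."""
    k = kme(values.loc[list(members)], eigengene)
    return [m for m in members if abs(k[m]) >= kme_cutoff]


def module_trait_correlation(eigengene: np.ndarray, trait: np.ndarray) -> tuple[float, float]:
    """Pearson r of an eigengene with a per-sample trait indicator and
    the two-sided p from the t transform with n - 2 df."""
    e = np.asarray(eigengene, dtype=float)
    t = np.asarray(trait, dtype=float)
    if np.ptp(t) == 0:
        raise CalncError("trait indicator is constant")
    r = float(np.corrcoef(e, t)[0, 1])
    n = e.size
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(tstat), df=n - 2))
    return r, p


def module_trait_table(eigengenes: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """All module x trait correlations; traits is samples x indicators."""
    rows = []
    for mod in eigengenes.columns:
        for tr in traits.columns:
            r, p = module_trait_correlation(
                eigengenes[mod].to_numpy(), traits[tr].to_numpy()
            )
            rows.append({"module": mod, "trait": tr, "r": r, "p": p})
    return pd.DataFrame(rows)


def group_trait_indicators(samples) -> pd.DataFrame:
    """Binary (genotype, treatment, time) group indicators per sample."""
    idx = [s.sample_id for s in samples]
    cols = {}
    for s in samples:
        tag = "|".join(map(str, s.group))
        cols.setdefault(tag, np.zeros(len(idx)))
    for j, s in enumerate(samples):
        cols["|".join(map(str, s.group))][j] = 1.0
    return pd.DataFrame(cols, index=idx)


# ---------------------------------------------------------------------------
# enrichment + export
# ---------------------------------------------------------------------------

def enrich_hypergeometric(
    module_genes: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a user-supplied gene->terms
    map, BH-corrected across terms."""
    universe = set(universe)
    module = set(module_genes)
    if not module <= universe:
        raise CalncError("module genes must be a subset of the universe")
    by_term: dict[str, set] = {}
    for gene, terms in term_map.items():
        if gene in universe:
            for t in terms:
                by_term.setdefault(t, set()).add(gene)
    if not by_term:
        return pd.DataFrame(columns=["term", "overlap", "term_size", "p", "q"])
    big_n, n = len(universe), len(module)
    rows = []
    for term, genes in sorted(by_term.items()):
        k = len(genes & module)
        p = float(stats.hypergeom.sf(k - 1, big_n, len(genes), n))
        rows.append({"term": term, "overlap": k, "term_size": len(genes), "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df.p.to_numpy())
    return df


def export_network(
    weights: np.ndarray,
    gene_ids: Sequence[str],
    edge_weight_threshold: float,
    labels: Optional[pd.Series] = None,
    gene_types: Optional[Mapping[str, str]] = None,
    module: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Undirected edge list of weights >= threshold (isolated nodes
    dropped) plus a node table with module and gene-type annotations.
    ``module`` restricts the export to one module's genes."""
    gene_ids = list(gene_ids)
    w = np.asarray(weights, dtype=float)
    keep_idx = range(len(gene_ids))
    if module is not None:
        if labels is None:
            raise CalncError("module export needs labels")
        keep_idx = [i for i, g in enumerate(gene_ids) if labels[g] == module]
    edges = []
    for ii, i in enumerate(keep_idx):
        for j in list(keep_idx)[ii + 1:]:
            if w[i, j] >= edge_weight_threshold:
                edges.append({"source": gene_ids[i], "target": gene_ids[j],
                              "weight": float(w[i, j])})
    edge_df = pd.DataFrame(edges, columns=["source", "target", "weight"])
    connected = sorted(set(edge_df.source) | set(edge_df.target))
    node_df = pd.DataFrame({
        "gene": connected,
        "module": [labels[g] if labels is not None else "" for g in connected],
        "gene_type": [gene_types.get(g, "") if gene_types else "" for g in connected],
    })
    return edge_df, node_df


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionResult:
    labels: pd.Series                 # gene -> module color
    kme_table: pd.DataFrame           # gene, module, kME, retained
    eigengenes: pd.DataFrame          # samples x modules
    variance_explained: dict
    beta: int
    fit_table: pd.DataFrame
    tom: np.ndarray
    gene_ids: list
    module_trait: Optional[pd.DataFrame] = None


def run_coexpress(values: pd.DataFrame, config: NetworkConfig,
                  traits: Optional[pd.DataFrame] = None) -> CoexpressionResult:
    """Full chain: prefilter -> MAD top-N -> log2 -> soft threshold ->
    adjacency -> TOM -> modules -> merge -> eigengenes/kME (-> traits)."""
    expr = prefilter(values, config.expr_cutoff, config.sample_frac)
    expr = mad_topn(expr, min(config.mad_top_n, config.max_block_size))
    logx = log_transform(expr)
    sd = logx.to_numpy().std(axis=1)
    flat = sd < 1e-9   # tolerance: exp/log round-trips leave ~1e-15 jitter
    if flat.any():
        log.warning("dropping %d constant genes before correlation", int(flat.sum()))
        logx = logx.loc[~flat]
    beta, fit = pick_soft_threshold(
        logx, r2_cutoff=config.r2_cutoff, beta_max=config.beta_max,
        network_type=config.network_type,
    )
    cor = correlation_matrix(logx).to_numpy()
    adj = adjacency(cor, beta, config.network_type)
    tom = tom_similarity(adj)
    labels = detect_modules(
        tom, list(logx.index), config.min_module_size, cut_height=config.cut_height
    )
    labels = merge_modules(logx, labels, config.merge_cut_height)

    eigs = eigengene_table(logx, labels)
    ve, kme_rows = {}, []
    for mod in eigs.columns:
        members = list(labels.index[labels == mod])
        eig, v = module_eigengene(logx, members)
        ve[mod] = v
        kvals = kme(logx.loc[members], eig)
        for g in members:
            kme_rows.append({
                "gene": g, "module": mod, "kME": float(kvals[g]),
                "retained": bool(abs(kvals[g]) >= config.kme_cutoff),
            })
    for g in labels.index[labels == GREY]:
        kme_rows.append({"gene": g, "module": GREY, "kME": float("nan"), "retained": False})
    kme_table = pd.DataFrame(kme_rows)

    mt = module_trait_table(eigs, traits) if traits is not None and not eigs.empty else None
    return CoexpressionResult(
        labels=labels, kme_table=kme_table, eigengenes=eigs,
        variance_explained=ve, beta=beta, fit_table=fit, tom=tom,
        gene_ids=list(logx.index), module_trait=mt,
    )
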