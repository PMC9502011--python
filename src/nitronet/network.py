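"""Spearman co-occurrence network inference with RMT threshold selection.

The chain is: pairwise Spearman correlation with FDR control, selection of
a hard correlation cutoff by random-matrix-theory (RMT) spectral
statistics, construction of a signed network, modularity-based module
detection, and per-sample module abundance.

RMT thresholding rests on a universality result: the nearest-neighbour
spacing distribution (NNSD) of unfolded eigenvalues of a dense random
correlation matrix follows Wigner-Dyson (GOE) statistics, while a matrix
whose remaining entries reflect genuine modular structure - effectively a
set of nearly independent blocks - shows Poisson spacing, P(s) = exp(-s).
Scanning the cutoff upward, the smallest cutoff at which the NNSD becomes
Poisson-consistent marks the transition from noise-dominated to
structure-dominated correlations and is taken as the network threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class CorrelationResult:
    """Pairwise Spearman correlations with raw and FDR-adjusted p-values.

    All three frames are taxon x taxon, symmetric, with unit diagonal for
    ``rho``.  Taxa with zero variance produce undefined correlations,
    recorded as NaN and excluded from any network built from this result.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    @property
    def taxa(self) -> list:
        return list(self.rho.index)


@dataclass(frozen=True)
class ModulePartition:
    """Taxon -> module assignment with the modularity of the partition.

    Modules are ranked by node count and named Mod1..Modk; ``module_of``
    covers every non-isolated node of the network it was computed on.
    """

    module_of: pd.Series
    modularity: float

    @property
    def modules(self) -> list[str]:
        order = self.module_of.value_counts().index
        return list(order)


def spearman_matrix(table: pd.DataFrame, fdr_method: str = "bh", q_cut: float = 0.001) -> CorrelationResult:
    """All-pairs Spearman correlation across sample columns.

    Average ranks are used for ties and two-sided p-values come from the
    t-approximation.  ``q`` holds FDR-adjusted p-values (Benjamini-Hochberg
    step-up by default), adjusted jointly over the upper triangle.
    """
    n_taxa, n_samples = table.shape
    if n_samples < 4:
        raise ValueError("need >= 4 samples for Spearman correlation")
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    values = table.to_numpy(dtype=float)
    constant = values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho, p = stats.spearmanr(values, axis=1)
    rho = np.atleast_2d(rho)
    p = np.atleast_2d(p)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = table.index
    q = np.full_like(p, np.nan)
    iu = np.triu_indices(n_taxa, k=1)
    flat_p = p[iu]
    ok = ~np.isnan(flat_p)
    if ok.any():
        flat_q = np.full(flat_p.shape, np.nan)
        flat_q[ok] = fdr_adjust(flat_p[ok], method=fdr_method, q_cut=q_cut)[0]
        q[iu] = flat_q
        q.T[iu] = flat_q
    np.fill_diagonal(q, 0.0)
    return CorrelationResult(
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
        pd.DataFrame(q, index=idx, columns=idx),
    )


def fdr_adjust(p, method: str = "bh", q_cut: float = 0.05):
    """Adjust a collection of p-values for multiple testing.

    Returns ``(q, mask)`` where ``mask = q <= q_cut``.  ``method`` is
    ``"bh"`` (Benjamini-Hochberg step-up, default), ``"by"``
    (Benjamini-Yekutieli) or ``"bonferroni"``.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    codes = {"bh": "fdr_bh", "by": "fdr_by", "bonferroni": "bonferroni"}
    if method not in codes:
        raise ValueError(f"unknown FDR method {method!r}")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, alpha=q_cut, method=codes[method])
    return q, q <= q_cut


def _unfolded_spacings(eigvals: np.ndarray, poly_order: int) -> np.ndarray | None:
    """Unfold a spectrum and return nearest-neighbour spacings (mean 1).

    Degenerate (numerically equal) eigenvalues are collapsed before
    unfolding; the cumulative spectral density is smoothed with a
    polynomial of ``poly_order`` and spacings are taken on the unfolded
    scale.  Returns None when too few distinct eigenvalues remain for a
    meaningful spacing distribution.
    """
    lam = np.sort(eigvals)
    scale = max(abs(lam[0]), abs(lam[-1]), 1.0)
    distinct = [lam[0]]
    for value in lam[1:]:
        if value - distinct[-1] > 1e-8 * scale:
            distinct.append(value)
    lam = np.asarray(distinct)
    # Detached outlier eigenvalues (module/global factors far above the
    # bulk) wreck the polynomial fit of the cumulative density; trim them
    # from either end when their gap exceeds 10x the median bulk gap,
    # capped at 20% of the spectrum.  Bulk spacing statistics are what the
    # GOE/Poisson test is about.
    max_trim = lam.size // 5
    for _ in range(max_trim):
        if lam.size < 3:
            break
        gaps = np.diff(lam)
        cut = 10.0 * np.median(gaps)
        if gaps[-1] > cut:
            lam = lam[:-1]
        elif gaps[0] > cut:
            lam = lam[1:]
        else:
            break
    m = lam.size
    if m < max(poly_order + 2, 12):
        return None
    cumulative = np.arange(m) / (m - 1)
    coeffs = np.polyfit(lam, cumulative, poly_order)
    unfolded = m * np.polyval(coeffs, lam)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if spacings.size < 10:
        return None
    return spacings / spacings.mean()


def _poisson_chi2(spacings: np.ndarray) -> tuple[float, float]:
    """Chi-square goodness of fit of spacings to the Poisson law exp(-s)."""
    n = spacings.size
    n_bins = int(np.ceil(np.sqrt(n)))
    edges = np.linspace(0.0, spacings.max(), n_bins + 1)
    observed, _ = np.histogram(spacings, bins=edges)
    cdf = 1.0 - np.exp(-edges)
    expected = n * np.diff(cdf)
    # absorb the open tail beyond the last edge into the final bin
    expected[-1] += n * np.exp(-edges[-1])
    keep = expected > 1e-12
    statistic = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
    dof = max(int(keep.sum()) - 2, 1)
    return statistic, float(stats.chi2.sf(statistic, dof))


def rmt_threshold(
    corr: CorrelationResult | pd.DataFrame,
    grid=None,
    poly_order: int = 5,
    alpha: float = 0.05,
    n_consecutive: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Select a correlation cutoff by the GOE-to-Poisson NNSD transition.

    For each candidate cutoff t in ``grid`` (ascending, within (0, 1)) the
    correlation matrix is truncated (|rho| < t zeroed, unit diagonal kept),
    its eigenvalues unfolded, and the NNSD tested against the Poisson law
    by chi-square.  Returns the smallest cutoff at which the spectrum
    *enters and stays in* the Poisson regime - Poisson-consistent
    (chi-square p > ``alpha``) there and at the next ``n_consecutive - 1``
    grid points - together with the full per-cutoff diagnostic table
    (columns: threshold, n_distinct_eigvals, chi2, p,
    poisson_consistent).  Requiring a sustained run guards against a
    single chance acceptance below the true transition, where the test
    has limited power on small matrices.

    Raises
    ------
    ValueError
        If no candidate passes, with an instruction to extend the grid; a
        spectrum too degenerate to test (e.g. the identity matrix) counts
        as not passing.
    """
    rho = corr.rho if isinstance(corr, CorrelationResult) else corr
    matrix = np.asarray(rho, dtype=float).copy()
    matrix[np.isnan(matrix)] = 0.0
    np.fill_diagonal(matrix, 1.0)
    if grid is None:
        grid = np.round(np.arange(0.30, 0.951, 0.01), 2)
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any() or grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("grid must be ascending and lie within (0, 1)")
    rows = []
    for t in grid:
        truncated = np.where(np.abs(matrix) >= t, matrix, 0.0)
        np.fill_diagonal(truncated, 1.0)
        eigvals = np.linalg.eigvalsh(truncated)
        spacings = _unfolded_spacings(eigvals, poly_order)
        if spacings is None:
            rows.append((t, _n_distinct(eigvals), np.nan, np.nan, False))
            continue
        chi2, p = _poisson_chi2(spacings)
        rows.append((t, _n_distinct(eigvals), chi2, p, p > alpha))
    diagnostics = pd.DataFrame(
        rows, columns=["threshold", "n_distinct_eigvals", "chi2", "p", "poisson_consistent"]
    )
    ok = diagnostics["poisson_consistent"].to_numpy()
    selected = None
    run_length = min(n_consecutive, len(grid))
    for i in range(len(grid)):
        window = ok[i : i + run_length]
        if window.size == run_length and window.all():
            selected = float(grid[i])
            break
    if selected is None:
        raise ValueError(
            "no candidate threshold produced a Poisson-consistent spacing "
            "distribution; extend the grid or inspect the diagnostics table"
        )
    return selected, diagnostics


def _n_distinct(eigvals: np.ndarray) -> int:
    lam = np.sort(eigvals)
    scale = max(abs(lam[0]), abs(lam[-1]), 1.0)
    return int(1 + (np.diff(lam) > 1e-8 * scale).sum())


def build_network(
    corr: CorrelationResult,
    threshold: float,
    q_cut: float = 0.001,
    abundance: pd.Series | None = None,
) -> nx.Graph:
    """Build the signed co-occurrence graph from a correlation result.

    Edges connect taxon pairs with |rho| >= ``threshold`` and q <=
    ``q_cut``; each edge carries ``rho``, ``sign`` (+1/-1), ``weight`` =
    |rho| and ``q``.  Isolated nodes are retained and flagged.  ``abundance``
    (mean relative abundance per taxon) is attached as a node attribute
    when given.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    rho = corr.rho.to_numpy()
    q = corr.q.to_numpy()
    taxa = corr.taxa
    graph = nx.Graph(threshold=float(threshold), q_cut=float(q_cut))
    for i, taxon in enumerate(taxa):
        attrs = {}
        if abundance is not None:
            attrs["mean_abundance"] = float(abundance.get(taxon, np.nan))
        graph.add_node(taxon, **attrs)
    iu, ju = np.triu_indices(len(taxa), k=1)
    keep = (~np.isnan(rho[iu, ju])) & (np.abs(rho[iu, ju]) >= threshold) & (q[iu, ju] <= q_cut)
    for i, j in zip(iu[keep], ju[keep]):
        value = float(rho[i, j])
        graph.add_edge(
            taxa[i], taxa[j], rho=value, sign=1 if value > 0 else -1,
            weight=abs(value), q=float(q[i, j]),
        )
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree(node) == 0
    return graph


def detect_modules(graph: nx.Graph, seed: int = 0) -> ModulePartition:
    """Partition the network into modules by |rho|-weighted modularity.

    Louvain community detection on the absolute-correlation weights,
    seeded for determinism; isolated nodes are left out of the partition.
    Modules are ranked by node count (ties broken by smallest node
    identifier) and named Mod1..Modk.
    """
    connected = [n for n in graph.nodes if graph.degree(n) > 0]
    if not connected:
        raise ValueError("cannot detect modules on an edgeless network")
    sub = graph.subgraph(connected)
    communities = nx.community.louvain_communities(sub, weight="weight", seed=seed)
    q_value = nx.community.modularity(sub, communities, weight="weight")
    ranked = sorted(communities, key=lambda c: (-len(c), min(str(n) for n in c)))
    mapping = {}
    for k, members in enumerate(ranked, start=1):
        for node in sorted(members, key=str):
            mapping[node] = f"Mod{k}"
    module_of = pd.Series(mapping, name="module").loc[[n for n in graph.nodes if n in mapping]]
    return ModulePartition(module_of, float(q_value))


def module_abundance(partition: ModulePartition, table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance of each module (sum over member taxa)."""
    missing = set(partition.module_of.index) - set(table.index)
    if missing:
        raise ValueError(f"partition taxa absent from the table: {sorted(missing)[:5]}")
    member_rows = table.loc[partition.module_of.index]
    out = member_rows.groupby(partition.module_of).sum()
    order = [m for m in partition.modules if m in out.index]
    return out.loc[order]


def network_stats(graph: nx.Graph, partition: ModulePartition | None = None) -> dict:
    """Summary statistics used to compare networks between treatments."""
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    signs = [d["sign"] for _, _, d in graph.edges(data=True)]
    stats_out = {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "n_positive_edges": int(sum(1 for s in signs if s > 0)),
        "n_negative_edges": int(sum(1 for s in signs if s < 0)),
        "mean_degree": (2 * n_edges / n_nodes) if n_nodes else 0.0,
        "n_isolated": int(sum(1 for n in graph.nodes if graph.degree(n) == 0)),
    }
    if partition is not None:
        stats_out["n_modules"] = len(set(partition.module_of))
        stats_out["modularity"] = partition.modularity
    return stats_out
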