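"""Module-environment association, differential taxa, and Mantel tests.

Links the co-occurrence network's modules and functional guilds
(nitrifiers, denitrifiers, N-fixers, ammonia oxidizers) to environmental
covariates: a Pearson module-by-factor correlation table with
significance stars, per-OTU enrichment/depletion calls between two
treatments for Manhattan-style display, and simple/partial Mantel tests
between community and environmental distance matrices.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .community import to_relative_abundance
from .network import ModulePartition, fdr_adjust
from .ordination import bray_curtis


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    conditioning: str | None = None


def _stars(p: float) -> str:
    # boundary values get the weaker star: p == 0.05 is not starred
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def module_env_correlation(
    module_abund: pd.DataFrame, env: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Correlate per-sample module abundances with environmental factors.

    Parameters
    ----------
    module_abund : DataFrame
        Module x sample relative abundances (from
        :func:`nitronet.network.module_abundance`).
    env : DataFrame
        Sample x factor covariates.
    method : str
        ``"pearson"`` (default, used for the module heatmap) or
        ``"spearman"`` (used for factor-by-factor panels).

    Returns a tidy frame with one row per (module, factor): r, p, stars at
    p < 0.05 / < 0.01 / < 0.001.
    """
    shared = [s for s in module_abund.columns if s in env.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples between modules and environment")
    corr_fn = stats.pearsonr if method == "pearson" else stats.spearmanr
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for module in module_abund.index:
        x = module_abund.loc[module, shared].to_numpy(dtype=float)
        for factor in env.columns:
            y = env.loc[shared, factor].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = corr_fn(x[ok], y[ok])
            rows.append((module, factor, float(r), float(p), _stars(p) if np.isfinite(p) else ""))
    return pd.DataFrame(rows, columns=["module", "factor", "r", "p", "stars"])


def differential_otus(
    table: pd.DataFrame,
    group_a: list,
    group_b: list,
    taxa: list | None = None,
    alpha: float = 0.05,
    taxonomy: pd.DataFrame | None = None,
    partition: ModulePartition | None = None,
) -> pd.DataFrame:
    """Call taxa enriched or depleted in ``group_b`` relative to ``group_a``.

    With three replicates per treatment a rank test cannot reach q <= 0.05,
    so the default test is Welch's t on log-transformed relative abundance;
    a pseudo-fraction of half the smallest nonzero relative abundance is
    added before the log.  P-values are BH-adjusted across the tested taxa
    and a taxon is ``enriched`` (``depleted``) when q <= ``alpha`` and its
    mean in ``group_b`` is above (below) the mean in ``group_a``.

    The result carries ``neg_log10_p`` plus ``module`` and ``phylum``
    columns when a partition / taxonomy is supplied, ready for
    Manhattan-style plotting.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = table if taxa is None else table.loc[[t for t in table.index if t in set(taxa)]]
    a = sub[list(group_a)].to_numpy(dtype=float)
    b = sub[list(group_b)].to_numpy(dtype=float)
    nonzero = sub.to_numpy()[sub.to_numpy() > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1e-6
    log_a, log_b = np.log(a + pseudo), np.log(b + pseudo)
    _, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties in both groups
    q, signif = fdr_adjust(p, method="bh", q_cut=alpha)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    direction = np.where(~signif, "ns", np.where(mean_b > mean_a, "enriched", "depleted"))
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "p": p,
            "q": q,
            "neg_log10_p": -np.log10(np.maximum(p, np.finfo(float).tiny)),
            "status": direction,
        },
        index=sub.index,
    )
    if partition is not None:
        out["module"] = partition.module_of.reindex(out.index)
    if taxonomy is not None and "phylum" in taxonomy.columns:
        out["phylum"] = taxonomy.reindex(out.index)["phylum"]
    return out


def _offdiag(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def _align(*dms: DistanceMatrix) -> list[np.ndarray]:
    ids = list(dms[0].ids)
    for dm in dms[1:]:
        if set(dm.ids) != set(ids):
            raise ValueError("distance matrices must share the same samples")
    return [dm.filter(ids).data for dm in dms]


def mantel(
    d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 9999, seed: int = 0
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the vectorized off-diagonal entries;
    the one-sided permutation p-value permutes rows and columns of ``d2``
    jointly and uses the +1 convention,
    p = (1 + #{permuted r >= observed}) / (1 + n_perm).
    """
    m1, m2 = _align(d1, d2)
    n = m1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    x, y = _offdiag(m1), _offdiag(m2)
    observed = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y_perm = _offdiag(m2[np.ix_(perm, perm)])
        if stats.pearsonr(x, y_perm)[0] >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(observed, p, n_perm)


def partial_mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    d_cond: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
) -> MantelResult:
    """Partial Mantel test of d1 vs d2 controlling for d_cond.

    The statistic is the Pearson correlation of the residuals of the
    vectorized d1 and d2 after regressing each on the vectorized
    conditioning matrix; the permutation scheme permutes d2 and recomputes
    the partial statistic (+1 convention, one-sided).
    """
    m1, m2, mc = _align(d1, d2, d_cond)
    n = m1.shape[0]
    if n < 4:
        raise ValueError("partial Mantel test needs >= 4 samples")
    x, z = _offdiag(m1), _offdiag(mc)
    design = np.column_stack([z, np.ones_like(z)])

    def residualize(v: np.ndarray) -> np.ndarray:
        coef, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ coef

    x_res = residualize(x)

    def partial_r(y: np.ndarray) -> float:
        y_res = residualize(y)
        # a conditioner explaining either matrix completely leaves nothing
        # to correlate: partial r is 0 by convention
        if x_res.std() <= 1e-10 * max(x.std(), 1e-30) or y_res.std() <= 1e-10 * max(
            y.std(), 1e-30
        ):
            return 0.0
        return float(stats.pearsonr(x_res, y_res)[0])

    observed = partial_r(_offdiag(m2))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if partial_r(_offdiag(m2[np.ix_(perm, perm)])) >= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(observed, p, n_perm, conditioning="d_cond")


def guild_distances(
    table: pd.DataFrame,
    taxonomy: pd.DataFrame,
    guild_map: pd.Series,
    guild: str,
) -> DistanceMatrix:
    """Bray-Curtis distances on the sub-community of one functional guild.

    ``guild_map`` maps genus names to guild labels (e.g. ``nitrifier``,
    ``denitrifier``, ``N-fixer``, ``ammonia-oxidizer``); taxa whose genus
    belongs to ``guild`` form the sub-community.
    """
    genera = set(guild_map.index[guild_map == guild])
    if not genera:
        raise ValueError(f"guild {guild!r} has no genera in the guild map")
    taxon_genus = taxonomy.reindex(table.index)["genus"]
    members = table.index[taxon_genus.isin(genera)]
    if len(members) == 0:
        raise ValueError(f"guild {guild!r} is absent from the data")
    sub = table.loc[members]
    keep = sub.sum(axis=0) > 0
    return bray_curtis(sub.loc[:, keep])


def env_factor_distance(env: pd.DataFrame, factor: str) -> DistanceMatrix:
    """Euclidean distance between samples on one z-standardized factor."""
    if factor not in env.columns:
        raise ValueError(f"unknown factor {factor!r}")
    values = env[factor].dropna()
    if len(values) < 2:
        raise ValueError("need >= 2 non-missing samples")
    x = values.to_numpy(dtype=float)
    sd = x.std()  # population SD: two samples at 0 and 2 standardize to -/+1
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    d = np.abs(z[:, None] - z[None, :])
    return DistanceMatrix(d, ids=list(values.index))


def day_distance(metadata: pd.DataFrame, day_column: str = "day") -> DistanceMatrix:
    """|day_i - day_j| matrix, the default conditioning matrix for partial
    Mantel tests in a time-course incubation (there is no geography to
    correct for)."""
    days = metadata[day_column].to_numpy(dtype=float)
    d = np.abs(days[:, None] - days[None, :])
    return DistanceMatrix(d, ids=list(metadata.index))
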