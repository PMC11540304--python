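"""Pseudobulk RNA differential expression and ADT differential testing.

RNA DE follows the pseudobulk design: cells of each group are randomly
partitioned into a small number of replicates whose counts are summed, then
a self-contained negative-binomial Wald test is run per gene on size-factor
normalized replicate counts (median-of-ratios size factors, method-of-moments
dispersion, log-scale delta-method standard errors), with Benjamini-Hochberg
adjustment. Significance uses adjusted p < 0.01 and |log2FC| > 1;
mitochondrial/ribosomal genes and genes with total count below 10 are
excluded before testing.

ADT differences are tested per antibody on CLR-normalized values with a
two-sided Mann-Whitney U test, Bonferroni correction, and the significance
rule p < 0.05 and |log2FC| > 1 on the antilog (linear) scale.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._norm import to_dense

log = logging.getLogger(__name__)

MIN_CLUSTER_CELLS = 25     # minimum cells for primitive-cell DE comparisons
DISPERSION_FLOOR = 1e-8
DEFAULT_EXCLUDE_PREFIXES = ("MT-", "RPS", "RPL")
EXACT_MW_MAX_N = 8


def pseudobulk_replicates(counts, cells, n_reps: int = 3,
                          seed: int = 0) -> pd.DataFrame:
    """Sum counts over a random near-equal partition of ``cells``.

    ``counts`` is an AnnData; ``cells`` selects the group (ids or boolean
    mask). Returns a replicates x genes table; the partition is seeded.
    """
    if isinstance(cells, (np.ndarray, list)) and len(cells) == counts.n_obs and (
        np.asarray(cells).dtype == bool
    ):
        ids = counts.obs_names[np.asarray(cells)]
    else:
        ids = pd.Index(cells)
    if len(ids) < n_reps:
        raise ValueError(
            f"group has {len(ids)} cells, fewer than n_reps={n_reps}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    assignment = np.array_split(perm, n_reps)
    X = to_dense(counts[ids].X)
    rows = [X[idx].sum(axis=0) for idx in assignment]
    return pd.DataFrame(
        rows,
        index=[f"rep{i + 1}" for i in range(n_reps)],
        columns=counts.var_names,
    )


def _size_factors(table: np.ndarray) -> np.ndarray:
    """DESeq-style median-of-ratios size factors across replicates."""
    with np.errstate(divide="ignore"):
        log_geo = np.log(table).mean(axis=0)
    usable = np.isfinite(log_geo)
    if not usable.any():
        return np.ones(table.shape[0])
    ratios = np.log(table[:, usable]) - log_geo[usable]
    return np.exp(np.median(ratios, axis=1))


def _moment_dispersion(norm: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Pooled method-of-moments NB dispersion per gene, floored."""
    num = np.zeros(norm.shape[1])
    den = np.zeros(norm.shape[1])
    for g in np.unique(groups):
        sub = norm[groups == g]
        if sub.shape[0] < 2:
            continue
        m = sub.mean(axis=0)
        v = sub.var(axis=0, ddof=1)
        num += v - m
        den += m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / den, 0.0)
    return np.maximum(phi, DISPERSION_FLOOR)


def de_test(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    padj_cut: float = 0.01,
    lfc_cut: float = 1.0,
    min_total: int = 10,
    exclude_prefixes: tuple[str, ...] = DEFAULT_EXCLUDE_PREFIXES,
) -> pd.DataFrame:
    """NB Wald test per gene between two replicate tables (a vs b).

    log2FC is group a over group b. Returns a table with columns log2fc,
    mean_a, mean_b, pvalue, padj, significant; excluded genes (name prefix
    or total count below ``min_total``) are absent from the table.
    """
    if group_a.shape[0] < 2 or group_b.shape[0] < 2:
        raise ValueError("need at least 2 replicates per group")
    if not group_a.columns.equals(group_b.columns):
        raise ValueError("replicate tables must share the same genes")
    genes = group_a.columns
    keep = ~genes.str.startswith(exclude_prefixes)
    totals = group_a.sum(axis=0).to_numpy() + group_b.sum(axis=0).to_numpy()
    keep &= totals >= min_total
    if not keep.any():
        log.warning("de_test: all genes excluded")
        return pd.DataFrame(
            columns=["log2fc", "mean_a", "mean_b", "pvalue", "padj", "significant"]
        )
    table = np.vstack([group_a.to_numpy(float), group_b.to_numpy(float)])[:, keep]
    groups = np.array([0] * group_a.shape[0] + [1] * group_b.shape[0])
    sf = _size_factors(table)
    norm = table / sf[:, None]

    phi = _moment_dispersion(norm, groups)
    a, b = norm[groups == 0], norm[groups == 1]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    pseudo = 0.5
    log2fc = np.log2((ma + pseudo) / (mb + pseudo))
    # delta-method SE of log mean difference under NB variance m + phi m^2
    var_a = (ma + phi * ma**2) / (na * np.maximum(ma, pseudo) ** 2)
    var_b = (mb + phi * mb**2) / (nb * np.maximum(mb, pseudo) ** 2)
    se = np.sqrt(var_a + var_b)
    z = np.log((ma + pseudo) / (mb + pseudo)) / np.maximum(se, 1e-12)
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    padj = benjamini_hochberg(pvalue)

    result = pd.DataFrame(
        {
            "log2fc": log2fc,
            "mean_a": ma,
            "mean_b": mb,
            "pvalue": pvalue,
            "padj": padj,
        },
        index=genes[keep],
    )
    result["significant"] = (result.padj < padj_cut) & (result.log2fc.abs() > lfc_cut)
    return result


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def significant_sets(result: pd.DataFrame) -> tuple[set[str], set[str]]:
    """(up, down) significant gene sets of one DE result."""
    sig = result[result.significant]
    return (
        set(sig.index[sig.log2fc > 0]),
        set(sig.index[sig.log2fc < 0]),
    )


def cluster_specific_genes(
    results: dict[str, pd.DataFrame],
) -> dict[str, dict[str, set[str]]]:
    """Per cluster, the significant up/down genes unique to its comparison
    (not significant in any other cluster's comparison, either direction)."""
    if len(results) < 2:
        raise ValueError("need results for at least 2 clusters")
    sets = {c: significant_sets(r) for c, r in results.items()}
    out: dict[str, dict[str, set[str]]] = {}
    for c, (up, down) in sets.items():
        others: set[str] = set()
        for c2, (up2, down2) in sets.items():
            if c2 != c:
                others |= up2 | down2
        out[c] = {"up": up - others, "down": down - others}
    return out


def pan_signature(
    results: dict[str, pd.DataFrame],
    required_clusters: list[str] | None = None,
) -> dict[str, set[str]]:
    """Genes significantly up (resp. down) in every required cluster."""
    required = list(required_clusters) if required_clusters is not None \
        else list(results)
    missing = [c for c in required if c not in results]
    if missing:
        raise ValueError(f"missing DE results for clusters: {missing}")
    ups, downs = zip(*(significant_sets(results[c]) for c in required))
    return {
        "up": set.intersection(*ups) if ups else set(),
        "down": set.intersection(*downs) if downs else set(),
    }


def clr_normalize(adt) -> pd.DataFrame:
    """Per-cell centered log-ratio: log(x+1) minus the cell's mean log(x+1)."""
    if adt.n_vars < 1:
        raise ValueError("no antibodies in matrix")
    logx = np.log(to_dense(adt.X) + 1.0)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=adt.obs_names, columns=adt.var_names)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, normal
    approximation with tie correction otherwise. Returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_N
                         and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_enumerated(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of labelings.

    Brute force over all C(n+m, n) assignments of the pooled values;
    intended for verification on small samples only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    mu = n * m / 2.0
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return float(u_obs), count / total


def adt_differential(
    adt,
    group_pos,
    group_neg,
    p_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Per-antibody differential test between two cell groups.

    Values are CLR-normalized; log2FC is the log2 ratio of group means on
    the antilog (linear, exp(CLR)) scale; p-values are two-sided
    Mann-Whitney with Bonferroni correction over the tested antibodies.
    Significant iff adjusted p < ``p_cut`` and |log2FC| > ``lfc_cut``.
    """
    pos = pd.Index(group_pos)
    neg = pd.Index(group_neg)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    clr = clr_normalize(adt)
    a = clr.loc[pos]
    b = clr.loc[neg]
    rows = []
    m = clr.shape[1]
    for ab in clr.columns:
        lin_a = np.exp(a[ab]).mean()
        lin_b = np.exp(b[ab]).mean()
        log2fc = float(np.log2(lin_a / lin_b))
        if len(pos) < 2 or len(neg) < 2:
            log.warning("adt_differential: group of size 1, p set to 1")
            u, p = np.nan, 1.0
        else:
            u, p = mann_whitney(a[ab], b[ab])
        rows.append((ab, log2fc, u, p))
    result = pd.DataFrame(
        rows, columns=["antibody", "log2fc", "u_statistic", "pvalue"]
    ).set_index("antibody")
    result["padj"] = np.minimum(result.pvalue * m, 1.0)
    result["significant"] = (result.padj < p_cut) & (result.log2fc.abs() > lfc_cut)
    return result
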