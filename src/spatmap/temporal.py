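"""Temporal core-proteome statistics.

The differentiation time-course workflow: log2 transform, valid-value
filtering, per-sample width adjustment (robust z), left-censored Gaussian
imputation (downshift 1.8 SD, width 0.3 SD), one-way ANOVA with a pooled
permutation null and FDR-style q-values, z-scored temporal profiles,
conserved-trajectory calling across cell models, tenfold-change classes,
supervised hierarchical clustering, and histone-based absolute copy numbers
(the proteomic ruler).

Intensity matrices are DataFrames (proteins x samples). Statistics operate
on log2 scale; copy numbers and fold-change classes operate on linear scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .tables import ProteinGroupTable

AVOGADRO = 6.02214076e23


# ---------------------------------------------------------------------------
# filtering / adjustment / imputation


def filter_valid(
    df: pd.DataFrame, groups: pd.Series, min_valid: int = 2, mode: str = "any-group"
) -> pd.DataFrame:
    """Keep proteins with at least ``min_valid`` observed values per group.

    ``mode='any-group'`` requires the count in at least one group (the
    standard pre-test filter); ``mode='per-group'`` requires it in every
    group (the stricter copy-number filter).
    """
    if mode not in ("any-group", "per-group"):
        raise ValueError("mode must be 'any-group' or 'per-group'")
    sizes = groups.value_counts()
    if min_valid > sizes.min():
        raise ValueError(
            f"min_valid={min_valid} exceeds the smallest group size ({sizes.min()})"
        )
    counts = pd.DataFrame(
        {g: df[groups.index[groups == g]].notna().sum(axis=1) for g in sizes.index}
    )
    keep = counts.ge(min_valid).any(axis=1) if mode == "any-group" else counts.ge(min_valid).all(axis=1)
    return df.loc[keep]


def width_adjust(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample robust standardization: x' = (x - median) / (IQR / 1.349).

    1.349 is the IQR of the standard normal, so the divisor is a robust SD
    estimate. Missing values are untouched. Idempotent: a second pass maps
    the data to itself (median 0, IQR 1.349 after the first pass).
    """
    out = {}
    for col in df.columns:
        x = df[col].to_numpy(dtype=float)
        obs = x[np.isfinite(x)]
        if obs.size < 10:
            raise ValueError(f"sample {col!r} has fewer than 10 observed values")
        med = np.median(obs)
        iqr = np.percentile(obs, 75) - np.percentile(obs, 25)
        if iqr == 0:
            raise ValueError(f"sample {col!r} has zero IQR; cannot width-adjust")
        out[col] = (x - med) / (iqr / 1.349)
    return pd.DataFrame(out, index=df.index)[df.columns]


def impute_gaussian(
    df: pd.DataFrame, downshift: float = 1.8, width: float = 0.3, seed: int = 0
) -> pd.DataFrame:
    """Left-censored imputation from a downshifted normal, per sample.

    Each missing value in a sample with observed mean m and SD s is drawn
    i.i.d. from Normal(m - downshift*s, (width*s)^2). Observed values are
    untouched; the draw order is fixed (column-major) so a given seed
    reproduces the imputation exactly.
    """
    rng = np.random.default_rng(seed)
    out = df.copy()
    for col in df.columns:
        x = out[col].to_numpy(dtype=float)
        obs = x[np.isfinite(x)]
        if obs.size < 3:
            raise ValueError(f"sample {col!r} has fewer than 3 observed values")
        m, s = obs.mean(), obs.std(ddof=1)
        miss = ~np.isfinite(x)
        if miss.any():
            x[miss] = rng.normal(m - downshift * s, width * s, size=miss.sum())
        out[col] = x
    return out


# ---------------------------------------------------------------------------
# permutation-FDR tests


@dataclass
class DifferentialResult:
    """Per-protein statistics with permutation-based q-values."""

    table: pd.DataFrame  # columns: statistic, q, significant, n_groups
    n_permutations: int
    fdr: float

    @property
    def significant_ids(self) -> pd.Index:
        return self.table.index[self.table["significant"]]


def _anova_f(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F across rows; degenerate rows get F = 0."""
    glabels = np.unique(groups)
    n = X.shape[1]
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in glabels:
        sel = groups == g
        gm = X[:, sel].mean(axis=1, keepdims=True)
        ssb += sel.sum() * (gm - grand).ravel() ** 2
        ssw += ((X[:, sel] - gm) ** 2).sum(axis=1)
    df1 = len(glabels) - 1
    df2 = n - len(glabels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F[~np.isfinite(F)] = np.where(ssb[~np.isfinite(F)] > 0, np.inf, 0.0)
    F[(ssb == 0) & (ssw == 0)] = 0.0
    return F


def _pooled_q(stat_obs: np.ndarray, stat_perm: np.ndarray) -> np.ndarray:
    """FDR-style q-values from a pooled permutation null.

    q(s) = (mean over permutations of #{null > s}) / #{observed >= s},
    clipped to [0, 1] and monotonized so q is non-increasing in the statistic.
    The numerator is strict: permutations that merely recreate the observed
    grouping reproduce the observed statistic exactly and carry no evidence
    against it.
    """
    n_perm = stat_perm.shape[0]
    pool = np.sort(stat_perm.ravel())
    obs_sorted = np.sort(stat_obs)
    n = len(stat_obs)
    # relative epsilon absorbs float jitter between relabeled but identical
    # groupings, which would otherwise count as exceedances
    thresh = stat_obs * (1 + 1e-9) + 1e-12
    exp_false = (len(pool) - np.searchsorted(pool, thresh, side="right")) / n_perm
    n_called = n - np.searchsorted(obs_sorted, stat_obs, side="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        q = exp_false / n_called
    q = np.clip(q, 0.0, 1.0)
    # monotonize: walking down from the largest statistic, q never decreases
    order = np.argsort(-stat_obs, kind="stable")
    q_sorted = np.maximum.accumulate(q[order])
    out = np.empty_like(q)
    out[order] = q_sorted
    return out


def permutation_anova(
    df: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 250,
    fdr: float = 0.01,
    seed: int = 0,
) -> DifferentialResult:
    """One-way ANOVA with a pooled label-permutation null.

    The null distribution of F is pooled across proteins (stable at small
    group sizes); significance is q < fdr. The complete-data requirement
    means imputation runs first. Constant proteins get F = 0, q = 1.
    """
    groups = groups.loc[df.columns]
    glabels = groups.unique()
    if len(glabels) < 2:
        raise ValueError("need at least 2 groups")
    if groups.value_counts().min() < 2:
        raise ValueError("every group needs at least 2 members")
    if n_permutations < 25:
        warnings.warn("fewer than 25 permutations gives unstable q-values", UserWarning, stacklevel=2)
    from math import factorial

    n_distinct = factorial(len(groups))
    for c in groups.value_counts():
        n_distinct //= factorial(c)
    if n_distinct < n_permutations:
        warnings.warn(
            f"only {n_distinct} distinct group-label permutations exist; "
            f"q-values use {n_permutations} redundant draws",
            UserWarning,
            stacklevel=2,
        )
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("permutation_anova requires a complete (imputed) matrix")
    g = groups.to_numpy()
    F_obs = _anova_f(X, g)
    rng = np.random.default_rng(seed)
    F_perm = np.empty((n_permutations, X.shape[0]))
    for b in range(n_permutations):
        F_perm[b] = _anova_f(X, rng.permutation(g))
    q = _pooled_q(F_obs, F_perm)
    q[F_obs == 0] = 1.0
    table = pd.DataFrame(
        {"statistic": F_obs, "q": q, "significant": q < fdr, "n_groups": len(glabels)},
        index=df.index,
    )
    return DifferentialResult(table, n_permutations, fdr)


def _t_unpaired(X: np.ndarray, mask1: np.ndarray) -> np.ndarray:
    x1, x2 = X[:, mask1], X[:, ~mask1]
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp * (1 / n1 + 1 / n2))
    t[~np.isfinite(t)] = 0.0
    return t


def two_group_test(
    df: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 250,
    fdr: float = 0.01,
    paired: bool = False,
    seed: int = 0,
) -> DifferentialResult:
    """Two-sided Student's t-test with permutation FDR.

    Unpaired: group-label permutations. Paired: replicate-matched
    differences with sign-flip permutations (pairs are matched by the order
    of samples within each group — callers pass matched orderings).
    """
    groups = groups.loc[df.columns]
    glabels = list(pd.unique(groups))
    if len(glabels) != 2:
        raise ValueError("two_group_test requires exactly 2 groups")
    X = df.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("two_group_test requires a complete (imputed) matrix")
    rng = np.random.default_rng(seed)
    if paired:
        c1 = [c for c in df.columns if groups[c] == glabels[0]]
        c2 = [c for c in df.columns if groups[c] == glabels[1]]
        if len(c1) != len(c2):
            raise ValueError("paired test requires equally sized, matched groups")
        D = df[c1].to_numpy() - df[c2].to_numpy()
        n = D.shape[1]

        def tstat(d):
            sd = d.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = d.mean(axis=1) / (sd / np.sqrt(n))
            t[~np.isfinite(t)] = 0.0
            return t

        t_obs = tstat(D)
        t_perm = np.empty((n_permutations, D.shape[0]))
        for b in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=n)
            t_perm[b] = tstat(D * signs)
    else:
        mask1 = (groups == glabels[0]).to_numpy()
        t_obs = _t_unpaired(X, mask1)
        t_perm = np.empty((n_permutations, X.shape[0]))
        for b in range(n_permutations):
            t_perm[b] = _t_unpaired(X, rng.permutation(mask1))
    q = _pooled_q(np.abs(t_obs), np.abs(t_perm))
    q[t_obs == 0] = 1.0
    table = pd.DataFrame(
        {"statistic": t_obs, "q": q, "significant": q < fdr, "n_groups": 2}, index=df.index
    )
    return DifferentialResult(table, n_permutations, fdr)


# ---------------------------------------------------------------------------
# temporal profiles


def common_timepoints(meta: pd.DataFrame) -> list[float]:
    """Timepoints present in every cell model (others are excluded)."""
    sets = [
        set(meta.loc[meta["model"] == m, "timepoint_days"].dropna().unique())
        for m in meta["model"].unique()
    ]
    common = set.intersection(*sets)
    if len(common) < 2:
        raise ValueError("fewer than 2 timepoints shared across all models")
    return sorted(common)


def zscore_profiles(
    table: ProteinGroupTable, log2: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein, per-model z-scored temporal profiles.

    Replicate means per timepoint are taken on log2 scale, restricted to the
    timepoints common to all models, then z-scored across timepoints with
    the population-SD convention (keeps 3-point profiles well defined).
    Constant profiles get all-zero z-values and a degeneracy flag.

    Returns a DataFrame with MultiIndex rows (protein_id, model) and the
    common timepoints as columns, plus a boolean degenerate-profile flag.
    """
    meta = table.samples
    tps = common_timepoints(meta)
    vals = np.log2(table.intensities) if log2 else table.intensities
    rows, keys, degen = [], [], []
    for model in meta["model"].unique():
        means = pd.DataFrame(
            {
                t: vals[meta.index[(meta["model"] == model) & (meta["timepoint_days"] == t)]].mean(axis=1)
                for t in tps
            }
        )
        mu = means.mean(axis=1)
        sd = means.std(axis=1, ddof=0)
        z = means.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
        z[sd == 0] = 0.0
        for pid in z.index:
            keys.append((pid, model))
            degen.append(bool(sd[pid] == 0) or means.loc[pid].isna().any())
        rows.append(z)
    out = pd.concat(rows)
    out.index = pd.MultiIndex.from_tuples(keys, names=["protein_id", "model"])
    return out, pd.Series(degen, index=out.index, name="degenerate")


def conserved_trajectory(zprofiles: pd.DataFrame, degenerate: pd.Series | None = None) -> pd.Series:
    """True iff every pairwise cross-model Pearson correlation is > 0.

    Requires a profile in every model; degenerate (constant) profiles make a
    protein non-conserved.
    """
    models = zprofiles.index.get_level_values("model").unique()
    if len(models) < 2:
        raise ValueError("need profiles from at least 2 models")
    wide = {m: zprofiles.xs(m, level="model") for m in models}
    shared = wide[models[0]].index
    for m in models[1:]:
        shared = shared.intersection(wide[m].index)
    flags = {}
    mats = {m: wide[m].loc[shared].to_numpy() for m in models}
    bad = np.zeros(len(shared), dtype=bool)
    if degenerate is not None:
        for m in models:
            d = degenerate.xs(m, level="model").reindex(shared).fillna(True).to_numpy(dtype=bool)
            bad |= d
    n_t = next(iter(mats.values())).shape[1]
    ok = np.ones(len(shared), dtype=bool)
    for i, m1 in enumerate(models):
        for m2 in models[i + 1:]:
            a, b = mats[m1], mats[m2]
            ac = a - a.mean(axis=1, keepdims=True)
            bc = b - b.mean(axis=1, keepdims=True)
            denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
            with np.errstate(divide="ignore", invalid="ignore"):
                r = (ac * bc).sum(axis=1) / denom
            ok &= np.nan_to_num(r, nan=-1.0) > 0
    ok &= ~bad
    return pd.Series(ok, index=shared, name="conserved")


# ---------------------------------------------------------------------------
# fold-change classes


def fold_change_classes(
    df_linear: pd.DataFrame,
    groups: pd.Series,
    reference: str,
    comparison: str,
    threshold: float = 10.0,
    min_valid: int = 2,
) -> pd.Series:
    """Classify proteins by their change from the undifferentiated state.

    ``exclusive-undifferentiated`` / ``exclusive-mature``: quantified (>=
    min_valid observed values) in only one of the two states; otherwise the
    ratio of linear means is classified against the threshold
    (up>10x / down>10x / other at the default tenfold threshold).
    """
    ref_cols = groups.index[groups == reference]
    cmp_cols = groups.index[groups == comparison]
    if len(ref_cols) == 0 or len(cmp_cols) == 0:
        raise ValueError("reference and comparison conditions must both have samples")
    ref_valid = df_linear[ref_cols].notna().sum(axis=1) >= min_valid
    cmp_valid = df_linear[cmp_cols].notna().sum(axis=1) >= min_valid
    ref_mean = df_linear[ref_cols].mean(axis=1)
    cmp_mean = df_linear[cmp_cols].mean(axis=1)
    out = pd.Series("other", index=df_linear.index, name="fold_change_class")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cmp_mean / ref_mean
    out[ref_valid & cmp_valid & (ratio > threshold)] = "up>10x"
    out[ref_valid & cmp_valid & (ratio < 1.0 / threshold)] = "down>10x"
    out[ref_valid & ~cmp_valid] = "exclusive-undifferentiated"
    out[~ref_valid & cmp_valid] = "exclusive-mature"
    return out[ref_valid | cmp_valid]  # both-invalid proteins are skipped


# ---------------------------------------------------------------------------
# clustering


def hierarchical_cluster(
    matrix: pd.DataFrame, n_clusters: int, method: str = "average"
) -> tuple[pd.Series, np.ndarray]:
    """Agglomerative clustering (Euclidean distance) of profile rows.

    Returns cluster labels (1..n_clusters) and the linkage matrix for
    dendrogram cutting at other heights. Deterministic.
    """
    if n_clusters > len(matrix):
        raise ValueError("n_clusters exceeds the number of proteins")
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("clustering requires a complete matrix")
    Z = hierarchy.linkage(X, method=method, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster"), Z


def compose_model_blocks(zprofiles: pd.DataFrame, model_order: list[str] | None = None) -> pd.DataFrame:
    """Side-by-side per-model z-profile blocks (proteins x models*timepoints)."""
    models = model_order or list(zprofiles.index.get_level_values("model").unique())
    blocks = []
    shared = None
    for m in models:
        blk = zprofiles.xs(m, level="model")
        shared = blk.index if shared is None else shared.intersection(blk.index)
    for m in models:
        blk = zprofiles.xs(m, level="model").loc[shared]
        blk = blk.rename(columns=lambda t, m=m: f"{m}_d{t:g}")
        blocks.append(blk)
    return pd.concat(blocks, axis=1)


# ---------------------------------------------------------------------------
# proteomic ruler


def proteomic_ruler(
    table: ProteinGroupTable,
    histone_ids,
    dna_mass_per_cell_pg: float = 6.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histone-based absolute copy numbers per cell.

    The summed histone MS intensity is assumed proportional to the DNA mass
    in the sample, and hence to cell count; protein copy numbers follow

        copies_p = I_p * m_DNA * N_A / (sum_h I_h * M_p)

    with m_DNA the DNA mass per cell (grams) and M_p the molar mass (g/mol).
    Intensity units cancel, so the result is unit-independent. Returns the
    copies matrix and per-sample descending ranks (1 = most copies).
    Proteins without a molar mass are skipped.
    """
    if table.molar_mass_da is None:
        raise ValueError("molar masses are required for the proteomic ruler")
    histone_ids = [h for h in histone_ids]
    missing_h = [h for h in histone_ids if h not in table.protein_ids]
    if missing_h:
        raise ValueError(f"histones absent from table: {missing_h}")
    mass = table.molar_mass_da.reindex(table.protein_ids)
    scored = mass.index[mass.notna()]
    intens = table.intensities.loc[scored]
    hist_sum = table.intensities.loc[histone_ids].sum(axis=0, skipna=True)
    if (hist_sum <= 0).any():
        bad = list(hist_sum.index[hist_sum <= 0])
        raise ValueError(f"zero histone intensity sum in samples: {bad}")
    dna_g = dna_mass_per_cell_pg * 1e-12
    copies = intens.div(hist_sum, axis=1).mul(dna_g * AVOGADRO).div(mass.loc[scored], axis=0)
    ranks = copies.rank(axis=0, ascending=False, method="average")
    return copies, ranks


def ranked_copy_zscores(ranks: pd.DataFrame, proteins=None) -> pd.DataFrame:
    """z-score ranked copy numbers per protein across samples (for clustering)."""
    sub = ranks if proteins is None else ranks.loc[[p for p in proteins if p in ranks.index]]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    return sub.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
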