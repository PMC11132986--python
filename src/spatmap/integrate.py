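"""Spatial-temporal and cross-omics integrations.

Organelle proportions of the total proteome (first assignments weighted by
summed LFQ intensity), over-representation and one-dimensional annotation
enrichment, proteome-transcriptome correlation, and fixed/random-effects
meta-analysis of correlation coefficients across cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AnnotationTable, ProteinGroupTable


# ---------------------------------------------------------------------------
# organelle proportions


@dataclass
class OrganelleComposition:
    """Percentage of summed proteome intensity per compartment."""

    condition: str
    percentages: pd.Series  # index compartment, sums to 100
    excluded_mass_fraction: float  # intensity share of unassigned proteins

    def __post_init__(self) -> None:
        total = float(self.percentages.sum())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"percentages sum to {total}, not 100")


def organelle_proportions(
    assignments: pd.DataFrame,
    total: ProteinGroupTable,
    condition: str | None = None,
    aggregate: str = "replicate-mean",
) -> OrganelleComposition:
    """Share of total proteome mass per compartment.

    Each assigned protein contributes its replicate-mean linear intensity
    (or per-condition sum with ``aggregate='sum'``) to its *first* organelle;
    compartment totals are normalized to percent. Unassigned proteins are
    excluded and their intensity share reported.
    """
    meta = total.samples
    cols = meta.index if condition is None else meta.index[meta["condition"] == condition]
    if len(cols) == 0:
        raise ValueError(f"no samples for condition {condition!r}")
    if aggregate == "replicate-mean":
        per_protein = total.intensities[cols].mean(axis=1, skipna=True)
    elif aggregate == "sum":
        per_protein = total.intensities[cols].sum(axis=1, skipna=True)
    else:
        raise ValueError("aggregate must be 'replicate-mean' or 'sum'")
    per_protein = per_protein.fillna(0.0)

    amap = assignments.set_index("protein_id")["first_organelle"].replace("", np.nan).dropna()
    assigned = amap.index.intersection(per_protein.index)
    mass_assigned = per_protein.loc[assigned]
    total_assigned = float(mass_assigned.sum())
    if total_assigned <= 0:
        raise ValueError("zero assigned intensity mass")
    sums = mass_assigned.groupby(amap.loc[assigned]).sum()
    pct = sums / total_assigned * 100.0
    pct = pct / pct.sum() * 100.0  # exact renormalization against fp drift
    grand = float(per_protein.sum())
    excluded = 1.0 - total_assigned / grand if grand > 0 else 0.0
    return OrganelleComposition(condition or "all", pct.sort_index(), excluded)


# ---------------------------------------------------------------------------
# enrichment


def fisher_enrichment(
    foreground,
    background,
    annotations: AnnotationTable,
    min_fold: float = 2.0,
    fdr: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-sided (over-representation) Fisher's exact test per term.

    For each term: k members in the foreground out of n foreground proteins,
    against K of N in the background; p is the hypergeometric upper tail,
    fold enrichment is (k/n)/(K/N), q is Benjamini-Hochberg across tested
    terms. Returns (full table, table filtered by fold > min_fold and
    q < fdr).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of the background")
    n, N = len(fg), len(bg)
    rows = []
    for _, term in annotations.terms.iterrows():
        members = term["members"] & bg
        K = len(members)
        if K == 0:
            continue
        k = len(members & fg)
        fold = (k / n) / (K / N)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term["term_id"], term["term_name"], k, n, K, N, fold, p))
    full = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "fold_enrichment", "p"]
    )
    if len(full):
        full["q"] = multipletests(full["p"], method="fdr_bh")[1]
    else:
        full["q"] = []
    filtered = full[(full["fold_enrichment"] > min_fold) & (full["q"] < fdr)].reset_index(drop=True)
    return full, filtered


def one_d_enrichment(
    values: pd.Series,
    annotations: AnnotationTable,
    fdr: float = 0.1,
    min_size: int = 3,
) -> pd.DataFrame:
    """Rank-based one-dimensional annotation enrichment.

    Proteins are ranked by ``values`` (average ranks on ties); each term's
    score is

        s = 2 * (mean member rank - (N + 1)/2) / (N - n_members)

    with N the scored-set size, so s = +1 when all members occupy the top
    (highest-value) ranks, -1 at the bottom, and ~0 under exchangeability.
    p is the two-sided Wilcoxon rank-sum test of members vs non-members;
    q is Benjamini-Hochberg. Terms smaller than ``min_size`` within the
    scored set, or covering it entirely, are skipped.
    """
    values = values.dropna()
    if len(values) < 10:
        raise ValueError("need at least 10 scored proteins")
    N = len(values)
    ranks = pd.Series(stats.rankdata(values.to_numpy()), index=values.index)
    rows = []
    for _, term in annotations.terms.iterrows():
        members = [p for p in term["members"] if p in values.index]
        nm = len(members)
        if nm < min_size or nm == N:
            continue
        s = 2.0 * (ranks.loc[members].mean() - (N + 1) / 2.0) / (N - nm)
        non = values.index.difference(pd.Index(members))
        p = float(
            stats.mannwhitneyu(
                values.loc[members], values.loc[non], alternative="two-sided"
            ).pvalue
        )
        rows.append((term["term_id"], term["term_name"], nm, s, p))
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "n_members", "score", "p"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = []
    return out


# ---------------------------------------------------------------------------
# proteome-transcriptome correlation


def omics_correlation(
    proteome_log2: pd.DataFrame,
    transcriptome_log2: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Correlate matched proteome and transcriptome time courses.

    Both inputs are genes x timepoints on log2 scale; only shared genes and
    shared timepoints are used. Returns (per-timepoint Spearman rho across
    genes, per-gene Pearson r of the z-scored profiles across timepoints).
    Genes with fewer than 3 shared observed timepoints or a constant profile
    are skipped in the per-gene output.
    """
    genes = proteome_log2.index.intersection(transcriptome_log2.index)
    tps = [t for t in proteome_log2.columns if t in set(transcriptome_log2.columns)]
    if len(genes) == 0:
        raise ValueError("no shared gene/protein identifiers")
    if len(tps) == 0:
        raise ValueError("no shared timepoints")
    P = proteome_log2.loc[genes, tps]
    T = transcriptome_log2.loc[genes, tps]

    rho_t = pd.Series(
        {
            t: stats.spearmanr(P[t], T[t], nan_policy="omit").statistic
            for t in tps
        },
        name="spearman_rho",
    )

    r_gene = {}
    for g in genes:
        x, y = P.loc[g].to_numpy(float), T.loc[g].to_numpy(float)
        mask = np.isfinite(x) & np.isfinite(y)
        if mask.sum() < 3:
            continue
        xs, ys = x[mask], y[mask]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r_gene[g] = float(np.corrcoef(xs, ys)[0, 1])
    return rho_t, pd.Series(r_gene, name="pearson_r")


# ---------------------------------------------------------------------------
# meta-analysis of correlations


@dataclass
class MetaCorrelationResult:
    pooled_rho: float
    ci_low: float
    ci_high: float
    p: float
    per_cohort: pd.DataFrame  # r, n, weight
    model: str  # "fixed" | "random"
    tau2: float = 0.0


def meta_correlation(
    cohorts: list[tuple[float, int]], random_effects: bool = False
) -> MetaCorrelationResult:
    """Pool per-cohort correlations via the Fisher z transform.

    Each cohort's z = atanh(r) has sampling variance 1/(n - 3); the fixed-
    effect pooled estimate is the inverse-variance weighted mean, back-
    transformed with tanh, with a 95% normal CI and two-sided p. With
    ``random_effects`` the DerSimonian-Laird between-cohort variance tau^2
    is added to each cohort's variance.
    """
    rs = np.array([c[0] for c in cohorts], dtype=float)
    ns = np.array([c[1] for c in cohorts], dtype=float)
    if np.any(np.abs(rs) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    if np.any(ns < 4):
        raise ValueError("all cohorts need n >= 4")
    z = np.arctanh(rs)
    w = ns - 3.0
    tau2 = 0.0
    model = "fixed"
    if random_effects and len(rs) > 1:
        zbar = np.sum(w * z) / np.sum(w)
        Q = np.sum(w * (z - zbar) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (len(rs) - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (1.0 / w + tau2)
        model = "random"
    zp = np.sum(w * z) / np.sum(w)
    se = 1.0 / np.sqrt(np.sum(w))
    ci = (np.tanh(zp - 1.959963984540054 * se), np.tanh(zp + 1.959963984540054 * se))
    p = 2.0 * stats.norm.sf(abs(zp) / se)
    per = pd.DataFrame({"r": rs, "n": ns.astype(int), "weight": w})
    return MetaCorrelationResult(float(np.tanh(zp)), float(ci[0]), float(ci[1]), float(p), per, model, float(tau2))
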