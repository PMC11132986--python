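"""End-to-end orchestration: simulate -> PCP map -> temporal stats -> integrations.

Files are the only interface between stages; a JSON manifest records the
stage list, resolved configuration, per-stage seeds and output paths, and is
written both before and after execution. One global seed fans out to
per-stage seeds via a CRC32 hash of the stage name, so stages are
individually reproducible without seed collisions.

The ``check_*`` functions each recompute one parameter-recovery or
calibration property of the pipeline on freshly simulated data (α recovery,
marker accuracy, change calling, permutation-FDR control, conserved-
trajectory oracle agreement, ruler closed form, composition recovery,
enrichment exactness, meta-analysis coverage, imputation moments); the demo
runs all of them and writes the combined summary report.
"""

from __future__ import annotations

import itertools
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

from . import __version__
from .classify import (
    assign_map,
    call_localization_changes,
    change_summary,
    estimate_second_localization,
    marker_accuracy,
)
from .config import RunConfig
from .integrate import (
    fisher_enrichment,
    meta_correlation,
    omics_correlation,
    one_d_enrichment,
    organelle_proportions,
)
from .pcp import (
    concatenate_replicates,
    filter_reproducible,
    merge_replicates,
    organelle_median_profiles,
    protein_median_profiles,
    scale_profiles,
)
from .synthetic import (
    FractionationSimSpec,
    TemporalSimSpec,
    rescale_composition,
    simulate_cohorts,
    simulate_fractionation,
    simulate_temporal,
    simulate_transcriptome,
)
from .tables import AnnotationTable, ProteinGroupTable, write_assignments, write_markers, write_protein_table
from .temporal import (
    conserved_trajectory,
    filter_valid,
    fold_change_classes,
    hierarchical_cluster,
    impute_gaussian,
    permutation_anova,
    proteomic_ruler,
    width_adjust,
    zscore_profiles,
)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (documented, collision-safe)."""
    return (seed + zlib.crc32(stage.encode("utf-8"))) % (2**31)


# ---------------------------------------------------------------------------
# stage drivers


def build_pcp_map(tables, markers, config: RunConfig, estimate_second: bool = True):
    """Scaled profiles -> replicate filter -> features -> SVM (+ α) map."""
    pset = merge_replicates([scale_profiles(t, config.min_observed_fractions) for t in tables])
    pset = filter_reproducible(pset)
    features = concatenate_replicates(pset, missing_as_zero=config.missing_as_zero_in_features)
    org_medians = organelle_median_profiles(pset, markers)
    if config.exclude_compartments:
        org_medians = org_medians.drop(index=list(config.exclude_compartments), errors="ignore")
    medians = protein_median_profiles(pset)
    accuracy = marker_accuracy(features, markers, config)
    assignments = assign_map(features, medians, org_medians, markers, config, estimate_second)
    return {
        "profiles": pset,
        "features": features,
        "accuracy": accuracy,
        "organelle_medians": org_medians,
        "median_profiles": medians,
        "assignments": assignments,
    }


def run_temporal_stage(table: ProteinGroupTable, config: RunConfig, anova_model: str | None = None):
    """Filter, adjust, impute, test, profile and scale one temporal table."""
    meta = table.samples
    log2 = np.log2(table.intensities)
    groups = meta["condition"]
    filtered = filter_valid(log2, groups, config.min_valid, mode="any-group")
    adjusted = width_adjust(filtered)
    imputed = impute_gaussian(
        adjusted, config.imputation_downshift, config.imputation_width, seed=config.seed
    )
    model = anova_model or meta["model"].iloc[0]
    cols = meta.index[meta["model"] == model]
    anova = permutation_anova(
        imputed[cols],
        meta.loc[cols, "condition"],
        n_permutations=config.n_permutations,
        fdr=config.fdr,
        seed=config.seed,
    )
    zprof, degen = zscore_profiles(table)
    conserved = conserved_trajectory(zprof, degen)
    copies, ranks = proteomic_ruler(
        table,
        histone_ids=[p for p in table.protein_ids if p.startswith("HIST")],
        dna_mass_per_cell_pg=config.dna_mass_per_cell_pg,
    )
    return {
        "log2_filtered": filtered,
        "imputed": imputed,
        "anova": anova,
        "zprofiles": zprof,
        "degenerate": degen,
        "conserved": conserved,
        "copies": copies,
        "ranks": ranks,
        "anova_model": model,
    }


# ---------------------------------------------------------------------------
# parameter-recovery / calibration checks


def _alpha_recovery(noise_sd: float, seed: int, tol: float) -> float:
    """Fraction of 200 planted dual proteins with |α̂ - α*| within tol.

    Isolates the mixing estimator: the search starts from the true dominant
    compartment, as when auditing the α machinery against ground truth.
    """
    spec = FractionationSimSpec(seed=seed, noise_sd=noise_sd, n_single=0, n_dual=200)
    tables, markers, truth = simulate_fractionation(spec)
    pset = filter_reproducible(merge_replicates([scale_profiles(t) for t in tables]))
    org = organelle_median_profiles(pset, markers)
    med = protein_median_profiles(pset)
    hits = total = 0
    for pid in truth.index[truth["kind"] == "dual"]:
        if pid not in med.index:
            continue
        o1, o2, a = truth.loc[pid, ["organelle1", "organelle2", "true_alpha"]]
        second, ahat, _ = estimate_second_localization(med.loc[pid].to_numpy(), o1, org)
        total += 1
        if second == o2 and abs(ahat - a) <= tol:
            hits += 1
    return hits / total


def check_alpha_recovery(seed: int) -> dict:
    return {
        "noiseless_exact_rate": _alpha_recovery(0.0, seed, tol=0.025),
        "noisy_within_0p10_rate": _alpha_recovery(0.05, seed + 1, tol=0.10),
        "n_dual": 200,
    }


def check_marker_accuracy(seed: int) -> dict:
    """Mean 5-fold CV accuracy on 8 separable organelles, and the ~0.5
    accuracy symmetry of two compartments given identical archetypes."""
    spec = FractionationSimSpec(seed=seed, n_single=0, n_dual=0)
    tables, markers, _ = simulate_fractionation(spec)
    cfg = RunConfig(seed=seed)
    pset = filter_reproducible(merge_replicates([scale_profiles(t) for t in tables]))
    feats = concatenate_replicates(pset)
    report = marker_accuracy(feats, markers, cfg)

    # same 8-organelle layout but Lysosome shares the Endosome archetype; the
    # per-compartment accuracy of the pair is a coin flip in expectation, so
    # it is averaged over independent simulations to beat binomial noise
    confusable = tuple(
        (label, 13.0, 1.5) if label in ("Endosome", "Lysosome") else (label, c, w)
        for label, c, w in spec.organelles
    )
    acc_e, acc_l = [], []
    for rep_i in range(5):
        spec2 = FractionationSimSpec(seed=seed + 1 + rep_i, organelles=confusable, n_single=0, n_dual=0)
        t2, m2, _ = simulate_fractionation(spec2)
        pset2 = filter_reproducible(merge_replicates([scale_profiles(t) for t in t2]))
        rep2 = marker_accuracy(concatenate_replicates(pset2), m2, RunConfig(seed=seed + 1 + rep_i))
        acc_e.append(float(rep2.per_compartment["Endosome"]))
        acc_l.append(float(rep2.per_compartment["Lysosome"]))
    return {
        "mean_cv_accuracy": report.mean_accuracy,
        "per_compartment_min": float(report.per_compartment.min()),
        "identical_archetype_accuracies": [float(np.mean(acc_e)), float(np.mean(acc_l))],
    }


def check_localization_changes(seed: int, n_planted: int = 25) -> dict:
    """Zero-noise two-state comparison among 2,000 proteins, 25 relocations."""
    spec = FractionationSimSpec(seed=seed, noise_sd=0.0, n_single=1480, n_dual=200)
    tables_a, markers, truth = simulate_fractionation(spec)
    rng = np.random.default_rng(seed)
    labels = [o[0] for o in spec.organelles]
    singles = truth.index[truth["kind"] == "single"]
    moved = rng.choice(singles, size=n_planted, replace=False)
    reassign = {
        pid: labels[(labels.index(truth.loc[pid, "organelle1"]) + 1) % len(labels)] for pid in moved
    }
    tables_b, _, _ = simulate_fractionation(spec, reassign=reassign)
    cfg = RunConfig(seed=seed)
    res_a = build_pcp_map(tables_a, markers, cfg, estimate_second=False)
    res_b = build_pcp_map(tables_b, markers, cfg, estimate_second=False)
    changes = call_localization_changes(res_a["assignments"], res_b["assignments"])
    called = set(changes.loc[changes["high_confidence_change"], "protein_id"])
    return {
        "n_proteins": int(len(changes)),
        "planted": int(n_planted),
        "high_confidence_changes": int(len(called)),
        "recovered": int(len(called & set(moved))),
        "false_positives": int(len(called - set(moved))),
    }


def check_null_fdr(seed: int, n_seeds: int = 10) -> dict:
    """Fraction called significant at q < 0.01 under a global-null simulation."""
    fracs = []
    for s in range(n_seeds):
        spec = TemporalSimSpec(
            n_models=1,
            timepoints_days=(0.0, 1.0, 2.0, 3.0),
            n_replicates=3,
            archetypes=[("flat", np.zeros(4), 1000)],
            frac_nonconserved=0.0,
            mnar_quantile=0.0,
            n_histones=1,
            seed=seed + s,
        )
        table, _ = simulate_temporal(spec)
        df = np.log2(table.intensities.drop(index=["HIST_0"]))
        res = permutation_anova(
            df, table.samples["condition"], n_permutations=250, fdr=0.01, seed=seed + s
        )
        fracs.append(res.table["significant"].mean())
    return {"mean_fraction_significant": float(np.mean(fracs)), "n_seeds": n_seeds}


def check_conserved_oracle(seed: int, n_proteins: int = 1000, n_models: int = 4) -> dict:
    """Exact agreement of conserved-trajectory calls with a brute-force oracle."""
    rng = np.random.default_rng(seed)
    tps = [0.0, 1.0, 2.0, 4.0, 8.0, 12.0]
    pids = [f"P{i:04d}" for i in range(n_proteins)]
    models = [f"M{j+1}" for j in range(n_models)]
    frames, keys = [], []
    raw = {}
    for m in models:
        X = rng.standard_normal((n_proteins, len(tps)))
        raw[m] = X
        z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        frames.append(pd.DataFrame(z, columns=tps))
        keys.extend((p, m) for p in pids)
    zdf = pd.concat(frames)
    zdf.index = pd.MultiIndex.from_tuples(keys, names=["protein_id", "model"])
    called = conserved_trajectory(zdf)

    agree = 0
    for i, pid in enumerate(pids):
        expect = all(
            stats.pearsonr(raw[m1][i], raw[m2][i]).statistic > 0
            for m1, m2 in itertools.combinations(models, 2)
        )
        agree += int(expect == bool(called[pid]))
    return {"agreement": agree / n_proteins, "n_proteins": n_proteins}


def check_ruler() -> dict:
    """Closed-form single-histone example plus the two scale invariances."""
    meta = pd.DataFrame(
        {
            "model": "M1",
            "timepoint_days": 0.0,
            "replicate": 1,
            "condition": "d0",
            "fraction_index": np.nan,
        },
        index=pd.Index(["s1"], name="sample_id"),
    )

    def make(hist_i, prot_i):
        intens = pd.DataFrame(
            {"s1": [hist_i, prot_i]}, index=pd.Index(["HIST_0", "P1"], name="protein_id")
        )
        return ProteinGroupTable(
            intens, meta, molar_mass_da=pd.Series([15000.0, 15000.0], index=intens.index)
        )

    copies, _ = proteomic_ruler(make(1e9, 1e9), ["HIST_0"], dna_mass_per_cell_pg=6.5)
    value = float(copies.loc["P1", "s1"])
    expected = 6.5e-12 * 6.02214076e23 / 15000.0
    copies2, _ = proteomic_ruler(make(2e9, 2e9), ["HIST_0"], dna_mass_per_cell_pg=6.5)
    copies3, _ = proteomic_ruler(make(0.5e9, 1e9), ["HIST_0"], dna_mass_per_cell_pg=6.5)
    return {
        "copies_single_histone": value,
        "closed_form_rel_error": abs(value - expected) / expected,
        "doubling_invariance_error": abs(float(copies2.loc["P1", "s1"]) - value) / value,
        "histone_halving_ratio": float(copies3.loc["P1", "s1"]) / value,
    }


def check_proportions(seed: int) -> dict:
    """Recovery of a planted 40/30/20/10 organelle composition."""
    organelles = (
        ("LipidDroplet", 2.0, 1.5),
        ("ER", 9.0, 1.8),
        ("Mitochondrion", 16.0, 1.8),
        ("Cytosol", 22.0, 2.0),
    )
    targets = {"LipidDroplet": 40.0, "ER": 30.0, "Mitochondrion": 20.0, "Cytosol": 10.0}
    spec = FractionationSimSpec(seed=seed, organelles=organelles, n_single=400, n_dual=0)
    tables, markers, truth = simulate_fractionation(spec)
    tables = rescale_composition(tables, truth, targets)
    cfg = RunConfig(seed=seed)
    res = build_pcp_map(tables, markers, cfg, estimate_second=False)
    comp = organelle_proportions(res["assignments"], tables[0])
    err = {o: abs(float(comp.percentages.get(o, 0.0)) - t) for o, t in targets.items()}
    return {
        "percent_sum": float(comp.percentages.sum()),
        "max_abs_error_points": max(err.values()),
        "recovered": {o: float(comp.percentages.get(o, 0.0)) for o in targets},
    }


def _hypergeom_tail_oracle(N: int, K: int, n: int, ks: np.ndarray) -> np.ndarray:
    """Brute-force upper tail: sum of binomial-product terms over j >= k."""
    j = np.arange(0, min(n, K) + 1)
    pmf = special.comb(K, j) * special.comb(N - K, n - j) / special.comb(N, n)
    tail = np.cumsum(pmf[::-1])[::-1]
    tail = np.append(tail, 0.0)
    ks = np.clip(ks, 0, len(tail) - 1)
    return tail[ks]


def check_fisher_exactness(n_max: int = 50, n_api: int = 25) -> dict:
    """Compare enrichment p-values with exhaustive tail sums for all N <= n_max.

    Tables with N <= n_api are built as real foreground/background/term sets
    and run through ``fisher_enrichment``; the remaining sizes check the same
    upper-tail expression vectorized (the API loop adds nothing but time).
    """
    worst = 0.0
    count = 0
    for N in range(2, n_api + 1):
        bg = [f"P{i}" for i in range(N)]
        for n in range(1, N + 1):
            fg = bg[:n]
            terms, expected = [], []
            for K in range(1, N + 1):
                for k in range(max(0, K + n - N), min(n, K) + 1):
                    members = frozenset(bg[:k] + bg[n : n + K - k])
                    terms.append((f"T_{K}_{k}", members))
                    expected.append(_hypergeom_tail_oracle(N, K, n, np.array([k]))[0])
            annot = AnnotationTable(
                pd.DataFrame(
                    {
                        "term_id": [t[0] for t in terms],
                        "term_name": [t[0] for t in terms],
                        "members": [t[1] for t in terms],
                    }
                )
            )
            full, _ = fisher_enrichment(fg, bg, annot)
            worst = max(worst, float(np.max(np.abs(full["p"].to_numpy() - np.array(expected)))))
            count += len(terms)
    for N in range(n_api + 1, n_max + 1):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                ks = np.arange(0, min(n, K) + 1)
                p_impl = stats.hypergeom.sf(ks - 1, N, K, n)
                p_oracle = _hypergeom_tail_oracle(N, K, n, ks)
                worst = max(worst, float(np.max(np.abs(p_impl - p_oracle))))
                count += len(ks)
    return {"max_abs_p_difference": worst, "n_tables": count}


def check_one_d_enrichment(seed: int, n_null: int = 1000) -> dict:
    """Extreme-ranking scores and null calibration of the 1D enrichment score."""
    n, k = 200, 20
    pids = [f"P{i}" for i in range(n)]
    values = pd.Series(np.arange(n, dtype=float), index=pids)
    top = AnnotationTable(
        pd.DataFrame({"term_id": ["top"], "term_name": ["top"], "members": [frozenset(pids[-k:])]})
    )
    bottom = AnnotationTable(
        pd.DataFrame({"term_id": ["bot"], "term_name": ["bot"], "members": [frozenset(pids[:k])]})
    )
    s_top = float(one_d_enrichment(values, top)["score"].iloc[0])
    s_bot = float(one_d_enrichment(values, bottom)["score"].iloc[0])

    rng = np.random.default_rng(seed)
    scores, pvals = [], []
    members = frozenset(pids[:k])
    annot = AnnotationTable(
        pd.DataFrame({"term_id": ["t"], "term_name": ["t"], "members": [members]})
    )
    for _ in range(n_null):
        v = pd.Series(rng.standard_normal(n), index=pids)
        res = one_d_enrichment(v, annot)
        scores.append(res["score"].iloc[0])
        pvals.append(res["p"].iloc[0])
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    return {
        "score_top": s_top,
        "score_bottom": s_bot,
        "null_mean_score": float(np.mean(scores)),
        "null_p_ks_uniform": ks_p,
        "n_null": n_null,
    }


def check_meta_correlation(seed: int, n_rep: int = 1000, true_rho: float = -0.3) -> dict:
    """Hand Fisher-z example plus CI coverage over simulated cohort sets."""
    res = meta_correlation([(0.3, 28), (0.6, 19)])
    zp = (25 * np.arctanh(0.3) + 16 * np.arctanh(0.6)) / 41
    hand_err = abs(res.pooled_rho - float(np.tanh(zp)))

    covered = 0
    for i in range(n_rep):
        cohorts = simulate_cohorts(true_rho, [50, 100], seed=seed + i)
        m = meta_correlation(cohorts)
        covered += int(m.ci_low <= true_rho <= m.ci_high)
    return {
        "hand_example_pooled_rho": res.pooled_rho,
        "hand_example_abs_error": hand_err,
        "ci_coverage": covered / n_rep,
        "n_replicates": n_rep,
    }


def check_imputation(seed: int, n_missing: int = 10_000) -> dict:
    """Moments of imputed draws for a sample with observed mean 20, SD 2."""
    rng = np.random.default_rng(seed)
    obs = rng.standard_normal(500)
    obs = (obs - obs.mean()) / obs.std(ddof=1) * 2.0 + 20.0  # exact m=20, s=2
    col = np.concatenate([obs, np.full(n_missing, np.nan)])
    df = pd.DataFrame({"s1": col})
    out = impute_gaussian(df, downshift=1.8, width=0.3, seed=seed)
    imputed = out["s1"].to_numpy()[len(obs):]
    return {
        "imputed_mean": float(imputed.mean()),
        "imputed_sd": float(imputed.std(ddof=1)),
        "expected_mean": 20.0 - 1.8 * 2.0,
        "expected_sd": 0.3 * 2.0,
        "n_imputed": n_missing,
    }


def run_checks(seed: int) -> dict:
    """All parameter-recovery and calibration checks, individually seeded."""
    return {
        "alpha_recovery": check_alpha_recovery(stage_seed(seed, "alpha")),
        "marker_accuracy": check_marker_accuracy(stage_seed(seed, "svm")),
        "localization_changes": check_localization_changes(stage_seed(seed, "changes")),
        "null_fdr": check_null_fdr(stage_seed(seed, "anova")),
        "conserved_oracle": check_conserved_oracle(stage_seed(seed, "conserved")),
        "ruler": check_ruler(),
        "proportions": check_proportions(stage_seed(seed, "proportions")),
        "fisher_exactness": check_fisher_exactness(),
        "one_d_enrichment": check_one_d_enrichment(stage_seed(seed, "one_d")),
        "meta_correlation": check_meta_correlation(stage_seed(seed, "meta")),
        "imputation": check_imputation(stage_seed(seed, "impute")),
    }


# ---------------------------------------------------------------------------
# demo


def run_demo(out_dir, seed: int = 7, config: RunConfig | None = None) -> dict:
    """Run every stage on synthetic data, write all artifacts and the summary.

    The summary report combines the end-to-end pipeline outputs (marker
    accuracy, localization map and change calls, conserved-trajectory and
    copy-number recovery, transcriptome and cohort integration) with the
    full battery of parameter-recovery checks.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or RunConfig(seed=seed)
    stages = ["simulate", "pcp", "pcp-diff", "temporal", "integrate", "checks"]
    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in stages},
        "config": config.to_dict(),
        "stages": stages,
        "started": datetime.now(timezone.utc).isoformat(),
        "status": "running",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    summary: dict = {"seed": seed}

    # --- spatial: two cellular states with shared ground truth -------------
    sim_seed = stage_seed(seed, "simulate")
    frac_spec = FractionationSimSpec(seed=sim_seed)
    tables_a, markers, truth = simulate_fractionation(frac_spec)
    rng = np.random.default_rng(sim_seed)
    labels = [o[0] for o in frac_spec.organelles]
    singles = truth.index[truth["kind"] == "single"]
    moved = rng.choice(singles, size=25, replace=False)
    reassign = {
        pid: labels[(labels.index(truth.loc[pid, "organelle1"]) + 1) % len(labels)] for pid in moved
    }
    tables_b, _, truth_b = simulate_fractionation(frac_spec, reassign=reassign, noise_seed=sim_seed + 1)

    pcp_cfg = RunConfig(**{**config.to_dict(), "seed": stage_seed(seed, "pcp")})
    res_a = build_pcp_map(tables_a, markers, pcp_cfg)
    res_b = build_pcp_map(tables_b, markers, pcp_cfg, estimate_second=False)
    write_protein_table(tables_a[0], out / "pg_stateA_rep1.tsv", out / "pg_stateA_rep1_meta.tsv")
    write_markers(markers, out / "markers.tsv")
    write_assignments(res_a["assignments"], out / "map_stateA.tsv")
    write_assignments(res_b["assignments"], out / "map_stateB.tsv")
    res_a["accuracy"].confusion.to_csv(out / "confusion_stateA.tsv", sep="\t")
    res_a["accuracy"].per_compartment.to_csv(out / "accuracy_stateA.tsv", sep="\t")
    summary["marker_mean_cv_accuracy"] = res_a["accuracy"].mean_accuracy

    changes = call_localization_changes(res_a["assignments"], res_b["assignments"])
    changes.to_csv(out / "localization_changes.tsv", sep="\t", index=False)
    called = set(changes.loc[changes["high_confidence_change"], "protein_id"])
    summary["localization_changes"] = {
        **change_summary(changes),
        "planted": int(len(moved)),
        "recovered": int(len(called & set(moved))),
        "false_positives": int(len(called - set(moved))),
    }

    comp = organelle_proportions(res_a["assignments"], tables_a[0])
    comp.percentages.to_csv(out / "organelle_proportions.tsv", sep="\t")
    summary["composition_sum"] = float(comp.percentages.sum())

    # --- temporal ----------------------------------------------------------
    temporal_seed = stage_seed(seed, "temporal")
    tspec = TemporalSimSpec(seed=temporal_seed)
    ttable, ttruth = simulate_temporal(tspec)
    write_protein_table(ttable, out / "pg_temporal.tsv", out / "pg_temporal_meta.tsv")
    tcfg = RunConfig(**{**config.to_dict(), "seed": temporal_seed})
    tres = run_temporal_stage(ttable, tcfg)
    tres["anova"].table.to_csv(out / "anova.tsv", sep="\t")
    tres["conserved"].to_csv(out / "conserved.tsv", sep="\t")
    tres["copies"].to_csv(out / "copies_per_cell.tsv", sep="\t")

    truth_flags = ttruth.proteins["true_conserved"].reindex(tres["conserved"].index)
    summary["conserved_counts"] = {
        "called": int(tres["conserved"].sum()),
        "true": int(truth_flags.sum()),
        "agreement": float((tres["conserved"] == truth_flags).mean()),
    }
    summary["anova_significant"] = int(tres["anova"].table["significant"].sum())

    obs = ttable.intensities.notna()
    rel_err = ((tres["copies"] - ttruth.copies) / ttruth.copies)[obs].abs()
    summary["ruler_max_rel_error"] = float(np.nanmax(rel_err.to_numpy()))

    sig = tres["anova"].significant_ids
    model = tres["anova_model"]
    zm = tres["zprofiles"].xs(model, level="model")
    members = sig.intersection(zm.index)
    clusters, _ = hierarchical_cluster(zm.loc[members], n_clusters=config.n_clusters)
    clusters.to_csv(out / "clusters.tsv", sep="\t")
    summary["n_clustered"] = int(len(clusters))

    meta = ttable.samples
    m1 = meta["model"].iloc[0]
    tps = sorted(meta.loc[meta["model"] == m1, "timepoint_days"].unique())
    fc_groups = meta.loc[meta["model"] == m1, "condition"]
    fc = fold_change_classes(
        ttable.intensities[fc_groups.index],
        fc_groups,
        reference=f"{m1}_d{tps[0]:g}",
        comparison=f"{m1}_d{tps[-1]:g}",
        threshold=config.fold_change_threshold,
        min_valid=config.min_valid,
    )
    fc.to_csv(out / "fold_change_classes.tsv", sep="\t")
    summary["fold_change_remodelled_fraction"] = float((fc != "other").mean())

    # --- transcriptome integration -----------------------------------------
    tx_seed = stage_seed(seed, "integrate")
    tx = simulate_transcriptome(ttable, lag_timepoints=0, target_rho=0.45, seed=tx_seed)
    log2p = np.log2(ttable.intensities[meta.index[meta["model"] == m1]])
    by_tp = pd.DataFrame(
        {
            t: log2p[meta.index[(meta["model"] == m1) & (meta["timepoint_days"] == t)]].mean(axis=1)
            for t in tps
        }
    )
    rho_t, r_gene = omics_correlation(by_tp, tx)
    r_gene.to_csv(out / "omics_pearson.tsv", sep="\t")
    summary["omics_mean_pearson"] = float(r_gene.mean())
    summary["omics_median_spearman"] = float(rho_t.median())

    # --- cohort meta-analysis ----------------------------------------------
    cohorts = simulate_cohorts(true_rho=0.3, cohort_sizes=[60, 120, 240, 90], seed=tx_seed)
    meta_res = meta_correlation(cohorts, random_effects=config.meta_random_effects)
    summary["meta_pooled_rho"] = meta_res.pooled_rho
    summary["meta_ci"] = [meta_res.ci_low, meta_res.ci_high]

    # --- recovery / calibration checks -------------------------------------
    summary["checks"] = run_checks(seed)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    manifest["status"] = "completed"
    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.suffix in (".tsv", ".json"))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
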