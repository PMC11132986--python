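"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the four data families the pipeline consumes:

* density-gradient fractionation profiles (organelle archetypes as Gaussian
  bumps over fraction index, dual-localized proteins as convex mixtures),
* temporal LFQ matrices over several cell models with planted trajectory
  archetypes, left-censored missingness and histones for copy-number scaling,
* matched transcriptome time courses with a controllable lag and target
  profile correlation,
* multi-cohort bivariate samples with a set true correlation.

All randomness flows from one seeded ``numpy.random.Generator`` per call; the
same spec and seed reproduce the outputs bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .tables import MarkerTable, ProteinGroupTable

AVOGADRO = 6.02214076e23

#: Default organelle layout: 8 compartments, peak centers >= 2 fractions apart.
DEFAULT_ORGANELLES = (
    ("LipidDroplet", 1.0, 1.2),
    ("PlasmaMembrane", 4.0, 1.5),
    ("Golgi", 7.0, 1.5),
    ("ER", 10.0, 1.8),
    ("Endosome", 13.0, 1.5),
    ("Lysosome", 16.0, 1.5),
    ("Mitochondrion", 19.0, 1.8),
    ("Cytosol", 22.0, 2.0),
)


@dataclass
class FractionationSimSpec:
    """Conditions for a simulated density-gradient fractionation experiment."""

    n_fractions: int = 25
    organelles: tuple = DEFAULT_ORGANELLES
    markers_per_organelle: int = 40
    n_single: int = 400
    n_dual: int = 200
    alpha_values: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 5:
            raise ValueError("n_fractions must be >= 5")
        labels = [o[0] for o in self.organelles]
        if len(labels) != len(set(labels)):
            raise ValueError("organelle labels must be unique")
        for label, center, width in self.organelles:
            if not 0 <= center <= self.n_fractions - 1:
                raise ValueError(f"peak center of {label} outside fraction range")
            if width <= 0:
                raise ValueError(f"peak width of {label} must be positive")
        if self.n_dual > 0 and len(self.organelles) < 2:
            raise ValueError("dual-localized proteins require at least 2 organelles")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if any(not 0 <= a <= 1 for a in self.alpha_values):
            raise ValueError("alpha values must lie in [0, 1]")


def organelle_archetype(center: float, width: float, n_fractions: int) -> np.ndarray:
    """Discretized Gaussian bump over fraction index, min-max scaled to [0, 1]."""
    x = np.arange(n_fractions, dtype=float)
    bump = np.exp(-0.5 * ((x - center) / width) ** 2)
    return (bump - bump.min()) / (bump.max() - bump.min())


def simulate_fractionation(
    spec: FractionationSimSpec,
    reassign: dict[str, str] | None = None,
    noise_seed: int | None = None,
):
    """Simulate per-replicate fractionation tables plus markers and ground truth.

    Single-localized profiles are ``archetype + noise``; dual-localized
    profiles are the convex mixture ``(1 - alpha) * archetype1 + alpha *
    archetype2 + noise`` (alpha is the second organelle's weight). Profiles
    are clipped to [0, 1] after noise and exported as linear intensities via
    a per-protein amplitude, so downstream 0-1 scaling recovers the shapes.

    ``reassign`` overrides the true organelle of named single-localized
    proteins, and ``noise_seed`` (default: the spec seed) draws measurement
    noise independently of the protein layout — together they produce a
    second cellular state sharing ground truth with the first except for
    planted localization changes.

    Returns
    -------
    tables : list of ProteinGroupTable, one per replicate
    markers : MarkerTable
    truth : DataFrame indexed by protein_id with columns ``organelle1,
        organelle2, true_alpha, kind``
    """
    rng = np.random.default_rng(spec.seed)
    rng_noise = np.random.default_rng(spec.seed if noise_seed is None else noise_seed)
    labels = [o[0] for o in spec.organelles]
    arch = {
        label: organelle_archetype(center, width, spec.n_fractions)
        for label, center, width in spec.organelles
    }

    rows = []  # (protein_id, kind, org1, org2, alpha, base_profile)
    for label in labels:
        for i in range(spec.markers_per_organelle):
            rows.append((f"MK_{label}_{i:03d}", "marker", label, None, np.nan, arch[label]))
    single_orgs = rng.choice(len(labels), size=spec.n_single)
    for i, oi in enumerate(single_orgs):
        rows.append((f"SP_{i:04d}", "single", labels[oi], None, np.nan, arch[labels[oi]]))
    if spec.n_dual:
        alphas = np.asarray(spec.alpha_values, dtype=float)
        dual_alpha = alphas[np.arange(spec.n_dual) % len(alphas)]
        for i, a in enumerate(dual_alpha):
            o1, o2 = rng.choice(len(labels), size=2, replace=False)
            profile = (1.0 - a) * arch[labels[o1]] + a * arch[labels[o2]]
            rows.append((f"DP_{i:04d}", "dual", labels[o1], labels[o2], a, profile))

    if reassign:
        rows2 = []
        for pid, kind, o1, o2, a, prof in rows:
            if pid in reassign:
                new = reassign[pid]
                if new not in arch:
                    raise ValueError(f"unknown organelle {new!r} in reassign")
                if kind == "dual":
                    raise ValueError("can only reassign single-localized proteins")
                rows2.append((pid, kind, new, None, np.nan, arch[new]))
            else:
                rows2.append((pid, kind, o1, o2, a, prof))
        rows = rows2

    pids = [r[0] for r in rows]
    base = np.vstack([r[5] for r in rows])  # proteins x fractions
    amplitude = rng.lognormal(mean=np.log(1e7), sigma=0.8, size=len(pids))

    tables = []
    for rep in range(1, spec.n_replicates + 1):
        profiles = base + rng_noise.normal(0.0, spec.noise_sd, size=base.shape)
        if spec.noise_sd > 0:
            profiles = np.clip(profiles, 0.0, 1.0)
        intens = profiles * amplitude[:, None]
        if spec.missing_rate > 0:
            mask = rng_noise.random(size=intens.shape) < spec.missing_rate
            intens = np.where(mask, np.nan, intens)
        cols = [f"rep{rep}_F{f:02d}" for f in range(spec.n_fractions)]
        meta = pd.DataFrame(
            {
                "model": "synthetic",
                "timepoint_days": np.nan,
                "replicate": rep,
                "condition": "pcp",
                "fraction_index": np.arange(spec.n_fractions),
            },
            index=pd.Index(cols, name="sample_id"),
        )
        tables.append(
            ProteinGroupTable(pd.DataFrame(intens, index=pd.Index(pids, name="protein_id"), columns=cols), meta)
        )

    marker_mask = [r[1] == "marker" for r in rows]
    markers = MarkerTable(
        pd.Series(
            [r[2] for r, m in zip(rows, marker_mask) if m],
            index=pd.Index([r[0] for r, m in zip(rows, marker_mask) if m], name="protein_id"),
        ),
        vocabulary=tuple(labels),
    )
    truth = pd.DataFrame(
        {
            "kind": [r[1] for r in rows],
            "organelle1": [r[2] for r in rows],
            "organelle2": [r[3] if r[3] is not None else "" for r in rows],
            "true_alpha": [r[4] for r in rows],
        },
        index=pd.Index(pids, name="protein_id"),
    )
    return tables, markers, truth


def rescale_composition(tables, truth: pd.DataFrame, targets: dict[str, float]):
    """Rescale per-protein amplitudes so compartment intensity shares are planted.

    ``targets`` maps organelle label -> target percentage of the summed
    replicate-mean intensity. Scaling a protein's intensities by a constant
    leaves its 0-1 profile (and hence its classification) unchanged, so this
    plants a known organelle composition without touching the spatial signal.
    Returns new tables; proteins are grouped by their true first organelle.
    """
    if abs(sum(targets.values()) - 100.0) > 1e-9:
        raise ValueError("target percentages must sum to 100")
    mean_int = pd.concat([t.intensities.mean(axis=1, skipna=True) for t in tables], axis=1).mean(axis=1)
    group = truth["organelle1"].reindex(mean_int.index)
    current = mean_int.groupby(group).sum()
    missing = [o for o in targets if o not in current.index or current[o] <= 0]
    if missing:
        raise ValueError(f"no intensity mass for organelles: {missing}")
    factor = pd.Series(
        {o: targets[o] / current[o] for o in targets}, dtype=float
    )
    per_protein = group.map(factor).fillna(0.0)
    out = []
    for t in tables:
        scaled = t.intensities.mul(per_protein, axis=0)
        out.append(ProteinGroupTable(scaled, t.samples, t.molar_mass_da, t.gene_name))
    return out


# ---------------------------------------------------------------------------
# temporal simulation


def _default_archetypes(timepoints: np.ndarray) -> list[tuple[str, np.ndarray, int]]:
    """Early/intermediate/late/flat trajectory shapes on the given time grid."""
    t = (timepoints - timepoints.min()) / (timepoints.max() - timepoints.min())
    early = 1.0 - 2.0 * np.sqrt(t)            # rapid decrease from day 0
    late = 2.0 * t - 1.0                       # monotone increase
    intermediate = 1.0 - 4.0 * (t - 0.5) ** 2  # transient mid-course peak
    flat = np.zeros_like(t)
    return [
        ("early", early, 300),
        ("intermediate", intermediate, 300),
        ("late", late, 300),
        ("flat", flat, 300),
    ]


@dataclass
class TemporalSimSpec:
    """Conditions for a simulated multi-model differentiation time course."""

    n_models: int = 4
    timepoints_days: tuple = (0.0, 1.0, 2.0, 4.0, 8.0, 12.0)
    n_replicates: int = 3
    archetypes: list | None = None  # [(label, shape over timepoints, n_proteins)]
    log2_effect_sd: float = 1.0
    noise_sd: float = 0.3
    mnar_quantile: float = 0.0
    frac_nonconserved: float = 0.15
    n_histones: int = 5
    cells_per_sample: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints_days) < 2:
            raise ValueError("at least 2 timepoints required")
        if list(self.timepoints_days) != sorted(self.timepoints_days):
            raise ValueError("timepoints must be sorted")
        if self.archetypes is None:
            self.archetypes = _default_archetypes(np.asarray(self.timepoints_days, float))
        for label, shape, n in self.archetypes:
            if len(shape) != len(self.timepoints_days):
                raise ValueError(f"archetype {label!r} shape length mismatch")
        if sum(n for _, _, n in self.archetypes) <= 0:
            raise ValueError("total protein count must be positive")
        if not 0 <= self.mnar_quantile < 1:
            raise ValueError("mnar_quantile must lie in [0, 1)")


@dataclass
class TemporalGroundTruth:
    """Planted parameters of a temporal simulation.

    ``proteins`` holds per-protein truth (archetype label per model, conserved
    flag, histone flag, molar mass); ``copies`` holds the realized per-sample
    copies per cell that histone-based scaling should recover exactly.
    """

    proteins: pd.DataFrame
    copies: pd.DataFrame


def simulate_temporal(spec: TemporalSimSpec):
    """Simulate a multi-model temporal LFQ table with planted trajectories.

    The per-cell copy number of protein p in model m follows
    ``log2 copies = base_p + effect_p * shape_a(t) + replicate noise``; the
    measured intensity is ``response_s * copies * molar_mass * cells``, so
    intensities are proportional to protein mass and the histone-sum ruler
    inverts exactly. Histone copies are constant over time and normalized so
    the summed histone mass per cell equals the DNA mass per cell (6.5 pg).
    A ``frac_nonconserved`` share of non-flat proteins receives a different
    archetype in each model, breaking cross-model trajectory correlation.
    Low-abundance values are censored with probability rising logistically
    below the ``mnar_quantile`` abundance rank.
    """
    rng = np.random.default_rng(spec.seed)
    tps = np.asarray(spec.timepoints_days, dtype=float)
    models = [f"M{i+1}" for i in range(spec.n_models)]
    arch_labels = [a[0] for a in spec.archetypes]
    arch_shapes = {a[0]: np.asarray(a[1], dtype=float) for a in spec.archetypes}

    pids, labels0 = [], []
    for label, _, n in spec.archetypes:
        for i in range(n):
            pids.append(f"TP_{label}_{i:04d}")
            labels0.append(label)
    n_prot = len(pids)

    # per-model archetype: conserved proteins keep one label everywhere
    per_model = np.tile(np.array(labels0, dtype=object)[:, None], (1, spec.n_models))
    nonflat = np.array([l != "flat" for l in labels0])
    n_nc = int(round(spec.frac_nonconserved * nonflat.sum()))
    nc_idx = rng.choice(np.flatnonzero(nonflat), size=n_nc, replace=False)
    pool = [l for l in arch_labels]
    for i in nc_idx:
        choices = rng.permutation(pool)
        per_model[i, :] = choices[np.arange(spec.n_models) % len(choices)]
    conserved = np.ones(n_prot, dtype=bool)
    conserved[nc_idx] = False
    conserved &= nonflat  # flat z-profiles are degenerate, not conserved

    base = rng.normal(17.0, 1.5, size=n_prot)  # log2 copies per cell
    effect = np.abs(rng.normal(0.0, spec.log2_effect_sd, size=n_prot)) + 0.5
    effect[~nonflat] = 0.0
    mass = rng.uniform(2e4, 2e5, size=n_prot)

    # histones: constant copies, summed mass per cell = DNA mass per cell
    hist_ids = [f"HIST_{i}" for i in range(spec.n_histones)]
    hist_mass = rng.uniform(11e3, 22e3, size=spec.n_histones)
    rel = rng.dirichlet(np.full(spec.n_histones, 5.0))
    dna_mass_g = 6.5e-12
    hist_copies = rel * dna_mass_g * AVOGADRO / hist_mass
    hist_copies *= dna_mass_g * AVOGADRO / np.sum(hist_copies * hist_mass)

    sample_ids, meta_rows, cols_copies, cols_intens = [], [], [], []
    for m_i, model in enumerate(models):
        shapes = np.vstack([arch_shapes[per_model[p, m_i]] for p in range(n_prot)])
        for t_i, t in enumerate(tps):
            mean_log2 = base + effect * shapes[:, t_i]
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{model}_d{t:g}_r{rep}"
                sample_ids.append(sid)
                meta_rows.append((model, t, rep, f"{model}_d{t:g}"))
                log2_copies = mean_log2 + rng.normal(0.0, spec.noise_sd, size=n_prot)
                copies = np.concatenate([2.0 ** log2_copies, hist_copies])
                cols_copies.append(copies)
                # tables emulate upstream-normalized LFQ output: the per-sample
                # MS response is constant, intensity = copies * mass * cells
                cols_intens.append(copies * np.concatenate([mass, hist_mass]) * spec.cells_per_sample)

    all_ids = pids + hist_ids
    intens = pd.DataFrame(
        np.column_stack(cols_intens), index=pd.Index(all_ids, name="protein_id"), columns=sample_ids
    )
    copies_df = pd.DataFrame(
        np.column_stack(cols_copies), index=intens.index, columns=sample_ids
    )

    if spec.mnar_quantile > 0:
        vals = intens.to_numpy().copy()
        for j in range(vals.shape[1]):
            col = vals[:, j]
            rank_frac = stats.rankdata(col) / len(col)
            p_miss = 0.8 / (1.0 + np.exp(25.0 * (rank_frac - spec.mnar_quantile)))
            drop = rng.random(len(col)) < p_miss
            drop[-spec.n_histones:] = False  # histones stay observed for the ruler
            col[drop] = np.nan
        intens = pd.DataFrame(vals, index=intens.index, columns=intens.columns)

    meta = pd.DataFrame(
        meta_rows,
        columns=["model", "timepoint_days", "replicate", "condition"],
        index=pd.Index(sample_ids, name="sample_id"),
    )
    meta["fraction_index"] = np.nan

    table = ProteinGroupTable(
        intens,
        meta,
        molar_mass_da=pd.Series(np.concatenate([mass, hist_mass]), index=intens.index),
    )
    proteins = pd.DataFrame(
        {
            "is_histone": [False] * n_prot + [True] * spec.n_histones,
            "true_conserved": list(conserved) + [False] * spec.n_histones,
            "base_log2_copies": list(base) + list(np.log2(hist_copies)),
            "molar_mass_da": np.concatenate([mass, hist_mass]),
        },
        index=intens.index,
    )
    for m_i, model in enumerate(models):
        proteins[f"archetype_{model}"] = list(per_model[:, m_i]) + ["histone"] * spec.n_histones
    return table, TemporalGroundTruth(proteins, copies_df)


# ---------------------------------------------------------------------------
# transcriptome simulation


def _bias_corrected_rho(target: float, n: int) -> float:
    """Invert the small-sample Pearson bias E[r] ≈ ρ − ρ(1−ρ²)/(2(n−1))."""
    if abs(target) >= 0.999 or n < 4:
        return target

    def g(rho):
        return rho - rho * (1 - rho**2) / (2 * (n - 1)) - target

    return float(optimize.brentq(g, -0.9999, 0.9999))


def simulate_transcriptome(
    matched: ProteinGroupTable,
    lag_timepoints: int,
    target_rho: float,
    seed: int,
    model: str | None = None,
) -> pd.DataFrame:
    """Simulate mRNA time courses matched to one model's protein profiles.

    Per gene, the transcript z-profile is the protein z-profile shifted
    *earlier* by ``lag_timepoints`` (mRNA leads protein) with Gaussian noise
    mixed in at a weight calibrated — including the small-sample bias of the
    Pearson estimator — so the expected realized profile correlation is
    approximately ``target_rho``. Returns a genes x timepoints table on a
    log2-count-like scale.
    """
    if not -1 <= target_rho <= 1:
        raise ValueError("target_rho must lie in [-1, 1]")
    meta = matched.samples
    if model is None:
        model = meta["model"].iloc[0]
    sel = meta.index[meta["model"] == model]
    tps = sorted(meta.loc[sel, "timepoint_days"].unique())
    if len(tps) < 3:
        raise ValueError("matched table needs >= 3 timepoints")
    if lag_timepoints >= len(tps):
        raise ValueError("lag must be smaller than the number of timepoints")

    rng = np.random.default_rng(seed)
    log2 = np.log2(matched.intensities[sel])
    by_tp = pd.DataFrame(
        {t: log2[meta.index[(meta["model"] == model) & (meta["timepoint_days"] == t)]].mean(axis=1) for t in tps}
    )
    z = by_tp.sub(by_tp.mean(axis=1), axis=0)
    sd = by_tp.std(axis=1, ddof=0)
    flat = sd < 1e-9  # numerically constant protein profiles carry no shape
    z = z.div(sd.where(~flat, 1.0), axis=0)
    z[flat] = 0.0

    shifted = np.roll(z.to_numpy(), -lag_timepoints, axis=1)
    if lag_timepoints > 0:  # pad the trailing edge by holding the last value
        shifted[:, -lag_timepoints:] = shifted[:, [-lag_timepoints - 1]]
    rho = _bias_corrected_rho(target_rho, len(tps))
    noise = rng.standard_normal(shifted.shape)
    noise = noise - noise.mean(axis=1, keepdims=True)
    nsd = noise.std(axis=1, ddof=0)
    noise = noise / np.where(nsd > 0, nsd, 1.0)[:, None]
    profile = rho * shifted + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    # per-gene baseline tracks protein abundance (constant over time, so the
    # per-gene profile correlation is untouched) — mRNA and protein levels
    # correlate across genes, which the per-timepoint Spearman reads out
    base = by_tp.mean(axis=1).to_numpy()
    counts = 8.0 + (base - base.mean())[:, None] + 1.5 * profile
    return pd.DataFrame(counts, index=matched.intensities.index, columns=tps)


def simulate_cohorts(true_rho: float, cohort_sizes, seed: int) -> list[tuple[float, int]]:
    """Draw per-cohort bivariate-normal samples and return (Spearman r, n) pairs."""
    if abs(true_rho) >= 1:
        raise ValueError("|true_rho| must be < 1")
    if any(n < 5 for n in cohort_sizes):
        raise ValueError("all cohort sizes must be >= 5")
    rng = np.random.default_rng(seed)
    cov = [[1.0, true_rho], [true_rho, 1.0]]
    out = []
    for n in cohort_sizes:
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=int(n))
        r = stats.spearmanr(xy[:, 0], xy[:, 1]).statistic
        out.append((float(r), int(n)))
    return out
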