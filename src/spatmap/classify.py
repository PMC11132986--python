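"""Organelle assignment: marker-trained SVM plus α-mixing second localization.

First assignments come from a support-vector machine with an RBF kernel
``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))`` trained on organelle marker
profiles (sigma 0.2, C 8 by default). The second assignment models each
profile as a convex mixture of its first organelle's median profile with one
other compartment's: the mixing weight α of the best-correlating in-silico
mixture quantifies the second organelle's contribution, and α = 0 means the
protein is specific to a single organelle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .config import RunConfig
from .tables import ASSIGNMENT_COLUMNS, MarkerTable


@dataclass
class OrganelleModel:
    """A trained organelle classifier bound to its feature-column signature."""

    svc: SVC
    classes: list[str]          # in vocabulary order
    feature_columns: list[str]
    assignment_floor: float
    confidence_threshold: float


@dataclass
class AccuracyReport:
    per_compartment: pd.Series          # accuracy in [0, 1] per compartment
    mean_accuracy: float                # unweighted mean over compartments
    confusion: pd.DataFrame             # true (rows) x predicted (cols) counts
    evaluation_mode: str


def _check_markers(features: pd.DataFrame, markers: MarkerTable, min_per_class: int) -> pd.Series:
    labels = markers.assignments[markers.assignments.index.isin(features.index)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need markers from at least 2 compartments in the feature matrix")
    small = [f"{c} ({counts[c]})" for c in counts.index if counts[c] < min_per_class]
    if small:
        raise ValueError(
            f"compartments with fewer than {min_per_class} markers in features: {', '.join(small)}"
        )
    return labels


def _vocab_order(markers: MarkerTable, present: set[str]) -> list[str]:
    return [c for c in markers.vocabulary if c in present]


def train_classifier(
    features: pd.DataFrame, markers: MarkerTable, config: RunConfig | None = None
) -> OrganelleModel:
    """Train the RBF-SVM on marker rows of the feature matrix.

    Deterministic given identical inputs (the dual solver has no random
    initialization; the Platt-scaling CV uses a fixed seed). Compartments in
    ``config.exclude_compartments`` are removed from training.
    """
    config = config or RunConfig()
    labels = _check_markers(features, markers, config.cv_folds)
    if config.exclude_compartments:
        labels = labels[~labels.isin(config.exclude_compartments)]
    classes = _vocab_order(markers, set(labels.unique()))
    gamma = 1.0 / (2.0 * config.svm_sigma**2)
    svc = SVC(
        C=config.svm_c,
        kernel="rbf",
        gamma=gamma,
        probability=True,
        random_state=config.seed,
        decision_function_shape="ovr",
    )
    X = features.loc[labels.index].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(X, labels.to_numpy())
    floor = config.assignment_floor if config.assignment_floor is not None else 1.0 / len(classes)
    return OrganelleModel(svc, classes, list(features.columns), floor, config.confidence_threshold)


def predict_first(model: OrganelleModel, features: pd.DataFrame) -> pd.DataFrame:
    """Predict each protein's first organelle with a calibrated confidence.

    Confidence is the pairwise-coupled class probability of the winning
    compartment; ties break by the fixed vocabulary order. Proteins whose
    winning probability falls below the assignment floor (default
    1/n_classes) lack a positive assignment to any organelle and are
    returned unassigned.
    """
    if list(features.columns) != model.feature_columns:
        raise ValueError("feature columns do not match the trained model signature")
    out = pd.DataFrame(columns=list(ASSIGNMENT_COLUMNS))
    if len(features) == 0:
        return out
    proba = model.svc.predict_proba(features.to_numpy(dtype=float))
    # reorder probability columns to vocabulary order for deterministic ties
    order = [list(model.svc.classes_).index(c) for c in model.classes]
    proba = proba[:, order]
    win = np.argmax(proba, axis=1)  # first (= vocabulary-order) max wins ties
    conf = proba[np.arange(len(proba)), win]
    first = np.array(model.classes, dtype=object)[win]
    unassigned = conf < model.assignment_floor
    first = np.where(unassigned, "", first)
    return pd.DataFrame(
        {
            "protein_id": features.index,
            "first_organelle": first,
            "confidence": conf,
            "high_confidence": (~unassigned) & (conf >= model.confidence_threshold),
            "second_organelle": "",
            "alpha": np.nan,
            "best_mix_correlation": np.nan,
        }
    ).reset_index(drop=True)


def marker_accuracy(
    features: pd.DataFrame, markers: MarkerTable, config: RunConfig | None = None
) -> AccuracyReport:
    """Stratified k-fold cross-validated prediction accuracy per compartment."""
    config = config or RunConfig()
    labels = _check_markers(features, markers, config.cv_folds)
    if config.exclude_compartments:
        labels = labels[~labels.isin(config.exclude_compartments)]
    classes = _vocab_order(markers, set(labels.unique()))
    X = features.loc[labels.index].to_numpy(dtype=float)
    y = labels.to_numpy()
    gamma = 1.0 / (2.0 * config.svm_sigma**2)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        svc = SVC(C=config.svm_c, kernel="rbf", gamma=gamma, random_state=config.seed)
        svc.fit(X[train_idx], y[train_idx])
        pred = svc.predict(X[test_idx])
        for t, p in zip(y[test_idx], pred):
            confusion.loc[t, p] += 1
    per_comp = pd.Series(
        {c: confusion.loc[c, c] / confusion.loc[c].sum() for c in classes}, name="accuracy"
    )
    return AccuracyReport(per_comp, float(per_comp.mean()), confusion, "cross-validation")


def estimate_second_localization(
    profile: np.ndarray,
    first: str,
    organelle_profiles: pd.DataFrame,
    grid_step: float = 0.05,
) -> tuple[str | None, float, float]:
    """Best convex mixture of the first organelle's profile with one other.

    Scans every other compartment O2 and every α on the grid {0, step, ..., 1},
    scoring ``Pearson(profile, (1 - α) m_first + α m_O2)``. Returns the
    maximizing (O2, α, r); ties prefer smaller α, then the compartment order
    of ``organelle_profiles``. A maximizing α of 0 means no detectable second
    compartment: the protein is single-organelle specific and (None, 0, r)
    is returned.
    """
    if first not in organelle_profiles.index:
        raise ValueError(f"first organelle {first!r} has no median profile")
    others = [c for c in organelle_profiles.index if c != first]
    if not others:
        raise ValueError("need at least 2 compartments for mixture search")
    profile = np.asarray(profile, dtype=float)
    mask = np.isfinite(profile)
    if mask.sum() < 3:
        raise ValueError("profile needs >= 3 observed fractions")
    p = profile[mask]
    pc = p - p.mean()
    pn = np.sqrt(np.sum(pc**2))
    if pn == 0:
        raise ValueError("constant profile has no defined correlation")

    m_first = organelle_profiles.loc[first].to_numpy(dtype=float)[mask]
    alphas = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    best = (None, 0.0, -np.inf)
    for comp in others:
        m2 = organelle_profiles.loc[comp].to_numpy(dtype=float)[mask]
        for a in alphas:
            mix = (1.0 - a) * m_first + a * m2
            mc = mix - mix.mean()
            mn = np.sqrt(np.sum(mc**2))
            if mn == 0:
                continue  # degenerate mixture at this grid point
            r = float(np.dot(pc, mc) / (pn * mn))
            if r > best[2] + 1e-12:
                best = (comp, float(a), r)
    comp, alpha, r = best
    if alpha == 0.0 or comp is None:
        return None, 0.0, r
    return comp, alpha, r


def assign_map(
    features: pd.DataFrame,
    median_profiles: pd.DataFrame,
    organelle_profiles: pd.DataFrame,
    markers: MarkerTable,
    config: RunConfig | None = None,
    estimate_second: bool = True,
) -> pd.DataFrame:
    """Full localization map: first assignment by SVM, second by α-mixing."""
    config = config or RunConfig()
    model = train_classifier(features, markers, config)
    assignments = predict_first(model, features)
    assignments = assignments.set_index("protein_id")
    if not estimate_second:
        return assignments.reset_index()
    for pid, row in assignments.iterrows():
        first = row["first_organelle"]
        if not first or pid not in median_profiles.index or first not in organelle_profiles.index:
            continue
        second, alpha, r = estimate_second_localization(
            median_profiles.loc[pid].to_numpy(), first, organelle_profiles, config.alpha_grid_step
        )
        assignments.loc[pid, ["second_organelle", "alpha", "best_mix_correlation"]] = (
            second or "",
            alpha,
            r,
        )
    return assignments.reset_index()


def call_localization_changes(map_a: pd.DataFrame, map_b: pd.DataFrame) -> pd.DataFrame:
    """Compare two localization maps protein-by-protein.

    A protein has a localization change iff its first organelle assignments
    differ; a high-confidence change additionally requires a high-confidence
    assignment in both maps. Computed over the shared protein id space.
    """
    a = map_a.set_index("protein_id")
    b = map_b.set_index("protein_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between the two maps")
    a, b = a.loc[shared], b.loc[shared]
    fa = a["first_organelle"].fillna("")
    fb = b["first_organelle"].fillna("")
    assigned = (fa != "") & (fb != "")
    changed = assigned & (fa != fb)
    high = changed & a["high_confidence"].astype(bool) & b["high_confidence"].astype(bool)
    return pd.DataFrame(
        {
            "protein_id": shared,
            "first_a": fa.to_numpy(),
            "first_b": fb.to_numpy(),
            "changed": changed.to_numpy(),
            "high_confidence_change": high.to_numpy(),
            "both_high_confidence": (
                a["high_confidence"].astype(bool) & b["high_confidence"].astype(bool)
            ).to_numpy(),
        }
    ).reset_index(drop=True)


def change_summary(changes: pd.DataFrame) -> dict:
    """Counts of (un)changed assignments stratified by confidence."""
    both_high = changes["both_high_confidence"]
    return {
        "n_shared": int(len(changes)),
        "n_changed": int(changes["changed"].sum()),
        "n_high_confidence_changed": int(changes["high_confidence_change"].sum()),
        "n_high_confidence_same": int((both_high & ~changes["changed"]).sum()),
    }
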