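"""Protein correlation profiles: 0-1 scaling, replicate QC, organelle medians.

The fractionation signal of a protein is its *shape* across the density
gradient, not its absolute intensity; profiles are therefore min-max scaled
to [0, 1] per protein and replicate before any comparison. Organelle
reference profiles are fraction-wise medians over marker proteins and
replicates, rescaled to [0, 1] a second time.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import ProteinGroupTable


@dataclass
class ScaledProfileSet:
    """Per-replicate matrices of 0-1 scaled fraction profiles.

    ``profiles`` maps replicate id -> DataFrame (proteins x fractions, values
    in [0, 1] or NaN); all replicates share the fraction grid (column order =
    gradient order, fraction 0 at the top of the gradient). ``exclusions``
    records proteins removed at any stage with the stage and reason.
    """

    profiles: dict[int, pd.DataFrame]
    fractions: list[int]
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["protein_id", "stage", "reason"])
    )

    @property
    def replicates(self) -> list[int]:
        return list(self.profiles)

    def proteins(self) -> pd.Index:
        idx = None
        for df in self.profiles.values():
            idx = df.index if idx is None else idx.union(df.index)
        return idx if idx is not None else pd.Index([])


def _minmax_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise (x - min)/(max - min) over observed entries.

    Returns the scaled matrix and a boolean mask of degenerate rows
    (constant, or fewer than the minimum observed fractions — handled by the
    caller)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanmin(mat, axis=1, keepdims=True)
        hi = np.nanmax(mat, axis=1, keepdims=True)
    span = hi - lo
    constant = (span == 0).ravel() | ~np.isfinite(span).ravel()
    safe = np.where(span > 0, span, 1.0)
    return (mat - lo) / safe, constant


def scale_profiles(table: ProteinGroupTable, min_observed: int = 3) -> ScaledProfileSet:
    """Scale each protein's fraction profile to [0, 1], per replicate.

    Samples are grouped by their ``replicate`` metadata and ordered by
    ``fraction_index``. Proteins with fewer than ``min_observed`` non-missing
    fractions in a replicate, or with a constant profile, are excluded from
    that replicate with a logged reason; missing fractions stay missing.
    """
    meta = table.samples
    if meta["fraction_index"].isna().any():
        raise ValueError("scale_profiles requires fraction-indexed samples")
    frac_sorted = meta.sort_values("fraction_index")
    fractions = sorted(meta["fraction_index"].astype(int).unique())
    if len(fractions) < 2:
        raise ValueError("at least 2 fractions required")

    profiles: dict[int, pd.DataFrame] = {}
    excl = []
    for rep, sub in frac_sorted.groupby("replicate", sort=True):
        cols = list(sub.index)
        mat = table.intensities[cols].to_numpy(dtype=float)
        n_obs = np.isfinite(mat).sum(axis=1)
        scaled, constant = _minmax_rows(mat)
        too_few = n_obs < min_observed
        keep = ~(too_few | constant)
        for pid in table.protein_ids[too_few]:
            excl.append((pid, f"scale[rep={rep}]", "fewer than %d observed fractions" % min_observed))
        for pid in table.protein_ids[constant & ~too_few]:
            excl.append((pid, f"scale[rep={rep}]", "constant profile"))
        df = pd.DataFrame(
            scaled[keep], index=table.protein_ids[keep], columns=[int(f) for f in sub["fraction_index"]]
        )
        profiles[int(rep)] = df
    return ScaledProfileSet(
        profiles, [int(f) for f in fractions], pd.DataFrame(excl, columns=["protein_id", "stage", "reason"])
    )


def merge_replicates(sets: list[ScaledProfileSet]) -> ScaledProfileSet:
    """Combine single-replicate sets (e.g. one table per replicate) into one."""
    profiles: dict[int, pd.DataFrame] = {}
    excl = []
    for s in sets:
        for rep, df in s.profiles.items():
            key = rep
            while key in profiles:
                key += 1
            profiles[key] = df
        excl.append(s.exclusions)
    fractions = sets[0].fractions
    for s in sets[1:]:
        if s.fractions != fractions:
            raise ValueError("replicates do not share the fraction grid")
    return ScaledProfileSet(profiles, fractions, pd.concat(excl, ignore_index=True))


def _pairwise_pearson(a: np.ndarray, b: np.ndarray, min_joint: int = 3) -> float:
    """Pearson r over jointly observed fractions; NaN if fewer than min_joint."""
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < min_joint:
        return np.nan
    x, y = a[mask], b[mask]
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def filter_reproducible(pset: ScaledProfileSet, min_joint: int = 3) -> ScaledProfileSet:
    """Drop proteins whose replicate profiles disagree.

    A protein is kept iff every pairwise replicate Pearson correlation (over
    jointly observed fractions, requiring at least ``min_joint``) is >= 0; a
    pair with too few joint observations counts as failing. Proteins present
    in fewer than two replicates pass through unchecked.
    """
    reps = pset.replicates
    if len(reps) < 2:
        warnings.warn("single replicate: reproducibility filter is a no-op", UserWarning, stacklevel=2)
        return pset

    excl = []
    failed: set = set()
    for pid in pset.proteins():
        present = [r for r in reps if pid in pset.profiles[r].index]
        if len(present) < 2:
            continue
        for r1, r2 in itertools.combinations(present, 2):
            r = _pairwise_pearson(
                pset.profiles[r1].loc[pid].to_numpy(),
                pset.profiles[r2].loc[pid].to_numpy(),
                min_joint,
            )
            if np.isnan(r) or r < 0:
                failed.add(pid)
                reason = (
                    "insufficient joint fractions" if np.isnan(r) else f"replicate Pearson {r:.3f} < 0"
                )
                excl.append((pid, "replicate-filter", reason))
                break
    profiles = {r: df.loc[[p for p in df.index if p not in failed]] for r, df in pset.profiles.items()}
    exclusions = pd.concat(
        [pset.exclusions, pd.DataFrame(excl, columns=["protein_id", "stage", "reason"])],
        ignore_index=True,
    )
    return ScaledProfileSet(profiles, pset.fractions, exclusions)


def _rescale01(v: np.ndarray) -> np.ndarray:
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        raise ValueError("constant median profile cannot be rescaled")
    return (v - lo) / (hi - lo)


def median_profile(pset: ScaledProfileSet, members) -> np.ndarray:
    """Fraction-wise median over member proteins and replicates, rescaled to [0, 1]."""
    members = [m for m in members]
    stack = []
    for rep in pset.replicates:
        df = pset.profiles[rep]
        hit = [m for m in members if m in df.index]
        if hit:
            stack.append(df.loc[hit].to_numpy())
    if not stack:
        raise ValueError("no member protein has a profile in any replicate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(np.vstack(stack), axis=0)
    return _rescale01(med)


def organelle_median_profiles(pset: ScaledProfileSet, markers) -> pd.DataFrame:
    """Median reference profile per compartment (rows) over the fraction grid."""
    out = {}
    for comp in markers.compartments_present:
        out[comp] = median_profile(pset, markers.members(comp))
    return pd.DataFrame.from_dict(out, orient="index", columns=pset.fractions)


def protein_median_profiles(pset: ScaledProfileSet, proteins=None) -> pd.DataFrame:
    """Per-protein replicate-median profile, second 0-1 scaling applied.

    Proteins whose median profile is constant are dropped.
    """
    ids = pset.proteins() if proteins is None else pd.Index(proteins)
    rows, kept = [], []
    for pid in ids:
        stack = [
            pset.profiles[r].loc[pid].to_numpy() for r in pset.replicates if pid in pset.profiles[r].index
        ]
        if not stack:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(np.vstack(stack), axis=0)
        lo, hi = np.nanmin(med), np.nanmax(med)
        if not np.isfinite(lo) or hi == lo:
            continue
        rows.append((med - lo) / (hi - lo))
        kept.append(pid)
    return pd.DataFrame(rows, index=pd.Index(kept, name="protein_id"), columns=pset.fractions)


def concatenate_replicates(
    pset: ScaledProfileSet,
    replicate_order: list[int] | None = None,
    missing_as_zero: bool = True,
) -> pd.DataFrame:
    """Build the classifier feature matrix: proteins x (fractions * replicates).

    Columns are replicate-major, fraction-minor in the declared order.
    Proteins missing an entire replicate are dropped; remaining missing
    fractions become 0 (absence from a gradient region reads as
    below-detection there) unless ``missing_as_zero`` is disabled.
    """
    if replicate_order is None:
        replicate_order = pset.replicates
    if not replicate_order:
        raise ValueError("replicate_order must not be empty")
    unknown = [r for r in replicate_order if r not in pset.profiles]
    if unknown:
        raise ValueError(f"unknown replicates: {unknown}")

    common = None
    for r in replicate_order:
        idx = pset.profiles[r].index
        common = idx if common is None else common.intersection(idx)
    blocks = []
    for r in replicate_order:
        df = pset.profiles[r].loc[common]
        df = df.rename(columns=lambda f, r=r: f"rep{r}_F{f:02d}")
        blocks.append(df)
    feat = pd.concat(blocks, axis=1)
    if missing_as_zero:
        feat = feat.fillna(0.0)
    return feat
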