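"""Tabular artifacts: quantification tables, marker/annotation tables, assignments.

All tables are TSV (UTF-8, header row). Missing intensities are encoded as
empty cells on disk and as NaN in memory — never as 0, since in label-free
proteomics a missing value means "below detection / not quantified", which is
categorically different from a measured zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The default compartment vocabulary for adipocyte organelle maps.
DEFAULT_COMPARTMENTS = (
    "Cytosol",
    "Nucleus",
    "Mitochondrion",
    "ER",
    "Golgi",
    "PlasmaMembrane",
    "Endosome",
    "Lysosome",
    "Peroxisome",
    "LipidDroplet",
    "ProteinSynthesis",
    "ProteinComplex",
)

SAMPLE_FIELDS = ("sample_id", "model", "timepoint_days", "replicate", "condition", "fraction_index")


class TableFormatError(ValueError):
    """Raised when an input table violates its format contract."""


@dataclass
class ProteinGroupTable:
    """Proteins x samples matrix of linear-scale LFQ intensities.

    Parameters
    ----------
    intensities : DataFrame
        Index protein_id (unique), columns sample_id, values linear-scale
        intensities (NaN = missing). Non-negative.
    samples : DataFrame
        Index sample_id, columns ``model, timepoint_days, replicate,
        condition, fraction_index``. Every intensity column must be present.
    molar_mass_da : Series, optional
        Per-protein molar mass in Da; required only for copy-number scaling.
    gene_name : Series, optional
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    molar_mass_da: pd.Series | None = None
    gene_name: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise TableFormatError(f"duplicate protein ids: {dups[:10]}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise TableFormatError("negative intensities are not allowed")
        missing_meta = [c for c in self.intensities.columns if c not in self.samples.index]
        if missing_meta:
            raise TableFormatError(f"samples without metadata: {missing_meta}")

    @property
    def protein_ids(self) -> pd.Index:
        return self.intensities.index

    def subset_samples(self, sample_ids) -> "ProteinGroupTable":
        sample_ids = list(sample_ids)
        return ProteinGroupTable(
            intensities=self.intensities[sample_ids],
            samples=self.samples.loc[sample_ids],
            molar_mass_da=self.molar_mass_da,
            gene_name=self.gene_name,
        )


@dataclass
class MarkerTable:
    """Organelle marker list: protein_id -> compartment.

    The compartment vocabulary is declared in the file header (a
    ``# compartments: A,B,...`` comment line) and defaults to the 12-label
    set used for the adipocyte maps.
    """

    assignments: pd.Series  # index protein_id, values compartment label
    vocabulary: tuple[str, ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self) -> None:
        if self.assignments.index.duplicated().any():
            dup = self.assignments.index[self.assignments.index.duplicated()]
            raise TableFormatError(f"duplicate marker rows: {sorted(set(dup))[:10]}")
        unknown = set(self.assignments.unique()) - set(self.vocabulary)
        if unknown:
            raise TableFormatError(f"compartments outside declared vocabulary: {sorted(unknown)}")

    def members(self, compartment: str) -> list[str]:
        return list(self.assignments.index[self.assignments == compartment])

    @property
    def compartments_present(self) -> list[str]:
        return [c for c in self.vocabulary if (self.assignments == c).any()]


@dataclass
class AnnotationTable:
    """Annotation terms (GO/KEGG/CORUM-style): term -> member protein set."""

    terms: pd.DataFrame  # columns term_id, term_name, members (frozenset)

    def __post_init__(self) -> None:
        if self.terms["term_id"].duplicated().any():
            raise TableFormatError("duplicate term_id")
        if any(len(m) == 0 for m in self.terms["members"]):
            raise TableFormatError("empty member set")

    def as_dict(self) -> dict[str, frozenset]:
        return dict(zip(self.terms["term_id"], self.terms["members"]))


# ---------------------------------------------------------------------------
# readers / writers


def _read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_FIELDS if c not in meta.columns]
    if missing:
        raise TableFormatError(f"sample metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise TableFormatError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    has_time = meta["timepoint_days"].notna()
    has_frac = meta["fraction_index"].notna()
    orphans = meta.index[~(has_time | has_frac)]
    if len(orphans):
        raise TableFormatError(
            f"samples with neither timepoint nor fraction semantics: {list(orphans)}"
        )
    return meta


def read_protein_table(path, metadata_path) -> ProteinGroupTable:
    """Read a wide protein-group TSV plus its sample-metadata TSV.

    First column holds protein ids; optional ``gene_name`` and
    ``molar_mass_da`` columns are recognized; all remaining columns must be
    described in the metadata. Empty cells parse to missing. Emits a warning
    when the intensity scale looks logarithmic (max < 100).
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    pid_col = raw.columns[0]
    if raw[pid_col].duplicated().any():
        dups = sorted(raw.loc[raw[pid_col].duplicated(), pid_col].unique())
        raise TableFormatError(f"duplicate protein ids in {path}: {dups[:10]}")
    raw = raw.set_index(pid_col)
    raw.index.name = "protein_id"

    gene = raw.pop("gene_name").astype(str) if "gene_name" in raw.columns else None
    mass = raw.pop("molar_mass_da").astype(float) if "molar_mass_da" in raw.columns else None

    meta = _read_sample_metadata(metadata_path)
    unknown = [c for c in raw.columns if c not in meta.index]
    if unknown:
        raise TableFormatError(f"intensity columns absent from metadata: {unknown}")

    intens = raw.astype(float)
    finite = intens.to_numpy()[np.isfinite(intens.to_numpy())]
    if finite.size and finite.max() < 100:
        warnings.warn(
            "maximum intensity < 100; values may be log-scale — linear scale is required",
            UserWarning,
            stacklevel=2,
        )
    return ProteinGroupTable(intens, meta.loc[list(intens.columns)], mass, gene)


def write_protein_table(table: ProteinGroupTable, path, metadata_path) -> None:
    """Write a ProteinGroupTable and its sample metadata; round-trip safe."""
    out = table.intensities.copy()
    if table.gene_name is not None:
        out.insert(0, "gene_name", table.gene_name)
    if table.molar_mass_da is not None:
        out.insert(0, "molar_mass_da", table.molar_mass_da)
    out.to_csv(path, sep="\t", index_label="protein_id")
    table.samples.to_csv(metadata_path, sep="\t", index_label="sample_id")


def read_markers(path) -> MarkerTable:
    """Read a marker TSV; a ``# compartments:`` header line declares the vocabulary."""
    vocab = DEFAULT_COMPARTMENTS
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# compartments:"):
            vocab = tuple(s.strip() for s in first.split(":", 1)[1].split(",") if s.strip())
            df = pd.read_csv(fh, sep="\t", dtype=str)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in ("protein_id", "compartment"):
        if col not in df.columns:
            raise TableFormatError(f"marker table missing column {col!r}")
    return MarkerTable(df.set_index("protein_id")["compartment"], vocab)


def write_markers(markers: MarkerTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# compartments: " + ",".join(markers.vocabulary) + "\n")
        markers.assignments.rename("compartment").to_csv(fh, sep="\t", index_label="protein_id")


def read_annotations(path) -> AnnotationTable:
    """Read term table: columns term_id, term_name, members (';'-separated ids)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["members"] = [frozenset(m.split(";")) for m in df["members"]]
    return AnnotationTable(df[["term_id", "term_name", "members"]])


def write_annotations(annot: AnnotationTable, path) -> None:
    out = annot.terms.copy()
    out["members"] = [";".join(sorted(m)) for m in out["members"]]
    out.to_csv(path, sep="\t", index=False)


ASSIGNMENT_COLUMNS = (
    "protein_id",
    "first_organelle",
    "confidence",
    "high_confidence",
    "second_organelle",
    "alpha",
    "best_mix_correlation",
)


def write_assignments(assignments: pd.DataFrame, path) -> None:
    """Write localization assignments with a stable column order.

    An absent α is written as an empty cell, never as 0: α = 0 is a
    *statement* (single-organelle specific), absence means "not evaluated".
    """
    out = assignments.reindex(columns=list(ASSIGNMENT_COLUMNS))
    out.to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "first_organelle": str, "second_organelle": str},
    )
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"assignment table missing columns: {missing}")
    if "high_confidence" in df.columns:
        df["high_confidence"] = df["high_confidence"].astype(bool)
    return df
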