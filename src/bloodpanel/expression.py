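"""Expression-matrix containers, ingestion, and normalization.

Whole-blood microarray expression is handled as a probes x samples matrix of
log2 intensities with a binary clinical label (control / disease) per sample.
Probes are matched across same-platform cohorts by exact probe ID; across
manufacturers, probes are collapsed to genes (averaging probes that share an
EntrezID) and matched at the gene level.

Per-sample reference normalization follows the standard reference-transcript
(GUSB-style) convention: on the log2 scale, each sample is shifted so that
its reference-probe value equals the cohort mean reference value — i.e. a
per-sample ratio correction on the linear scale. The operation preserves all
within-sample differences between probes and is invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
DISEASE = "disease"
VALID_LABELS = (CONTROL, DISEASE)

__all__ = [
    "CONTROL",
    "DISEASE",
    "ExpressionDataset",
    "ProbeAnnotation",
    "ScaleReport",
    "IngestionError",
    "read_expression_matrix",
    "write_expression_matrix",
    "write_labels",
    "verify_log2_scale",
    "normalize_to_reference",
    "match_probe_ids",
    "collapse_to_genes",
    "stratified_split",
]


class IngestionError(ValueError):
    """A file could not be ingested as a valid expression dataset."""


@dataclass
class ExpressionDataset:
    """Probes x samples log2 expression with per-sample class labels.

    ``values`` is a DataFrame indexed by probe ID with sample IDs as
    columns; ``labels`` maps every sample ID to ``"control"`` or
    ``"disease"``. ``normalized`` records whether reference normalization
    was already applied.
    """

    values: pd.DataFrame
    labels: pd.Series
    platform: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise IngestionError(f"duplicate probe IDs: {dupes[:10]}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise IngestionError(f"duplicate sample IDs: {dupes[:10]}")
        missing = [s for s in self.values.columns if s not in self.labels.index]
        if missing:
            raise IngestionError(f"samples without a label: {missing}")
        self.labels = self.labels.reindex(self.values.columns)
        bad = sorted(set(self.labels.unique()) - set(VALID_LABELS))
        if bad:
            raise IngestionError(f"labels must be in {VALID_LABELS}; got {bad}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise IngestionError("expression values must be finite")

    # -- convenience views -------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Labels encoded int8, 1 = disease (positive class)."""
        return (self.labels.to_numpy() == DISEASE).astype(np.int8)

    @property
    def X(self) -> np.ndarray:
        """Samples x probes float64 matrix (the ML orientation)."""
        return np.ascontiguousarray(self.values.to_numpy().T, dtype=np.float64)

    def class_counts(self) -> tuple[int, int]:
        y = self.y
        return int((y == 0).sum()), int((y == 1).sum())

    def subset_probes(self, probe_ids) -> "ExpressionDataset":
        return replace(self, values=self.values.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "ExpressionDataset":
        cols = list(sample_ids)
        return replace(self, values=self.values[cols], labels=self.labels[cols])


@dataclass
class ProbeAnnotation:
    """probe_id -> (gene_symbol, entrez_id) mapping table."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol, entrez_id

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_symbol", "entrez_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise IngestionError(f"annotation table missing columns: {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            raise IngestionError("annotation maps a probe to more than one entrez_id")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "ProbeAnnotation":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype=str))

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def entrez_for(self, probe_ids) -> pd.Series:
        mapping = self.table.set_index("probe_id")["entrez_id"]
        return mapping.reindex(probe_ids)


@dataclass
class ScaleReport:
    """Advisory check that a matrix looks like log2 microarray intensities."""

    minimum: float
    maximum: float
    suspect: bool
    message: str


def read_expression_matrix(matrix_path, labels_path, platform: str = "") -> ExpressionDataset:
    """Ingest a tab-separated expression matrix plus a sample-label table.

    The matrix file holds probe IDs in the first column and one column per
    sample; the label table has columns ``sample_id`` and ``label``. Lines
    starting with ``#`` are ignored and CRLF endings are tolerated. Rows
    containing any missing value are dropped (count logged); non-numeric
    cells and sample-ID mismatches raise :class:`IngestionError`.
    """
    matrix_path, labels_path = Path(matrix_path), Path(labels_path)
    raw = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)

    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna() & (raw.apply(lambda c: c.str.strip()) != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise IngestionError(
            f"non-numeric cell {raw.iloc[r, c]!r} at probe {values.index[r]!r}, "
            f"sample {values.columns[c]!r} in {matrix_path.name}"
        )
    n_dropped = int(values.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("dropped %d probe rows with missing values from %s", n_dropped, matrix_path.name)
        values = values.dropna(axis=0)

    labels_df = pd.read_csv(labels_path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "label"} <= set(labels_df.columns):
        raise IngestionError("label table needs columns sample_id, label")
    labels = labels_df.set_index("sample_id")["label"]

    unlabeled = [s for s in values.columns if s not in labels.index]
    extra = [s for s in labels.index if s not in values.columns]
    if unlabeled or extra:
        raise IngestionError(
            f"sample-ID mismatch between {matrix_path.name} and {labels_path.name}: "
            f"unlabeled={unlabeled} label-only={extra}"
        )
    return ExpressionDataset(values=values, labels=labels, platform=platform)


def write_expression_matrix(dataset: ExpressionDataset, path) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="probe_id")


def write_labels(dataset: ExpressionDataset, path) -> None:
    out = dataset.labels.rename("label").rename_axis("sample_id")
    out.to_csv(path, sep="\t")


def verify_log2_scale(dataset: ExpressionDataset, low: float = -5.0, high: float = 30.0) -> ScaleReport:
    """Flag matrices whose range is implausible for log2 intensities.

    Log2 microarray intensities live roughly in [2, 16]; a maximum above
    ``high`` usually means linear-scale data leaked in. Advisory only —
    the data are never modified.
    """
    if dataset.n_probes == 0 or dataset.n_samples == 0:
        raise ValueError("cannot verify the scale of an empty dataset")
    vmin = float(dataset.values.to_numpy().min())
    vmax = float(dataset.values.to_numpy().max())
    suspect = vmax > high or vmin < low
    message = (
        f"range [{vmin:.3g}, {vmax:.3g}] outside plausible log2 range [{low}, {high}]"
        if suspect
        else f"range [{vmin:.3g}, {vmax:.3g}] consistent with log2 intensities"
    )
    if suspect:
        logger.warning("%s: %s", dataset.platform or "dataset", message)
    return ScaleReport(minimum=vmin, maximum=vmax, suspect=suspect, message=message)


def normalize_to_reference(dataset: ExpressionDataset, reference_probe_id: str) -> ExpressionDataset:
    """Per-sample reference-transcript normalization on the log2 scale.

    Every value x_gs becomes x_gs - r_s + r_bar, where r_s is sample s's
    reference-probe value and r_bar the cohort mean reference value. The
    reference row becomes the constant r_bar and within-sample differences
    between probes are untouched.
    """
    if dataset.normalized:
        raise ValueError("dataset is already reference-normalized")
    if reference_probe_id not in dataset.probe_ids:
        raise KeyError(f"reference probe {reference_probe_id!r} not present in dataset")
    ref = dataset.values.loc[reference_probe_id]
    shift = ref - ref.mean()
    values = dataset.values.sub(shift, axis=1)
    return replace(dataset, values=values, normalized=True)


def match_probe_ids(a: ExpressionDataset, b: ExpressionDataset) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared probes, in identical order.

    Shared probes are sorted lexicographically so both outputs carry the
    same rows in the same order regardless of input ordering.
    """
    shared = sorted(set(a.probe_ids) & set(b.probe_ids))
    if not shared:
        raise ValueError("datasets share no probe IDs; collapse to genes first")
    return a.subset_probes(shared), b.subset_probes(shared)


def collapse_to_genes(dataset: ExpressionDataset, annotation: ProbeAnnotation) -> ExpressionDataset:
    """Average probes sharing an EntrezID; row IDs become EntrezIDs.

    Probes without an annotation entry are dropped (count logged). The mean
    is taken on the log2 scale, matching how multi-probe genes are usually
    summarized for cross-manufacturer matching.
    """
    entrez = annotation.entrez_for(dataset.probe_ids)
    keep = entrez.notna().to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d probes without annotation", n_dropped)
    if not keep.any():
        raise ValueError("no probes carry an EntrezID annotation")
    values = dataset.values.loc[keep]
    collapsed = values.groupby(entrez[keep].to_numpy()).mean()
    collapsed.index = collapsed.index.astype(str)
    collapsed = collapsed.sort_index()
    return replace(dataset, values=collapsed)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def stratified_split(
    dataset: ExpressionDataset, test_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Class-stratified train/test split of samples.

    Per class, round(test_fraction x class size) samples — at least one —
    are drawn uniformly without replacement into the test set. Expression
    values are never altered; train and test partition the input samples.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    test_samples: list[str] = []
    for cls in VALID_LABELS:
        members = [s for s in dataset.sample_ids if labels[s] == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has {len(members)} sample(s); need at least 2")
        n_test = max(1, _round_half_away(test_fraction * len(members)))
        chosen = rng.choice(len(members), size=n_test, replace=False)
        test_samples.extend(members[i] for i in sorted(chosen))
    test_set = set(test_samples)
    train_ids = [s for s in dataset.sample_ids if s not in test_set]
    test_ids = [s for s in dataset.sample_ids if s in test_set]
    return dataset.subset_samples(train_ids), dataset.subset_samples(test_ids)
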