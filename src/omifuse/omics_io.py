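"""Reading, writing and harmonizing per-layer expression matrices and clinical tables.

Expression matrices are tab-separated text with an ID header row and an ID
first column (Firehose-style).  Clinical tables are three-column TSV:
``sample_id``, ``time_days``, ``event``.  Harmonization intersects cohorts at
the case level of TCGA-style barcodes so the three omics layers and the
clinical table end up with one shared, deterministically ordered sample list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("gene", "isoform", "methylation")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "CohortBundle",
    "OmicsIOError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "filter_tumor_samples",
    "harmonize",
    "case_prefix",
    "sample_type_code",
]


class OmicsIOError(ValueError):
    """Raised for malformed inputs: parse failures, duplicate IDs, empty joins."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise OmicsIOError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """One omics layer, samples x features, with ordered string IDs."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    layer: str = "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.ndim != 2:
            raise OmicsIOError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise OmicsIOError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.feature_ids, "feature_ids")
        if not np.all(np.isfinite(self.values)):
            raise OmicsIOError("expression values must all be finite")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset to ``keep`` (order taken from ``keep``)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionMatrix(
            self.values[idx], list(keep), list(self.feature_ids), self.layer
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )


@dataclass
class ClinicalTable:
    """Per-sample right-censored survival: time in days, event flag (1=death)."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        _check_unique(self.sample_ids, "sample_ids")
        if self.time.shape != (len(self.sample_ids),) or self.event.shape != (
            len(self.sample_ids),
        ):
            raise OmicsIOError("clinical columns must align with sample_ids")
        finite = np.isfinite(self.time)
        if np.any(self.time[finite] < 0):
            raise OmicsIOError("survival times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise OmicsIOError("event flags must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: Sequence[str]) -> "ClinicalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ClinicalTable(list(keep), self.time[idx], self.event[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "time_days": self.time, "event": self.event}
        )


@dataclass
class CohortBundle:
    """Harmonized multi-layer cohort: every layer and the clinical table share
    one identical, identically ordered sample_ids list."""

    layers: dict[str, ExpressionMatrix]
    clinical: ClinicalTable

    def __post_init__(self) -> None:
        ref = self.clinical.sample_ids
        for name, m in self.layers.items():
            if m.sample_ids != ref:
                raise OmicsIOError(
                    f"layer {name!r} sample order differs from clinical table"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.clinical.sample_ids

    @property
    def n_samples(self) -> int:
        return self.clinical.n_samples


# ---------------------------------------------------------------------------
# TCGA-style barcode handling
# ---------------------------------------------------------------------------

def case_prefix(sample_id: str) -> str:
    """Case-level barcode: first three dash-delimited fields (or the whole id
    when it has fewer than three fields)."""
    return "-".join(sample_id.split("-")[:3])


def sample_type_code(sample_id: str) -> int:
    """Two-digit sample-type code from the fourth dash-delimited barcode field."""
    fields = sample_id.split("-")
    if len(fields) < 4 or len(fields[3]) < 2 or not fields[3][:2].isdigit():
        raise OmicsIOError(
            f"barcode {sample_id!r} has no parseable sample-type field"
        )
    return int(fields[3][:2])


def filter_tumor_samples(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only tumor samples (sample-type codes 01-09), preserving order."""
    keep = [s for s in m.sample_ids if 1 <= sample_type_code(s) <= 9]
    return m.subset_samples(keep)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _parse_numeric(df: pd.DataFrame, path: str) -> np.ndarray:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise OmicsIOError(
                f"{path}: non-numeric cell {df.loc[row, col]!r} "
                f"at row {row!r}, column {col!r}"
            )
        out[:, j] = coerced.to_numpy()
    return out


def read_expression_matrix(
    path: str | Path,
    layer: str = "gene",
    orientation: str = "features_by_samples",
    skip_rows: int = 0,
) -> ExpressionMatrix:
    """Read a TSV expression matrix into samples x features orientation.

    ``orientation`` names the layout *on disk*: ``features_by_samples``
    (Firehose convention, header row = sample barcodes) or
    ``samples_by_features``.  ``skip_rows`` skips platform junk rows after
    the header.
    """
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise OmicsIOError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        skiprows=range(1, 1 + skip_rows) if skip_rows else None,
    )
    values = _parse_numeric(df, str(path))
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if orientation == "features_by_samples":
        return ExpressionMatrix(values.T, col_ids, row_ids, layer)
    return ExpressionMatrix(values, row_ids, col_ids, layer)


def write_expression_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    orientation: str = "samples_by_features",
    float_format: str = "%.10g",
) -> None:
    df = m.to_frame()
    if orientation == "features_by_samples":
        df = df.T
        df.index.name = "feature_id"
    elif orientation == "samples_by_features":
        df.index.name = "sample_id"
    else:
        raise OmicsIOError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep="\t", float_format=float_format)


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 3:
        raise OmicsIOError(f"{path}: clinical table needs 3 columns")
    df.columns = ["sample_id", "time_days", "event", *df.columns[3:]]
    time = pd.to_numeric(df["time_days"], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(df["event"], errors="raise").to_numpy()
    return ClinicalTable(list(df["sample_id"]), time, event)


def write_clinical_table(c: ClinicalTable, path: str | Path) -> None:
    c.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

def _case_map(ids: Sequence[str]) -> dict[str, str]:
    """case prefix -> lexicographically smallest full id among aliquots."""
    out: dict[str, str] = {}
    for s in ids:
        c = case_prefix(s)
        if c not in out or s < out[c]:
            out[c] = s
    return out


def harmonize(
    layers: Mapping[str, ExpressionMatrix], clinical: ClinicalTable
) -> CohortBundle:
    """Restrict all layers and the clinical table to their shared cases.

    Matching is on the case-level barcode prefix.  When a case has several
    aliquots inside one input, the lexicographically smallest full barcode is
    retained.  The bundle's shared sample id for a case is the smallest full
    barcode seen in any *expression* layer (so sample-type codes survive
    harmonization); cases are ordered by sorted id.  Samples with missing
    survival time are dropped with a warning.
    """
    if not layers:
        raise OmicsIOError("harmonize needs at least one layer")
    layer_maps = {name: _case_map(m.sample_ids) for name, m in layers.items()}
    clin_map = _case_map(clinical.sample_ids)

    common = set(clin_map)
    for cm in layer_maps.values():
        common &= set(cm)

    # drop cases with missing survival time
    tpos = {s: i for i, s in enumerate(clinical.sample_ids)}
    missing = {c for c in common if not np.isfinite(clinical.time[tpos[clin_map[c]]])}
    if missing:
        logger.warning(
            "dropping %d case(s) with missing survival time: %s",
            len(missing),
            sorted(missing),
        )
        common -= missing

    if not common:
        counts = {name: m.n_samples for name, m in layers.items()}
        counts["clinical"] = clinical.n_samples
        raise OmicsIOError(
            f"no cases shared across inputs (per-input sample counts: {counts})"
        )

    # canonical shared id per case: smallest full barcode among the layers
    canon: dict[str, str] = {}
    for c in sorted(common):
        candidates = [layer_maps[name][c] for name in layers]
        canon[c] = min(candidates)
    order = sorted(common, key=lambda c: canon[c])
    shared_ids = [canon[c] for c in order]

    new_layers: dict[str, ExpressionMatrix] = {}
    for name, m in layers.items():
        rows = m.subset_samples([layer_maps[name][c] for c in order])
        new_layers[name] = ExpressionMatrix(
            rows.values, shared_ids, rows.feature_ids, rows.layer
        )
    clin_rows = clinical.subset([clin_map[c] for c in order])
    new_clin = ClinicalTable(shared_ids, clin_rows.time, clin_rows.event)
    return CohortBundle(new_layers, new_clin)
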