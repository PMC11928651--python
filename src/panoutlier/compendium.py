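"""Expression-compendium containers and on-disk formats.

The working unit is a genes x samples matrix of log2(TPM+1) expression values
with a per-sample metadata table (disease label, age at diagnosis, data
source, QC status).  Expression is assumed to be already normalized and
log-transformed upstream; this package performs no re-normalization.

On-disk formats are deliberately plain: tab-separated matrices with gene ids
in the first column and sample ids in the header row, named-column TSV
metadata, one-gene-per-line lists ('#' comments allowed), and standard GMT
gene-set collections.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SOURCES = ("tcga", "institution", "other")
VALID_QC = ("pass", "fail")


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations used for cohort construction."""

    sample_id: str
    disease: str
    age_at_diagnosis: Optional[float] = None
    source: str = "other"
    qc_status: str = "pass"

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.disease or not self.disease.strip():
            raise ValueError(f"sample {self.sample_id!r}: disease label must be non-empty")
        if self.age_at_diagnosis is not None and self.age_at_diagnosis < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: age_at_diagnosis must be >= 0, "
                f"got {self.age_at_diagnosis}"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"sample {self.sample_id!r}: source must be one of {VALID_SOURCES}, "
                f"got {self.source!r}"
            )
        if self.qc_status not in VALID_QC:
            raise ValueError(
                f"sample {self.sample_id!r}: qc_status must be one of {VALID_QC}, "
                f"got {self.qc_status!r}"
            )


class ExpressionCompendium:
    """A genes x samples expression matrix plus optional sample metadata.

    Hard invariants enforced at construction: unique gene and sample
    identifiers, all values finite, metadata keys (when present) exactly
    matching the sample columns.  Softer data-quality checks (negative
    values, all-zero samples, singleton disease labels) are reported by
    :func:`validate_compendium` rather than raised.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        metadata: Optional[Mapping[str, SampleMetadata] | Iterable[SampleMetadata]] = None,
    ) -> None:
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifier(s): {dup}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifier(s): {dup}")
        arr = values.to_numpy(dtype=float, copy=False)
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
        self.values = values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)

        if metadata is None:
            self.metadata: Optional[Dict[str, SampleMetadata]] = None
        else:
            if not isinstance(metadata, Mapping):
                metadata = {m.sample_id: m for m in metadata}
            meta = dict(metadata)
            missing = [s for s in self.values.columns if s not in meta]
            extra = [s for s in meta if s not in set(self.values.columns)]
            if missing:
                raise ValueError(f"metadata missing for sample(s): {missing}")
            if extra:
                raise ValueError(f"metadata for unknown sample(s): {extra}")
            # keep metadata in matrix column order
            self.metadata = {s: meta[s] for s in self.values.columns}

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def profile(self, sample: str) -> pd.Series:
        if sample not in self.values.columns:
            raise KeyError(f"unknown sample {sample!r}")
        return self.values[sample]

    def meta(self, sample: str) -> SampleMetadata:
        if self.metadata is None:
            raise ValueError("compendium has no metadata")
        return self.metadata[sample]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionCompendium":
        samples = list(samples)
        unknown = [s for s in samples if s not in set(self.values.columns)]
        if unknown:
            raise KeyError(f"unknown sample(s): {unknown}")
        meta = None
        if self.metadata is not None:
            meta = {s: self.metadata[s] for s in samples}
        return ExpressionCompendium(self.values[samples].copy(), meta)

    def copy(self) -> "ExpressionCompendium":
        meta = dict(self.metadata) if self.metadata is not None else None
        return ExpressionCompendium(self.values.copy(), meta)

    def focus_profile(self, sample: str) -> "FocusProfile":
        qc = "pass"
        if self.metadata is not None:
            qc = self.metadata[sample].qc_status
        return FocusProfile(sample_id=sample, expression=self.profile(sample), qc_status=qc)


@dataclass
class FocusProfile:
    """One sample's expression vector, analyzed against comparator cohorts."""

    sample_id: str
    expression: pd.Series
    qc_status: str = "pass"


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. an MSigDB collection) with an optional universe."""

    sets: Dict[str, frozenset]
    universe: Optional[frozenset] = None

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and self.universe == other.universe


# -- expression matrix I/O ---------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionCompendium:
    """Read a genes x samples TSV (gene ids in column 1, sample ids in row 1)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: no data rows")
    header = text.splitlines()[0].rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dup = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample identifier(s) in header: {dup}")
    try:
        raw = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample identifier(s) in header: {dup}")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene identifier(s): {dup}")
    def _parse(cell):
        # Python's float() is correctly rounded, so write-then-read
        # reproduces values bit-identically
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return np.nan
        try:
            return float(cell)
        except (TypeError, ValueError):
            return np.nan

    numeric = raw.apply(lambda col: col.map(_parse))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[gi, si]!r} at gene "
            f"{raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {raw.index[gi]!r}, sample {raw.columns[si]!r}"
        )
    return ExpressionCompendium(numeric)


def write_expression_matrix(c: ExpressionCompendium, path: str | Path) -> None:
    df = c.values.copy()
    df.index.name = "gene"
    # str(float) is the shortest round-tripping representation in Python 3,
    # so write-then-read reproduces values bit-identically.
    df.to_csv(path, sep="\t")


# -- metadata I/O ------------------------------------------------------------

_REQUIRED_META_COLS = ("sample_id", "disease")
_OPTIONAL_META_COLS = ("age_at_diagnosis", "source", "qc_status")


def read_metadata(path: str | Path) -> List[SampleMetadata]:
    """Read a named-column metadata TSV.

    Required columns: sample_id, disease.  Optional: age_at_diagnosis,
    source, qc_status.  Blank optional cells are recorded as absent (age) or
    as the defaults source=other, qc_status=pass.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required metadata column(s): {missing}")
    out: List[SampleMetadata] = []
    for i, row in df.iterrows():
        age: Optional[float] = None
        raw_age = row.get("age_at_diagnosis")
        if raw_age is not None and not pd.isna(raw_age) and str(raw_age).strip():
            try:
                age = float(raw_age)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric age_at_diagnosis {raw_age!r} on row {i + 1}"
                ) from None
        source = row.get("source")
        source = str(source).strip() if source is not None and not pd.isna(source) else ""
        qc = row.get("qc_status")
        qc = str(qc).strip() if qc is not None and not pd.isna(qc) else ""
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]).strip(),
                disease=str(row["disease"]).strip(),
                age_at_diagnosis=age,
                source=source or "other",
                qc_status=qc or "pass",
            )
        )
    ids = [m.sample_id for m in out]
    if len(ids) != len(set(ids)):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"{path}: duplicate sample_id(s) in metadata: {dup}")
    return out


def write_metadata(metadata: Iterable[SampleMetadata], path: str | Path) -> None:
    rows = []
    for m in metadata:
        rows.append(
            {
                "sample_id": m.sample_id,
                "disease": m.disease,
                "age_at_diagnosis": "" if m.age_at_diagnosis is None else m.age_at_diagnosis,
                "source": m.source,
                "qc_status": m.qc_status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_compendium(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionCompendium:
    c = read_expression_matrix(matrix_path)
    meta = read_metadata(metadata_path)
    return ExpressionCompendium(c.values, meta)


# -- gene lists and gene sets ------------------------------------------------


def read_gene_list(path: str | Path) -> List[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes: List[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        g = line.split("#", 1)[0].strip()
        if not g:
            continue
        if g in seen:
            logger.warning("duplicate gene %r in list %s; keeping first", g, path)
            continue
        seen.add(g)
        genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: name, description, members (tab-separated)."""
    sets: Dict[str, frozenset] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields "
                f"(name, description, members), got {len(fields)}"
            )
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}: line {lineno}: duplicate gene-set name {name!r}")
        members = [g for g in fields[2:] if g.strip()]
        if len(members) != len(set(members)):
            logger.warning(
                "%s: line %d: duplicate member(s) within set %r; deduplicated",
                path,
                lineno,
                name,
            )
        sets[name] = frozenset(members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in sorted(collection.sets):
        members = sorted(collection.sets[name])
        lines.append("\t".join([name, "na"] + members))
    Path(path).write_text("".join(f"{ln}\n" for ln in lines))


# -- validation --------------------------------------------------------------


def validate_compendium(
    c: ExpressionCompendium,
    metadata: Optional[Iterable[SampleMetadata]] = None,
) -> List[str]:
    """Report data-quality issues without raising.

    Checks: negative expression values, all-zero samples, disease labels
    carried by a single sample, and metadata/matrix mismatches.  An external
    ``metadata`` list may be supplied to check against the matrix columns
    (e.g. before attaching it); otherwise the compendium's own metadata is
    used.
    """
    issues: List[str] = []
    arr = c.values.to_numpy()
    if arr.size:
        neg = np.argwhere(arr < 0)
        for gi, si in neg[:20]:
            issues.append(
                f"negative expression value {arr[gi, si]:g} at gene "
                f"{c.genes[gi]!r}, sample {c.samples[si]!r}"
            )
        if len(neg) > 20:
            issues.append(f"... and {len(neg) - 20} further negative values")
        zero_samples = [s for s, col in zip(c.samples, (arr == 0).all(axis=0)) if col]
        for s in zero_samples:
            issues.append(f"sample {s!r} has zero expression for every gene")

    meta_map: Optional[Dict[str, SampleMetadata]]
    if metadata is not None:
        meta_map = {m.sample_id: m for m in metadata}
        for s in c.samples:
            if s not in meta_map:
                issues.append(f"sample {s!r} in matrix is missing from metadata")
        for s in meta_map:
            if s not in set(c.samples):
                issues.append(f"metadata row {s!r} matches no matrix column")
    else:
        meta_map = c.metadata

    if meta_map is not None:
        counts: Dict[str, int] = {}
        for m in meta_map.values():
            counts[m.disease] = counts.get(m.disease, 0) + 1
        for disease, n in sorted(counts.items()):
            if n == 1:
                issues.append(f"disease label {disease!r} has only a single sample")
    else:
        issues.append("compendium has no sample metadata")
    return issues
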