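"""Count-table data model, sample metadata, taxonomy, and basic transforms.

The central container is :class:`FeatureTable`, a taxa x samples matrix of
non-negative integer counts with unique identifiers on both axes — the
in-memory form of an ASV (amplicon sequence variant) table.  Sample-level
metadata lives in :class:`SampleRecord` objects (batch, sequencing run,
sample type, DNA concentration); taxonomy in :class:`TaxonAnnotation`
(7-rank lineage, missing ranks explicit).

I/O covers wide TSV (taxa rows, sample columns) and dense BIOM-JSON 1.0.0,
plus metadata and taxonomy TSVs.  Transforms: per-group prevalence,
relative abundance, lineage-rule filtering (off-target organelle and
unassigned reads) and aggregation to a taxonomic rank.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

SAMPLE_TYPES = frozenset(
    {"biological", "negative_control", "mock", "biological_control"}
)

#: lineage-based removal rules: (rank, case-insensitive substring) pairs.
#: "unassigned" at kingdom is handled specially (empty / bare-prefix labels
#: also count as unassigned).
DEFAULT_LINEAGE_RULES = (
    ("kingdom", "unassigned"),
    ("phylum", "cyanobacteria"),
    ("family", "mitochondria"),
    ("class", "chloroplast"),
)


class ValidationError(ValueError):
    """Input violates a structural invariant (duplicates, bad category...)."""


class ParseError(ValueError):
    """File content cannot be interpreted (non-integer cell, missing column)."""


@dataclass
class FeatureTable:
    """Taxa x samples matrix of non-negative integer counts.

    Parameters
    ----------
    taxon_ids : sequence of str
        Row identifiers, unique.
    sample_ids : sequence of str
        Column identifiers, unique.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integers.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValidationError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            t, s = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at taxon {self.taxon_ids[t]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))
                raise ValidationError(f"duplicate {name} identifier {dup!r}")
        self.counts = counts
        self._taxon_index = {t: i for i, t in enumerate(self.taxon_ids)}
        self._sample_index = {s: i for i, s in enumerate(self.sample_ids)}

    # -- shape / access ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=self.sample_ids)

    def taxon_totals(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=self.taxon_ids)

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown sample identifier {e.args[0]!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    # -- subsetting -------------------------------------------------------

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        idx = self.sample_indices(sample_ids)
        return FeatureTable(list(self.taxon_ids), list(sample_ids), self.counts[:, idx])

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "FeatureTable":
        try:
            idx = [self._taxon_index[t] for t in taxon_ids]
        except KeyError as e:
            raise KeyError(f"unknown taxon identifier {e.args[0]!r}") from None
        return FeatureTable(list(taxon_ids), list(self.sample_ids), self.counts[idx, :])

    def drop_taxa(self, taxon_ids: Iterable[str]) -> "FeatureTable":
        drop = set(taxon_ids)
        keep = [t for t in self.taxon_ids if t not in drop]
        return self.subset_taxa(keep)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class SampleRecord:
    """Per-sample metadata: batch, sequencing run, type, DNA concentration."""

    sample_id: str
    batch: str
    run: str
    sample_type: str
    dna_concentration: float | None = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sample_type {self.sample_type!r} "
                f"not one of {sorted(SAMPLE_TYPES)}"
            )
        if self.dna_concentration is not None:
            if not np.isfinite(self.dna_concentration) or self.dna_concentration <= 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: dna_concentration must be > 0, "
                    f"got {self.dna_concentration}"
                )


@dataclass
class TaxonAnnotation:
    """7-rank lineage (kingdom..species); missing ranks are 'unassigned'."""

    taxon_id: str
    lineage: tuple[str, ...] = field(default_factory=lambda: ("unassigned",) * 7)

    def __post_init__(self) -> None:
        self.lineage = tuple(str(r) for r in self.lineage)
        if len(self.lineage) != len(RANKS):
            raise ValidationError(
                f"taxon {self.taxon_id!r}: lineage must have {len(RANKS)} ranks, "
                f"got {len(self.lineage)}"
            )

    def rank(self, name: str) -> str:
        return self.lineage[RANKS.index(name)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, format: str = "tsv") -> FeatureTable:
    """Read a count table from wide TSV or dense BIOM-JSON.

    TSV dialect: first column taxon id, header row of sample ids,
    tab-separated integer cells.  Axis order is preserved from the file.
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}; use 'tsv' or 'biom_json'")


def _read_tsv(path: Path) -> FeatureTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        seen: set[str] = set()
        dup = next(h for h in header if h in seen or seen.add(h))
        raise ValidationError(f"{path}: duplicate sample identifier {dup!r} in header")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    sample_ids = list(df.columns)
    taxon_ids = [str(i) for i in df.index]
    counts = np.zeros((len(taxon_ids), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        col = df[s]
        for i, raw in enumerate(col):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-integer count {raw!r} at taxon "
                    f"{taxon_ids[i]!r}, sample {s!r}"
                ) from None
            if v < 0:
                raise ParseError(
                    f"{path}: negative count at taxon {taxon_ids[i]!r}, sample {s!r}"
                )
            counts[i, j] = v
    return FeatureTable(taxon_ids, sample_ids, counts)


def write_feature_table(table: FeatureTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="taxon_id")
    elif format == "biom_json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "contamqc",
            "date": "1970-01-01T00:00:00",
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [table.n_taxa, table.n_samples],
            "data": table.counts.tolist(),
        }
        path.write_text(json.dumps(doc))
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom_json(path: Path) -> FeatureTable:
    doc = json.loads(Path(path).read_text())
    taxon_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if doc.get("matrix_type") == "dense":
        counts = np.asarray(doc["data"])
    elif doc.get("matrix_type") == "sparse":
        counts = np.zeros((len(taxon_ids), len(sample_ids)))
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unsupported matrix_type {doc.get('matrix_type')!r}")
    if not np.allclose(counts, np.round(counts)) or (counts < 0).any():
        raise ParseError(f"{path}: counts must be non-negative integers")
    return FeatureTable(taxon_ids, sample_ids, counts.astype(np.int64))


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata TSV.

    Required columns: sample_id, batch, run, sample_type.
    Optional: dna_concentration (empty / NA allowed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "batch", "run", "sample_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    records = []
    for _, row in df.iterrows():
        dna: float | None = None
        if "dna_concentration" in df.columns:
            raw = row["dna_concentration"]
            if raw is not None and not pd.isna(raw) and str(raw).strip() not in ("", "NA"):
                dna = float(raw)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                batch=str(row["batch"]),
                run=str(row["run"]),
                sample_type=str(row["sample_type"]),
                dna_concentration=dna,
            )
        )
    return records


def write_metadata(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "batch": r.batch,
            "run": r.run,
            "sample_type": r.sample_type,
            "dna_concentration": "" if r.dna_concentration is None else repr(r.dna_concentration),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def metadata_by_id(records: Iterable[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}


def read_taxonomy(path: str | Path) -> list[TaxonAnnotation]:
    """Read taxonomy TSV: taxon_id column plus the 7 rank columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unassigned")
    missing = [c for c in ("taxon_id", *RANKS) if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return [
        TaxonAnnotation(str(row["taxon_id"]), tuple(str(row[r]) for r in RANKS))
        for _, row in df.iterrows()
    ]


def write_taxonomy(annotations: Iterable[TaxonAnnotation], path: str | Path) -> None:
    rows = [
        {"taxon_id": a.taxon_id, **dict(zip(RANKS, a.lineage))} for a in annotations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def prevalence(
    table: FeatureTable,
    sample_subset: Iterable[str] | None = None,
    detection_threshold: int = 1,
) -> pd.Series:
    """Fraction of subset samples in which each taxon is detected.

    Detection means count >= ``detection_threshold`` (default 1 read).
    """
    if detection_threshold < 1:
        raise ValueError("detection_threshold must be >= 1")
    if sample_subset is None:
        sub = table.counts
        n = table.n_samples
    else:
        idx = table.sample_indices(sample_subset)
        if idx.size == 0:
            raise ValueError("sample_subset is empty")
        sub = table.counts[:, idx]
        n = idx.size
    if n == 0:
        raise ValueError("sample_subset is empty")
    frac = (sub >= detection_threshold).sum(axis=1) / n
    return pd.Series(frac, index=table.taxon_ids, name="prevalence")


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample relative abundances; columns sum to 1.

    Samples with zero total are excluded with a logged warning rather than
    raising — rarefaction drops shallow samples downstream anyway.
    """
    totals = table.counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        dropped = [s for s, z in zip(table.sample_ids, zero) if z]
        logger.warning("relative_abundance: dropping zero-total samples %s", dropped)
    keep = ~zero
    cols = [s for s, k in zip(table.sample_ids, keep) if k]
    rel = table.counts[:, keep] / totals[keep]
    return pd.DataFrame(rel, index=table.taxon_ids, columns=cols)


def _normalize_label(label: str) -> str:
    """Strip Greengenes-style rank prefixes ('k__', 'f__'...) and whitespace."""
    label = label.strip()
    if len(label) >= 3 and label[1:3] == "__":
        label = label[3:]
    return label.lower()


def _is_unassigned(label: str) -> bool:
    return _normalize_label(label) in ("", "unassigned", "unclassified", "na")


def filter_taxa_by_lineage(
    table: FeatureTable,
    annotations: Iterable[TaxonAnnotation],
    rules: Sequence[tuple[str, str]] = DEFAULT_LINEAGE_RULES,
) -> tuple[FeatureTable, list[str]]:
    """Remove off-target taxa by lineage rules; return (kept table, removed ids).

    Default rules drop unassigned-kingdom taxa, phylum Cyanobacteria,
    family mitochondria and class chloroplast (case-insensitive substring
    match on the designated rank, robust to 'f__'-style prefixes).
    """
    ann = {a.taxon_id: a for a in annotations}
    unannotated = [t for t in table.taxon_ids if t not in ann]
    if unannotated:
        raise ValidationError(f"unannotated taxa: {unannotated}")
    removed = []
    for t in table.taxon_ids:
        lineage = ann[t]
        for rank_name, term in rules:
            label = lineage.rank(rank_name)
            if term == "unassigned":
                hit = _is_unassigned(label)
            else:
                hit = term in _normalize_label(label)
            if hit:
                removed.append(t)
                break
    return table.drop_taxa(removed), removed


def aggregate_by_rank(
    table: FeatureTable,
    annotations: Iterable[TaxonAnnotation],
    rank: str,
) -> FeatureTable:
    """Sum counts over taxa sharing a label at ``rank``.

    Unassigned labels at that rank pool under a single 'unassigned' key;
    per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    ann = {a.taxon_id: a for a in annotations}
    labels = []
    for t in table.taxon_ids:
        if t not in ann:
            raise ValidationError(f"unannotated taxon {t!r}")
        label = ann[t].rank(rank)
        labels.append("unassigned" if _is_unassigned(label) else label)
    df = table.to_dataframe()
    df.index = pd.Index(labels)
    agg = df.groupby(level=0, sort=True).sum()
    return FeatureTable(list(agg.index), list(agg.columns), agg.to_numpy())
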