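"""Readers, writers and identifier mapping for metabolomics matrices.

The in-memory containers are thin wrappers around pandas objects:
:class:`MetaboliteMatrix` holds a samples x metabolites intensity frame
(NaN marks a missing measurement), :class:`PathwayDatabase` the
pathway -> member-metabolite mapping plus a free-text-name -> standard-ID
dictionary, and :class:`FeatureMapping` the result of matching matrix
columns against that database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteMatrix",
    "SurvivalData",
    "PathwayDatabase",
    "FeatureMapping",
    "read_metabolite_matrix",
    "write_metabolite_matrix",
    "read_pathway_db",
    "map_features",
    "read_survival",
]


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites intensity matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric frame, rows = samples, columns = metabolite features.
        Missing measurements are NaN; :attr:`missing_mask` exposes them
        as a boolean frame.
    labels : pandas.Series, optional
        Per-sample categorical phenotype (e.g. case/control), indexed
        like ``values``.
    """

    values: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("empty metabolite matrix")
        dup_s = self.values.index[self.values.index.duplicated()].unique().tolist()
        dup_f = self.values.columns[self.values.columns.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample IDs: {dup_s}")
        if dup_f:
            raise ValueError(f"duplicate feature IDs: {dup_f}")
        self.values = self.values.astype(float)
        if self.labels is not None:
            self.labels = self.labels.reindex(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.values.columns]

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(),
            None if self.labels is None else self.labels.copy(),
        )


@dataclass
class SurvivalData:
    """Right-censored survival outcomes aligned with sample IDs.

    ``time`` is nonnegative follow-up time (one consistent unit);
    ``event`` is 1 when the event (e.g. death) was observed, 0 when the
    sample was censored.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise ValueError("sample_ids, time and event must be aligned 1:1")
        if np.any(self.time < 0):
            raise ValueError("negative survival times")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalData":
        ids = [self.sample_ids[i] for i in np.atleast_1d(idx)]
        return SurvivalData(ids, self.time[idx], self.event[idx])


@dataclass
class PathwayDatabase:
    """Pathway membership sets plus a metabolite-name dictionary.

    ``pathways`` maps pathway ID -> set of standard metabolite IDs;
    ``name_map`` maps free-text metabolite names (as they appear in
    matrix headers) to those standard IDs.  When no dictionary is
    supplied the identity map is assumed, i.e. matrix columns are
    already standard IDs.
    """

    pathways: dict[str, set[str]]
    name_map: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has an empty member set")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.pathways)


@dataclass
class FeatureMapping:
    """Outcome of matching matrix features against a pathway database.

    ``mapped`` sends matrix feature IDs to standard metabolite IDs,
    ``unmapped`` lists features with no match, and ``pathway_cover``
    gives, per retained pathway, the matrix feature IDs it contains.
    """

    mapped: dict[str, str]
    unmapped: list[str]
    pathway_cover: dict[str, list[str]]


def _normalize_name(name: str) -> str:
    return str(name).strip().casefold()


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","


def read_metabolite_matrix(
    path: str | Path,
    orientation: str = "samples_in_rows",
    label_column: str | None = None,
    delimiter: str | None = None,
) -> MetaboliteMatrix:
    """Read a delimited intensity matrix into samples-in-rows form.

    The first column holds IDs, the header holds the other axis.  Any
    cell that does not parse as a number is flagged missing.  With
    ``orientation='samples_in_columns'`` the file is transposed after
    reading, so the returned matrix is always samples x metabolites.
    """
    path = Path(path)
    if orientation not in {"samples_in_rows", "samples_in_columns"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    raw = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0, dtype=str)
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ValueError(f"{path}: empty matrix")
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "samples_in_columns":
        raw = raw.T
    raw.index.name = None
    raw.columns.name = None
    labels = None
    if label_column is not None:
        if label_column not in raw.columns:
            raise ValueError(f"label column {label_column!r} not found")
        labels = raw[label_column].astype(str)
        raw = raw.drop(columns=[label_column])
    values = raw.apply(pd.to_numeric, errors="coerce")
    return MetaboliteMatrix(values, labels)


def write_metabolite_matrix(
    matrix: MetaboliteMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix (samples in rows); missing entries serialize as NA."""
    path = Path(path)
    out = matrix.values.copy()
    if matrix.labels is not None:
        out = out.assign(label=matrix.labels)
    out.to_csv(path, sep=_delimiter_for(path, delimiter), na_rep="NA")


def read_survival(
    path: str | Path,
    time_column: str = "time",
    event_column: str = "event",
    delimiter: str | None = None,
) -> SurvivalData:
    """Read per-sample (time, event) pairs from a delimited table."""
    path = Path(path)
    tab = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    return SurvivalData(
        [str(s) for s in tab.index],
        tab[time_column].to_numpy(dtype=float),
        tab[event_column].to_numpy(dtype=int),
    )


def read_pathway_db(
    gmt_path: str | Path, name_map_path: str | Path | None = None
) -> PathwayDatabase:
    """Read a GMT pathway file and an optional two-column name map.

    GMT lines are tab-delimited ``pathway<TAB>description<TAB>member...``.
    Lines with fewer than three fields are skipped with a warning.
    """
    gmt_path = Path(gmt_path)
    pathways: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line with <3 fields skipped", gmt_path, lineno)
                continue
            pid, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                logger.warning("%s:%d: GMT line with no members skipped", gmt_path, lineno)
                continue
            pathways[pid] = set(members)
            descriptions[pid] = desc
    if n_lines == 0:
        raise ValueError(f"{gmt_path}: empty GMT file")
    name_map: dict[str, str] = {}
    if name_map_path is not None:
        nm = pd.read_csv(name_map_path, sep="\t", header=None, dtype=str)
        for name, std in zip(nm.iloc[:, 0], nm.iloc[:, 1]):
            name_map[_normalize_name(name)] = str(std)
    return PathwayDatabase(pathways, name_map, descriptions)


def map_features(
    matrix: MetaboliteMatrix, db: PathwayDatabase, min_size: int = 3
) -> FeatureMapping:
    """Match matrix feature names to standard IDs and cover pathways.

    Matching is exact after case-folding and whitespace trimming.  A
    pathway enters ``pathway_cover`` only when at least ``min_size`` of
    its members are present in the matrix (a principal curve through
    fewer than three points is degenerate, hence the default of 3).
    """
    lookup = {_normalize_name(k): v for k, v in db.name_map.items()}
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for feat in matrix.feature_ids:
        key = _normalize_name(feat)
        if key in lookup:
            mapped[feat] = lookup[key]
        elif db.name_map:
            unmapped.append(feat)
        else:
            # identity map: the matrix columns are standard IDs already
            mapped[feat] = feat
    if not mapped:
        raise ValueError("no matrix feature mapped to a standard metabolite ID")
    pathway_cover: dict[str, list[str]] = {}
    for pid, members in db.pathways.items():
        # keep the matrix's feature order
        feats = [f for f in matrix.feature_ids if mapped.get(f) in members]
        if len(feats) >= min_size:
            pathway_cover[pid] = feats
    logger.info(
        "feature mapping: %d mapped, %d unmapped, %d pathways covered (min_size=%d)",
        len(mapped), len(unmapped), len(pathway_cover), min_size,
    )
    return FeatureMapping(mapped, unmapped, pathway_cover)
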