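"""Downstream pathway analysis.

Ranks pathway scores by information gain against the phenotype,
regresses each pathway's dysregulation score on its member metabolites
one at a time (both z-scored, so the slope is the Pearson
correlation), exports the significant pathway-metabolite associations
as a bipartite graph, and tabulates per-metabolite log2 fold changes
between phenotype groups keyed by standard compound ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureMapping, MetaboliteMatrix
from .pds import PDSMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionRecord",
    "select_top_pathways",
    "information_gain",
    "pathway_metabolite_regression",
    "export_bipartite",
    "pathway_foldchange_table",
]


@dataclass
class RegressionRecord:
    """One pathway ~ metabolite simple regression result."""

    pathway_id: str
    metabolite_id: str
    coefficient: float
    p_value: float
    significant: bool


def information_gain(x: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """Information gain (bits) of a label given x discretized into
    equal-frequency bins."""
    labels = np.asarray(labels)
    x = np.asarray(x, dtype=float)
    binned = pd.qcut(x, q=bins, labels=False, duplicates="drop")

    def entropy(y) -> float:
        _, counts = np.unique(y, return_counts=True)
        p = counts / counts.sum()
        return float(-(p * np.log2(p)).sum())

    h = entropy(labels)
    cond = 0.0
    for b in np.unique(binned):
        sel = binned == b
        cond += sel.mean() * entropy(labels[sel])
    return h - cond


def select_top_pathways(
    pds: PDSMatrix, labels, k: int = 10, bins: int = 10
) -> list[str]:
    """Rank pathways by information gain between label and discretized
    PDS; returns the top k (ties broken by pathway ID)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if k > len(pds.pathway_ids):
        logger.warning("k=%d exceeds the %d pathways; returning all", k, len(pds.pathway_ids))
        k = len(pds.pathway_ids)
    gains = {
        pid: information_gain(pds.scores[pid].to_numpy(), labels, bins=bins)
        for pid in pds.pathway_ids
    }
    ranked = sorted(gains, key=lambda pid: (-gains[pid], pid))
    return ranked[:k]


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def pathway_metabolite_regression(
    pds: PDSMatrix,
    matrix: MetaboliteMatrix,
    mapping: FeatureMapping,
    pathways: list[str] | None = None,
    fdr: str | None = None,
) -> list[RegressionRecord]:
    """Simple regression of each pathway's PDS on each member metabolite.

    Both variables are z-scored, so the slope equals the Pearson
    correlation; significance is raw p < 0.05 by default, with an
    optional Benjamini-Hochberg correction (``fdr='bh'``).
    """
    if list(pds.scores.index) != list(matrix.values.index):
        raise ValueError("PDS and metabolite matrix sample order differ")
    if pathways is None:
        pathways = pds.pathway_ids
    records: list[RegressionRecord] = []
    for pid in pathways:
        if pid not in pds.scores.columns or pid not in mapping.pathway_cover:
            continue
        y = pds.scores[pid].to_numpy(dtype=float)
        if y.std(ddof=1) == 0:
            logger.warning("pathway %s has constant PDS; skipped", pid)
            continue
        yz = _zscore(y)
        for feat in mapping.pathway_cover[pid]:
            x = matrix.values[feat].to_numpy(dtype=float)
            if x.std(ddof=1) == 0:
                logger.warning("metabolite %s has zero variance; record skipped", feat)
                continue
            res = stats.linregress(_zscore(x), yz)
            records.append(
                RegressionRecord(
                    pathway_id=pid,
                    metabolite_id=mapping.mapped.get(feat, feat),
                    coefficient=float(res.slope),
                    p_value=float(res.pvalue),
                    significant=bool(res.pvalue < 0.05),
                )
            )
    if fdr == "bh" and records:
        rej, _, _, _ = multipletests([r.p_value for r in records], alpha=0.05, method="fdr_bh")
        for r, keep in zip(records, rej):
            r.significant = bool(keep)
    return records


def export_bipartite(
    records: list[RegressionRecord], path: str | Path
) -> nx.Graph:
    """Write significant associations as GraphML plus an edge-list CSV.

    Pathways and metabolites form the two node classes; each edge
    carries ``weight`` = |coefficient| (edge thickness) and ``sign``.
    """
    path = Path(path)
    g = nx.Graph()
    sig = [r for r in records if r.significant]
    if not sig:
        logger.warning("no significant records: writing an empty graph")
    for r in sig:
        g.add_node(f"pw::{r.pathway_id}", kind="pathway", name=r.pathway_id)
        g.add_node(f"met::{r.metabolite_id}", kind="metabolite", name=r.metabolite_id)
        g.add_edge(
            f"pw::{r.pathway_id}",
            f"met::{r.metabolite_id}",
            weight=abs(r.coefficient),
            sign="+" if r.coefficient >= 0 else "-",
            coefficient=r.coefficient,
        )
    nx.write_graphml(g, path)
    edge_rows = [
        {
            "pathway": r.pathway_id,
            "metabolite": r.metabolite_id,
            "coefficient": r.coefficient,
            "weight": abs(r.coefficient),
            "sign": "+" if r.coefficient >= 0 else "-",
        }
        for r in sig
    ]
    pd.DataFrame(
        edge_rows, columns=["pathway", "metabolite", "coefficient", "weight", "sign"]
    ).to_csv(path.with_suffix(".edges.csv"), index=False)
    return g


def pathway_foldchange_table(
    matrix: MetaboliteMatrix,
    mapping: FeatureMapping,
    labels,
    pathway_id: str,
    group1=None,
    group2=None,
) -> pd.DataFrame:
    """Per-metabolite log2 ratio of group means for one pathway.

    The table (metabolite, standard ID, log2 ratio of mean(group1) over
    mean(group2)) is the data contract replacing pathway-image
    rendering; entries with a nonpositive group mean are flagged
    undefined (NaN ratio).
    """
    labels = pd.Series(np.asarray(labels), index=matrix.values.index)
    groups = sorted(labels.unique())
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValueError("specify group1/group2 when labels are not binary")
        group2, group1 = groups  # ratio of the later-sorted class over the first
    sel1, sel2 = labels == group1, labels == group2
    if sel1.sum() == 0 or sel2.sum() == 0:
        raise ValueError("both groups must be non-empty")
    if pathway_id not in mapping.pathway_cover:
        raise ValueError(f"pathway {pathway_id!r} not covered by the mapping")
    rows = []
    for feat in mapping.pathway_cover[pathway_id]:
        m1 = float(matrix.values.loc[sel1, feat].mean())
        m2 = float(matrix.values.loc[sel2, feat].mean())
        if m1 <= 0 or m2 <= 0:
            ratio, undefined = np.nan, True
        else:
            ratio, undefined = float(np.log2(m1 / m2)), False
        rows.append(
            {
                "metabolite": feat,
                "compound_id": mapping.mapped.get(feat, feat),
                "log2_ratio": ratio,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
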