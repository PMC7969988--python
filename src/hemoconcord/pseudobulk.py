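"""Pseudo-bulk profiles, Pearson-correlation annotation, and signatures.

A pseudo-transcriptome collapses each subgroup to the arithmetic mean of
its cells' depth-normalized (pre-log) expression.  Query subgroups from
one dataset (e.g. hemocytes found inside a tissue atlas) are annotated
against a reference by the Pearson correlation of their pseudo-bulk
profiles on the shared-gene intersection, after an ``ln(1+x)``
re-transform that keeps a few very high expressers from dominating r.
The module also scores tissue clusters for canonical hemocyte-marker
expression, and extracts query-specific signatures (genes expressed
well above every reference subgroup).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClusterLabeling, NormMatrix, ValidationError

#: canonical hemocyte markers used to spot hemocyte clusters in tissue data
DEFAULT_HEMOCYTE_MARKERS = ["Srp", "Hml", "Pxn", "NimC1", "He", "Crq", "Sn"]


@dataclass
class PseudoTranscriptome:
    """Gene×subgroup mean depth-normalized expression with cell counts."""

    values: pd.DataFrame  # genes as index, subgroups as columns
    cell_counts: dict[str, int]

    @property
    def subgroups(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def column(self, subgroup: str) -> pd.Series:
        return self.values[subgroup]


@dataclass
class CorrelationTable:
    """Query×reference Pearson r with the gene counts used per pair."""

    r: pd.DataFrame  # query subgroups as index, reference as columns
    n_genes: int
    gene_policy: str = "intersection"


def pseudo_transcriptome(norm: NormMatrix, labeling: ClusterLabeling) -> PseudoTranscriptome:
    """Average depth-normalized (pre-log) expression per subgroup."""
    ex = norm.expm1()
    cols = {}
    counts = {}
    for sub in labeling.labels:
        mask = labeling.mask_for(sub, norm.cell_ids)
        if not mask.any():
            raise ValidationError(f"subgroup {sub!r} has no cells in the matrix")
        cols[sub] = ex[mask].mean(axis=0)
        counts[sub] = int(mask.sum())
    df = pd.DataFrame(cols, index=norm.gene_ids)
    return PseudoTranscriptome(values=df, cell_counts=counts)


def correlate(
    pseudo_query: PseudoTranscriptome,
    pseudo_ref: PseudoTranscriptome,
    gene_policy: str = "intersection",
    gene_list: list[str] | None = None,
) -> CorrelationTable:
    """Pearson r between every query and reference pseudo-bulk profile.

    Profiles are compared on the shared-gene intersection (optionally
    further restricted to a supplied list, e.g. the reference's highly
    variable genes) after ``ln(1+x)`` re-transform.  A zero-variance
    profile yields NaN for its pairs, with a warning.
    """
    shared = sorted(set(pseudo_query.genes) & set(pseudo_ref.genes))
    if gene_policy == "gene-list":
        if gene_list is None:
            raise ValidationError("gene_policy 'gene-list' requires gene_list")
        shared = sorted(set(shared) & set(gene_list))
    elif gene_policy != "intersection":
        raise ValidationError(f"unknown gene_policy {gene_policy!r}")
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared genes; need >= 3")

    Q = np.log1p(pseudo_query.values.loc[shared].to_numpy(float))
    R = np.log1p(pseudo_ref.values.loc[shared].to_numpy(float))

    def _standardize(M: np.ndarray) -> np.ndarray:
        Mc = M - M.mean(axis=0, keepdims=True)
        sd = np.sqrt((Mc**2).sum(axis=0))
        zero = sd == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} zero-variance pseudo-bulk profiles; r reported as NaN")
        sd[zero] = np.nan
        return Mc / sd

    r = _standardize(Q).T @ _standardize(R)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationTable(
        r=pd.DataFrame(r, index=pseudo_query.subgroups, columns=pseudo_ref.subgroups),
        n_genes=len(shared),
        gene_policy=gene_policy,
    )


def annotate_best_match(ct: CorrelationTable, top_k: int = 3) -> pd.DataFrame:
    """Rank reference subgroups per query by r.

    Returns one row per (query, rank) with the correlation, the margin
    to the next-ranked reference (NaN when there is none), and a tie
    flag.  Exact ties are broken lexicographically on the reference
    name, deterministically.
    """
    rows = []
    for q in ct.r.index:
        series = ct.r.loc[q].dropna()
        ordered = series.sort_index().sort_values(ascending=False, kind="stable")
        for rank in range(min(top_k, len(ordered))):
            ref = ordered.index[rank]
            r = float(ordered.iloc[rank])
            nxt = float(ordered.iloc[rank + 1]) if rank + 1 < len(ordered) else np.nan
            rows.append(
                {
                    "query": q,
                    "rank": rank + 1,
                    "reference": ref,
                    "r": r,
                    "margin": r - nxt if np.isfinite(nxt) else np.nan,
                    "tie": bool(np.isfinite(nxt) and r == nxt)
                    or (rank > 0 and float(ordered.iloc[rank - 1]) == r),
                }
            )
    return pd.DataFrame(rows, columns=["query", "rank", "reference", "r", "margin", "tie"])


def identify_hemocyte_cluster(
    pseudo: PseudoTranscriptome,
    canonical_markers: list[str] | None = None,
    score_min: float = 0.9,
) -> tuple[list[str], pd.DataFrame]:
    """Spot hemocyte clusters in a tissue dataset by canonical markers.

    Each cluster is scored as the mean, over markers, of the cluster's
    expression quantile for that marker across clusters (0 = lowest,
    1 = highest; midranked under ties).  Clusters pass when the score is
    at least ``score_min`` and they hold the per-gene maximum for at
    least half the informative markers.  The per-cluster per-marker
    evidence table is always returned.
    """
    markers = canonical_markers or DEFAULT_HEMOCYTE_MARKERS
    if not markers:
        raise ValidationError("canonical marker list is empty")
    present = [m for m in markers if m in pseudo.values.index]
    informative = [m for m in present if pseudo.values.loc[m].max() > 0]
    missing = sorted(set(markers) - set(present))
    if missing:
        warnings.warn(f"canonical markers absent from matrix: {missing}")
    clusters = pseudo.subgroups
    rows = []
    if not informative:
        warnings.warn("no canonical hemocyte marker expressed in any cluster")
        return [], pd.DataFrame(columns=["cluster", "marker", "expression", "quantile", "is_max"])

    K = len(clusters)
    for m in informative:
        vals = pseudo.values.loc[m]
        ranks = vals.rank(method="average")  # 1..K, midrank ties
        quantile = (ranks - 1) / (K - 1) if K > 1 else pd.Series(1.0, index=vals.index)
        vmax = vals.max()
        for c in clusters:
            rows.append(
                {
                    "cluster": c,
                    "marker": m,
                    "expression": float(vals[c]),
                    "quantile": float(quantile[c]),
                    "is_max": bool(vals[c] == vmax),
                }
            )
    evidence = pd.DataFrame(rows)
    scores = evidence.groupby("cluster")["quantile"].mean()
    n_max = evidence.groupby("cluster")["is_max"].sum()
    passing = [
        c
        for c in clusters
        if scores[c] >= score_min and n_max[c] >= len(informative) / 2.0
    ]
    if not passing:
        warnings.warn("no cluster passes the hemocyte-marker criteria")
    return passing, evidence


def specific_signature(
    pseudo_query: pd.Series,
    pseudo_ref: pd.DataFrame,
    query_pct: pd.Series,
    fold_min: float = 2.0,
    detect_min: float = 0.5,
) -> pd.DataFrame:
    """Genes specifically expressed in the query vs every reference subgroup.

    A gene qualifies when its query pseudo-bulk expression, with a
    pseudocount of 1 on the depth-normalized scale, is at least
    ``fold_min`` times the maximum over all reference subgroups
    (boundary inclusive) and it is detected in at least ``detect_min``
    of query cells.  Sorted by the fold ratio, descending.
    """
    shared = sorted(set(pseudo_query.index) & set(pseudo_ref.index))
    q = pseudo_query.loc[shared].to_numpy(float)
    ref_max = pseudo_ref.loc[shared].to_numpy(float).max(axis=1)
    fold = (q + 1.0) / (ref_max + 1.0)
    pct = query_pct.reindex(shared).fillna(0.0).to_numpy(float)
    keep = (fold >= fold_min) & (pct >= detect_min)
    df = pd.DataFrame(
        {
            "gene": np.asarray(shared)[keep],
            "fold": fold[keep],
            "query_expression": q[keep],
            "ref_max": ref_max[keep],
            "query_pct": pct[keep],
        }
    )
    return df.sort_values("fold", ascending=False).reset_index(drop=True)


def detection_fractions(norm: NormMatrix, labeling: ClusterLabeling, subgroup: str) -> pd.Series:
    """Fraction of a subgroup's cells expressing each gene."""
    mask = labeling.mask_for(subgroup, norm.cell_ids)
    if not mask.any():
        raise ValidationError(f"subgroup {subgroup!r} has no cells")
    return pd.Series((norm.values[mask] > 0).mean(axis=0), index=norm.gene_ids)


def marker_dotplot_table(
    norm: NormMatrix, labeling: ClusterLabeling, markers: list[str]
) -> pd.DataFrame:
    """Mean expression and detection fraction per marker per subgroup
    (the data behind a marker dot plot)."""
    ex = norm.expm1()
    gidx = {g: i for i, g in enumerate(norm.gene_ids)}
    rows = []
    for sub in labeling.labels:
        mask = labeling.mask_for(sub, norm.cell_ids)
        for m in markers:
            if m not in gidx:
                continue
            col = ex[mask, gidx[m]]
            rows.append(
                {
                    "subgroup": sub,
                    "gene": m,
                    "mean_expression": float(col.mean()),
                    "pct_expressing": float((col > 0).mean()),
                }
            )
    return pd.DataFrame(rows, columns=["subgroup", "gene", "mean_expression", "pct_expressing"])
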