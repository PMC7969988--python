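"""Cross-dataset subgroup matching from marker overlap and enrichment.

Two studies of the same cell population rarely agree on cluster labels;
what they do agree on is marker genes.  Subgroups are matched by three
kinds of evidence: how many retained markers they share, how strongly
those shared markers are enriched in each study, and how specific each
shared marker is (a gene that marks most subgroups carries little
information about which pair corresponds).  The evidence is folded into
an additive score,

    score(a, b) = sum over shared genes g of
        min(log2fc_a(g), log2fc_b(g)) * (1 - max(spec_A(g), spec_B(g)) + 1/Kbar)

where spec is the fraction of subgroups listing g as a marker in that
dataset and Kbar the mean subgroup count of the two datasets.  The
consensus map reports reciprocal-best-hit pairs, flags near-ties
(runner-up within a configurable band of the best), and can annotate
pairs that disagree on an externally supplied trajectory-root flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerTable, ValidationError
from .markers import specificity_table


@dataclass
class OverlapMatrix:
    """Shared retained-marker counts between the subgroups of two datasets."""

    counts: pd.DataFrame  # rows = subgroups of A, columns = subgroups of B
    unmatched_a: int = 0  # marker genes of A absent from B's marker namespace
    unmatched_b: int = 0

    def __getitem__(self, key: tuple[str, str]) -> int:
        a, b = key
        return int(self.counts.loc[a, b])


@dataclass
class PairedEnrichment:
    """Shared markers of one subgroup pair with both enrichment values."""

    subgroup_a: str
    subgroup_b: str
    df: pd.DataFrame  # columns: gene, log2fc_a, log2fc_b

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CorrespondenceMap:
    """Scored subgroup correspondence between two datasets.

    ``pairs`` holds one row per reported pair: subgroup_a, subgroup_b,
    score, n_shared, reciprocal_best, tie, tie_partners (';'-joined),
    trajectory_discordant.  ``scores`` is the full score matrix.
    """

    pairs: pd.DataFrame
    scores: pd.DataFrame
    tie_band: float = 0.8

    def best_pairs(self) -> dict[str, str]:
        """Reciprocal-best-hit assignment, subgroup_a -> subgroup_b."""
        rb = self.pairs[self.pairs["reciprocal_best"]]
        return dict(zip(rb["subgroup_a"], rb["subgroup_b"]))


def overlap_matrix(markers_a: MarkerTable, markers_b: MarkerTable) -> OverlapMatrix:
    """Count shared retained markers for every subgroup pair (exact name match)."""
    if len(markers_a) == 0 or len(markers_b) == 0:
        raise ValidationError("empty marker table")
    subs_a = markers_a.subgroups
    subs_b = markers_b.subgroups
    sets_a = {a: markers_a.genes_of(a) for a in subs_a}
    sets_b = {b: markers_b.genes_of(b) for b in subs_b}
    counts = pd.DataFrame(
        [[len(sets_a[a] & sets_b[b]) for b in subs_b] for a in subs_a],
        index=subs_a,
        columns=subs_b,
        dtype=int,
    )
    genes_a = set(markers_a.df["gene"])
    genes_b = set(markers_b.df["gene"])
    return OverlapMatrix(
        counts=counts,
        unmatched_a=len(genes_a - genes_b),
        unmatched_b=len(genes_b - genes_a),
    )


def paired_enrichment(
    markers_a: MarkerTable, markers_b: MarkerTable, a: str, b: str
) -> PairedEnrichment:
    """Shared markers of (a, b) with both log2 enrichments.

    Sorted by the smaller of the two enrichments, descending (the
    conservative estimate of how strongly the gene marks the pair).
    """
    fa = markers_a.log2fc_of(a)
    fb = markers_b.log2fc_of(b)
    shared = sorted(set(fa) & set(fb))
    if not shared:
        warnings.warn(f"subgroups {a!r} and {b!r} share no retained markers")
    df = pd.DataFrame(
        {
            "gene": shared,
            "log2fc_a": [fa[g] for g in shared],
            "log2fc_b": [fb[g] for g in shared],
        }
    )
    if len(df):
        df = (
            df.assign(_min=np.minimum(df["log2fc_a"], df["log2fc_b"]))
            .sort_values("_min", ascending=False)
            .drop(columns="_min")
            .reset_index(drop=True)
        )
    return PairedEnrichment(subgroup_a=a, subgroup_b=b, df=df)


def match_score(
    pe: PairedEnrichment,
    specificity_a: dict[str, float],
    specificity_b: dict[str, float],
    k_mean: float,
    score_mode: str = "enrichment",
) -> float:
    """Specificity-weighted additive match score of one subgroup pair.

    ``score_mode='overlap'`` scores by shared-marker count only
    (enrichment and specificity weights fixed at 1), for tables that
    carry no enrichment values.
    """
    if len(pe) == 0:
        return 0.0
    if score_mode == "overlap":
        return float(len(pe))
    if score_mode != "enrichment":
        raise ValidationError(f"unknown score_mode {score_mode!r}")
    lo = np.minimum(pe.df["log2fc_a"].to_numpy(float), pe.df["log2fc_b"].to_numpy(float))
    spec = np.array(
        [
            max(specificity_a.get(g, 0.0), specificity_b.get(g, 0.0))
            for g in pe.df["gene"]
        ]
    )
    weights = 1.0 - spec + 1.0 / k_mean
    return float(np.sum(lo * weights))


def consensus_map(
    markers_a: MarkerTable,
    markers_b: MarkerTable,
    trajectory_roots: tuple[set[str], set[str]] | None = None,
    tie_band: float = 0.8,
    exclude_a: list[str] | None = None,
    exclude_b: list[str] | None = None,
    score_mode: str = "enrichment",
) -> CorrespondenceMap:
    """Score all subgroup pairs and extract the consensus correspondence.

    Reports every pair that is a best hit in at least one direction,
    plus any partner whose score is within ``tie_band`` of that best
    (one-to-many reporting).  Reciprocal best hits are mutual argmaxes.
    When ``trajectory_roots`` is given (root-flagged subgroups of each
    dataset), pairs where exactly one member is a root are annotated
    trajectory-discordant but never dropped.
    """
    for sub in exclude_a or []:
        markers_a = markers_a.drop_subgroup(sub)
    for sub in exclude_b or []:
        markers_b = markers_b.drop_subgroup(sub)
    if len(markers_a) == 0 or len(markers_b) == 0:
        raise ValidationError("empty marker table after exclusions")

    subs_a = markers_a.subgroups
    subs_b = markers_b.subgroups
    k_mean = (len(subs_a) + len(subs_b)) / 2.0
    spec_a = specificity_table(markers_a)
    spec_b = specificity_table(markers_b)

    pes = {
        (a, b): paired_enrichment(markers_a, markers_b, a, b)
        for a in subs_a
        for b in subs_b
        if markers_a.genes_of(a) & markers_b.genes_of(b)
    }
    scores = pd.DataFrame(0.0, index=subs_a, columns=subs_b)
    for (a, b), pe in pes.items():
        scores.loc[a, b] = match_score(pe, spec_a, spec_b, k_mean, score_mode)

    S = scores.to_numpy()
    best_b_of_a = {a: subs_b[int(np.argmax(S[i]))] for i, a in enumerate(subs_a) if S[i].max() > 0}
    best_a_of_b = {b: subs_a[int(np.argmax(S[:, j]))] for j, b in enumerate(subs_b) if S[:, j].max() > 0}

    roots_a, roots_b = trajectory_roots if trajectory_roots else (set(), set())

    rows = []
    seen = set()

    def add_pair(a: str, b: str) -> None:
        if (a, b) in seen:
            return
        seen.add((a, b))
        score = float(scores.loc[a, b])
        pe = pes.get((a, b))
        best_a = float(scores.loc[a].max())
        best_b = float(scores[b].max())
        partners = sorted(
            {
                b2
                for b2 in subs_b
                if b2 != b and best_a > 0 and scores.loc[a, b2] >= tie_band * best_a
            }
            | {
                a2
                for a2 in subs_a
                if a2 != a and best_b > 0 and scores.loc[a2, b] >= tie_band * best_b
            }
        )
        rows.append(
            {
                "subgroup_a": a,
                "subgroup_b": b,
                "score": score,
                "n_shared": len(pe) if pe is not None else 0,
                "reciprocal_best": best_b_of_a.get(a) == b and best_a_of_b.get(b) == a,
                "tie": bool(partners),
                "tie_partners": ";".join(partners),
                "trajectory_discordant": bool(trajectory_roots)
                and ((a in roots_a) != (b in roots_b)),
            }
        )

    for a, b in best_b_of_a.items():
        add_pair(a, b)
        best = float(scores.loc[a].max())
        for b2 in subs_b:
            if b2 != b and scores.loc[a, b2] >= tie_band * best:
                add_pair(a, b2)
    for b, a in best_a_of_b.items():
        add_pair(a, b)
        best = float(scores[b].max())
        for a2 in subs_a:
            if a2 != a and scores.loc[a2, b] >= tie_band * best:
                add_pair(a2, b)

    pairs = pd.DataFrame(
        rows,
        columns=[
            "subgroup_a",
            "subgroup_b",
            "score",
            "n_shared",
            "reciprocal_best",
            "tie",
            "tie_partners",
            "trajectory_discordant",
        ],
    ).sort_values(["subgroup_a", "score"], ascending=[True, False]).reset_index(drop=True)
    return CorrespondenceMap(pairs=pairs, scores=scores, tie_band=tie_band)
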