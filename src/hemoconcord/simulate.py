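"""Multi-study synthetic scRNA-seq with planted ground truth.

The generator emulates the situation the comparative pipeline was built
for: several "studies" profile the same immune-cell population with
different sequencing depth and dropout, the population splits into a
handful of subgroups dominated by a large unspecified pool (>50%) with
one rare niche-like subgroup (<1%), each specified subgroup carries a
set of planted marker genes at a controlled log2 enrichment, and
regulon target genes can be activated in designated subgroups.

Counts are negative-binomial with a lognormal per-gene baseline mean,
a lognormal per-cell depth factor times a per-study depth factor, and
independent Bernoulli dropout applied after the draw.  A fixed seed
gives byte-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClusterLabeling, CountMatrix, RegulonSet, ValidationError

logger = logging.getLogger(__name__)

#: Default subgroup composition: a dominant unspecified pool, several
#: specified subgroups, and one rare (<1%) niche-like subgroup.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "unspecified": 0.55,
    "antimicrobial": 0.15,
    "proliferative": 0.10,
    "phagocytic": 0.08,
    "secretory": 0.06,
    "crystal": 0.03,
    "lamellocyte": 0.022,
    "psc_like": 0.008,
}

@dataclass
class StudyConfig:
    """Parameters of one synthetic study.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2/dispersion); ``math.inf`` gives the Poisson limit.
    ``depth_factor`` scales every cell's expected library size and
    stands in for platform differences between studies.  Subgroups in
    ``unmarked_subgroups`` get no planted markers (a reservoir
    population with no distinctive signature).
    """

    n_cells: int = 2000
    n_genes: int = 2000
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    markers_per_subgroup: int = 20
    marker_log2fc: float = 3.5
    baseline_log_mean: float = -1.0
    baseline_log_sigma: float = 1.0
    marker_baseline_floor: float = 1.0
    unmarked_subgroups: tuple[str, ...] = ()
    dispersion: float = 2.0
    depth_factor: float = 1.0
    cell_depth_sigma: float = 0.3
    dropout: float = 0.1
    seed: int = 0
    gene_prefix: str = "g"
    cell_prefix: str = "c"

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"subgroup proportions sum to {total}, not 1")
        if self.marker_log2fc < 0:
            raise ValidationError("planted log2 enrichment must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        if self.markers_per_subgroup * len(self.proportions) > self.n_genes:
            raise ValidationError("not enough genes for the requested markers")


@dataclass
class GroundTruth:
    """Planted truth of one synthetic study (test oracle).

    ``markers`` has columns (gene, subgroup, log2fc) listing the planted
    enrichments; ``correspondence`` maps this study's labels to the
    partner study's labels when the study was generated as a pair;
    ``regulon_active`` maps regulon name -> set of subgroups where its
    targets were activated.  ``latent`` retains the generative state
    (baseline means, per-cell scale, per-cell subgroup) so that regulon
    effects can be re-drawn from the exact same model.
    """

    labeling: ClusterLabeling
    markers: pd.DataFrame
    correspondence: dict[str, str] | None = None
    regulon_active: dict[str, set[str]] | None = None
    latent: dict = field(default_factory=dict)

    def markers_of(self, subgroup: str) -> set[str]:
        return set(self.markers.loc[self.markers["subgroup"] == subgroup, "gene"])


# ---------------------------------------------------------------------------
# biology draw (shared between paired studies)
# ---------------------------------------------------------------------------

def _draw_biology(
    rng: np.random.Generator, config: StudyConfig
) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Baseline per-gene means and disjoint marker-gene assignment."""
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sigma, config.n_genes)
    )
    marked = [s for s in config.proportions if s not in config.unmarked_subgroups]
    pool = rng.permutation(config.n_genes)
    markers: dict[str, list[int]] = {}
    k = 0
    for sub in marked:
        markers[sub] = list(pool[k : k + config.markers_per_subgroup])
        k += config.markers_per_subgroup
    # planted enrichment must be observable: floor the baseline of marker
    # genes so they are not lost below the detection pre-filter
    for idx in markers.values():
        baseline[idx] = np.maximum(baseline[idx], config.marker_baseline_floor)
    return baseline, markers


def _subgroup_sizes(
    rng: np.random.Generator, config: StudyConfig, floor: int = 5
) -> dict[str, int]:
    """Multinomial composition with a floor for rare subgroups."""
    names = list(config.proportions)
    sizes = rng.multinomial(config.n_cells, [config.proportions[s] for s in names])
    sizes = dict(zip(names, sizes))
    donor = max(sizes, key=sizes.get)
    for sub in names:
        if 0 < sizes[sub] < floor or (sizes[sub] == 0 and config.proportions[sub] > 0):
            bump = floor - sizes[sub]
            logger.info("rare subgroup %s resampled from %d to %d cells", sub, sizes[sub], floor)
            sizes[sub] += bump
            sizes[donor] -= bump
    return sizes


def _draw_counts(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(mu)
    p = dispersion / (dispersion + mu)
    return rng.negative_binomial(dispersion, p)


def generate_study(
    config: StudyConfig | None = None,
    *,
    _biology: tuple[np.ndarray, dict[str, list[int]]] | None = None,
    _label_map: dict[str, str] | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate one study and return its counts plus planted truth.

    ``_biology``/``_label_map`` are used internally by
    :func:`generate_study_pair` to share planted subgroup identities and
    to rename subgroups in the partner study.
    """
    config = config or StudyConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    if _biology is None:
        biology_rng = np.random.default_rng(config.seed + 10_000)
        baseline, marker_idx = _draw_biology(biology_rng, config)
    else:
        baseline, marker_idx = _biology
        if len(baseline) != config.n_genes:
            raise ValidationError("incompatible gene universes")
        for idx in marker_idx.values():
            if max(idx, default=0) >= config.n_genes:
                raise ValidationError("marker gene not in gene universe")

    gene_ids = [f"{config.gene_prefix}{i:05d}" for i in range(config.n_genes)]
    cell_ids = [f"{config.cell_prefix}{i:05d}" for i in range(config.n_cells)]
    label_map = _label_map or {s: s for s in config.proportions}

    sizes = _subgroup_sizes(rng, config)
    subs = list(config.proportions)
    label_per_cell = np.repeat(
        np.arange(len(subs)), [sizes[s] for s in subs]
    )
    rng.shuffle(label_per_cell)

    # per-subgroup multiplicative profile
    mult = np.ones((len(subs), config.n_genes))
    rows = []
    for si, sub in enumerate(subs):
        for gi in marker_idx.get(sub, []):
            mult[si, gi] = 2.0 ** config.marker_log2fc
            rows.append((gene_ids[gi], label_map[sub], config.marker_log2fc))
    planted = pd.DataFrame(rows, columns=["gene", "subgroup", "log2fc"])

    cell_scale = config.depth_factor * np.exp(
        rng.normal(0.0, config.cell_depth_sigma, config.n_cells)
    )
    mu = cell_scale[:, None] * (mult[label_per_cell] * baseline[None, :])
    counts = _draw_counts(rng, mu, config.dispersion)
    if config.dropout > 0:
        keep = rng.random(counts.shape) >= config.dropout
        counts = counts * keep

    labeling = ClusterLabeling(
        {cell_ids[i]: label_map[subs[label_per_cell[i]]] for i in range(config.n_cells)}
    )
    truth = GroundTruth(
        labeling=labeling,
        markers=planted,
        latent={
            "baseline": baseline,
            "cell_scale": cell_scale,
            "subgroup_index": label_per_cell,
            "subgroups": [label_map[s] for s in subs],
            "mult": mult,
            "dispersion": config.dispersion,
            "dropout": config.dropout,
            "seed": config.seed,
        },
    )
    return CountMatrix(counts, cell_ids, gene_ids), truth


def generate_study_pair(
    config_a: StudyConfig | None = None,
    config_b: StudyConfig | None = None,
    shared_truth_seed: int = 42,
    shared_marker_fraction: float = 0.6,
) -> tuple[tuple[CountMatrix, GroundTruth], tuple[CountMatrix, GroundTruth]]:
    """Simulate two studies of the same population with partly shared markers.

    Both studies draw from one shared "biology" (gene baselines, subgroup
    identities); each subgroup keeps ``shared_marker_fraction`` of its
    markers in common between the studies, the rest being study-specific.
    Study B's subgroups are renamed so the planted correspondence (a
    bijection, returned in each study's ``GroundTruth.correspondence``)
    is not legible from the labels.
    """
    config_a = config_a or StudyConfig(seed=1)
    config_b = config_b or replace(config_a, seed=config_a.seed + 500, depth_factor=0.6, dropout=0.2)
    if config_a.n_genes != config_b.n_genes or config_a.gene_prefix != config_b.gene_prefix:
        raise ValidationError("incompatible gene universes")
    if set(config_a.proportions) != set(config_b.proportions):
        raise ValidationError("studies must share subgroup identities")
    if not (0.0 <= shared_marker_fraction <= 1.0):
        raise ValidationError("shared_marker_fraction must be in [0, 1]")

    rng = np.random.default_rng(shared_truth_seed)
    baseline, shared_idx = _draw_biology(rng, config_a)

    m = config_a.markers_per_subgroup
    n_shared = int(round(shared_marker_fraction * m))
    used = {g for idx in shared_idx.values() for g in idx}
    free = [g for g in rng.permutation(config_a.n_genes) if g not in used]

    markers_a: dict[str, list[int]] = {}
    markers_b: dict[str, list[int]] = {}
    k = 0
    for sub, idx in shared_idx.items():
        common = idx[:n_shared]
        markers_a[sub] = common + free[k : k + (m - n_shared)]
        k += m - n_shared
        markers_b[sub] = common + free[k : k + (m - n_shared)]
        k += m - n_shared
    # floor the baselines of the study-specific markers too
    for mk in (markers_a, markers_b):
        for idx in mk.values():
            baseline[idx] = np.maximum(baseline[idx], config_a.marker_baseline_floor)

    subs = list(config_a.proportions)
    perm = rng.permutation(len(subs))
    map_b = {sub: f"B{perm[i]:02d}" for i, sub in enumerate(subs)}

    cm_a, gt_a = generate_study(config_a, _biology=(baseline, markers_a))
    cm_b, gt_b = generate_study(
        replace(config_b, cell_prefix=config_b.cell_prefix + "b"),
        _biology=(baseline, markers_b),
        _label_map=map_b,
    )
    gt_a.correspondence = dict(map_b)
    gt_b.correspondence = {v: k for k, v in map_b.items()}
    return (cm_a, gt_a), (cm_b, gt_b)


def plant_regulons(
    cm: CountMatrix,
    truth: GroundTruth,
    regulons: RegulonSet,
    active_map: dict[str, set[str]],
    effect_log2fc: float,
    seed: int | None = None,
) -> CountMatrix:
    """Re-draw regulon target counts in designated subgroups at a shifted mean.

    For every regulon in ``active_map``, the counts of its target genes in
    cells of the listed subgroups are re-drawn from the generative model
    with mean scaled by ``2**effect_log2fc``; every other entry is left
    untouched.  The planted activity is recorded in
    ``truth.regulon_active``.
    """
    lat = truth.latent
    if not lat:
        raise ValidationError("ground truth carries no latent generative state")
    rng = np.random.default_rng(lat["seed"] + 77_003 if seed is None else seed)
    gidx = cm.gene_index()
    sub_names = lat["subgroups"]
    counts = cm.values.copy()
    factor = 2.0 ** effect_log2fc
    for reg, subgroups in active_map.items():
        targets = regulons[reg]
        missing = [g for g in targets if g not in gidx]
        if missing:
            raise ValidationError(
                f"regulon {reg!r} targets absent from gene universe: {missing[:5]}"
            )
        cols = np.array([gidx[g] for g in sorted(targets)])
        for sub in subgroups:
            if sub not in sub_names:
                raise ValidationError(f"unknown subgroup {sub!r} in active map")
            si = sub_names.index(sub)
            cell_rows = np.where(lat["subgroup_index"] == si)[0]
            mu = (
                lat["cell_scale"][cell_rows, None]
                * lat["mult"][si, cols][None, :]
                * lat["baseline"][cols][None, :]
                * factor
            )
            block = _draw_counts(rng, mu, lat["dispersion"])
            if lat["dropout"] > 0:
                block = block * (rng.random(block.shape) >= lat["dropout"])
            counts[np.ix_(cell_rows, cols)] = block
    truth.regulon_active = {r: set(s) for r, s in active_map.items()}
    return CountMatrix(counts, cm.cell_ids, cm.gene_ids)
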