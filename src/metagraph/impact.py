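"""Node-pair permutation importance ("impact scores") for the graph regressor.

For every species-function edge (node pair), the pair's weight is substituted
in each sample's graph by the lowest and then the highest weight observed for
that pair across all samples; the impact score for that sample is the
prediction at the maximum weight minus the prediction at the minimum weight.
A graph lacking the pair contributes an observed weight of zero (zero read
pairs), and the substitution inserts the edge — with any missing endpoint
node carrying its usual features — so both predictions are defined for every
sample.  Pairs are ranked by mean impact across samples (descending, ties
broken lexicographically); an absolute-value ranking mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import is_k_number
from .graphs import SampleGraph

logger = logging.getLogger(__name__)

__all__ = [
    "impact_scores",
    "group_pairs",
    "coverage_contrast",
    "local_explanation",
    "CoverageContrast",
]

Pair = tuple[str, str]


def _taxon_function_pairs(graph: SampleGraph) -> dict[Pair, float]:
    out = {}
    for (i, j), w in zip(graph.edges.tolist(), graph.weights.tolist()):
        a, b = graph.node_names[i], graph.node_names[j]
        if is_k_number(b) and not is_k_number(a):
            out[(a, b)] = w
        elif is_k_number(a) and not is_k_number(b):
            out[(b, a)] = w
    return out


def observed_weight_ranges(graphs: list[SampleGraph]) -> dict[Pair, tuple[float, float]]:
    """Global (min, max) observed weight per pair; absence counts as 0."""
    per_graph = [_taxon_function_pairs(g) for g in graphs]
    all_pairs = sorted(set().union(*per_graph)) if per_graph else []
    ranges = {}
    for pair in all_pairs:
        ws = [pg.get(pair, 0.0) for pg in per_graph]
        ranges[pair] = (min(ws), max(ws))
    return ranges


def _node_feature_registry(graphs: list[SampleGraph]) -> dict[str, tuple[int, int]]:
    reg: dict[str, tuple[int, int]] = {}
    for g in graphs:
        for name, feat in zip(g.node_names, g.node_features.tolist()):
            reg.setdefault(name, tuple(feat))
    return reg


def _substituted(
    graph: SampleGraph, pair: Pair, value: float, registry: dict[str, tuple[int, int]]
) -> SampleGraph:
    """Copy of *graph* with the pair's weight set to *value* (edge inserted if absent)."""
    source, target = pair
    names = list(graph.node_names)
    feats = graph.node_features
    edges = graph.edges
    weights = graph.weights.copy()
    idx = {n: i for i, n in enumerate(names)}
    added = []
    for name in (source, target):
        if name not in idx:
            idx[name] = len(names)
            names.append(name)
            added.append(registry.get(name, (1 if is_k_number(name) else 0, 0)))
    if added:
        feats = np.vstack([feats, np.array(added, dtype=np.int64)])
    i, j = idx[source], idx[target]
    hit = np.where(((edges[:, 0] == i) & (edges[:, 1] == j)) | ((edges[:, 0] == j) & (edges[:, 1] == i)))[0]
    if len(hit):
        weights[hit[0]] = value
    else:
        edges = np.vstack([edges, [i, j]])
        weights = np.append(weights, value)
    g = SampleGraph.__new__(SampleGraph)  # skip revalidation of an already-valid graph
    g.sample_id = graph.sample_id
    g.node_names = names
    g.node_features = feats
    g.edges = edges
    g.weights = weights
    g.label = graph.label
    return g


def impact_scores(
    model,
    graphs: list[SampleGraph],
    pairs: list[Pair] | None = None,
    rank_mode: str = "signed",
) -> pd.DataFrame:
    """Impact table: one row per pair, mean/SD/rank plus one column per sample.

    *model* is anything exposing ``predict(list[SampleGraph]) -> array`` (the
    trained regressor, or a surrogate).  ``rank_mode='signed'`` ranks by mean
    impact descending (the default); ``'abs'`` ranks by absolute mean impact.
    """
    if rank_mode not in ("signed", "abs"):
        raise ValueError("rank_mode must be 'signed' or 'abs'")
    ranges = observed_weight_ranges(graphs)
    if pairs is None:
        use_pairs = sorted(ranges)
    else:
        use_pairs = list(pairs)
        for p in use_pairs:
            if p not in ranges:
                logger.info("pair %s absent from every sample; impact will be 0", p)
                ranges[p] = (0.0, 0.0)
    registry = _node_feature_registry(graphs)
    sample_ids = [g.sample_id for g in graphs]

    modified: list[SampleGraph] = []
    layout = []  # per pair: offset of its 2*n substituted graphs (lo/hi interleaved)
    for pair in use_pairs:
        lo, hi = ranges[pair]
        if lo == hi:
            layout.append(None)
            continue
        layout.append(len(modified))
        for g in graphs:
            modified.append(_substituted(g, pair, lo, registry))
            modified.append(_substituted(g, pair, hi, registry))
    preds = np.asarray(model.predict(modified)) if modified else np.array([])

    n = len(graphs)
    rows = []
    for pair, off in zip(use_pairs, layout):
        if off is None:
            impacts = np.zeros(n)
        else:
            block = preds[off : off + 2 * n]
            impacts = block[1::2] - block[0::2]
        rows.append(
            {
                "source": pair[0],
                "target": pair[1],
                "mean_impact": float(impacts.mean()),
                "sd_impact": float(impacts.std()),
                **dict(zip(sample_ids, impacts)),
            }
        )
    table = pd.DataFrame(rows)
    if rank_mode == "abs":
        keyfun = lambda c: -c.abs() if c.name == "mean_impact" else c
    else:
        keyfun = lambda c: -c if c.name == "mean_impact" else c
    table = table.sort_values(by=["mean_impact", "source", "target"], key=keyfun).reset_index(
        drop=True
    )
    table.insert(4, "rank", np.arange(1, len(table) + 1))
    return table


def group_pairs(records: pd.DataFrame, tolerance: float = 0.01) -> list[dict]:
    """Group pairs sharing a source node and an equal mean impact (within tol).

    Returns a list of groups, each ``{"source", "representative_mean",
    "pairs"}``; the partition is greedy over pairs of one source sorted by
    mean impact descending, so the within-group spread never exceeds
    *tolerance*.
    """
    groups = []
    for source, sub in records.groupby("source", sort=True):
        sub = sub.sort_values(["mean_impact", "target"], ascending=[False, True])
        current: list[tuple[str, float]] = []
        rep = None
        for row in sub.itertuples(index=False):
            if rep is not None and abs(row.mean_impact - rep) > tolerance:
                groups.append({"source": source, "representative_mean": rep, "pairs": current})
                current, rep = [], None
            if rep is None:
                rep = row.mean_impact
            current.append((row.source, row.target))
        if current:
            groups.append({"source": source, "representative_mean": rep, "pairs": current})
    groups.sort(key=lambda g: (-g["representative_mean"], g["source"]))
    return groups


@dataclass
class CoverageContrast:
    mean_covered: float
    mean_uncovered: float
    t_statistic: float
    df: int
    p_value: float


def coverage_contrast(
    pair_set: list[Pair],
    pair_counts: pd.DataFrame,
    soc: pd.Series,
    welch: bool = False,
) -> CoverageContrast:
    """Compare SOC between (sample, pair) observations with and without coverage.

    The observation unit is one (sample, pair) combination; it is *covered*
    when the pair's read-pair count is positive in that sample.  The default
    test is the pooled-variance two-sample t (df = n1 + n2 - 2); ``welch=True``
    drops the equal-variance assumption.
    """
    covered_lookup = {
        (r.sample_id, r.species, r.function)
        for r in pair_counts.itertuples(index=False)
        if r.count > 0
    }
    covered_vals, uncovered_vals = [], []
    for sid, y in soc.items():
        for sp, fn in pair_set:
            (covered_vals if (sid, sp, fn) in covered_lookup else uncovered_vals).append(y)
    if not covered_vals or not uncovered_vals:
        raise ValueError(
            f"one coverage group is empty (covered={len(covered_vals)}, "
            f"uncovered={len(uncovered_vals)})"
        )
    res = stats.ttest_ind(covered_vals, uncovered_vals, equal_var=not welch)
    df = len(covered_vals) + len(uncovered_vals) - 2 if not welch else int(res.df)
    return CoverageContrast(
        mean_covered=float(np.mean(covered_vals)),
        mean_uncovered=float(np.mean(uncovered_vals)),
        t_statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
    )


def local_explanation(
    model: TrainedRegressor,
    graphs: list[SampleGraph],
    sample_id: str,
    top_k: int,
) -> pd.DataFrame:
    """The *top_k* pairs with largest |impact| for one sample, signs retained.

    Weight ranges are still taken globally over *graphs* (the sample's graph
    alone cannot define a min/max substitution).
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    ids = [g.sample_id for g in graphs]
    if sample_id not in ids:
        raise ValueError(f"sample {sample_id!r} not among the provided graphs")
    table = impact_scores(model, graphs)
    local = table[["source", "target", sample_id]].rename(columns={sample_id: "impact"})
    local = local.sort_values(
        by=["impact", "source", "target"], key=lambda c: -c.abs() if c.name == "impact" else c
    ).reset_index(drop=True)
    if top_k > len(local):
        logger.warning("top_k=%d exceeds %d available pairs; returning all", top_k, len(local))
    return local.head(top_k)
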