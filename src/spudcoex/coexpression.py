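"""Pearson co-expression at a fixed cutoff, Venn cores and consensus.

Per platform, every valid probe of a query gene is used as a query
feature; the entities correlating at ``r >= pcc_cutoff`` (inclusive,
one-sided: negative correlations never qualify) with *all* features of
the query gene form that gene's co-expression set.  The platform core is
the central Venn intersection over the query genes.  Probe-level cores
are mapped to gene identifiers through the probe table, and the
cross-platform consensus is the strict intersection across platforms.

Correlations use pairwise-complete observations with at least
``min_pairs`` pairs; zero-variance entities are skipped and reported.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ParamSet
from .preprocess import ExpressionMatrix


class CoexpressionError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    """Raised when an input series has zero variance."""


def pearson(x, y, min_pairs: int = 3) -> float:
    """Sample Pearson correlation with pairwise deletion of missing values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise CoexpressionError("series lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs:
        raise CoexpressionError(
            f"fewer than min_pairs={min_pairs} complete pairs")
    x, y = x[ok], y[ok]
    dx = x - x.mean()
    dy = y - y.mean()
    den = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if den == 0.0:
        raise UndefinedCorrelationError("zero variance input")
    return float(dx @ dy) / den


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a sample correlation under the t reference
    distribution with ``n - 2`` degrees of freedom; ``|r| = 1`` gives 0."""
    if n < 3:
        raise CoexpressionError("p-value needs n >= 3")
    if not -1.0 <= r <= 1.0:
        raise CoexpressionError(f"correlation out of range: {r}")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * float(stats.t.sf(abs(t), df=n - 2))


def correlate_with_feature(m: ExpressionMatrix, feature_id: str,
                           min_pairs: int = 3) -> pd.Series:
    """Correlation of one feature against every feature of the matrix.

    Vectorized two-pass computation when the matrix is complete; falls
    back to pairwise-complete per-row evaluation in the presence of
    missing values.  Zero-variance rows (and rows with too few complete
    pairs) come back as NaN.
    """
    if feature_id not in m.values.index:
        raise CoexpressionError(
            f"query feature {feature_id!r} absent from {m.platform_id}")
    vals = m.values.to_numpy(float)
    y = m.values.loc[feature_id].to_numpy(float)
    if np.isfinite(vals).all():
        dy = y - y.mean()
        ny = float(dy @ dy)
        dx = vals - vals.mean(axis=1, keepdims=True)
        nx = np.einsum("ij,ij->i", dx, dx)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (dx @ dy) / np.sqrt(nx * ny)
        if ny == 0.0:
            raise UndefinedCorrelationError(
                f"query feature {feature_id!r} has zero variance")
        if vals.shape[1] < min_pairs:
            raise CoexpressionError("fewer samples than min_pairs")
    else:
        r = np.empty(len(vals))
        for i in range(len(vals)):
            try:
                r[i] = pearson(vals[i], y, min_pairs)
            except (CoexpressionError, UndefinedCorrelationError):
                r[i] = np.nan
    out = pd.Series(r, index=m.values.index, name=feature_id)
    out[feature_id] = 1.0  # self-correlation is exact by definition
    return out


def coexpressed_set(m: ExpressionMatrix, query_features: list[str],
                    params: ParamSet) -> tuple[set[str], dict[str, set[str]]]:
    """Entities correlating at ``r >= pcc_cutoff`` with *all* query features.

    Returns the intersection and the per-feature sets (for Venn
    reconciliation across the probes of one query gene).
    """
    if not query_features:
        raise CoexpressionError("no query features given")
    per_feature: dict[str, set[str]] = {}
    for f in query_features:
        r = correlate_with_feature(m, f, params.min_pairs)
        keep = r.index[(r >= params.pcc_cutoff).fillna(False)]
        per_feature[f] = set(keep)
    core = set.intersection(*per_feature.values())
    return core, per_feature


def platform_core(sets_per_query: dict[str, set[str]]
                  ) -> tuple[set[str], dict[str, int]]:
    """Central Venn intersection over query sets plus all region counts.

    Region keys are sorted '&'-joined query names; a region counts the
    elements belonging to exactly that combination of sets.
    """
    if not sets_per_query:
        raise CoexpressionError("platform_core needs >= 1 query set")
    names = sorted(sets_per_query)
    core = set.intersection(*(sets_per_query[q] for q in names))
    regions: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            inside = set.intersection(*(sets_per_query[q] for q in combo))
            outside = set().union(*(sets_per_query[q] for q in names
                                    if q not in combo)) if k < len(names) else set()
            regions["&".join(combo)] = len(inside - outside)
    return core, regions


def entities_to_genes(entities: set[str], probe_table: pd.DataFrame | None,
                      platform_id: str):
    """Map probe-level entities to gene ids through their valid assignments.

    Ambiguous entities contribute all their genes (flagged); entities
    without a valid assignment are dropped and counted.  With
    ``probe_table=None`` (gene-level platform) the mapping is identity.

    Returns ``(genes, ambiguous_genes, n_unmapped)``.
    """
    if probe_table is None:
        return set(entities), set(), 0
    sub = probe_table[(probe_table["platform"] == platform_id)
                      & probe_table["valid"]]
    by_probe: dict[str, list[tuple[str, bool]]] = {}
    for row in sub.itertuples():
        by_probe.setdefault(row.probe_id, []).append((row.gene_id, row.ambiguous))
    genes: set[str] = set()
    flagged: set[str] = set()
    unmapped = 0
    for e in entities:
        hits = by_probe.get(e)
        if not hits:
            unmapped += 1
            continue
        for g, amb in hits:
            genes.add(g)
            if amb:
                flagged.add(g)
    return genes, flagged, unmapped


@dataclass
class ConsensusResult:
    """Genes supported by every query on every platform."""

    genes: list[str]
    support: dict[str, dict[str, set[str]]]  # gene -> platform -> queries
    platform_gene_sets: dict[str, set[str]] = field(default_factory=dict)
    venn_regions: dict[str, dict[str, int]] = field(default_factory=dict)
    ambiguous_genes: set[str] = field(default_factory=set)


def cross_platform_consensus(gene_sets: dict[str, set[str]],
                             support: dict[str, dict[str, set[str]]] | None = None
                             ) -> ConsensusResult:
    """Strict intersection of per-platform gene sets (>= 2 platforms).

    Genes not measurable on some platform simply never enter that
    platform's set and are therefore excluded by the intersection.
    """
    if len(gene_sets) < 2:
        raise CoexpressionError("consensus needs >= 2 platforms")
    consensus = sorted(set.intersection(*gene_sets.values()))
    gene_support: dict[str, dict[str, set[str]]] = {}
    for g in consensus:
        gene_support[g] = {p: set((support or {}).get(p, {}).get(g, set()))
                           for p in gene_sets}
    return ConsensusResult(consensus, gene_support,
                           platform_gene_sets={p: set(s) for p, s in gene_sets.items()})


def evaluate_recovery(consensus_genes, truth_module, query_genes) -> dict[str, float]:
    """Precision/recall/F1 of the consensus against the planted module,
    with the query genes excluded from both sides."""
    queries = set(query_genes)
    truth = set(truth_module) - queries
    if not truth:
        raise CoexpressionError("empty truth module")
    found = set(consensus_genes) - queries
    tp = len(found & truth)
    precision = tp / len(found) if found else (1.0 if not truth else 0.0)
    recall = tp / len(truth)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_consensus": len(found), "n_truth": len(truth),
            "n_true_positive": tp}


def plot_venn(sets_per_query: dict[str, set[str]], path) -> None:
    """Optional 2- or 3-set Venn figure (circle patches + region counts)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    names = sorted(sets_per_query)
    if len(names) not in (2, 3):
        raise CoexpressionError("venn figure supports 2 or 3 query sets")
    _, regions = platform_core(sets_per_query)
    centers = {2: [(-0.35, 0.0), (0.35, 0.0)],
               3: [(-0.35, -0.2), (0.35, -0.2), (0.0, 0.42)]}[len(names)]
    # Label anchors per exclusive region, keyed by membership pattern.
    anchor = {}
    for combo, count in regions.items():
        members = combo.split("&")
        xs = [centers[names.index(q)][0] for q in members]
        ys = [centers[names.index(q)][1] for q in members]
        # Exclusive single-set regions sit away from the centre.
        scale = 1.6 if len(members) == 1 else 1.0
        anchor[combo] = (scale * sum(xs) / len(xs), scale * sum(ys) / len(ys), count)

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = ["tab:red", "tab:blue", "tab:green"]
    for (x, y), name, col in zip(centers, names, colors):
        ax.add_patch(Circle((x, y), 0.62, alpha=0.3, color=col))
        ax.annotate(name, (x * 1.9, y * 1.9 + (0.75 if y >= 0 else -0.75)),
                    ha="center", fontsize=10)
    for combo, (x, y, count) in anchor.items():
        ax.annotate(str(count), (x, y), ha="center", va="center", fontsize=11)
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def run_platform_coexpression(m: ExpressionMatrix,
                              query_probe_features: dict[str, list[str]],
                              params: ParamSet,
                              probe_table: pd.DataFrame | None = None):
    """Full per-platform analysis for a set of query genes.

    ``query_probe_features`` maps each query gene to its query features on
    this platform (valid probes, or the gene itself on the FPKM
    platform).  Returns a dict with per-query entity sets, the platform
    Venn core, the mapped gene set and bookkeeping counts.
    """
    per_query_sets: dict[str, set[str]] = {}
    hits_rows = []
    n = len(m.sample_ids)
    for qgene, features in query_probe_features.items():
        if not features:
            raise CoexpressionError(
                f"query gene {qgene} has no query features on {m.platform_id}")
        per_feature: dict[str, set[str]] = {}
        for f in features:
            r = correlate_with_feature(m, f, params.min_pairs)
            keep = r.index[(r >= params.pcc_cutoff).fillna(False)]
            per_feature[f] = set(keep)
            for e in sorted(keep):
                hits_rows.append({"platform": m.platform_id, "query_gene": qgene,
                                  "query_feature": f, "entity_id": e,
                                  "r": float(r[e]), "n_pairs": n})
        per_query_sets[qgene] = set.intersection(*per_feature.values())
    core_entities, regions = platform_core(per_query_sets)
    genes, flagged, unmapped = entities_to_genes(core_entities, probe_table,
                                                 m.platform_id)
    support = {g: set(query_probe_features) for g in genes}
    return {
        "per_query_sets": per_query_sets,
        "core_entities": core_entities,
        "venn_regions": regions,
        "genes": genes,
        "ambiguous_genes": flagged,
        "n_unmapped": unmapped,
        "support": support,
        "hits": pd.DataFrame(hits_rows),
    }
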