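"""Tissue-specificity, developmental fold-change and query-gene selection.

Tissue specificity follows the leaf-versus-tuber rule: all leaf samples
against all stolon + tuber + sprout samples, linear fold-change strictly
above the threshold (default 10) in either direction.  On normalized
log2 platforms the fold-change is ``2 ** (mean_leaf - mean_tuber)``; on
the FPKM platform it is the ratio of group means with a small
pseudocount.  The developmental score is the stage5-versus-stage1 log2
ratio.  Query genes must be tuber-specific on every platform where they
are measurable and developmentally up-regulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TUBER_GROUP, ParamSet
from .preprocess import ExpressionMatrix


class NotMeasurableError(ValueError):
    """Gene has no valid probe on the platform."""


class DifferentialError(ValueError):
    pass


@dataclass
class GeneProfileResult:
    """Gene-level per-sample values plus ambiguity warnings."""

    values: pd.DataFrame  # genes x samples
    ambiguous_only: list[str]  # genes quantified from ambiguous probes alone


def gene_profiles(m: ExpressionMatrix, valid_probe_map: dict[str, list[str]] | None,
                  probe_table: pd.DataFrame | None = None,
                  genes=None) -> GeneProfileResult:
    """Per-sample gene values: mean over the gene's valid, unambiguous probes.

    If a gene has only ambiguous probes they are used and the gene is
    reported in ``ambiguous_only``.  On the gene-level FPKM platform
    (``valid_probe_map is None``) rows map to genes directly.  Genes with
    no probe/row raise :class:`NotMeasurableError` when explicitly
    requested, otherwise they are silently absent.
    """
    if valid_probe_map is None:
        values = m.values if genes is None else m.values.loc[
            [g for g in genes if g in m.values.index]]
        if genes is not None:
            missing = [g for g in genes if g not in m.values.index]
            if missing:
                raise NotMeasurableError(
                    f"gene(s) not measurable on {m.platform_id}: {missing}")
        return GeneProfileResult(values.astype(float), [])

    ambiguous_probes: set[str] = set()
    if probe_table is not None:
        sub = probe_table[(probe_table["platform"] == m.platform_id)
                          & probe_table["ambiguous"]]
        ambiguous_probes = set(sub["probe_id"])

    wanted = list(valid_probe_map) if genes is None else list(genes)
    vals = m.values.to_numpy(float)
    row_of = {p: i for i, p in enumerate(m.values.index)}
    out_rows, names, amb_only, not_measurable = [], [], [], []
    for g in wanted:
        idx = [row_of[p] for p in valid_probe_map.get(g, []) if p in row_of]
        if not idx:
            not_measurable.append(g)
            continue
        clean = [i for i in idx if m.values.index[i] not in ambiguous_probes]
        use = clean if clean else idx
        if not clean:
            amb_only.append(g)
        out_rows.append(vals[use].mean(axis=0))
        names.append(g)
    if genes is not None and not_measurable:
        raise NotMeasurableError(
            f"gene(s) not measurable on {m.platform_id}: {not_measurable}")
    values = (pd.DataFrame(np.vstack(out_rows), index=names,
                           columns=m.values.columns)
              if out_rows else pd.DataFrame(columns=m.values.columns))
    return GeneProfileResult(values, amb_only)


def _group_means(profiles: pd.DataFrame, samples: pd.DataFrame,
                 platform_id: str):
    sheet = samples[samples["platform_id"] == platform_id]
    leaf = [s for s in profiles.columns
            if s in set(sheet.loc[sheet["tissue"] == "leaf", "sample_id"])]
    tuber = [s for s in profiles.columns
             if s in set(sheet.loc[sheet["tissue"].isin(TUBER_GROUP), "sample_id"])]
    if not leaf or not tuber:
        raise DifferentialError(
            f"{platform_id}: both leaf and tuber groups must be non-empty")
    return profiles[leaf].mean(axis=1), profiles[tuber].mean(axis=1)


def tissue_fold_change(profiles: pd.DataFrame, samples: pd.DataFrame,
                       platform_id: str, scale: str,
                       params: ParamSet) -> pd.DataFrame:
    """Leaf/tuber fold-change and tissue-specificity calls per gene.

    Columns: ``mean_leaf, mean_tuber, fc, log2fc, specific_in``.  ``fc`` is
    the linear leaf/tuber ratio; ``specific_in`` is ``leaf`` when
    ``fc > threshold``, ``tuber`` when ``fc < 1/threshold`` and ``none``
    otherwise (strictly "above" the threshold, so a fold-change of
    exactly 10 is not tissue-specific).
    """
    mean_leaf, mean_tuber = _group_means(profiles, samples, platform_id)
    if scale in ("log2_norm", "log2"):
        log2fc = mean_leaf - mean_tuber
        fc = np.exp2(log2fc)
    elif scale == "fpkm":
        eps = params.fpkm_pseudocount
        fc = (mean_leaf + eps) / (mean_tuber + eps)
        log2fc = np.log2(fc)
    else:
        raise DifferentialError(f"unsupported scale {scale!r} for fold-change")
    thr = params.tissue_fc_threshold
    specific = np.where(fc > thr, "leaf", np.where(fc < 1.0 / thr, "tuber", "none"))
    return pd.DataFrame({
        "gene_id": profiles.index, "platform": platform_id,
        "mean_leaf": mean_leaf.to_numpy(), "mean_tuber": mean_tuber.to_numpy(),
        "fc": np.asarray(fc, float), "log2fc": np.asarray(log2fc, float),
        "specific_in": specific,
    }).set_index("gene_id")


def developmental_log2fc(profiles: pd.DataFrame, samples: pd.DataFrame,
                         platform_id: str, stage_a: str = "stage5",
                         stage_b: str = "stage1") -> pd.DataFrame:
    """Log2 fold-change between two developmental stages (default
    small tubers, stage 5, versus unswollen stolons, stage 1) on
    normalized log2 values."""
    sheet = samples[samples["platform_id"] == platform_id]
    cols_a = [s for s in profiles.columns
              if s in set(sheet.loc[sheet["stage"] == stage_a, "sample_id"])]
    cols_b = [s for s in profiles.columns
              if s in set(sheet.loc[sheet["stage"] == stage_b, "sample_id"])]
    if not cols_a or not cols_b:
        raise DifferentialError(
            f"{platform_id}: stages {stage_a!r}/{stage_b!r} not both present")
    log2fc = profiles[cols_a].mean(axis=1) - profiles[cols_b].mean(axis=1)
    if not np.isfinite(log2fc.to_numpy(float)).all():
        raise DifferentialError("non-finite developmental log2 fold-change")
    return pd.DataFrame({"gene_id": profiles.index,
                         "platform": platform_id,
                         "dev_log2fc": log2fc.to_numpy(float)}).set_index("gene_id")


def select_query_genes(ts_results: dict[str, pd.DataFrame],
                       dev_results: dict[str, pd.DataFrame],
                       params: ParamSet,
                       pool=None) -> list[str]:
    """Select query genes: tuber-specific everywhere measurable and
    developmentally up-regulated.

    A gene qualifies when ``specific_in == "tuber"`` on every platform
    where it appears in ``ts_results`` (at least one) and its mean
    developmental log2 fold-change across platforms reaches
    ``params.dev_min_log2fc``.  Survivors are ranked by developmental
    score descending (ties broken lexicographically) and the top
    ``params.n_queries`` are returned; fewer survivors are returned
    as-is with a warning.
    """
    candidates: set[str] = set()
    for df in ts_results.values():
        candidates.update(df.index)
    if pool is not None:
        candidates &= set(pool)

    survivors = []
    for g in candidates:
        calls = [df.loc[g, "specific_in"] for df in ts_results.values()
                 if g in df.index]
        if not calls or any(c != "tuber" for c in calls):
            continue
        devs = [df.loc[g, "dev_log2fc"] for df in dev_results.values()
                if g in df.index]
        if not devs:
            continue
        dev = float(np.mean(devs))
        if dev >= params.dev_min_log2fc:
            survivors.append((g, dev))

    survivors.sort(key=lambda t: (-t[1], t[0]))
    selected = [g for g, _ in survivors[: params.n_queries]]
    if len(selected) < params.n_queries:
        warnings.warn(
            f"only {len(selected)} of {params.n_queries} requested query "
            "genes satisfy the selection criteria", stacklevel=2)
    return selected
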