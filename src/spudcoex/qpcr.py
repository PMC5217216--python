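"""qRT-PCR validation arithmetic: dCT, stage profiles, correlation matrix.

Relative expression is quantified against a reference gene (the EF1-alpha
role): ``dCT = CT_target - CT_reference`` and relative expression
``2 ** (-dCT)``.  Technical replicates are averaged first, dCT is formed
per biological replicate, biological replicates are averaged per stage,
and the resulting stage-mean profiles are compared pairwise by Pearson
correlation with two-sided p-values flagged at ``p <= p_threshold``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import STAGE_RANK
from .coexpression import (
    UndefinedCorrelationError,
    pearson,
    pearson_pvalue,
)

#: Technical replicates spread (cycles) above which a warning is issued.
TECHNICAL_SPREAD_WARN = 0.5

REQUIRED_COLUMNS = ("sample_id", "stage", "replicate", "gene_id", "ct",
                    "is_reference")


class QPCRError(ValueError):
    pass


class MissingMeasurementError(ValueError):
    pass


def technical_mean(cts) -> float:
    """Mean CT over technical replicates; warns on spread > 0.5 cycles."""
    arr = np.asarray(cts, float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise MissingMeasurementError("no finite CT measurement")
    if arr.size > 1 and (arr.max() - arr.min()) > TECHNICAL_SPREAD_WARN:
        warnings.warn(f"technical replicate spread {arr.max() - arr.min():.2f} "
                      "cycles exceeds 0.5", stacklevel=2)
    return float(arr.mean())


def delta_ct(ct_gene: float, ct_ref: float) -> tuple[float, float]:
    """``dCT = ct_gene - ct_ref``; relative expression ``2 ** (-dCT)``."""
    if not np.isfinite(ct_gene) or not np.isfinite(ct_ref):
        raise MissingMeasurementError("CT values must be finite")
    d = float(ct_gene) - float(ct_ref)
    return d, 2.0 ** (-d)


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise QPCRError(f"CT table misses column(s): {sorted(missing)}")
    ct = records["ct"].to_numpy(float)
    if ((ct <= 0) | (ct >= 45)).any():
        raise QPCRError("CT values must lie in (0, 45) cycles")
    bad = set(records["stage"]) - set(STAGE_RANK)
    if bad:
        raise QPCRError(f"unknown stage(s): {sorted(bad)}")
    return records


def stage_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean relative expression per stage (genes x stages).

    Averaging order: technical replicates -> per-replicate dCT against
    the sample's reference measurement -> biological mean of
    ``2 ** (-dCT)`` per stage.  Stage columns follow the ordinal stage
    vocabulary.  Stages without any replicate for a gene are dropped
    with a warning.
    """
    records = _validate(records)
    stages = sorted(set(records["stage"]), key=STAGE_RANK.get)
    if len(stages) < 2:
        raise QPCRError("stage profiles need >= 2 stages")

    ref_ct: dict[str, float] = {}
    for sid, grp in records[records["is_reference"]].groupby("sample_id"):
        ref_ct[sid] = technical_mean(grp["ct"])

    targets = records[~records["is_reference"]]
    genes = sorted(set(targets["gene_id"]))
    rel: dict[tuple[str, str], list[float]] = {}
    for (sid, gene), grp in targets.groupby(["sample_id", "gene_id"]):
        if sid not in ref_ct:
            raise MissingMeasurementError(f"sample {sid} lacks a reference measurement")
        d, r = delta_ct(technical_mean(grp["ct"]), ref_ct[sid])
        stage = grp["stage"].iloc[0]
        rel.setdefault((gene, stage), []).append(r)

    out = pd.DataFrame(index=genes, columns=stages, dtype=float)
    for (gene, stage), vals in rel.items():
        out.loc[gene, stage] = float(np.mean(vals))
    empty = [c for c in out.columns if out[c].isna().all()]
    if empty:
        warnings.warn(f"stage(s) without measurements dropped: {empty}",
                      stacklevel=2)
        out = out.drop(columns=empty)
    return out


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson matrix over stage profiles with significance flags."""

    genes: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    significant: pd.DataFrame
    n: int
    p_threshold: float


def qpcr_correlation_matrix(profiles: pd.DataFrame,
                            p_threshold: float = 0.1) -> CorrelationMatrix:
    """Pairwise Pearson correlation of stage-mean expression profiles.

    ``n`` for the p-value is the number of paired stage points.  Constant
    profiles give undefined correlations, reported as missing cells.
    """
    n = profiles.shape[1]
    if n < 3:
        raise QPCRError("correlation matrix needs >= 3 stages")
    genes = list(profiles.index)
    r = pd.DataFrame(np.nan, index=genes, columns=genes)
    p = pd.DataFrame(np.nan, index=genes, columns=genes)
    for i, gi in enumerate(genes):
        r.loc[gi, gi] = 1.0
        p.loc[gi, gi] = 0.0
        for gj in genes[i + 1:]:
            try:
                rij = pearson(profiles.loc[gi], profiles.loc[gj], min_pairs=3)
            except UndefinedCorrelationError:
                continue
            pij = pearson_pvalue(rij, n)
            r.loc[gi, gj] = r.loc[gj, gi] = rij
            p.loc[gi, gj] = p.loc[gj, gi] = pij
    significant = (p <= p_threshold) & p.notna()
    return CorrelationMatrix(genes, r, p, significant, n, p_threshold)
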