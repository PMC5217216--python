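"""Normalization chain for probe-level platforms; FPKM passthrough.

The microarray chain reproduces a standard analysis-suite default:

1. :func:`detection_filter` — keep features detected (raw signal >=
   ``min_signal``) in at least ``min_samples`` samples,
2. :func:`log2_transform` — log2 with a positive floor,
3. :func:`percentile_shift` — per-sample (per-chip) shift to the q-th
   percentile (default 75), linear interpolation,
4. :func:`median_baseline` — per-feature baseline to the median across
   all samples.

Each step records the new scale on the matrix; the FPKM platform skips
the chain entirely and keeps its ``fpkm`` scale.  Missing values are
excluded from percentile and median computation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import STAGE_RANK, TISSUES


class PreprocessError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """A features x samples numeric table tagged with platform and scale.

    ``scale`` is one of ``raw_linear`` (microarray intensities), ``log2``,
    ``log2_norm`` (after the full chain) or ``fpkm``.
    """

    platform_id: str
    scale: str
    values: pd.DataFrame

    def __post_init__(self):
        if self.scale not in ("raw_linear", "log2", "log2_norm", "fpkm"):
            raise PreprocessError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            raise PreprocessError(f"{self.platform_id}: duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise PreprocessError(f"{self.platform_id}: duplicate sample ids")
        if self.scale in ("raw_linear", "fpkm"):
            vals = self.values.to_numpy(float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise PreprocessError(
                    f"{self.platform_id}: negative values on {self.scale} scale")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def validate_sample_sheet(sheet: pd.DataFrame,
                          matrices: dict[str, ExpressionMatrix] | None = None
                          ) -> pd.DataFrame:
    """Check the sample sheet schema and its consistency with matrices."""
    required = {"sample_id", "platform_id", "tissue", "stage", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise PreprocessError(f"sample sheet misses column(s): {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise PreprocessError("duplicate sample_id in sample sheet")
    bad = set(sheet["tissue"]) - set(TISSUES)
    if bad:
        raise PreprocessError(f"unknown tissue value(s): {sorted(bad)}")
    known_stage = set(STAGE_RANK) | {""}
    bad = {s for s in sheet["stage"].fillna("") if s not in known_stage}
    if bad:
        raise PreprocessError(f"unknown stage value(s): {sorted(bad)}")
    if matrices is not None:
        listed = set(sheet["sample_id"])
        for m in matrices.values():
            for sid in m.sample_ids:
                if sid not in listed:
                    raise PreprocessError(
                        f"sample {sid} of {m.platform_id} missing from sheet")
    return sheet


def detection_filter(m: ExpressionMatrix, min_signal: float,
                     min_samples: int = 1) -> ExpressionMatrix:
    """Keep features with signal >= ``min_signal`` in >= ``min_samples``
    samples ("detected in at least one condition"); order preserved."""
    if m.scale not in ("raw_linear", "fpkm"):
        raise PreprocessError(f"detection filter expects linear values, got {m.scale}")
    n = len(m.sample_ids)
    if min_samples > n:
        raise PreprocessError(f"min_samples={min_samples} exceeds {n} samples")
    vals = m.values.to_numpy(float)
    detected = np.nansum(vals >= min_signal, axis=1) >= min_samples
    return replace(m, values=m.values.loc[detected])


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """``v -> log2(max(v, floor))``; requires non-negative input."""
    if m.scale != "raw_linear":
        raise PreprocessError(f"log2_transform expects raw_linear, got {m.scale}")
    vals = m.values.to_numpy(float)
    if np.nanmin(vals, initial=np.inf) < 0:
        raise PreprocessError("negative intensity values")
    out = np.log2(np.maximum(vals, floor))
    out[np.isnan(vals)] = np.nan
    return ExpressionMatrix(m.platform_id, "log2",
                            pd.DataFrame(out, index=m.values.index,
                                         columns=m.values.columns))


def percentile_shift(m: ExpressionMatrix, q: float = 75.0) -> ExpressionMatrix:
    """Per-sample shift so each sample's q-th percentile becomes zero.

    The percentile uses linear interpolation at index ``(n - 1) * q / 100``
    over the sorted non-missing values of the sample.
    """
    if m.scale != "log2":
        raise PreprocessError(f"percentile_shift expects log2 scale, got {m.scale}")
    vals = m.values.to_numpy(float).copy()
    for c in range(vals.shape[1]):
        col = vals[:, c]
        finite = col[np.isfinite(col)]
        if finite.size < 2:
            raise PreprocessError(
                f"sample {m.values.columns[c]} has < 2 non-missing values")
        col -= np.percentile(finite, q)
    return ExpressionMatrix(m.platform_id, "log2",
                            pd.DataFrame(vals, index=m.values.index,
                                         columns=m.values.columns))


def median_baseline(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature baseline correction to the median of all samples."""
    if m.scale != "log2":
        raise PreprocessError(f"median_baseline expects log2 scale, got {m.scale}")
    vals = m.values.to_numpy(float)
    med = np.nanmedian(np.where(np.isfinite(vals), vals, np.nan), axis=1)
    if np.isnan(med).any():
        bad = m.values.index[np.isnan(med)][0]
        raise PreprocessError(f"feature {bad} is entirely missing")
    return ExpressionMatrix(m.platform_id, "log2_norm",
                            pd.DataFrame(vals - med[:, None],
                                         index=m.values.index,
                                         columns=m.values.columns))


def normalize_chain(m: ExpressionMatrix, min_signal: float,
                    min_samples: int = 1, q: float = 75.0,
                    floor: float = 1.0) -> ExpressionMatrix:
    """Full probe-platform chain; FPKM matrices pass through untouched."""
    if m.scale == "fpkm":
        return m
    m = detection_filter(m, min_signal, min_samples)
    m = log2_transform(m, floor)
    m = percentile_shift(m, q)
    return median_baseline(m)
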