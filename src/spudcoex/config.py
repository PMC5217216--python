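"""Configuration: analysis thresholds and synthetic-study design.

Two frozen parameter bundles drive the whole pipeline:

* :class:`ParamSet` — every numeric threshold of the analysis (probe
  identity, tissue fold-change, PCC cutoff, p-value flag, normalization
  percentile, ...).
* :class:`SimConfig` — the synthetic study design: genome/gene-model
  geometry, probe defect rates, planted expression structure and the
  sample design (tissue, stage, replicates).

Both load from a single YAML file via :func:`load_config`; unknown keys
are rejected so typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
import yaml

# Ordinal encoding of the developmental vocabulary: the tuberization
# series stage1..stage5 (unswollen stolon -> small tuber) followed by
# growing and dormant tubers, mapped onto a single ordinal axis.
STAGE_RANK: dict[str, int] = {
    "stage1": 1,
    "stage2": 2,
    "stage3": 3,
    "stage4": 4,
    "stage5": 5,
    "growing": 6,
    "dormant": 7,
}

TISSUES = ("leaf", "stolon", "tuber", "sprout")
#: Tissues pooled into the "tuber" group when scoring tissue specificity.
TUBER_GROUP = ("stolon", "tuber", "sprout")

#: Probe-level microarray platforms and the gene-level RNA-Seq platform.
ARRAY_PLATFORMS = ("arrayA", "arrayB")
FPKM_PLATFORM = "fpkm"
ALL_PLATFORMS = ARRAY_PLATFORMS + (FPKM_PLATFORM,)


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass(frozen=True)
class ParamSet:
    """Numeric thresholds of the analysis.

    Attributes
    ----------
    min_identity:
        Minimum percent identity (over full probe length) for a probe to
        be accepted as representing a gene.
    tissue_fc_threshold:
        Linear fold-change between leaf and the tuber group above which
        (strictly) a gene is called tissue-specific.
    pcc_cutoff:
        Inclusive Pearson correlation cutoff for co-expression.
    p_threshold:
        Two-sided p-value at or below which a correlation is flagged.
    percentile_q:
        Per-sample normalization percentile.
    fpkm_pseudocount:
        Added to FPKM group means before forming the leaf/tuber ratio.
    dev_min_log2fc:
        Minimum stage5-vs-stage1 log2 fold-change for query selection.
    n_queries:
        Number of query genes returned by selection.
    min_signal:
        Raw-intensity detection threshold (detected in >= min_samples).
    min_samples:
        Number of samples in which ``min_signal`` must be reached.
    min_pairs:
        Minimum pairwise-complete observations for a correlation.
    fpkm_log:
        Correlate RNA-Seq data on log2(FPKM+1) (default) instead of the
        raw linear FPKM values used by the original spreadsheet recipe.
    log2_floor:
        Linear floor applied before log2 transform of raw intensities.
    """

    min_identity: float = 85.0
    tissue_fc_threshold: float = 10.0
    pcc_cutoff: float = 0.8
    p_threshold: float = 0.1
    percentile_q: float = 75.0
    fpkm_pseudocount: float = 0.1
    dev_min_log2fc: float = 1.0
    n_queries: int = 3
    min_signal: float = 8.0
    min_samples: int = 1
    min_pairs: int = 3
    fpkm_log: bool = True
    log2_floor: float = 1.0

    def validate(self) -> "ParamSet":
        if not (0.0 < self.pcc_cutoff <= 1.0):
            raise ConfigError(f"pcc_cutoff must be in (0, 1], got {self.pcc_cutoff}")
        for name in (
            "min_identity",
            "tissue_fc_threshold",
            "p_threshold",
            "percentile_q",
            "fpkm_pseudocount",
            "dev_min_log2fc",
            "log2_floor",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_identity > 100:
            raise ConfigError("min_identity is a percentage <= 100")
        if self.percentile_q > 100:
            raise ConfigError("percentile_q is a percentage <= 100")
        if self.p_threshold > 1:
            raise ConfigError("p_threshold must be <= 1")
        if self.n_queries < 1 or self.min_pairs < 2 or self.min_samples < 1:
            raise ConfigError("n_queries, min_pairs and min_samples must be >= 1")
        return self


def _default_sample_design() -> list[tuple[str, str, int]]:
    # Leaves sampled alongside the tuberization series plus growing and
    # dormant tuber material: 36 biological samples per platform.
    design = [("leaf", f"stage{i}", 3) for i in range(1, 6)]
    design += [("stolon", f"stage{i}", 3) for i in range(1, 4)]
    design += [("tuber", "stage4", 3), ("tuber", "stage5", 3), ("tuber", "growing", 3)]
    design += [("sprout", "dormant", 3)]
    return design


@dataclass(frozen=True)
class SimConfig:
    """Synthetic study design (see docs/methods.md for rationale).

    Planted structure: ``n_tissue_specific_*`` genes carry a +/- tissue
    effect, ``n_ramp_genes`` carry a developmental slope of random sign,
    and ``module_size`` genes (containing the ``n_query_genes`` queries)
    load on a shared latent factor that tracks the tuber developmental
    program with weight ``module_program_weight``.
    """

    n_genes: int = 2000
    n_chromosomes: int = 12
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (120, 400)
    intron_len: tuple[int, int] = (60, 250)
    intergenic_len: tuple[int, int] = (100, 300)
    probes_per_gene: tuple[int, int] = (1, 3)
    probe_len: int = 60

    frac_low_identity_probes: float = 0.10
    frac_intronic_probes: float = 0.10
    frac_crosshyb_probes: float = 0.05

    n_tissue_specific_leaf: int = 20
    n_tissue_specific_tuber: int = 20
    tissue_log2_effect: float = math.log2(20.0)
    n_ramp_genes: int = 20
    ramp_log2_per_stage: float = 0.5
    query_ramp_log2_per_stage: float = 1.5
    module_size: int = 15
    n_query_genes: int = 3
    module_loading: float = 1.5
    module_program_weight: float = 0.9
    noise_sd: float = 0.5
    probe_noise_sd: float = 0.1
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    invalid_probe_log2_mean: float = 5.0
    invalid_probe_log2_sd: float = 1.0
    background_floor: float = 1.0
    fpkm_scale: float = 1.0
    sample_design: tuple[tuple[str, str, int], ...] = field(
        default_factory=lambda: tuple(_default_sample_design())
    )
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ConfigError("n_genes and n_chromosomes must be >= 1")
        for name in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len",
                     "probes_per_gene"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ConfigError(f"{name} must be a (low, high) range with 1 <= low <= high")
        if self.intron_len[0] < 4:
            raise ConfigError("intron lengths < 4 bp give degenerate gene models")
        if self.probe_len < 20:
            raise ConfigError("probe_len must be >= 20")
        if self.probe_len > self.exon_len[0]:
            raise ConfigError("probe_len must not exceed the shortest exon")
        fracs = (
            self.frac_low_identity_probes,
            self.frac_intronic_probes,
            self.frac_crosshyb_probes,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ConfigError("probe defect fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ConfigError("probe defect fractions must sum to <= 1")
        if (self.frac_low_identity_probes or self.frac_intronic_probes) and \
                self.probes_per_gene[1] < 2:
            raise ConfigError(
                "probe defects require probes_per_gene upper bound >= 2 "
                "(one valid probe per gene is always preserved)")
        if self.module_size < self.n_query_genes:
            raise ConfigError("module_size must be >= n_query_genes")
        planted = (self.n_tissue_specific_leaf + self.n_tissue_specific_tuber +
                   self.n_ramp_genes + self.module_size)
        if planted > self.n_genes:
            raise ConfigError("planted gene roles exceed n_genes")
        if not self.sample_design:
            raise ConfigError("sample_design must not be empty")
        for tissue, stage, reps in self.sample_design:
            if tissue not in TISSUES:
                raise ConfigError(f"unknown tissue {tissue!r}")
            if stage not in STAGE_RANK:
                raise ConfigError(f"unknown stage {stage!r}")
            if reps < 1:
                raise ConfigError("replicate counts must be >= 1")
        if not (0.0 <= self.module_program_weight <= 1.0):
            raise ConfigError("module_program_weight must lie in [0, 1]")
        for name in ("noise_sd", "probe_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.fpkm_scale <= 0 or self.background_floor <= 0:
            raise ConfigError("fpkm_scale and background_floor must be positive")
        return self

    @property
    def n_biological_samples(self) -> int:
        return sum(reps for _, _, reps in self.sample_design)


_STAGE_DEFAULT_TOGGLES = {
    "simulate": True,
    "validate_probes": True,
    "normalize": True,
    "specificity": True,
    "select_queries": True,
    "coexpress": True,
    "consensus": True,
    "qpcr": True,
}


def _build(cls, section: dict, label: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown {label} key(s): {', '.join(sorted(unknown))}")
    kwargs = dict(section)
    # YAML lists come back as lists; the dataclasses use tuples.
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            v = kwargs[f.name]
            kwargs[f.name] = tuple(tuple(x) if isinstance(x, list) else x for x in v)
    return cls(**kwargs).validate()


def load_config(path) -> tuple[SimConfig, ParamSet, dict[str, bool]]:
    """Load a YAML config with ``simulation:``, ``params:`` and ``stages:``
    sections (all optional; missing keys take the documented defaults)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - {"simulation", "params", "stages"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    sim = _build(SimConfig, raw.get("simulation") or {}, "simulation")
    params = _build(ParamSet, raw.get("params") or {}, "params")
    stages = dict(_STAGE_DEFAULT_TOGGLES)
    for key, val in (raw.get("stages") or {}).items():
        if key not in stages:
            raise ConfigError(f"unknown stage toggle: {key}")
        stages[key] = bool(val)
    return sim, params, stages
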