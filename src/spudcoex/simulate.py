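"""Synthetic genomes, probes and three-platform expression data.

The generator plants a known ground truth so every downstream stage of
the pipeline (probe validation, normalization, tissue-specificity
scoring, query selection, co-expression consensus) can be checked
against it:

* a small multi-chromosome genome with multi-exon gene models,
* two probe-level microarray platforms whose 60-mers are drawn from the
  transcripts, with configurable fractions of defective probes
  (< 85% identity, intron-binding, cross-hybridizing),
* a gene-level FPKM platform,
* leaf / stolon / tuber / sprout samples across developmental stages,
* planted tissue-specific genes, stage-ramp genes and a latent-factor
  co-expression module containing the query genes.

Expression model (log2 scale), for gene *g* in biological sample *s*::

    y_gs = mu_g + t_g * 1[tissue(s) in tuber group]
                + d_g * rank(stage(s)) + lambda_g * z_s + eps_gs

with ``eps ~ N(0, noise_sd^2)`` drawn per platform and the module factor
``z_s = w * p_s + sqrt(1 - w^2) * eta_s`` shared across platforms, where
``p`` is the standardized tuber-development program (the query genes'
tissue + ramp profile) and ``eta`` is iid standard normal.  With unit
variance of ``z`` the expected correlation between two plain module
genes is ``lambda^2 / (lambda^2 + noise_sd^2)`` regardless of ``w``;
``w`` controls how strongly the module tracks tuber development and is
what makes the planted module discoverable from query genes that are
themselves tuber-specific and developmentally ramped.  Setting
``module_loading = 0`` removes all planted co-expression (null model).

Identical :class:`~spudcoex.config.SimConfig` plus seed give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ARRAY_PLATFORMS,
    FPKM_PLATFORM,
    STAGE_RANK,
    TUBER_GROUP,
    ConfigError,
    SimConfig,
)
from .preprocess import ExpressionMatrix
from .probe_validation import GeneModel, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Width of a duplicated exon window shared by a cross-hybridizing
#: gene pair; leaves room for distinct probe offsets per platform.
_DUP_WINDOW_PAD = 30

#: Length of the exact block preserved in low-identity probes; keeps
#: them discoverable by k-mer candidate screening while their best
#: identity stays below the acceptance threshold.
_PRESERVED_BLOCK = 24

QPCR_REFERENCE_GENE = "EF1a"


@dataclass
class ProbeTruth:
    probe_id: str
    platform: str
    true_gene: str
    identity: float
    intronic: bool
    crosshyb: bool


@dataclass
class GroundTruth:
    """Planted truth: gene roles, probe provenance and the latent factor."""

    roles: dict[str, str] = field(default_factory=dict)
    probes: dict[str, ProbeTruth] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    module_genes: list[str] = field(default_factory=list)
    query_genes: list[str] = field(default_factory=list)
    duplicated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]

    def to_json(self) -> str:
        payload = {
            "roles": self.roles,
            "probes": {p: dataclasses.asdict(t) for p, t in self.probes.items()},
            "z": self.z,
            "module_genes": self.module_genes,
            "query_genes": self.query_genes,
            "duplicated_pairs": [list(p) for p in self.duplicated_pairs],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            roles=d["roles"],
            probes={p: ProbeTruth(**t) for p, t in d["probes"].items()},
            z={k: float(v) for k, v in d["z"].items()},
            module_genes=d["module_genes"],
            query_genes=d["query_genes"],
            duplicated_pairs=[tuple(p) for p in d["duplicated_pairs"]],
        )


@dataclass
class GeneLayout:
    """Internal per-gene geometry in strand-oriented local coordinates."""

    gene_id: str
    chromosome: str
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    seq: bytearray  # pre-mRNA, genomic plus-strand orientation
    start: int = 0  # absolute chromosome start (filled at assembly)
    forbidden: list[tuple[int, int]] = field(default_factory=list)  # transcript coords

    @property
    def length(self) -> int:
        return sum(self.exon_lens) + sum(self.intron_lens)

    def local_exons_plus(self) -> list[tuple[int, int]]:
        """Exon intervals within the plus-strand pre-mRNA."""
        out, pos = [], 0
        for i, el in enumerate(self.exon_lens):
            out.append((pos, pos + el))
            pos += el
            if i < len(self.intron_lens):
                pos += self.intron_lens[i]
        return out

    def premrna_oriented(self) -> str:
        s = self.seq.decode("ascii") if isinstance(self.seq, (bytes, bytearray)) else self.seq
        return s if self.strand == "+" else reverse_complement(s)

    def local_exons_oriented(self) -> list[tuple[int, int]]:
        """Exon intervals within the strand-oriented pre-mRNA."""
        exons = self.local_exons_plus()
        if self.strand == "+":
            return exons
        n = self.length
        return [(n - e, n - s) for s, e in reversed(exons)]

    def transcript(self) -> str:
        pre = self.premrna_oriented()
        return "".join(pre[s:e] for s, e in self.local_exons_oriented())


@dataclass
class SimResult:
    """Bundle returned by :func:`generate`."""

    config: SimConfig
    chromosomes: dict[str, str]
    models: list[GeneModel]
    transcripts: dict[str, str]
    premrnas: dict[str, str]
    probes: dict[str, dict[str, str]]  # platform -> probe_id -> sequence
    matrices: dict[str, ExpressionMatrix]
    sample_sheet: pd.DataFrame
    truth: GroundTruth


def _random_bases(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=n)].tobytes())


def _assign_roles(cfg: SimConfig, gene_ids: list[str], rng: np.random.Generator) -> GroundTruth:
    truth = GroundTruth(roles={g: "background" for g in gene_ids})
    order = [gene_ids[i] for i in rng.permutation(len(gene_ids))]
    it = iter(order)

    def take(n):
        return [next(it) for _ in range(n)]

    module = sorted(take(cfg.module_size))
    queries = module[: cfg.n_query_genes]
    for g in module:
        truth.roles[g] = "module"
    for g in queries:
        truth.roles[g] = "query"
    for g in take(cfg.n_tissue_specific_leaf):
        truth.roles[g] = "leaf_specific"
    for g in take(cfg.n_tissue_specific_tuber):
        truth.roles[g] = "tuber_specific"
    for g in take(cfg.n_ramp_genes):
        truth.roles[g] = "ramp"
    truth.module_genes = module
    truth.query_genes = queries
    return truth


# ---------------------------------------------------------------------------
# Gene models and sequences
# ---------------------------------------------------------------------------

def simulate_gene_models(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate genome sequences, gene models and transcript sequences.

    Returns ``(chromosomes, models, transcripts, premrnas, truth, layouts)``.
    Transcripts honor strand: on the minus strand the spliced transcript
    is the reverse complement of the concatenated exon sequence.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    gene_ids = [f"gene{str(i + 1).zfill(width)}" for i in range(cfg.n_genes)]
    truth = _assign_roles(cfg, gene_ids, rng)

    layouts: list[GeneLayout] = []
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chromosomes)
    for idx, gid in enumerate(gene_ids):
        chrom = f"chr{idx // per_chrom + 1:02d}"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                     for _ in range(n_ex)]
        intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                       for _ in range(n_ex - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        lay = GeneLayout(gid, chrom, strand, exon_lens, intron_lens, bytearray())
        lay.seq = _random_bases(rng, lay.length)
        layouts.append(lay)

    _plant_duplications(cfg, layouts, truth, rng)

    # Assemble chromosomes: intergenic spacer, gene, spacer, gene, ...
    chromosomes: dict[str, str] = {}
    models: list[GeneModel] = []
    by_chrom: dict[str, list[GeneLayout]] = {}
    for lay in layouts:
        by_chrom.setdefault(lay.chromosome, []).append(lay)
    for chrom, genes in by_chrom.items():
        parts: list[bytes] = []
        cursor = 0
        for lay in genes:
            gap = int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
            parts.append(bytes(_random_bases(rng, gap)))
            cursor += gap
            lay.start = cursor
            parts.append(bytes(lay.seq))
            cursor += lay.length
            exons = tuple((lay.start + s, lay.start + e) for s, e in lay.local_exons_plus())
            models.append(GeneModel(
                gene_id=lay.gene_id, chromosome=chrom, strand=lay.strand,
                exons=exons, transcript_id=f"{lay.gene_id}.t1"))
        tail = int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
        parts.append(bytes(_random_bases(rng, tail)))
        chromosomes[chrom] = b"".join(parts).decode("ascii")

    transcripts = {lay.gene_id: lay.transcript() for lay in layouts}
    premrnas = {lay.gene_id: lay.premrna_oriented() for lay in layouts}
    return chromosomes, models, transcripts, premrnas, truth, layouts


def _plant_duplications(cfg: SimConfig, layouts: list[GeneLayout],
                        truth: GroundTruth, rng: np.random.Generator) -> None:
    """Copy an exonic window between background gene pairs so that probes
    drawn from the window hybridize to two genes."""
    if cfg.frac_crosshyb_probes <= 0:
        return
    window = cfg.probe_len + _DUP_WINDOW_PAD
    n_pairs = math.ceil(cfg.frac_crosshyb_probes * cfg.n_genes * cfg.probes_per_gene[1])
    # Plus-strand background genes with a long-enough exon keep the
    # transcript-coordinate bookkeeping simple.
    eligible = [lay for lay in layouts
                if truth.roles[lay.gene_id] == "background" and lay.strand == "+"
                and max(lay.exon_lens) >= window]
    if len(eligible) < 2:
        raise ConfigError("not enough background genes to plant cross-hybridizing pairs")
    n_pairs = min(n_pairs, len(eligible) // 2)
    chosen = [eligible[i] for i in rng.permutation(len(eligible))[: 2 * n_pairs]]
    for donor, host in zip(chosen[0::2], chosen[1::2]):
        d_off, d_tx = _exon_window(donor, window, rng)
        h_off, h_tx = _exon_window(host, window, rng)
        host.seq[h_off:h_off + window] = donor.seq[d_off:d_off + window]
        donor.forbidden.append((d_tx, d_tx + window))
        host.forbidden.append((h_tx, h_tx + window))
        truth.duplicated_pairs.append((donor.gene_id, host.gene_id))


def _exon_window(lay: GeneLayout, window: int, rng: np.random.Generator):
    """Pick a window inside an exon; returns (premrna offset, transcript offset)."""
    exons = lay.local_exons_plus()
    tx_off = 0
    candidates = []
    for s, e in exons:
        if e - s >= window:
            candidates.append((s, e, tx_off))
        tx_off += e - s
    s, e, tx0 = candidates[int(rng.integers(0, len(candidates)))]
    off = int(rng.integers(s, e - window + 1))
    return off, tx0 + (off - s)


# ---------------------------------------------------------------------------
# Probes
# ---------------------------------------------------------------------------

def simulate_probes(cfg: SimConfig, layouts: list[GeneLayout], truth: GroundTruth,
                    rng: np.random.Generator) -> dict[str, dict[str, str]]:
    """Draw probe sets for both microarray platforms and record their truth.

    Most probes are exact exonic 60-mers.  A fraction are planted defective:
    low-identity (substitutions pushing best identity below 85%), intronic
    (verbatim intron sequence) or cross-hybridizing (drawn from an exon
    window duplicated into a second gene).  The first probe of every gene
    is always left valid so each gene stays measurable.
    """
    shortest = min(sum(lay.exon_lens) for lay in layouts)
    if cfg.probe_len > shortest:
        raise ConfigError(
            f"probe_len {cfg.probe_len} exceeds the shortest transcript ({shortest} nt)")

    lay_by_gene = {lay.gene_id: lay for lay in layouts}
    probes: dict[str, dict[str, str]] = {}
    for plat_idx, platform in enumerate(ARRAY_PLATFORMS):
        slots: list[tuple[str, int]] = []
        for lay in layouts:
            n_p = int(rng.integers(cfg.probes_per_gene[0], cfg.probes_per_gene[1] + 1))
            slots.extend((lay.gene_id, k) for k in range(n_p))
        n_total = len(slots)
        n_low = round(cfg.frac_low_identity_probes * n_total)
        n_int = round(cfg.frac_intronic_probes * n_total)
        n_ch = round(cfg.frac_crosshyb_probes * n_total)

        # Defects only ever replace probe slots >= 1; slot 0 stays valid.
        spare = [i for i, (_, k) in enumerate(slots) if k >= 1]
        intron_ok = [i for i in spare
                     if any(il >= cfg.probe_len for il in lay_by_gene[slots[i][0]].intron_lens)]
        if n_int > len(intron_ok):
            raise ConfigError("not enough introns >= probe_len for the requested "
                              "intronic probe fraction")
        picked_int = set(rng.choice(intron_ok, size=n_int, replace=False).tolist()) \
            if n_int else set()
        low_pool = [i for i in spare if i not in picked_int]
        if n_low > len(low_pool):
            raise ConfigError("not enough spare probe slots for the requested "
                              "low-identity fraction")
        picked_low = set(rng.choice(low_pool, size=n_low, replace=False).tolist()) \
            if n_low else set()
        if n_ch > len(truth.duplicated_pairs):
            raise ConfigError("not enough duplicated gene pairs for the requested "
                              "cross-hybridization fraction")

        plat_probes: dict[str, str] = {}
        counter = 0

        def new_id():
            nonlocal counter
            counter += 1
            return f"{platform}_p{counter:05d}"

        for i, (gid, _slot) in enumerate(slots):
            lay = lay_by_gene[gid]
            pid = new_id()
            if i in picked_int:
                seq = _intron_probe(lay, cfg.probe_len, rng)
                plat_probes[pid] = seq
                truth.probes[pid] = ProbeTruth(pid, platform, gid, 100.0, True, False)
            elif i in picked_low:
                seq, identity = _low_identity_probe(lay, cfg.probe_len, rng)
                plat_probes[pid] = seq
                truth.probes[pid] = ProbeTruth(pid, platform, gid, identity, False, False)
            else:
                seq = _exonic_probe(lay, cfg.probe_len, rng)
                plat_probes[pid] = seq
                truth.probes[pid] = ProbeTruth(pid, platform, gid, 100.0, False, False)

        for donor_id, _host_id in truth.duplicated_pairs[:n_ch]:
            lay = lay_by_gene[donor_id]
            tx_start, tx_end = lay.forbidden[0]
            offset = tx_start + plat_idx * (_DUP_WINDOW_PAD // 2)
            seq = lay.transcript()[offset:offset + cfg.probe_len]
            pid = new_id()
            plat_probes[pid] = seq
            truth.probes[pid] = ProbeTruth(pid, platform, donor_id, 100.0, False, True)

        probes[platform] = plat_probes
    return probes


def _exonic_probe(lay: GeneLayout, length: int, rng: np.random.Generator) -> str:
    tx = lay.transcript()
    # Strand-oriented forbidden windows (duplicated regions).
    if lay.strand == "+":
        forb = lay.forbidden
    else:
        n = len(tx)
        forb = [(n - e, n - s) for s, e in lay.forbidden]
    for _ in range(64):
        start = int(rng.integers(0, len(tx) - length + 1))
        if all(start + length <= s or start >= e for s, e in forb):
            return tx[start:start + length]
    return tx[: length]  # pragma: no cover - dense forbidden layout


def _intron_probe(lay: GeneLayout, length: int, rng: np.random.Generator) -> str:
    pre = lay.premrna_oriented()
    exons = lay.local_exons_oriented()
    introns = [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]
    introns = [iv for iv in introns if iv[1] - iv[0] >= length]
    s, e = introns[int(rng.integers(0, len(introns)))]
    start = int(rng.integers(s, e - length + 1))
    return pre[start:start + length]


def _low_identity_probe(lay: GeneLayout, length: int,
                        rng: np.random.Generator) -> tuple[str, float]:
    """Mutate an exonic probe until its best achievable identity against
    its own gene drops below 85%.

    Substitution counts alone do not bound the identity of the *best
    local alignment* (gapped alignments can re-match shifted bases), so
    each draw is certified with the aligner and re-mutated if a gapped
    alignment still reaches the threshold.
    """
    from .probe_validation import local_align, reverse_complement

    base = _exonic_probe(lay, length, rng)
    tx, pre = lay.transcript(), lay.premrna_oriented()
    n_sub = math.floor(0.15 * length) + 1 + int(rng.integers(0, 3))
    block_start = int(rng.integers(0, length - _PRESERVED_BLOCK + 1))
    positions = [p for p in range(length)
                 if not (block_start <= p < block_start + _PRESERVED_BLOCK)]
    for _attempt in range(16):
        chosen = rng.choice(positions, size=min(n_sub, len(positions)),
                            replace=False)
        seq = bytearray(base, "ascii")
        for p in chosen:
            old = seq[p]
            alternatives = [b for b in b"ACGT" if b != old]
            seq[p] = alternatives[int(rng.integers(0, 3))]
        probe = seq.decode("ascii")
        best = max(local_align(probe, tx).n_matches,
                   local_align(probe, pre).n_matches,
                   local_align(reverse_complement(probe), tx).n_matches,
                   local_align(reverse_complement(probe), pre).n_matches)
        if best * 100.0 < 85.0 * length:
            return probe, 100.0 * best / length
        n_sub = min(n_sub + 2, len(positions))
    raise ConfigError("could not construct a low-identity probe")  # pragma: no cover


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _biological_samples(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for tissue, stage, reps in cfg.sample_design:
        for r in range(1, reps + 1):
            rows.append({
                "bio_id": f"{tissue}_{stage}_r{r}",
                "tissue": tissue,
                "stage": stage,
                "replicate": r,
                "rank": STAGE_RANK[stage],
                "in_tuber_group": tissue in TUBER_GROUP,
            })
    return pd.DataFrame(rows)


def _development_program(cfg: SimConfig, bio: pd.DataFrame) -> np.ndarray:
    """Standardized tuber-development profile across the sample design."""
    f = (cfg.tissue_log2_effect * bio["in_tuber_group"].to_numpy(float)
         + cfg.query_ramp_log2_per_stage * bio["rank"].to_numpy(float))
    sd = f.std()
    if sd < 1e-12:
        return np.zeros(len(f))
    return (f - f.mean()) / sd


def _gene_effects(cfg: SimConfig, truth: GroundTruth, gene_ids: list[str],
                  rng: np.random.Generator):
    n = len(gene_ids)
    mu = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, n)
    t = np.zeros(n)
    d = np.zeros(n)
    lam = np.zeros(n)
    for i, g in enumerate(gene_ids):
        role = truth.roles[g]
        if role == "leaf_specific":
            t[i] = -cfg.tissue_log2_effect
        elif role == "tuber_specific":
            t[i] = cfg.tissue_log2_effect
        elif role == "ramp":
            # Decoys ramp up or down; down-ramps emulate genes repressed
            # during tuber development.
            sign = 1.0 if rng.random() < 0.5 else -1.0
            d[i] = sign * cfg.ramp_log2_per_stage
        elif role == "module":
            lam[i] = cfg.module_loading
        elif role == "query":
            # Queries are tuber-specific, developmentally ramped members
            # of the module -- the profile they are selected for.
            t[i] = cfg.tissue_log2_effect
            d[i] = cfg.query_ramp_log2_per_stage
            lam[i] = cfg.module_loading
    return mu, t, d, lam


def simulate_expression(cfg: SimConfig, truth: GroundTruth,
                        probes: dict[str, dict[str, str]],
                        rng: np.random.Generator):
    """Simulate raw microarray matrices, the FPKM matrix and the sample sheet.

    Returns ``(matrices, sample_sheet)`` where ``matrices`` maps platform id
    to :class:`~spudcoex.preprocess.ExpressionMatrix` (microarrays on the
    raw linear scale, RNA-Seq on the FPKM scale).
    """
    bio = _biological_samples(cfg)
    gene_ids = sorted(truth.roles)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    mu, t, d, lam = _gene_effects(cfg, truth, gene_ids, rng)

    p = _development_program(cfg, bio)
    # A design without tissue/stage variation has no program axis; the
    # factor is then pure noise at full (unit) variance.
    w = cfg.module_program_weight if p.any() else 0.0
    eta = rng.normal(0.0, 1.0, len(bio))
    z = w * p + math.sqrt(1.0 - w * w) * eta
    truth.z = dict(zip(bio["bio_id"], z))

    tub = bio["in_tuber_group"].to_numpy(float)
    rank = bio["rank"].to_numpy(float)
    signal = (mu[:, None] + np.outer(t, tub) + np.outer(d, rank)
              + np.outer(lam, z))

    matrices: dict[str, ExpressionMatrix] = {}
    sheets = []
    for platform in ARRAY_PLATFORMS:
        eps = rng.normal(0.0, cfg.noise_sd, signal.shape)
        y = signal + eps
        plat_probes = probes[platform]
        rows = np.empty((len(plat_probes), len(bio)))
        pids = list(plat_probes)
        for r, pid in enumerate(pids):
            tr = truth.probes[pid]
            if tr.intronic or tr.identity < 85.0:
                # Defective probes measure hybridization noise unrelated
                # to their nominal gene.
                level = rng.normal(cfg.invalid_probe_log2_mean, cfg.invalid_probe_log2_sd)
                rows[r] = level + rng.normal(0.0, cfg.noise_sd, len(bio))
            else:
                g = gene_index[tr.true_gene]
                rows[r] = y[g] + rng.normal(0.0, cfg.probe_noise_sd, len(bio))
        raw = np.maximum(np.exp2(rows), cfg.background_floor)
        sample_ids = [f"{platform}.{b}" for b in bio["bio_id"]]
        df = pd.DataFrame(raw, index=pids, columns=sample_ids)
        matrices[platform] = ExpressionMatrix(platform, "raw_linear", df)
        sheets.append(_platform_sheet(bio, platform, sample_ids))

    eps = rng.normal(0.0, cfg.noise_sd, signal.shape)
    fpkm = cfg.fpkm_scale * np.exp2(signal + eps)
    sample_ids = [f"{FPKM_PLATFORM}.{b}" for b in bio["bio_id"]]
    df = pd.DataFrame(fpkm, index=gene_ids, columns=sample_ids)
    matrices[FPKM_PLATFORM] = ExpressionMatrix(FPKM_PLATFORM, "fpkm", df)
    sheets.append(_platform_sheet(bio, FPKM_PLATFORM, sample_ids))

    sheet = pd.concat(sheets, ignore_index=True)
    return matrices, sheet


def _platform_sheet(bio: pd.DataFrame, platform: str, sample_ids: list[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": sample_ids,
        "platform_id": platform,
        "tissue": bio["tissue"].to_numpy(),
        "stage": bio["stage"].to_numpy(),
        "replicate": bio["replicate"].to_numpy(),
    })


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

_QPCR_STAGE_TISSUE = {
    "stage1": "stolon", "stage2": "stolon", "stage3": "stolon",
    "stage4": "tuber", "stage5": "tuber", "growing": "tuber",
    "dormant": "sprout",
}


def simulate_qpcr(cfg: SimConfig, truth: GroundTruth, gene_ids: list[str],
                  stages: tuple[str, ...] = ("stage1", "stage3", "stage5",
                                             "growing", "dormant"),
                  n_biological: int = 4, n_technical: int = 2,
                  technical_sd: float = 0.05,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a long-format qRT-PCR CT table on an independent sample set.

    Samples follow the tuber developmental series; target CT values are
    ``32 - y`` for the same latent expression model (fresh replicates and
    latent-factor draws), the reference gene sits at CT 20, and each
    measurement gets ``n_technical`` technical replicates with
    ``technical_sd`` cycles of technical noise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    unknown = [g for g in gene_ids if g not in truth.roles]
    if unknown:
        raise ConfigError(f"unknown gene id(s) for qPCR: {unknown}")
    all_genes = sorted(truth.roles)
    idx = {g: i for i, g in enumerate(all_genes)}
    mu, t, d, lam = _gene_effects(cfg, truth, all_genes,
                                  np.random.default_rng(cfg.seed + 2))

    bio = pd.DataFrame([
        {"bio_id": f"qpcr_{st}_b{r}", "tissue": _QPCR_STAGE_TISSUE[st],
         "stage": st, "replicate": r, "rank": STAGE_RANK[st],
         "in_tuber_group": _QPCR_STAGE_TISSUE[st] in TUBER_GROUP}
        for st in stages for r in range(1, n_biological + 1)
    ])
    p = _development_program(cfg, bio)
    w = cfg.module_program_weight if p.any() else 0.0
    z = w * p + math.sqrt(1.0 - w * w) * rng.normal(0.0, 1.0, len(bio))

    rows = []
    tub = bio["in_tuber_group"].to_numpy(float)
    rank = bio["rank"].to_numpy(float)
    for s in range(len(bio)):
        sample = bio.iloc[s]
        ct_ref = 20.0
        for tech in range(n_technical):
            rows.append({
                "sample_id": sample["bio_id"], "stage": sample["stage"],
                "replicate": int(sample["replicate"]),
                "gene_id": QPCR_REFERENCE_GENE,
                "ct": ct_ref + rng.normal(0.0, technical_sd),
                "is_reference": True,
            })
        for g in gene_ids:
            i = idx[g]
            y = (mu[i] + t[i] * tub[s] + d[i] * rank[s] + lam[i] * z[s]
                 + rng.normal(0.0, cfg.noise_sd))
            ct = 32.0 - y
            for tech in range(n_technical):
                rows.append({
                    "sample_id": sample["bio_id"], "stage": sample["stage"],
                    "replicate": int(sample["replicate"]), "gene_id": g,
                    "ct": ct + rng.normal(0.0, technical_sd),
                    "is_reference": False,
                })
    df = pd.DataFrame(rows)
    if ((df["ct"] <= 0) | (df["ct"] >= 45)).any():
        raise ConfigError("simulated CT values left the (0, 45) cycle range")
    return df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def generate(cfg: SimConfig, seed: int | None = None) -> SimResult:
    """Run the full generator: genome, probes, expression, sample sheet."""
    cfg.validate()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    chromosomes, models, transcripts, premrnas, truth, layouts = \
        simulate_gene_models(cfg, rng)
    probes = simulate_probes(cfg, layouts, truth, rng)
    matrices, sheet = simulate_expression(cfg, truth, probes, rng)
    return SimResult(cfg, chromosomes, models, transcripts, premrnas,
                     probes, matrices, sheet, truth)
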