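"""Generator contracts: determinism, gene-model geometry, planted effects."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from spudcoex import ConfigError, generate
from spudcoex.io import spliced_sequences, write_fasta, write_gff3
from spudcoex.simulate import simulate_gene_models, simulate_qpcr
from conftest import SMALL_CFG


def _pairwise_mean_r(df: pd.DataFrame) -> float:
    r = np.corrcoef(df.to_numpy(float))
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


class TestGeneModels:
    def test_exon_counts_and_gene_count_match_config(self, small_sim):
        cfg = SMALL_CFG
        assert len(small_sim.models) == cfg.n_genes
        for m in small_sim.models:
            assert cfg.exons_per_gene[0] <= len(m.exons) <= cfg.exons_per_gene[1]
            for s, e in m.exons:
                assert cfg.exon_len[0] <= e - s <= cfg.exon_len[1]

    def test_transcript_is_spliced_genomic_sequence(self, small_sim):
        tx, pre = spliced_sequences({m.gene_id: m for m in small_sim.models},
                                    small_sim.chromosomes)
        assert tx == small_sim.transcripts
        assert pre == small_sim.premrnas

    def test_single_exon_transcript_equals_genomic_span(self):
        cfg = dataclasses.replace(
            SMALL_CFG, n_genes=20, exons_per_gene=(1, 1),
            n_tissue_specific_leaf=1, n_tissue_specific_tuber=1,
            n_ramp_genes=1, module_size=3,
            frac_intronic_probes=0.0)
        chroms, models, tx, pre, truth, _ = simulate_gene_models(cfg)
        for m in models:
            span = chroms[m.chromosome][m.start:m.end]
            expect = span if m.strand == "+" else _revcomp(span)
            assert tx[m.gene_id] == expect == pre[m.gene_id]

    def test_degenerate_intron_range_rejected(self):
        cfg = dataclasses.replace(SMALL_CFG, intron_len=(2, 50))
        with pytest.raises(ConfigError, match="intron"):
            cfg.validate()

    def test_probe_longer_than_shortest_exon_rejected(self):
        cfg = dataclasses.replace(SMALL_CFG, probe_len=500)
        with pytest.raises(ConfigError):
            cfg.validate()


def _revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestDeterminism:
    def test_same_seed_identical_files(self, tmp_path):
        cfg = dataclasses.replace(SMALL_CFG, n_genes=60, module_size=5,
                                  n_tissue_specific_leaf=3,
                                  n_tissue_specific_tuber=3, n_ramp_genes=3)
        outs = []
        for run in ("a", "b"):
            sim = generate(cfg, seed=5)
            fa = tmp_path / f"{run}.fasta"
            gff = tmp_path / f"{run}.gff3"
            write_fasta(sim.chromosomes, fa)
            write_gff3(sim.models, gff)
            outs.append((fa.read_bytes(), gff.read_bytes(),
                         {p: d for p, d in sim.probes.items()},
                         {p: m.values.to_csv() for p, m in sim.matrices.items()}))
        assert outs[0] == outs[1]


class TestProbes:
    def test_zero_defect_fractions_all_probes_valid(self, params):
        cfg = dataclasses.replace(
            SMALL_CFG, n_genes=40, module_size=4, n_tissue_specific_leaf=2,
            n_tissue_specific_tuber=2, n_ramp_genes=2,
            frac_low_identity_probes=0.0, frac_intronic_probes=0.0,
            frac_crosshyb_probes=0.0)
        sim = generate(cfg, seed=2)
        from spudcoex.probe_validation import build_probe_table
        table, _, ex = build_probe_table(
            sim.probes, {m.gene_id: m for m in sim.models},
            sim.transcripts, sim.premrnas, params.min_identity)
        assert table["valid"].all()
        assert all(not v for v in ex.values())

    def test_planted_low_identity_probe_below_threshold(self, small_sim):
        low = [t for t in small_sim.truth.probes.values()
               if not t.intronic and t.identity < 100 and not t.crosshyb]
        assert low, "config plants low-identity probes"
        assert all(t.identity < 85.0 for t in low)

    def test_crosshyb_probe_occurs_in_two_transcripts(self, small_sim):
        hits = 0
        for pid, tr in small_sim.truth.probes.items():
            if not tr.crosshyb:
                continue
            seq = small_sim.probes[tr.platform][pid]
            carriers = [g for g, tx in small_sim.transcripts.items()
                        if seq in tx]
            assert len(carriers) >= 2, pid
            hits += 1
        assert hits > 0


class TestExpression:
    def test_noise_free_module_correlates_perfectly(self):
        cfg = dataclasses.replace(
            SMALL_CFG, n_genes=40, module_size=6, n_tissue_specific_leaf=0,
            n_tissue_specific_tuber=0, n_ramp_genes=0,
            noise_sd=0.0, probe_noise_sd=0.0, module_loading=1.0)
        sim = generate(cfg, seed=3)
        plain = [g for g in sim.truth.module_genes
                 if g not in sim.truth.query_genes]
        fpkm = np.log2(sim.matrices["fpkm"].values.loc[plain])
        r = np.corrcoef(fpkm.to_numpy())
        assert np.allclose(r, 1.0, atol=1e-12)

    @pytest.mark.parametrize("lam,sigma", [(2.0, 1.0), (1.5, 0.5)])
    def test_module_correlation_converges_to_factor_share(self, lam, sigma):
        # Expected pairwise r between plain module genes: lam^2/(lam^2+sigma^2).
        design = (("tuber", "stage5", 240),)
        cfg = dataclasses.replace(
            SMALL_CFG, n_genes=40, module_size=10, n_tissue_specific_leaf=0,
            n_tissue_specific_tuber=0, n_ramp_genes=0,
            module_loading=lam, noise_sd=sigma, sample_design=design)
        sim = generate(cfg, seed=4)
        plain = [g for g in sim.truth.module_genes
                 if g not in sim.truth.query_genes]
        y = np.log2(sim.matrices["fpkm"].values.loc[plain])
        expected = lam ** 2 / (lam ** 2 + sigma ** 2)
        assert _pairwise_mean_r(y) == pytest.approx(expected, abs=0.05)

    def test_tissue_effect_recovered_within_tolerance(self):
        design = (("leaf", "stage3", 20), ("tuber", "stage3", 20))
        cfg = dataclasses.replace(
            SMALL_CFG, n_genes=60, module_size=3, n_ramp_genes=0,
            n_tissue_specific_leaf=10, n_tissue_specific_tuber=10,
            sample_design=design)
        sim = generate(cfg, seed=6)
        sheet = sim.sample_sheet
        y = np.log2(sim.matrices["fpkm"].values)
        leaf_cols = sheet.loc[(sheet.platform_id == "fpkm")
                              & (sheet.tissue == "leaf"), "sample_id"]
        tub_cols = sheet.loc[(sheet.platform_id == "fpkm")
                             & (sheet.tissue == "tuber"), "sample_id"]
        diff = y[leaf_cols].mean(axis=1) - y[tub_cols].mean(axis=1)
        for role, sign in (("leaf_specific", 1), ("tuber_specific", -1)):
            fcs = diff.loc[sim.truth.genes_with_role(role)] * sign
            assert abs(fcs.mean() - SMALL_CFG.tissue_log2_effect) < 0.15
            assert (np.abs(fcs - SMALL_CFG.tissue_log2_effect) < 0.6).all()

    def test_sample_sheet_covers_all_matrices(self, small_sim):
        listed = set(small_sim.sample_sheet["sample_id"])
        for m in small_sim.matrices.values():
            assert set(m.sample_ids) <= listed

    def test_raw_scales(self, small_sim):
        assert small_sim.matrices["arrayA"].scale == "raw_linear"
        assert small_sim.matrices["fpkm"].scale == "fpkm"
        for m in small_sim.matrices.values():
            assert (m.values.to_numpy() >= 0).all()


class TestQPCRSimulation:
    def test_ct_values_in_range_and_reference_present(self, small_sim):
        genes = small_sim.truth.query_genes[:2]
        ct = simulate_qpcr(small_sim.config, small_sim.truth, genes)
        assert ((ct["ct"] > 0) & (ct["ct"] < 45)).all()
        per_sample = ct.groupby("sample_id")["is_reference"].any()
        assert per_sample.all()

    def test_ramped_gene_profile_monotone_at_low_noise(self):
        cfg = dataclasses.replace(SMALL_CFG, noise_sd=0.0, module_loading=0.0,
                                  module_program_weight=0.0)
        sim = generate(cfg, seed=8)
        from spudcoex.qpcr import stage_profiles
        q = sim.truth.query_genes[0]
        ct = simulate_qpcr(cfg, sim.truth, [q], technical_sd=0.0)
        prof = stage_profiles(ct).loc[q]
        assert prof.is_monotonic_increasing
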