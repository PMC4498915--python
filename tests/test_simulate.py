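"""The synthetic-data generator: packing, planting, moments, determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ciliareg import io as io_mod
from ciliareg.models import RegulonSpec
from ciliareg.simulate import (SimulationConfig, X_BOX_CONSENSUS, generate_genome,
                               planted_site_interval, reference_trajectory,
                               revcomp, simulate_chip_coverage,
                               simulate_cilia_evidence, simulate_counts,
                               simulate_dev_profiles)


class TestGenerateGenome:
    def test_gene_models_fit_with_promoters(self, small_config, small_genome):
        annotation, _, _ = small_genome
        assert len(annotation) == small_config.n_genes
        up, down = small_config.promoter_window
        by_chrom = {}
        for g in annotation.genes:
            ps, pe = g.promoter(up, down)
            assert 0 <= ps and pe <= annotation.chrom_lengths[g.chrom]
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:])), \
                "gene models overlap"

    def test_strands_mixed(self, small_genome):
        annotation, _, _ = small_genome
        plus = sum(g.strand == "+" for g in annotation.genes)
        assert 0.25 < plus / len(annotation) < 0.75

    def test_empty_regulon_plants_nothing(self):
        cfg = SimulationConfig(n_genes=60, n_targets=0, n_indirect=0, seed=9)
        _, seqs, regulon = generate_genome(cfg)
        assert not regulon.target_gene_ids
        occurrences = sum(seq.count(X_BOX_CONSENSUS) for seq in seqs.values())
        # chance expectation over ~1 Mb is ~1e-3 for a 14-mer
        assert occurrences <= 1

    def test_planted_sites_at_recorded_offsets(self, small_config, small_genome):
        annotation, seqs, regulon = small_genome
        up, down = small_config.promoter_window
        L = len(small_config.motif_consensus)
        assert set(regulon.planted_site_offsets) == regulon.target_gene_ids
        for g, off in regulon.planted_site_offsets.items():
            assert -up <= off <= down - L
            chrom, s, e = planted_site_interval(annotation, g, off, L)
            word = seqs[chrom][s:e]
            gene = annotation.gene(g)
            expected = (small_config.motif_consensus if gene.strand == "+"
                        else revcomp(small_config.motif_consensus))
            assert word == expected

    def test_capacity_error(self):
        cfg = SimulationConfig(n_genes=50, n_targets=0, n_indirect=0,
                               chrom_lengths={"chr1": 10_000}, seed=0)
        with pytest.raises(ValueError, match="capacity"):
            generate_genome(cfg)

    def test_fixed_seed_outputs_byte_identical(self, tmp_path):
        paths = []
        for run in ("a", "b"):
            cfg = SimulationConfig(n_genes=40, n_targets=5, n_indirect=2, seed=4)
            annotation, seqs, _ = generate_genome(cfg)
            fa = tmp_path / f"{run}.fa"
            gff = tmp_path / f"{run}.gff3"
            io_mod.write_fasta(seqs, fa)
            io_mod.write_annotation(annotation, gff)
            paths.append((fa.read_bytes(), gff.read_bytes()))
        assert paths[0] == paths[1]


class TestChipCoverage:
    def test_unit_enrichment_indistinguishable_from_input(self):
        cfg = SimulationConfig(n_genes=250, n_targets=50, n_indirect=0,
                               chip_enrichment=1.0, seed=21)
        annotation, _, regulon = generate_genome(cfg)
        ip_tracks, input_track = simulate_chip_coverage(annotation, regulon, cfg)
        ip = np.concatenate([ip_tracks[0].counts[c] for c in sorted(ip_tracks[0].counts)])
        inp = np.concatenate([input_track.counts[c] for c in sorted(input_track.counts)])
        assert len(ip) >= 10_000
        p = stats.mannwhitneyu(ip, inp).pvalue
        assert p > 0.01

    def test_site_bin_ip_input_ratio_matches_enrichment(self):
        cfg = SimulationConfig(n_genes=300, n_targets=100, n_indirect=0, seed=8)
        annotation, _, regulon = generate_genome(cfg)
        ip_tracks, input_track = simulate_chip_coverage(annotation, regulon, cfg)
        L = len(cfg.motif_consensus)
        ip_vals, in_vals = [], []
        for g, off in regulon.planted_site_offsets.items():
            chrom, s, e = planted_site_interval(annotation, g, off, L)
            for b in range(s // cfg.bin_size, (e - 1) // cfg.bin_size + 1):
                ip_vals.append(ip_tracks[0].counts[chrom][b])
                in_vals.append(input_track.counts[chrom][b])
        ip_mean, in_mean = np.mean(ip_vals), np.mean(in_vals)
        ratio = ip_mean / in_mean
        n = len(ip_vals)
        # delta-method SE of a ratio of Poisson means
        se = ratio * np.sqrt(1 / (n * ip_mean) + 1 / (n * in_mean))
        assert abs(ratio - cfg.chip_enrichment) < 3 * se

    def test_replicates_are_distinct(self, small_config, small_genome):
        annotation, _, regulon = small_genome
        ip_tracks, _ = simulate_chip_coverage(annotation, regulon, small_config)
        a, b = ip_tracks[0], ip_tracks[1]
        assert any(not np.array_equal(a.counts[c], b.counts[c]) for c in a.counts)

    def test_single_replicate_rejected(self, small_genome):
        annotation, _, regulon = small_genome
        cfg = SimulationConfig(n_genes=120, n_targets=20, n_indirect=10,
                               n_ip_reps=1, seed=123)
        with pytest.raises(ValueError, match="replicate"):
            simulate_chip_coverage(annotation, regulon, cfg)


class TestCounts:
    def test_nb_variance_mean_relation(self):
        # all-null draws at a common mean; Var = mu + alpha*mu^2
        cfg = SimulationConfig(n_genes=1000, n_targets=0, n_indirect=0,
                               baseline_log2_mean=np.log2(100.0),
                               baseline_log2_sd=0.0, nb_dispersion=0.1, seed=31)
        annotation, _, regulon = generate_genome(cfg)
        counts, _ = simulate_counts(annotation, regulon, cfg)
        draws = counts.to_numpy().ravel()
        assert draws.size >= 10_000
        vm = draws.var(ddof=1) / draws.mean()
        expected = 1 + 0.1 * 100.0
        assert abs(vm - expected) / expected < 0.10

    def test_planted_effect_realized_in_group_means(self):
        cfg = SimulationConfig(n_genes=60, n_targets=10, n_indirect=0,
                               target_down_frac=1.0, p21_effect_prob=1.0,
                               effect_log2fc=2.0, n_reps_rna=50, seed=13)
        annotation, _, regulon = generate_genome(cfg)
        counts, meta = simulate_counts(annotation, regulon, cfg)
        meta = meta.set_index("sample")
        wt = meta.index[(meta.genotype == "WT") & (meta.age == "P30")]
        ko = meta.index[(meta.genotype == "KO") & (meta.age == "P30")]
        ratios = []
        for g in sorted(regulon.target_gene_ids):
            ratios.append(counts.loc[g, ko].mean() / counts.loc[g, wt].mean())
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.25) < 3 * se

    def test_null_groups_agree(self):
        cfg = SimulationConfig(n_genes=200, n_targets=0, n_indirect=0, seed=17)
        annotation, _, regulon = generate_genome(cfg)
        counts, meta = simulate_counts(annotation, regulon, cfg)
        meta = meta.set_index("sample")
        wt = meta.index[(meta.genotype == "WT") & (meta.age == "P21")]
        ko = meta.index[(meta.genotype == "KO") & (meta.age == "P21")]
        lfc = np.log2(counts[ko].mean(axis=1) + 0.5) - np.log2(counts[wt].mean(axis=1) + 0.5)
        assert abs(lfc.mean()) < 0.1


class TestProfiles:
    def test_noiseless_shapes(self):
        cfg = SimulationConfig(n_genes=60, n_targets=10, n_indirect=0,
                               profile_noise_sd=0.0, low_expression_frac=0.0,
                               seed=19)
        annotation, _, regulon = generate_genome(cfg)
        prof = simulate_dev_profiles(annotation, regulon, cfg)
        ref = reference_trajectory(cfg.timepoints)
        mat = prof.set_index("gene")
        for g, cls in regulon.profile_class.items():
            row = mat.loc[g].to_numpy()
            if cls == "rfx2_like":
                r = np.corrcoef(row, ref)[0, 1]
                assert r > 1 - 1e-9
            elif cls == "flat":
                assert row.std() < 1e-9

    def test_reference_rises_with_half_max_before_day_21(self):
        t = np.array([7, 14, 17, 21, 30])
        ref = reference_trajectory(t)
        assert np.all(np.diff(ref) > 0)
        half = (ref.min() + ref.max()) / 2
        assert ref[list(t).index(21)] >= half

    def test_fixed_seed_reproducible(self, small_config, small_genome):
        annotation, _, regulon = small_genome
        a = simulate_dev_profiles(annotation, regulon, small_config)
        b = simulate_dev_profiles(annotation, regulon, small_config)
        pd.testing.assert_frame_equal(a, b)


class TestCiliaEvidence:
    def test_regulon_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(n_genes=600, n_targets=200, n_indirect=0,
                               cilia_target_frac=0.6, seed=23)
        annotation, _, regulon = generate_genome(cfg)
        ev = simulate_cilia_evidence(annotation, regulon, cfg).set_index("gene")
        flags = (ev["gold"] | (ev["high"] >= 1))
        frac = flags.loc[sorted(regulon.target_gene_ids)].mean()
        half = 1.96 * np.sqrt(0.6 * 0.4 / 200)
        assert abs(frac - 0.6) < half

    def test_zero_background_has_no_positives(self):
        cfg = SimulationConfig(n_genes=200, n_targets=20, n_indirect=0,
                               cilia_background_frac=0.0, seed=29)
        annotation, _, regulon = generate_genome(cfg)
        ev = simulate_cilia_evidence(annotation, regulon, cfg)
        bg = ev[~ev["gene"].isin(regulon.target_gene_ids)]
        assert not bg["gold"].any() and (bg["high"] == 0).all()

    def test_counts_are_nonnegative_integers(self, small_config, small_genome):
        annotation, _, regulon = small_genome
        ev = simulate_cilia_evidence(annotation, regulon, small_config)
        for col in ("low", "medium", "high"):
            assert (ev[col] >= 0).all()
            assert ev[col].dtype.kind == "i"


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(chip_enrichment=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(timepoints=(7, 7, 21))
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=10, n_targets=11)
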