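"""The ground-truthed generator: determinism, planted structure, noise model."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from regulonkit.genome_io import read_annotation, read_counts, read_fasta, read_peaks
from regulonkit.motif import DEFAULT_CONSENSUS, match_count, scan
from regulonkit.qpcr import expression_from_table, fold_change_between
from regulonkit.regulon import peak_gene_distance
from regulonkit.synthetic import (
    ROLES,
    GroundTruth,
    SimulationParams,
    assign_roles,
    plant_sites,
    simulate_counts,
    simulate_ct,
    simulate_dataset,
    simulate_genome,
    simulate_peaks,
    write_dataset,
)


class TestGenome:
    def test_deterministic_given_seed(self):
        params = SimulationParams(seed=3)
        seq1, ann1 = simulate_genome(params)
        seq2, ann2 = simulate_genome(params)
        assert seq1 == seq2
        assert [
            (g.gene_id, g.start, g.end, g.strand) for g in ann1
        ] == [(g.gene_id, g.start, g.end, g.strand) for g in ann2]

    def test_layout_respects_gaps_and_alternates_strands(self):
        _, annotation = simulate_genome(SimulationParams(seed=5))
        genes = list(annotation)
        assert genes[0].start >= 200
        for left, right in zip(genes, genes[1:]):
            assert right.start - left.end >= 200
            assert left.strand != right.strand

    def test_zero_genes_gives_sequence_only(self):
        params = SimulationParams(
            seed=1, n_genes=0, n_direct_activated=0, n_direct_repressed=0,
            n_indirect=0, n_null=0,
        )
        sequences, annotation = simulate_genome(params)
        assert len(annotation) == 0
        assert len(sequences[params.contig]) == params.genome_length

    def test_overfull_genome_rejected_with_advice(self):
        params = SimulationParams(seed=1, genome_length=5_000)
        with pytest.raises(ValueError, match="genome_length"):
            simulate_genome(params)


class TestRoles:
    def test_roles_partition_the_gene_set(self):
        params = SimulationParams(seed=2)
        _, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        counts = truth.genes["role"].value_counts()
        assert counts.get("direct_activated", 0) == params.n_direct_activated
        assert counts.get("direct_repressed", 0) == params.n_direct_repressed
        assert counts.get("indirect", 0) == params.n_indirect
        assert counts.get("null", 0) == params.n_null
        assert set(truth.genes["role"]) <= set(ROLES)

    def test_flagship_carries_the_largest_effect(self):
        params = SimulationParams(seed=2)
        _, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        flagship = truth.genes[truth.genes["is_flagship"]]
        assert len(flagship) == 1
        assert flagship["beta_limitation"].iloc[0] == pytest.approx(-np.log2(238))
        assert flagship["role"].iloc[0] == "direct_activated"

    def test_null_model_removes_all_effects(self):
        params = SimulationParams(seed=2).null_model()
        _, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        assert (truth.genes["role"] == "null").all()
        for column in ("beta_glucose", "beta_limitation", "gamma"):
            assert (truth.genes[column] == 0).all()

    def test_inconsistent_role_counts_rejected(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimulationParams(n_null=10)


class TestPlantSites:
    def _setup(self, params):
        sequences, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        return sequences, annotation, truth

    def test_sites_match_consensus_everywhere_and_length_is_kept(self):
        params = SimulationParams(seed=4)
        sequences, annotation, truth = self._setup(params)
        planted, sites = plant_sites(sequences, annotation, truth, params)
        assert len(planted[params.contig]) == params.genome_length
        assert len(sites) == params.n_direct_activated + params.n_direct_repressed
        for row in sites.itertuples(index=False):
            window = planted[row.contig][row.start : row.end]
            assert window == row.sequence
            assert match_count(DEFAULT_CONSENSUS, window) == 22

    def test_rescan_recovers_every_planted_position(self):
        params = SimulationParams(seed=4)
        sequences, annotation, truth = self._setup(params)
        planted, sites = plant_sites(sequences, annotation, truth, params)
        hits = scan(planted[params.contig], DEFAULT_CONSENSUS, min_matches=22)
        positions = {h.position for h in hits}
        assert set(sites["start"]) <= positions

    def test_no_direct_genes_leaves_sequence_unchanged(self):
        params = SimulationParams(seed=4).null_model()
        sequences, annotation, truth = self._setup(params)
        planted, sites = plant_sites(sequences, annotation, truth, params)
        assert planted == sequences
        assert len(sites) == 0

    def test_site_region_must_be_intergenic_and_on_contig(self):
        from regulonkit.genome_io import Gene, GenomeAnnotation

        params = SimulationParams(
            seed=1, n_genes=1, n_direct_activated=1, n_direct_repressed=0,
            n_indirect=0, n_null=0, genome_length=2_000,
        )
        # gene starts too close to the contig edge to fit offset + motif
        annotation = GenomeAnnotation([Gene("SYN0001", params.contig, 40, 400)])
        truth = GroundTruth(
            genes=pd.DataFrame(
                {
                    "role": ["direct_activated"], "is_flagship": [False],
                    "beta_glucose": [-2.3], "beta_limitation": [-2.3],
                    "gamma": [0.0],
                    "site_start": pd.array([pd.NA], dtype="Int64"),
                    "site_end": pd.array([pd.NA], dtype="Int64"),
                },
                index=pd.Index(["SYN0001"], name="gene_id"),
            )
        )
        sequences = {params.contig: "A" * 2_000}
        with pytest.raises(ValueError, match="SYN0001"):
            plant_sites(sequences, annotation, truth, params)


class TestSimulatePeaks:
    def test_placement_arithmetic_with_no_jitter(self):
        params = SimulationParams(
            seed=1, peak_width_range=(200, 200), summit_jitter=0, n_decoy_peaks=0
        )
        sites = pd.DataFrame(
            [{"gene_id": "g", "contig": params.contig, "start": 500, "end": 522,
              "sequence": "A" * 22}]
        )
        peaks, truth = simulate_peaks(sites, params)
        (peak,) = peaks
        assert (peak.start, peak.end) == (411, 611)
        assert peak.summit_offset == 100
        assert truth.loc[peak.peak_id, "planted"]

    def test_empty_inputs_give_empty_set(self):
        params = SimulationParams(seed=1, n_decoy_peaks=0)
        peaks, truth = simulate_peaks(pd.DataFrame(columns=["gene_id", "contig", "start", "end", "sequence"]), params)
        assert peaks == [] and len(truth) == 0

    def test_summit_always_inside_peak_and_decoys_avoid_windows(self):
        params = SimulationParams(seed=6)
        sequences, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        _, sites = plant_sites(sequences, annotation, truth, params)
        peaks, peak_truth = simulate_peaks(sites, params)
        assert len(peaks) == len(sites) + params.n_decoy_peaks
        for peak in peaks:
            assert peak.start <= peak.summit < peak.end
        windows = [(s - 500, e + 500) for s, e in zip(sites["start"], sites["end"])]
        for peak in peaks:
            if not peak_truth.loc[peak.peak_id, "planted"]:
                assert not any(peak.start < we and ws < peak.end for ws, we in windows)

    def test_planted_scores_exceed_decoy_scores_stochastically(self):
        params = SimulationParams(seed=6)
        sequences, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        _, sites = plant_sites(sequences, annotation, truth, params)
        peaks, peak_truth = simulate_peaks(sites, params)
        planted = [p.score for p in peaks if peak_truth.loc[p.peak_id, "planted"]]
        decoy = [p.score for p in peaks if not peak_truth.loc[p.peak_id, "planted"]]
        assert np.mean(planted) > np.mean(decoy)


class TestSimulateCounts:
    def _truth_and_annotation(self, params):
        _, annotation = simulate_genome(params)
        truth = assign_roles(annotation, params)
        return annotation, truth

    def test_poisson_limit_recovers_the_planted_mean(self):
        params = SimulationParams(
            seed=7, nb_dispersion=0.0, mean_expression_log10_range=(3.0, 3.0),
            library_size_range=(1.0, 1.0),
        ).null_model()
        annotation, truth = self._truth_and_annotation(params)
        counts, _ = simulate_counts(annotation, truth, params)
        gene_means = counts.counts.mean(axis=1)
        assert (np.abs(gene_means - 1000) / 1000 < 0.05).all()

    def test_same_seed_reproduces_identical_matrices(self):
        params = SimulationParams(seed=8)
        annotation, truth = self._truth_and_annotation(params)
        counts1, sheet1 = simulate_counts(annotation, truth, params)
        counts2, sheet2 = simulate_counts(annotation, truth, params)
        pd.testing.assert_frame_equal(counts1.counts, counts2.counts)
        pd.testing.assert_frame_equal(sheet1.frame, sheet2.frame)

    def test_doubling_library_size_doubles_the_means(self):
        base = SimulationParams(
            seed=9, nb_dispersion=0.0, mean_expression_log10_range=(3.0, 3.0),
            library_size_range=(1.0, 1.0),
        ).null_model()
        doubled = dataclasses.replace(base, library_size_range=(2.0, 2.0))
        annotation, truth = self._truth_and_annotation(base)
        counts1, _ = simulate_counts(annotation, truth, base)
        counts2, _ = simulate_counts(annotation, truth, doubled)
        ratio = counts2.counts.to_numpy().mean() / counts1.counts.to_numpy().mean()
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_design_is_two_by_two_by_three(self):
        params = SimulationParams(seed=10)
        annotation, truth = self._truth_and_annotation(params)
        counts, sheet = simulate_counts(annotation, truth, params)
        assert counts.shape == (120, 12)
        tally = sheet.frame.groupby(["genotype", "condition"]).size()
        assert (tally == 3).all() and len(tally) == 4

    def test_planted_genotype_effect_shows_in_group_means(self):
        params = SimulationParams(seed=11)
        annotation, truth = self._truth_and_annotation(params)
        counts, sheet = simulate_counts(annotation, truth, params)
        repressed = truth.gene_ids("direct_repressed")
        wt = counts.counts.loc[repressed, sheet.samples(genotype="WT")].mean(axis=1)
        mut = counts.counts.loc[repressed, sheet.samples(genotype="mutant")].mean(axis=1)
        assert np.median(mut / wt) == pytest.approx(5.0, rel=0.25)


class TestSimulateCt:
    def _quantities(self, abundances):
        return pd.DataFrame(
            [
                {"sample_id": f"s{i}", "target": "t", "abundance": a}
                for i, a in enumerate(abundances)
            ]
        )

    def test_halving_abundance_adds_one_cycle(self):
        params = SimulationParams(seed=1, ct_noise_sd=0.0)
        table = simulate_ct(self._quantities([1.0, 0.5]), params)
        assert table["ct"].iloc[1] - table["ct"].iloc[0] == pytest.approx(1.0)

    def test_equal_abundances_give_equal_cts(self):
        params = SimulationParams(seed=1, ct_noise_sd=0.0)
        table = simulate_ct(self._quantities([0.3, 0.3, 0.3]), params)
        assert table["ct"].nunique() == 1

    def test_non_positive_abundance_rejected(self):
        params = SimulationParams(seed=1)
        with pytest.raises(ValueError, match="positive"):
            simulate_ct(self._quantities([1.0, 0.0]), params)

    def test_noise_free_fold_change_round_trips_exactly(self):
        # plant an 18.1-fold induction and recover it through the Ct arithmetic
        params = SimulationParams(seed=1, ct_noise_sd=0.0)
        planted_fold = 18.1
        rows = []
        for rep in (1, 2, 3):
            rows += [
                {"sample_id": "glu", "target": "araM", "abundance": 0.01,
                 "dilution": 10, "replicate": rep},
                {"sample_id": "glu", "target": "16S", "abundance": 50.0,
                 "dilution": 1000, "replicate": rep},
                {"sample_id": "lim", "target": "araM", "abundance": 0.01 * planted_fold,
                 "dilution": 10, "replicate": rep},
                {"sample_id": "lim", "target": "16S", "abundance": 50.0,
                 "dilution": 1000, "replicate": rep},
            ]
        table = simulate_ct(pd.DataFrame(rows), params)
        expr = expression_from_table(table, target="araM")
        result = fold_change_between(expr, "lim", "glu")
        assert result.value == pytest.approx(planted_fold, rel=1e-12)
        assert result.sem == pytest.approx(0.0, abs=1e-12)


class TestFullDataset:
    def test_every_direct_gene_has_a_planted_peak_within_range(self, default_dataset):
        ds = default_dataset
        planted = ds.truth.peaks[ds.truth.peaks["planted"]]
        by_gene = planted.reset_index().set_index("gene_id")
        peaks_by_id = {p.peak_id: p for p in ds.peaks}
        for gene_id in ds.truth.direct_gene_ids:
            peak = peaks_by_id[by_gene.loc[gene_id, "peak_id"]]
            gene = ds.annotation.by_id(gene_id)
            assert peak_gene_distance(peak, gene) <= 500

    def test_written_files_read_back_consistently(self, default_dataset, tmp_path):
        paths = write_dataset(default_dataset, tmp_path)
        annotation = read_annotation(paths["gff3"])
        assert len(annotation) == len(default_dataset.annotation)
        sequences = read_fasta(paths["fasta"])
        assert sequences == default_dataset.sequences
        peaks = read_peaks(paths["peaks"])
        assert peaks == default_dataset.peaks
        counts, sheet = read_counts(paths["counts"], paths["sheet"])
        pd.testing.assert_frame_equal(counts.counts, default_dataset.counts.counts)

    def test_dataset_generation_is_fully_deterministic(self, default_dataset, tmp_path):
        again = simulate_dataset(SimulationParams(seed=1))
        assert again.sequences == default_dataset.sequences
        assert again.peaks == default_dataset.peaks
        pd.testing.assert_frame_equal(again.counts.counts, default_dataset.counts.counts)
        pd.testing.assert_frame_equal(again.truth.genes, default_dataset.truth.genes)
        dir1, dir2 = tmp_path / "a", tmp_path / "b"
        for d in (dir1, dir2):
            write_dataset(again, d)
        for name in ("genome.fa", "genes.gff3", "peaks.narrowPeak", "counts.tsv"):
            assert (dir1 / name).read_bytes() == (dir2 / name).read_bytes()
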