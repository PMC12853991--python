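"""Generator audits: the synthetic inputs must embody their ground truth."""

import numpy as np
import pandas as pd
import pytest

from genecentric import synthetic as syn
from genecentric.study import two_group_design


class TestCohortDesign:
    def test_published_design_yields_238_cohort1_records(self):
        cfg = syn.TruthConfig(cohort_design=[
            ("c1", "healthy", 117), ("c1", "MASLD", 121)], seed=0)
        records = syn.simulate_cohort_design(cfg)
        assert len(records) == 238
        roles = {r.role for r in records}
        assert roles == {"control", "disease"}

    def test_default_design_matches_study_totals(self):
        records = syn.simulate_cohort_design(syn.TruthConfig(seed=0))
        assert len(records) == sum(n for *_, n in two_group_design())

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_cohort_design(syn.TruthConfig(cohort_design=[]))

    def test_zero_sample_group_rejected(self):
        cfg = syn.TruthConfig(cohort_design=[("c1", "h", "control", 0)])
        with pytest.raises(ValueError):
            syn.simulate_cohort_design(cfg)

    def test_same_seed_identical_records(self, small_config):
        a = syn.simulate_cohort_design(small_config)
        b = syn.simulate_cohort_design(small_config)
        assert a == b

    def test_library_sizes_within_range(self, small_samples, small_config):
        lo, hi = small_config.library_size_range
        assert all(lo <= s.library_size <= hi for s in small_samples)


class TestGeneFamilies:
    def test_family_sizes_within_range(self):
        cfg = syn.TruthConfig(n_families=3, s_range=(2, 4), seed=1)
        _, truths = syn.simulate_gene_families(cfg)
        assert len(truths) == 3
        assert all(2 <= t.s <= 4 for t in truths)

    def test_zero_divergence_members_identical_to_reference(self):
        cfg = syn.TruthConfig(n_families=2, divergence=0.0, seed=2)
        fasta, truths = syn.simulate_gene_families(cfg)
        seqs = dict(_parse_fasta(fasta))
        for t in truths:
            for m in t.member_ids:
                assert seqs[m] == t.reference_seq

    def test_same_seed_identical_fasta_bytes(self, small_config):
        a, _ = syn.simulate_gene_families(small_config)
        b, _ = syn.simulate_gene_families(small_config)
        assert a.encode() == b.encode()

    def test_decoys_present_with_annotated_headers(self, small_families):
        fasta, truths = small_families
        headers = [h for h, _ in _parse_fasta(fasta, with_headers=True)]
        t = truths[0]
        spur = [h for h in headers if h.startswith(t.spurious_ids[0])]
        assert spur and f"{t.product} 2" in spur[0]
        frag_seqs = {h.split()[0]: s for h, s in
                     _parse_fasta(fasta, with_headers=True)}
        for fid in t.fragment_ids:
            assert len(frag_seqs[fid]) < 0.5 * len(t.reference_seq)

    def test_degenerate_length_range_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_gene_families(syn.TruthConfig(length_range=(100, 50)))


class TestAlignmentHits:
    def test_poisson_mean_recovers_configured_rate(self):
        # a=2, S=2, Lbar=1 kb, lib=1e6 -> mean true-read count 4
        design = [("c1", "h", "control", 500)]
        cfg = syn.TruthConfig(
            n_families=1, s_range=(2, 2), length_range=(333, 333),
            baseline_abundance={"fam01": 2.0}, cohort_design=design,
            library_size_range=(1_000_000, 1_000_000),
            subthreshold_rate=0.0, multihit_rate=0.0, seed=3)
        samples = syn.simulate_cohort_design(cfg)
        _, truths = syn.simulate_gene_families(cfg)
        hits = syn.simulate_alignment_hits(cfg, samples, truths)
        lam = 2.0 * 2 * (truths[0].mean_length_nt / 1000.0) * 1.0  # ~3.99
        counts = np.array([len(df) for df in hits.values()])
        se = np.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se

    def test_zero_baseline_gives_zero_true_hits(self):
        cfg = syn.TruthConfig(
            n_families=1, baseline_abundance={"fam01": 1e-12},
            cohort_design=[("c1", "h", "control", 3)],
            subthreshold_rate=0.0, multihit_rate=0.0, seed=4)
        samples = syn.simulate_cohort_design(cfg)
        _, truths = syn.simulate_gene_families(cfg)
        hits = syn.simulate_alignment_hits(cfg, samples, truths)
        assert all(len(df) == 0 for df in hits.values())

    def test_subthreshold_noise_present_and_above_cutoff(
            self, small_config, small_samples, small_families):
        cfg = syn.TruthConfig(**{**vars(small_config),
                                 "subthreshold_rate": 0.5})
        _, truths = small_families
        hits = syn.simulate_alignment_hits(cfg, small_samples, truths)
        merged = pd.concat(hits.values())
        noisy = merged[merged["evalue"] >= 1e-10]
        assert len(noisy) > 0
        # true hits all below the read E-value cutoff
        clean = merged[~merged["qseqid"].str.contains("noise")]
        primary = clean.sort_values("evalue").drop_duplicates("qseqid")
        assert (primary["evalue"] < 1e-10).all()

    def test_secondary_hits_strictly_worse(self, small_hits):
        for df in small_hits.values():
            dup = df[df["qseqid"].duplicated(keep=False)]
            for _, grp in dup.groupby("qseqid"):
                ordered = grp.sort_values("evalue")
                assert ordered["evalue"].iloc[0] < ordered["evalue"].iloc[-1]

    def test_same_seed_identical_tables(self, small_config, small_samples,
                                        small_families):
        _, truths = small_families
        a = syn.simulate_alignment_hits(small_config, small_samples, truths)
        b = syn.simulate_alignment_hits(small_config, small_samples, truths)
        for sid in a:
            pd.testing.assert_frame_equal(a[sid], b[sid])


class TestTaxaTable:
    def test_columns_sum_to_100(self, small_samples):
        table, _ = syn.simulate_taxa_table(small_samples, seed=5)
        sums = table.sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)

    def test_group_exclusive_clade_zero_elsewhere(self, small_samples):
        table, truth = syn.simulate_taxa_table(small_samples, seed=5)
        clade, cohort, role = truth.group_exclusive
        row = table.loc[[i for i in table.index if clade in i][0]]
        for s in small_samples:
            if not (s.cohort == cohort and s.role == role):
                assert row[s.sample_id] == 0.0

    def test_cohort_specific_clade_confined(self, small_samples):
        table, truth = syn.simulate_taxa_table(small_samples, seed=5)
        for clade, cohort in truth.cohort_specific.items():
            row = table.loc[[i for i in table.index if clade in i][0]]
            outside = [s.sample_id for s in small_samples if s.cohort != cohort]
            assert (row[outside] == 0.0).all()

    def test_unclassified_row_present(self, small_samples):
        table, truth = syn.simulate_taxa_table(small_samples, seed=5)
        assert truth.unclassified in table.index

    def test_fixed_seed_identical_table(self, small_samples):
        a, _ = syn.simulate_taxa_table(small_samples, seed=5)
        b, _ = syn.simulate_taxa_table(small_samples, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestScreenInputs:
    def test_carrier_counts_match_configured_prevalence(self, screen_config,
                                                        screen_inputs):
        for (clade, gene), p in screen_config.prevalence.items():
            n = next(c.n_genomes for c in screen_config.clades
                     if c.name == clade)
            assert len(screen_inputs.carriers[(clade, gene)]) == round(p * n)

    def test_zero_prevalence_has_no_carriers(self, screen_inputs):
        assert screen_inputs.carriers[("Blautia", "yahK")] == []

    def test_plasmid_truth_counts_exact(self, screen_config, screen_inputs):
        for gene, k in screen_config.plasmid_counts.items():
            assert len(screen_inputs.plasmid_carriers[gene]) == k

    def test_failing_genomes_present(self, screen_inputs):
        g = screen_inputs.genomes
        uscg_cols = [c for c in g.columns if c.startswith("uscg_")]
        failing = (g["completeness"] <= 95) | ~g[uscg_cols].all(axis=1)
        assert failing.any()

    def test_determinism(self, screen_config):
        a = syn.simulate_screen_inputs(screen_config)
        b = syn.simulate_screen_inputs(screen_config)
        assert a.scan_text == b.scan_text
        pd.testing.assert_frame_equal(a.genomes, b.genomes)
        pd.testing.assert_frame_equal(a.plasmids, b.plasmids)


def _parse_fasta(text, with_headers=False):
    out, header, seq = [], None, []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                out.append((header if with_headers else header.split()[0],
                            "".join(seq)))
            header, seq = line[1:], []
        else:
            seq.append(line)
    if header is not None:
        out.append((header if with_headers else header.split()[0], "".join(seq)))
    return out
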