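"""Generator bookkeeping, NB moments, error planting and determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sagesac.synthetic_data import (
    SimulationConfig,
    evaluate_against_truth,
    simulate_counts,
    simulate_dataset,
    simulate_reads,
    simulate_transcriptome,
    write_dataset,
)
from sagesac.tag_reference import RETAINED, build_tag_reference


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(erythroid_fraction=(1.5,) * 5)
        with pytest.raises(ValueError):
            SimulationConfig(epsilon=1.0)
        with pytest.raises(ValueError):
            SimulationConfig(frac_no_anchor=0.6, frac_too_short=0.6)

    def test_metadata_shape(self):
        cfg = SimulationConfig(replicates=2)
        meta = cfg.metadata()
        assert len(meta) == 10 and set(meta["day"]) == set(cfg.days)


class TestTranscriptome:
    def test_all_clean_config(self):
        cfg = SimulationConfig(
            n_genes=40, frac_no_anchor=0, frac_too_short=0, frac_duplicate=0
        )
        transcripts, expected = simulate_transcriptome(cfg)
        ref = build_tag_reference(transcripts)
        assert all(e.status == RETAINED for e in ref.entries)
        assert (expected == RETAINED).all()

    def test_all_duplicates_zero_retained(self):
        cfg = SimulationConfig(
            n_genes=20, frac_no_anchor=0, frac_too_short=0, frac_duplicate=1.0
        )
        transcripts, _ = simulate_transcriptome(cfg)
        ref = build_tag_reference(transcripts)
        assert len(ref.tag_index) == 0

    def test_planted_fractions_match_statuses(self):
        cfg = SimulationConfig(
            n_genes=200, frac_no_anchor=0.1, frac_too_short=0.1,
            frac_duplicate=0.1, seed=13,
        )
        transcripts, expected = simulate_transcriptome(cfg)
        ref = build_tag_reference(transcripts)
        got = pd.Series({e.gene_id: e.status for e in ref.entries})
        assert (got[expected.index] == expected).all()
        assert (expected == "no_anchor").sum() == 20
        assert (expected == "redundant").sum() == 20


class TestCounts:
    def test_large_depth_small_phi_limit(self):
        """phi -> 0 at huge depth: observed/expected ratios approach 1."""
        cfg = SimulationConfig(
            n_genes=50, depth=10_000_000, phi=1e-9, replicates=1, seed=3,
            frac_no_anchor=0, frac_too_short=0, frac_duplicate=0,
        )
        genes = [f"G{i:05d}" for i in range(1, 51)]
        cm, truth = simulate_counts(cfg, genes)
        mu = truth.expected_counts.to_numpy()
        obs = cm.counts.to_numpy()
        big = mu > 250_000  # Poisson relative noise ~ 1/sqrt(mu) < 0.2%
        assert big.sum() > 10
        assert np.max(np.abs(obs[big] / mu[big] - 1)) < 0.01

    def test_no_erythroid_when_fraction_zero(self):
        cfg = SimulationConfig(n_genes=30, erythroid_gene_fraction=0.0, seed=4)
        _, truth = simulate_counts(cfg, [f"g{i}" for i in range(30)])
        assert (truth.gene_table["class"] == "epithelial").all()

    def test_nb_variance_mean_relation(self):
        """Var/mean of replicate counts consistent with 1 + phi*mu."""
        cfg = SimulationConfig(
            n_genes=1000, replicates=60, days=("E13",),
            erythroid_fraction=(0.3,), phi=0.2, depth=100_000, seed=5,
        )
        genes = [f"g{i}" for i in range(1000)]
        cm, truth = simulate_counts(cfg, genes)
        obs = cm.counts.to_numpy()
        mu = truth.expected_counts.to_numpy()[:, 0]
        keep = mu > 50
        ratio = obs[keep].var(axis=1, ddof=1) / obs[keep].mean(axis=1)
        expected = 1 + 0.2 * mu[keep]
        # regression of observed dispersion ratio on expectation ~ identity
        rel = ratio / expected
        assert abs(np.median(rel) - 1) < 0.15

    def test_erythroid_profiles_decline(self):
        cfg = SimulationConfig(n_genes=200, seed=6)
        _, truth = simulate_counts(cfg, [f"g{i}" for i in range(200)])
        ery = truth.gene_table["class"] == "erythroid"
        prof = truth.expected_profiles[ery.to_numpy()]
        assert (prof["E21"] < prof["E13"]).all()


class TestReads:
    def test_zero_error_round_trip_exact(self, small_dataset):
        """All counted tags come back verbatim: per-read error lists empty."""
        total_err = sum(e.sum() for e in small_dataset.planted_errors.values())
        assert total_err == 0
        n_reads = sum(len(r) for r in small_dataset.reads.values())
        assert n_reads == small_dataset.true_counts.counts.to_numpy().sum()

    def test_error_rate_matches_binomial(self):
        cfg = SimulationConfig(
            n_genes=60, depth=20_000, epsilon=0.01, seed=8,
            frac_no_anchor=0, frac_too_short=0, frac_duplicate=0,
        )
        ds = simulate_dataset(cfg)
        errs = np.concatenate([e for e in ds.planted_errors.values()])
        # per-base tag-region error count ~ Binomial(23, 0.01)
        p_hit = errs.mean() / 23
        se = np.sqrt(0.01 * 0.99 / (len(errs) * 23))
        assert abs(p_hit - 0.01) < 4 * se

    def test_zero_depth_no_reads(self):
        cfg = SimulationConfig(n_genes=20, depth=0, seed=9)
        ds = simulate_dataset(cfg)
        assert all(len(r) == 0 for r in ds.reads.values())

    def test_unretained_gene_rejected(self, small_dataset):
        cfg = small_dataset.config
        bad = small_dataset.true_counts.counts.copy()
        bad.index = ["BAD" + g for g in bad.index]
        from sagesac.tag_alignment import CountMatrix

        with pytest.raises(ValueError):
            simulate_reads(
                CountMatrix(bad, small_dataset.true_counts.metadata),
                small_dataset.reference, cfg,
            )


class TestEvaluate:
    def test_truth_vs_itself_perfect(self, small_dataset):
        m = evaluate_against_truth(small_dataset.true_counts, small_dataset.truth)
        assert m["count_pearson_r"] == pytest.approx(1.0)
        assert m["count_exact_fraction"] == 1.0

    def test_permuted_labels_null_ari(self, small_dataset, rng):
        truth = small_dataset.truth
        labels = truth.gene_table["template"].sample(
            frac=1.0, random_state=1
        )
        labels.index = truth.gene_table.index  # permuted labels
        m = evaluate_against_truth(
            small_dataset.true_counts, truth, cluster_labels=labels
        )
        assert abs(m["cluster_ari"]) < 0.15

    def test_universe_mismatch_rejected(self, small_dataset):
        cm = small_dataset.true_counts
        from sagesac.tag_alignment import CountMatrix

        other = CountMatrix(cm.counts.iloc[:3], cm.metadata)
        with pytest.raises(ValueError):
            evaluate_against_truth(other, small_dataset.truth)


def test_byte_identical_under_seed(tmp_path):
    import hashlib

    cfg = SimulationConfig(n_genes=40, depth=1500, epsilon=0.01, seed=21)
    sums = []
    for sub in ("a", "b"):
        ds = simulate_dataset(cfg)
        paths = write_dataset(ds, tmp_path / sub)
        digest = hashlib.sha256()
        for key in sorted(paths):
            digest.update(open(paths[key], "rb").read())
        sums.append(digest.hexdigest())
    assert sums[0] == sums[1]
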