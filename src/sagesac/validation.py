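"""Simulation-based validation of the pipeline's statistical properties.

Each check generates truth-known data with :mod:`sagesac.synthetic_data`,
runs the corresponding pipeline stage(s), and measures how well the stage
recovers the planted truth: oracle agreement for the discrete algorithms
(tag-reference construction, mismatch-tolerant matching), calibration and
power for the NB GLM tests, recovery scores for clustering and cell-type
separation, and byte-level determinism of the full pipeline.  The checks
are deliberately independent re-derivations (brute-force scans, closed
forms, truth bookkeeping) rather than reruns of the code paths they
validate.

Every function takes a seed and returns a flat dict of measured values
plus the problem size ``n`` it used, so results can be reported or
asserted against expected bands.
"""

from __future__ import annotations

import hashlib
import os
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from . import (
    cell_type_separation,
    differential_expression as de,
    normalization,
    qc_outliers,
    read_processing,
    synthetic_data,
    tag_alignment,
    tag_reference,
    temporal_clustering,
)

DAYS5 = ["E13"] * 3 + ["E15"] * 3 + ["E17"] * 3 + ["E19"] * 3 + ["E21"] * 3


# ---------------------------------------------------------------------------
# 1. tag-reference construction vs brute-force enumeration


def check_tag_reference_oracle(seed: int, n_transcripts: int = 500) -> dict:
    cfg = synthetic_data.SimulationConfig(
        n_genes=n_transcripts, frac_no_anchor=0.12, frac_too_short=0.1,
        frac_duplicate=0.14, frac_ambiguous=0.04, seed=seed,
    )
    transcripts, _ = synthetic_data.simulate_transcriptome(cfg)
    ref = tag_reference.build_tag_reference(transcripts)

    oracle: dict[str, str] = {}
    tag_of: dict[str, str] = {}
    for t in transcripts:
        hits = [
            i for i in range(len(t.sequence) - 3)
            if t.sequence[i : i + 4] == "CATG"
        ]
        if not hits:
            oracle[t.id] = tag_reference.NO_ANCHOR
            continue
        pos = max(hits)
        if len(t.sequence) - pos < 23:
            oracle[t.id] = tag_reference.TOO_SHORT
        elif "N" in t.sequence[pos : pos + 23]:
            oracle[t.id] = tag_reference.AMBIGUOUS
        else:
            tag_of[t.id] = t.sequence[pos : pos + 23]
    mult = Counter(tag_of.values())
    for gid, tag in tag_of.items():
        oracle[gid] = (
            tag_reference.REDUNDANT if mult[tag] > 1 else tag_reference.RETAINED
        )

    got = {e.gene_id: e.status for e in ref.entries}
    agree = np.mean([got[g] == oracle[g] for g in oracle])
    index_ok = set(ref.tag_index.values()) == {
        g for g, s in oracle.items() if s == tag_reference.RETAINED
    }
    return {
        "status_agreement": float(agree),
        "index_agreement": float(index_ok),
        "n": n_transcripts,
    }


# ---------------------------------------------------------------------------
# 2. matcher vs vectorized all-pairs Hamming scan


def _encode(seqs: list[str]) -> np.ndarray:
    lut = np.zeros(128, dtype=np.uint8)
    for i, b in enumerate("ACGTN"):
        lut[ord(b)] = i
    return np.vstack([lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs])


def check_matcher_oracle(
    seed: int, n_reads: int = 10_000, n_tags: int = 1_000
) -> dict:
    rng = np.random.default_rng(seed)
    tags, seen = [], set()
    while len(tags) < n_tags:
        t = "CATG" + "".join(rng.choice(list("ACGT"), 19))
        if t not in seen:
            seen.add(t)
            tags.append(t)
    genes = [f"g{i}" for i in range(n_tags)]
    matcher = tag_alignment.TagMatcher(tags, genes)

    reads = []
    for i in range(n_reads):
        k = int(rng.integers(0, 4))
        if k == 3:
            seq = "".join(rng.choice(list("ACGT"), 23))
        else:
            seq = list(tags[int(rng.integers(n_tags))])
            for pos in rng.choice(23, size=k, replace=False):
                seq[pos] = "ACGT"[int(rng.integers(4))]
            seq = "".join(seq)
        quals = tuple(int(q) for q in rng.integers(2, 41, 23))
        reads.append(read_processing.Read(f"r{i}", seq, quals))

    # vectorized all-pairs oracle
    T = _encode(tags)                          # n_tags x 23
    R = _encode([r.sequence for r in reads])   # n_reads x 23
    Q = np.array([r.qualities for r in reads])
    agree = 0
    chunk = 500
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        mism = R[lo:hi, None, :] != T[None, :, :]
        mm = mism.sum(axis=2)
        qs = (mism * Q[lo:hi, None, :]).sum(axis=2)
        ok = (mm <= 2) & (qs <= 70)
        for j in range(hi - lo):
            idx = np.flatnonzero(ok[j])
            got = matcher.match_read(reads[lo + j])
            if len(idx) == 0 or len(idx) > 10:
                expected = tag_alignment.Assignment(reads[lo + j].id,
                                                    tag_alignment.UNMAPPED)
            else:
                pairs = list(zip(mm[j, idx], qs[j, idx], idx))
                best = min(pairs)
                ties = [p for p in pairs if p[:2] == best[:2]]
                if len(ties) > 1:
                    expected = tag_alignment.Assignment(
                        reads[lo + j].id, tag_alignment.MULTI,
                        mismatches=int(best[0]),
                    )
                else:
                    expected = tag_alignment.Assignment(
                        reads[lo + j].id, tag_alignment.UNIQUE,
                        genes[int(best[2])], int(best[0]),
                    )
            agree += got == expected
    return {"assignment_agreement": agree / n_reads, "n": n_reads}


# ---------------------------------------------------------------------------
# 3. zero-error round trip and error-rate response


def _pipeline_counts(ds) -> tag_alignment.CountMatrix:
    matcher = tag_alignment.TagMatcher.from_reference(ds.reference)
    assignments = {}
    for sample, reads in ds.reads.items():
        kept, _ = read_processing.preprocess(reads)
        assignments[sample] = matcher.match_all(kept)
    cm, _ = tag_alignment.count_assignments(
        assignments, ds.true_counts.metadata, ds.reference.retained_genes
    )
    return cm


def check_count_round_trip(
    seed: int, n_genes: int = 120, depth: int = 10_000
) -> dict:
    cfg0 = synthetic_data.SimulationConfig(
        n_genes=n_genes, depth=depth, epsilon=0.0, seed=seed
    )
    ds0 = synthetic_data.simulate_dataset(cfg0)
    cm0 = _pipeline_counts(ds0)
    exact = float(
        (cm0.counts.to_numpy() == ds0.true_counts.counts.to_numpy()).mean()
    )

    eps = 0.01
    cfg1 = synthetic_data.SimulationConfig(
        n_genes=n_genes, depth=depth, epsilon=eps, seed=seed + 1
    )
    ds1 = synthetic_data.simulate_dataset(cfg1)
    matcher = tag_alignment.TagMatcher.from_reference(ds1.reference)
    n_unique = n_total = 0
    for sample, reads in ds1.reads.items():
        kept, _ = read_processing.preprocess(reads)
        for a in matcher.match_all(kept):
            n_total += 1
            n_unique += a.status == tag_alignment.UNIQUE
    p_mappable = float(stats.binom.cdf(2, 23, eps))
    observed = n_unique / n_total
    se = np.sqrt(p_mappable * (1 - p_mappable) / n_total)
    return {
        "zero_error_exact_fraction": exact,
        "unique_fraction_observed": observed,
        "unique_fraction_expected": p_mappable,
        "unique_fraction_z": float((observed - p_mappable) / se),
        "n": n_total,
    }


# ---------------------------------------------------------------------------
# 4. normalization defining property and scale invariance


def check_normalization_properties(seed: int, n_genes: int = 400) -> dict:
    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(2, 0.02, size=(n_genes, 12))
    counts[rng.random(counts.shape) < 0.25] = 0
    counts[0] += 1
    days = ("E13", "E15", "E17", "E19")
    meta = pd.DataFrame(
        {"sample_id": [f"{d}_r{r}" for d in days for r in (1, 2, 3)],
         "day": [d for d in days for _ in (1, 2, 3)],
         "replicate": [r for _ in days for r in (1, 2, 3)]}
    ).set_index("sample_id")
    cm = tag_alignment.CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)],
                     columns=list(meta.index)),
        meta,
    )
    norm = normalization.normalize(cm)
    nonzero = cm.counts.index[cm.counts.sum(axis=1) > 0]
    uqs = np.percentile(norm.norm_counts.loc[nonzero], 75, axis=0)
    uq_dev = float(np.max(np.abs(uqs - uqs[0])))

    c = float(rng.uniform(0.2, 5.0))
    scaled = cm.counts.astype(float).copy()
    target = cm.samples[3]
    scaled[target] *= c
    cm2 = tag_alignment.CountMatrix(scaled, meta)
    norm2 = normalization.normalize(cm2)
    inv_dev = float(
        np.max(np.abs(norm2.norm_counts[target] - norm.norm_counts[target]))
    )
    return {
        "uq_max_abs_deviation": uq_dev,
        "scale_invariance_max_abs_deviation": inv_dev,
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# 5. type-I error calibration of the overall test


def check_type1_calibration(seed: int, n_genes: int = 5_000) -> dict:
    rng = np.random.default_rng(seed)
    r = 1.0 / 0.1
    ps = []
    for _ in range(n_genes):
        mu = float(rng.uniform(20, 500))
        y = rng.negative_binomial(r, r / (r + np.full(15, mu)))
        fit = de.fit_nb_glm(y, DAYS5)
        ps.append(de.lrt_overall(fit)[1])
    ps = np.asarray(ps)
    _, sig = de.bh_adjust(ps, level=0.05)
    return {
        "type1_rate_at_0.05": float((ps < 0.05).mean()),
        "bh_declared_fraction": float(sig.mean()),
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# 6. FDR control and power (overall test + pairwise contrasts)


def check_fdr_and_power(
    seed: int, n_genes: int = 2_000, prop_de: float = 0.1,
    n_contrast_genes: int = 400,
) -> dict:
    rng = np.random.default_rng(seed)
    r = 1.0 / 0.1
    is_de = rng.random(n_genes) < prop_de
    ps = []
    for i in range(n_genes):
        mu = np.full(15, 100.0)
        if is_de[i]:
            mu[6:] = 400.0  # 4-fold step at mid-incubation
        y = rng.negative_binomial(r, r / (r + mu))
        ps.append(de.lrt_overall(de.fit_nb_glm(y, DAYS5))[1])
    _, sig = de.bh_adjust(np.asarray(ps), level=0.05)
    n_called = int(sig.sum())
    fdr = float((sig & ~is_de).sum() / n_called) if n_called else 0.0
    power = float((sig & is_de).sum() / is_de.sum())
    mc_se = float(np.sqrt(0.05 * 0.95 / max(n_called, 1)))

    # contrasts: genes carrying a 2-fold change between the contrast days
    contrast_power = {}
    for a, b, ib in (("E13", "E17", slice(6, 9)), ("E19", "E21", slice(12, 15))):
        pc = []
        for _ in range(n_contrast_genes):
            mu = np.full(15, 100.0)
            mu[ib] = 200.0
            y = rng.negative_binomial(r, r / (r + mu))
            fit = de.fit_nb_glm(y, DAYS5)
            pc.append(de.pairwise_contrast(fit, a, b)[1])
        _, csig = de.bh_adjust(np.asarray(pc), level=0.10)
        contrast_power[f"{a}_{b}"] = float(csig.mean())
    return {
        "empirical_fdr": fdr,
        "fdr_mc_se": mc_se,
        "de_power": power,
        "contrast_power_min": min(contrast_power.values()),
        **{f"contrast_power_{k}": v for k, v in contrast_power.items()},
        "n": n_genes,
    }


# ---------------------------------------------------------------------------
# 7. clustering recovery of planted temporal templates


def check_clustering_recovery(
    seed: int, n_per_template: int = 50, noise_sd: float = 0.3
) -> dict:
    from sklearn.metrics import adjusted_rand_score

    profiles, truth = synthetic_data.simulate_profiles(
        n_per_template=n_per_template, noise_sd=noise_sd, seed=seed
    )
    z, _ = temporal_clustering.standardize_profiles(profiles)
    assignment = temporal_clustering.hierarchical_cluster(z, cuts=(3, 8, 21))
    temporal_clustering.assert_nested(assignment)
    ari = float(adjusted_rand_score(truth, assignment.labels["k3"]))
    return {"cluster_ari": ari, "cuts_nested": 1.0, "n": len(profiles)}


# ---------------------------------------------------------------------------
# 8. cell-type separation and subset renormalization


def check_separation_recovery(
    seed: int,
    n_genes: int = 400,
    n_per_template: int = 60,
    marker_fraction: float = 0.5,
) -> dict:
    """Two-part check of the cell-type separation stage.

    Part A (labeling recovery): planted temporal profiles at noise SD 0.3
    where the declining template is the erythroid compartment (30% of the
    universe); erythroid genes must be recovered from a half-known marker
    list.  Part B (compositional bias): a count-level mixture with the
    erythroid library fraction declining 0.5 -> 0.05; epithelial-only
    upper-quartile renormalization must bring the fraction of truly
    constant epithelial genes called significant in any pairwise contrast
    below the nominal contrast FDR.
    """
    from sklearn.metrics import adjusted_rand_score  # noqa: F401

    rng = np.random.default_rng(seed + 1)

    # -- part A: profile-level labeling recovery ----------------------------
    profiles, templates = synthetic_data.simulate_profiles(
        n_per_template=n_per_template,
        templates=("monotone_down", "constant", "peak", "monotone_up"),
        noise_sd=0.3, seed=seed,
    )
    # erythroid compartment: the declining genes, ~30% of the universe
    keep = [g for i, g in enumerate(profiles.index)
            if templates.iloc[i] != "monotone_up" or i % 2 == 0]
    profiles, templates = profiles.loc[keep], templates.loc[keep]
    ery_true = [g for g in profiles.index if g.startswith("monotone_down")]
    z, _ = temporal_clustering.standardize_profiles(profiles)
    cuts = tuple(k for k in (3, 8, 21) if k <= len(z))
    assignment = temporal_clustering.hierarchical_cluster(z, cuts=cuts)
    markers = list(
        rng.choice(ery_true, size=max(1, int(marker_fraction * len(ery_true))),
                   replace=False)
    )
    partition = cell_type_separation.classify_genes(assignment, markers)
    recall = float(np.mean([
        partition.classes[g] == cell_type_separation.ERYTHROPOIETIC
        for g in ery_true
    ]))

    # -- part B: compositional-bias renormalization -------------------------
    # Isolate the compositional mechanism: a declining erythroid
    # compartment over a mostly stable epithelium, so any apparent
    # regulation of constant epithelial genes is mixture-induced.
    cfg = synthetic_data.SimulationConfig(
        n_genes=n_genes, depth=60_000, phi=0.05, seed=seed,
        erythroid_gene_fraction=0.3, effect_size_ln=0.5,
        template_mix=(0.1, 0.1, 0.1, 0.7),
        frac_no_anchor=0, frac_too_short=0, frac_duplicate=0,
    )
    genes = [f"g{i}" for i in range(n_genes)]
    counts, truth = synthetic_data.simulate_counts(cfg, genes, rng)
    norm = normalization.normalize(counts)
    retained = normalization.low_count_filter(norm.norm_counts)
    table = de.run_de(counts, norm.scale_factors, genes=list(retained))
    sig = list(table.index[table["significant"].fillna(False)])

    prof_b = temporal_clustering.day_mean_profiles(
        norm.values, counts.metadata, genes=sig
    )
    z_b, _ = temporal_clustering.standardize_profiles(prof_b)
    cuts_b = tuple(k for k in (3, 8, 21) if k <= len(z_b)) or (min(3, len(z_b)),)
    assign_b = temporal_clustering.hierarchical_cluster(z_b, cuts=cuts_b)
    ery_b = truth.gene_table.index[truth.gene_table["class"] == "erythroid"]
    markers_b = list(
        rng.choice(ery_b, size=max(1, int(marker_fraction * len(ery_b))),
                   replace=False)
    )
    part_b = cell_type_separation.classify_genes(assign_b, markers_b)
    ery_in = [g for g in ery_b if g in part_b.classes.index]
    count_recall = float(np.mean([
        part_b.classes[g] == cell_type_separation.ERYTHROPOIETIC
        for g in ery_in
    ])) if ery_in else float("nan")

    constant = truth.gene_table.query(
        "`class` == 'epithelial' and template == 'constant'"
    ).index
    constant = [g for g in constant if g in retained]

    def fp_fraction(tbl):
        """Mean per-contrast fraction of constant genes called significant
        (plus the any-of-4-contrasts union as a diagnostic)."""
        sub = tbl.loc[[g for g in constant if g in tbl.index]]
        cols = [c for c in sub.columns if c.startswith("sig_")]
        return (
            float(sub[cols].mean(axis=0).mean()),
            float(sub[cols].any(axis=1).mean()),
        )

    fp_before, fp_union_before = fp_fraction(table)
    epithelial = list(part_b.epithelial_genes) + [
        g for g in retained if g not in part_b.classes.index
    ]
    subset_norm = cell_type_separation.renormalize_subset(counts, epithelial)
    subset_table = de.run_de(
        counts.subset_genes(epithelial), subset_norm.scale_factors
    )
    fp_after, fp_union_after = fp_fraction(subset_table)
    return {
        "erythroid_recall": recall,
        "erythroid_recall_count_level": count_recall,
        "constant_gene_fp_before": fp_before,
        "constant_gene_fp_after": fp_after,
        "constant_gene_fp_any_contrast_before": fp_union_before,
        "constant_gene_fp_any_contrast_after": fp_union_after,
        "n": len(profiles),
    }


# ---------------------------------------------------------------------------
# 9. end-to-end determinism


def check_determinism(seed: int, outdir: str, n_genes: int = 100) -> dict:
    from .pipeline import run_pipeline

    config = {
        "seed": seed,
        "simulate": {
            "n_genes": n_genes, "depth": 8_000, "epsilon": 0.005,
            "effect_size_ln": 0.6,
        },
        "params": {"cuts": [3, 6, 12]},
    }
    digests = []
    for sub in ("run_a", "run_b"):
        d = os.path.join(outdir, sub)
        run_pipeline(config, d, resume=False)
        h = hashlib.sha256()
        for name in sorted(os.listdir(d)):
            path = os.path.join(d, name)
            if os.path.isfile(path) and name != "manifest.json":
                h.update(name.encode())
                h.update(open(path, "rb").read())
        digests.append(h.hexdigest())
    return {
        "identical_outputs": float(digests[0] == digests[1]),
        "n": n_genes,
    }
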