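"""Truth-known synthetic data with the structure the pipeline assumes.

The generator emulates a five-day (E13-E21) SAGE-Seq experiment on a
two-cell-type tissue: an erythropoietic compartment whose library fraction
declines across incubation (definitive erythropoiesis moving out of the
yolk sac) and an epithelial compartment whose genes follow temporal
templates (monotone-up, peak at E19, monotone-down, constant).  Expected
expression of gene g in a library of day d is

    mu_gd = depth * w_g * template_g(d) * (f_d if erythroid else 1 - f_d)

with counts drawn NB(mu, phi), Var = mu + phi*mu^2.  Reads carry the
gene's 23-bp tag at their 5' end, iid per-base substitution errors at rate
epsilon, random filler up to the instrument read length, and phred
qualities from a two-component quality model.  The planted transcriptome
has controlled anchor structure (no-anchor / too-short / duplicated-tag /
ambiguous-base / clean fractions) with the expected tag-reference status
recorded per transcript.  Everything is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .read_processing import Read
from .tag_alignment import CountMatrix
from .tag_reference import (
    AMBIGUOUS,
    NO_ANCHOR,
    REDUNDANT,
    RETAINED,
    TOO_SHORT,
    TagReference,
    Transcript,
    build_tag_reference,
)

DAYS = ("E13", "E15", "E17", "E19", "E21")
TEMPLATES = ("monotone_up", "peak", "monotone_down", "constant")
BASES = np.array(list("ACGT"))

# Declining erythropoietic library fraction, 0.5 on E13 down to 0.05 on E21
# (geometric interpolation).
DEFAULT_ERYTHROID_FRACTION = tuple(
    float(x) for x in np.geomspace(0.5, 0.05, len(DAYS))
)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 300
    days: tuple[str, ...] = DAYS
    replicates: int = 3
    erythroid_fraction: tuple[float, ...] = DEFAULT_ERYTHROID_FRACTION
    erythroid_gene_fraction: float = 0.3
    template_mix: tuple[float, ...] = (0.2, 0.15, 0.15, 0.5)  # up, peak, down, const
    effect_size_ln: float = float(np.log(2.0)) / 2.0  # ln-fold step per day
    phi: float = 0.1
    depth: int = 50_000
    epsilon: float = 0.0
    read_length: int = 50
    # Good-quality bases sit near phred 30 with little spread, so a read
    # with <=2 substitutions stays within the mismatch-quality budget of
    # the aligner contract (2 x 30 << 70) and the mismatch-count gate is
    # the binding constraint, as for good-quality libraries in practice.
    quality_mean: float = 30.0
    quality_sd: float = 2.0
    low_quality_fraction: float = 0.0
    low_quality_mean: float = 10.0
    # transcriptome structure
    transcript_length: int = 120
    frac_no_anchor: float = 0.1
    frac_too_short: float = 0.1
    frac_duplicate: float = 0.1
    frac_ambiguous: float = 0.0
    tag_length: int = 23
    motif: str = "CATG"
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0.0 <= f <= 1.0 for f in self.erythroid_fraction):
            raise ValueError("erythroid fractions must lie in [0, 1]")
        if len(self.erythroid_fraction) != len(self.days):
            raise ValueError("one erythroid fraction per day required")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must lie in [0, 1)")
        structural = (
            self.frac_no_anchor + self.frac_too_short
            + self.frac_duplicate + self.frac_ambiguous
        )
        if structural > 1.0 + 1e-12:
            raise ValueError("transcriptome structure fractions exceed 1")

    def sample_ids(self) -> list[str]:
        return [f"{d}_r{r+1}" for d in self.days for r in range(self.replicates)]

    def metadata(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{d}_r{r+1}", "day": d, "replicate": r + 1}
            for d in self.days
            for r in range(self.replicates)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class SimulationTruth:
    gene_table: pd.DataFrame       # class, template, weight, de_flag per gene
    expected_counts: pd.DataFrame  # genes x samples expected mu
    true_counts: CountMatrix       # the NB draws actually emitted as reads
    expected_profiles: pd.DataFrame  # genes x days expected normalized mean
    planted_errors: dict = field(default_factory=dict)  # sample -> per-read error counts


# ---------------------------------------------------------------------------
# transcriptome


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _random_no_motif(rng, length, motif) -> str:
    for _ in range(1000):
        seq = _random_dna(rng, length)
        if motif not in seq:
            return seq
    raise RuntimeError("could not draw a motif-free sequence")


def _clean_sequence(rng, length, motif, tag_length, used_tags) -> tuple[str, str]:
    """Sequence whose 3'-most motif starts exactly tag_length from the 3'
    end, with a globally unique tag."""
    anchor = length - tag_length
    for _ in range(1000):
        up = _random_dna(rng, anchor)
        tail = _random_dna(rng, tag_length - len(motif))
        tag = motif + tail
        seq = up + tag
        if seq.rfind(motif) == anchor and tag not in used_tags:
            return seq, tag
    raise RuntimeError("could not draw a clean sequence")


def simulate_transcriptome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[Transcript], pd.Series]:
    """Planted-structure transcriptome plus the expected status per gene."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_genes
    motif, L, tlen = config.motif, config.transcript_length, config.tag_length
    n_no_anchor = int(round(config.frac_no_anchor * n))
    n_short = int(round(config.frac_too_short * n))
    n_dup = int(round(config.frac_duplicate * n)) // 2 * 2
    n_ambig = int(round(config.frac_ambiguous * n))
    n_clean = n - n_no_anchor - n_short - n_dup - n_ambig
    if n_clean < 0:
        raise ValueError("structure fractions leave no room for clean genes")

    transcripts: list[Transcript] = []
    statuses: list[str] = []
    used_tags: set[str] = set()
    idx = 0

    def gid() -> str:
        nonlocal idx
        idx += 1
        return f"G{idx:05d}"

    for _ in range(n_no_anchor):
        transcripts.append(Transcript(gid(), _random_no_motif(rng, L, motif)))
        statuses.append(NO_ANCHOR)
    for _ in range(n_short):
        # 3'-most anchor closer than tag_length to the 3' end
        remain = int(rng.integers(len(motif), tlen))
        up = _random_no_motif(rng, L - remain, motif)
        tail = _random_no_motif(rng, remain - len(motif), motif)
        seq = up + motif + tail
        assert seq.rfind(motif) == L - remain
        transcripts.append(Transcript(gid(), seq))
        statuses.append(TOO_SHORT)
    for _ in range(n_dup // 2):
        seq1, tag = _clean_sequence(rng, L, motif, tlen, used_tags)
        used_tags.add(tag)
        for _ in range(200):
            up = _random_dna(rng, L - tlen)
            seq2 = up + tag
            if seq2.rfind(motif) == L - tlen:
                break
        else:
            raise RuntimeError("could not place a duplicate tag")
        transcripts.append(Transcript(gid(), seq1))
        transcripts.append(Transcript(gid(), seq2))
        statuses.extend([REDUNDANT, REDUNDANT])
    for _ in range(n_ambig):
        seq, tag = _clean_sequence(rng, L, motif, tlen, used_tags)
        pos = int(rng.integers(len(motif), tlen))  # N inside the tag, after motif
        seq = seq[: L - tlen + pos] + "N" + seq[L - tlen + pos + 1 :]
        transcripts.append(Transcript(gid(), seq))
        statuses.append(AMBIGUOUS)
    for _ in range(n_clean):
        seq, tag = _clean_sequence(rng, L, motif, tlen, used_tags)
        used_tags.add(tag)
        transcripts.append(Transcript(gid(), seq))
        statuses.append(RETAINED)

    expected = pd.Series(
        statuses, index=[t.id for t in transcripts], name="expected_status"
    )
    return transcripts, expected


# ---------------------------------------------------------------------------
# counts


def _template_values(name: str, n_days: int, step: float) -> np.ndarray:
    t = np.arange(n_days, dtype=float)
    if name == "monotone_up":
        shape = t
    elif name == "monotone_down":
        shape = -t
    elif name == "peak":
        peak_at = max(n_days - 2, 0)  # E19 in the five-day design
        shape = np.minimum(t, 2.0 * peak_at - t)
    elif name == "constant":
        shape = np.zeros(n_days)
    else:
        raise ValueError(f"unknown template {name!r}")
    return np.exp(step * (shape - shape.mean()))


def _draw_counts(rng, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi < 1e-7:
        return rng.poisson(mu)
    r = 1.0 / phi
    p = r / (r + np.maximum(mu, 1e-300))
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(r, p[pos])
    return out


def simulate_counts(
    config: SimulationConfig,
    genes: Sequence[str],
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountMatrix, SimulationTruth]:
    """NB counts for ``genes`` under the two-compartment mixture model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    genes = list(genes)
    G, D = len(genes), len(config.days)
    meta = config.metadata()
    day_index = np.array([list(config.days).index(d) for d in meta["day"]])

    is_ery = rng.random(G) < config.erythroid_gene_fraction
    mix = np.array(config.template_mix, dtype=float)
    mix = mix / mix.sum()
    templates = np.where(
        is_ery, "constant", rng.choice(TEMPLATES, size=G, p=mix)
    )
    weight = rng.lognormal(mean=0.0, sigma=1.2, size=G)
    weight /= weight.sum()

    f = np.asarray(config.erythroid_fraction)
    tmpl_vals = np.stack(
        [_template_values(t, D, config.effect_size_ln) for t in templates]
    )  # G x D
    mixture = np.where(is_ery[:, None], f[None, :], (1.0 - f)[None, :])
    profile = weight[:, None] * tmpl_vals * mixture  # expected library share
    mu_day = config.depth * profile  # G x D expected counts per library
    expected_profiles = pd.DataFrame(mu_day, index=genes, columns=list(config.days))

    mu = mu_day[:, day_index]  # G x S
    counts = np.column_stack(
        [_draw_counts(rng, mu[:, j], config.phi) for j in range(mu.shape[1])]
    )
    counts_df = pd.DataFrame(counts, index=genes, columns=list(meta.index))
    cm = CountMatrix(counts_df, meta)

    # A gene's expected normalized profile varies across days iff its
    # template is non-constant or it rides the erythroid mixture.
    with np.errstate(invalid="ignore"):
        rel = mu_day / mu_day.mean(axis=1, keepdims=True)
    gene_table = pd.DataFrame(
        {
            "class": np.where(is_ery, "erythroid", "epithelial"),
            "template": templates,
            "weight": weight,
            "de_flag": np.ptp(rel, axis=1) > 1e-9,
        },
        index=genes,
    )
    truth = SimulationTruth(
        gene_table=gene_table,
        expected_counts=pd.DataFrame(mu, index=genes, columns=list(meta.index)),
        true_counts=cm,
        expected_profiles=expected_profiles,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# reads


def _qualities(rng, config: SimulationConfig, n_bases: int, low: bool) -> np.ndarray:
    mean = config.low_quality_mean if low else config.quality_mean
    q = rng.normal(mean, config.quality_sd, size=n_bases)
    return np.clip(np.round(q), 2, 41).astype(int)


def simulate_reads(
    true_counts: CountMatrix,
    reference: TagReference,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[Read]], dict[str, np.ndarray]]:
    """Emit per-sample reads (tag + filler, substitution errors, phreds).

    Returns (reads per sample, per-read planted tag-region error counts).
    Every counted gene must have a retained tag.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    tag_of = {e.gene_id: e.tag for e in reference.entries if e.status == RETAINED}
    missing = [g for g in true_counts.genes if g not in tag_of
               and true_counts.counts.loc[g].sum() > 0]
    if missing:
        raise ValueError(f"counted gene(s) without retained tag: {missing[:5]}")

    tlen = reference.tag_length
    base_to_int = {b: i for i, b in enumerate("ACGT")}
    reads_by_sample: dict[str, list[Read]] = {}
    errors_by_sample: dict[str, np.ndarray] = {}
    for sample in true_counts.samples:
        col = true_counts.counts[sample]
        reads: list[Read] = []
        err_counts: list[int] = []
        serial = 0
        for gene in true_counts.genes:
            c = int(col[gene])
            if c == 0:
                continue
            tag = tag_of[gene]
            tag_ints = np.array([base_to_int[b] for b in tag], dtype=int)
            for _ in range(c):
                serial += 1
                filler_ints = rng.integers(0, 4, size=config.read_length - tlen)
                seq_ints = np.concatenate([tag_ints, filler_ints])
                if config.epsilon > 0:
                    hit = rng.random(config.read_length) < config.epsilon
                    shift = rng.integers(1, 4, size=config.read_length)
                    seq_ints[hit] = (seq_ints[hit] + shift[hit]) % 4
                    n_err = int(hit[:tlen].sum())
                else:
                    n_err = 0
                low = rng.random() < config.low_quality_fraction
                quals = _qualities(rng, config, config.read_length, low)
                seq = "".join("ACGT"[i] for i in seq_ints)
                reads.append(Read(f"{sample}.{serial}", seq, tuple(quals)))
                err_counts.append(n_err)
        order = rng.permutation(len(reads))
        reads_by_sample[sample] = [reads[i] for i in order]
        errors_by_sample[sample] = np.array(err_counts)[order] if reads else np.array([], dtype=int)
    return reads_by_sample, errors_by_sample


# ---------------------------------------------------------------------------
# profile-level generator (for clustering experiments)


def simulate_profiles(
    n_per_template: int = 50,
    templates: Sequence[str] = ("monotone_up", "peak", "monotone_down"),
    noise_sd: float = 0.3,
    n_days: int = 5,
    amplitude: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Planted temporal profiles with iid Gaussian noise, plus true labels."""
    rng = np.random.default_rng(seed)
    rows, labels, names = [], [], []
    for t in templates:
        base = np.log(_template_values(t, n_days, amplitude))
        for i in range(n_per_template):
            rows.append(base + rng.normal(0, noise_sd, n_days))
            labels.append(t)
            names.append(f"{t}_{i:03d}")
    profiles = pd.DataFrame(
        rows, index=names, columns=list(DAYS[:n_days])
    )
    return profiles, pd.Series(labels, index=names, name="template")


# ---------------------------------------------------------------------------
# evaluation


def evaluate_against_truth(
    pipeline_counts: CountMatrix,
    truth: SimulationTruth,
    de_table: Optional[pd.DataFrame] = None,
    cluster_labels: Optional[pd.Series] = None,
    partition: Optional[pd.Series] = None,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Reports count recovery (Pearson r and exact-match fraction), DE power
    and empirical FDR, clustering adjusted Rand index, and cell-type
    partition accuracy, for whichever outputs are supplied.
    """
    from scipy.stats import pearsonr
    from sklearn.metrics import adjusted_rand_score

    if list(pipeline_counts.genes) != list(truth.true_counts.genes):
        raise ValueError("gene universes differ between pipeline and truth")
    obs = pipeline_counts.counts.to_numpy().ravel()
    exp = truth.true_counts.counts.to_numpy().ravel()
    metrics: dict = {
        "count_pearson_r": float(pearsonr(obs, exp)[0]) if obs.std() > 0 else 1.0,
        "count_exact_fraction": float(np.mean(obs == exp)),
    }
    if de_table is not None:
        common = de_table.index.intersection(truth.gene_table.index)
        flag = truth.gene_table.loc[common, "de_flag"].to_numpy()
        sig = de_table.loc[common, "significant"].fillna(False).to_numpy()
        n_true, n_called = int(flag.sum()), int(sig.sum())
        metrics["de_power"] = float((sig & flag).sum() / n_true) if n_true else np.nan
        metrics["de_empirical_fdr"] = (
            float((sig & ~flag).sum() / n_called) if n_called else 0.0
        )
    if cluster_labels is not None:
        common = cluster_labels.index.intersection(truth.gene_table.index)
        metrics["cluster_ari"] = float(
            adjusted_rand_score(
                truth.gene_table.loc[common, "template"], cluster_labels.loc[common]
            )
        )
    if partition is not None:
        common = partition.index.intersection(truth.gene_table.index)
        true_cls = truth.gene_table.loc[common, "class"].map(
            {"erythroid": "erythropoietic", "epithelial": "epithelial"}
        )
        metrics["partition_accuracy"] = float(
            (partition.loc[common] == true_cls).mean()
        )
        ery = true_cls == "erythropoietic"
        if ery.any():
            metrics["erythroid_recall"] = float(
                (partition.loc[common][ery] == "erythropoietic").mean()
            )
    return metrics


# ---------------------------------------------------------------------------
# whole-dataset convenience


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    transcripts: list[Transcript]
    expected_statuses: pd.Series
    reference: TagReference
    true_counts: CountMatrix
    truth: SimulationTruth
    reads: dict[str, list[Read]]
    planted_errors: dict[str, np.ndarray]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Transcriptome -> reference -> counts -> reads, all truth-known."""
    rng = np.random.default_rng(config.seed)
    transcripts, expected = simulate_transcriptome(config, rng)
    reference = build_tag_reference(
        transcripts, motif=config.motif, tag_length=config.tag_length
    )
    retained = reference.retained_genes
    counts, truth = simulate_counts(config, retained, rng)
    reads, errors = simulate_reads(counts, reference, config, rng)
    truth.planted_errors = errors
    return SimulatedDataset(
        config, transcripts, expected, reference, counts, truth, reads, errors
    )


def write_dataset(ds: SimulatedDataset, outdir) -> dict[str, str]:
    """Write ref.fa, per-sample FASTQ, samples.tsv and truth.tsv."""
    import os

    from .read_processing import write_fastq

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    fasta = os.path.join(outdir, "ref.fa")
    with open(fasta, "w") as fh:
        for t in ds.transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")
    paths["fasta"] = fasta
    meta_path = os.path.join(outdir, "samples.tsv")
    ds.true_counts.metadata.reset_index().to_csv(meta_path, sep="\t", index=False)
    paths["metadata"] = meta_path
    for sample, reads in ds.reads.items():
        p = os.path.join(outdir, f"{sample}.fq")
        write_fastq(reads, p)
        paths[sample] = p
    truth_path = os.path.join(outdir, "truth.tsv")
    ds.truth.gene_table.to_csv(truth_path, sep="\t", index_label="gene_id")
    paths["truth"] = truth_path
    counts_path = os.path.join(outdir, "true_counts.tsv")
    ds.true_counts.to_tsv(counts_path)
    paths["true_counts"] = counts_path
    return paths
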