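"""Synthetic xenograft transcriptome and read-pair generator.

A xenograft RNA-seq sample is a two-species mixture: graft (tumor) reads and
host (stroma / microenvironment) reads sequenced together. This module builds
paired synthetic references with a known one-to-one orthologue structure,
plants cross-species expression differences on chosen orthologue pairs, and
simulates stranded 2x100 bp paired-end reads with per-read origin truth, so
that every downstream stage (classification, quantification, fold-change
calling, enrichment) can be scored against ground truth.

Design of the default experiment mirrors the xenograft study layout this
package targets: three samples, each a host/graft mixture with host fraction
drawn from {0.40, 0.52, 0.65}, 2x100 bp pairs.

Geometry is deliberately simple: one transcript per gene, fragment length
equal to the read length (mates fully overlap; R2 is the reverse complement
of R1), substitution errors only, constant Q40 qualities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seqio import write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: host fractions of the three-sample default design
DEFAULT_HOST_FRACTIONS = (0.40, 0.52, 0.65)

#: baseline log-normal sigma for per-gene mean expression (log-space, natural)
DEFAULT_EXPR_SIGMA = 0.6


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript of one gene (no isoforms) in one species."""

    transcript_id: str
    gene_id: str
    species: str  # "host" | "graft"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ExpressionTruth:
    """Planted per-gene mean TPM and per-orthologue fold-change truth."""

    host_tpm: pd.Series  # index: host gene ids, sums to 1e6
    graft_tpm: pd.Series  # index: graft gene ids, sums to 1e6
    pairs: pd.DataFrame  # host_gene_id, graft_gene_id, true_log2fc, de_flag
    effect_log2fc: float
    seed: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each base independently with probability ``rate``.

    A substitution always changes the base (draw among the other three).
    Returns the mutated sequence and the number of substitutions made.
    """
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # shift each hit base by 1..3 positions in the ACGT alphabet
        idx = np.flatnonzero(hit)
        base_idx = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=n_hit)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode(), n_hit


def generate_reference_pair(
    n_genes_host: int,
    n_genes_graft: int,
    n_orthologs: int,
    transcript_len_range: tuple[int, int],
    divergence: float,
    seed: int,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], pd.DataFrame]:
    """Build host and graft transcriptomes linked by one-to-one orthologues.

    The first ``n_orthologs`` genes of each species are paired; the graft copy
    of each orthologous transcript is the host sequence with independent
    per-base substitutions at probability ``divergence``. The remaining genes
    of each species get independent random sequences, which guarantees
    species-specific k-mers exist even at zero divergence.

    Returns ``(host_transcripts, graft_transcripts, ortholog_table)`` where
    the table has columns ``host_gene_id, graft_gene_id, homology_type``.
    """
    if n_genes_host <= 0 or n_genes_graft <= 0 or n_orthologs < 0:
        raise ValueError("gene and orthologue counts must be positive")
    if n_orthologs > min(n_genes_host, n_genes_graft):
        raise ValueError("n_orthologs exceeds the smaller gene count")
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("divergence must lie in [0, 1]")
    lo, hi = transcript_len_range
    if lo <= 0 or hi < lo:
        raise ValueError("invalid transcript length range")

    rng = np.random.default_rng(seed)
    lengths_host = rng.integers(lo, hi + 1, size=n_genes_host)
    lengths_graft = rng.integers(lo, hi + 1, size=n_genes_graft)

    host: list[TranscriptRecord] = []
    graft: list[TranscriptRecord] = []
    for i in range(n_genes_host):
        seq = _random_sequence(rng, int(lengths_host[i]))
        host.append(
            TranscriptRecord(f"hostT{i:05d}", f"hostG{i:05d}", "host", seq)
        )
    for j in range(n_genes_graft):
        gid, tid = f"graftG{j:05d}", f"graftT{j:05d}"
        if j < n_orthologs:
            seq, _ = _mutate(rng, host[j].sequence, divergence)
        else:
            seq = _random_sequence(rng, int(lengths_graft[j]))
        graft.append(TranscriptRecord(tid, gid, "graft", seq))

    table = pd.DataFrame(
        {
            "host_gene_id": [host[i].gene_id for i in range(n_orthologs)],
            "graft_gene_id": [graft[i].gene_id for i in range(n_orthologs)],
            "homology_type": "ortholog_one2one",
        }
    )
    return host, graft, table


def assign_expression_profiles(
    ortholog_table: pd.DataFrame,
    n_de: int,
    effect_log2fc: float,
    seed: int,
    host_genes: list[str] | None = None,
    graft_genes: list[str] | None = None,
    sigma: float = DEFAULT_EXPR_SIGMA,
) -> ExpressionTruth:
    """Plant baseline expression plus cross-species effects on orthologues.

    Baseline mean expression is log-normal per gene; orthologous partners
    share the same baseline so that their true log2 fold change is zero
    unless an effect is planted. ``n_de`` randomly chosen pairs receive a
    fold change of exactly ``±effect_log2fc`` (split half up-in-host, half
    up-in-graft; an odd remainder goes to host). Per-species means are then
    renormalized to sum to 1e6 (TPM scale).

    ``host_genes`` / ``graft_genes`` list every gene of the species (defaults
    to the orthologue table's genes); non-orthologous genes get independent
    baselines.
    """
    pairs = ortholog_table.reset_index(drop=True)
    n_pairs = len(pairs)
    if n_de < 0 or n_de > n_pairs:
        raise ValueError("n_de must lie in [0, number of orthologue pairs]")
    if effect_log2fc <= 0 and n_de > 0:
        raise ValueError("effect_log2fc must be positive")

    host_genes = list(host_genes) if host_genes is not None else list(pairs["host_gene_id"])
    graft_genes = list(graft_genes) if graft_genes is not None else list(pairs["graft_gene_id"])

    rng = np.random.default_rng(seed)
    host_mu = pd.Series(rng.lognormal(mean=0.0, sigma=sigma, size=len(host_genes)), index=host_genes)
    graft_mu = pd.Series(np.nan, index=graft_genes, dtype=float)
    # orthologous partners share the host baseline
    base = host_mu.reindex(pairs["host_gene_id"]).to_numpy()
    graft_mu.loc[pairs["graft_gene_id"]] = base
    lonely = graft_mu.index[graft_mu.isna()]
    graft_mu.loc[lonely] = rng.lognormal(mean=0.0, sigma=sigma, size=len(lonely))

    true_fc = np.zeros(n_pairs)
    de_flag = np.zeros(n_pairs, dtype=bool)
    if n_de:
        chosen = rng.choice(n_pairs, size=n_de, replace=False)
        n_host_up = n_de - n_de // 2  # ties toward host
        half = effect_log2fc / 2.0
        for rank, idx in enumerate(chosen):
            sgn = 1.0 if rank < n_host_up else -1.0
            hg = pairs.at[idx, "host_gene_id"]
            gg = pairs.at[idx, "graft_gene_id"]
            host_mu.loc[hg] *= 2.0 ** (sgn * half)
            graft_mu.loc[gg] *= 2.0 ** (-sgn * half)
            true_fc[idx] = sgn * effect_log2fc
            de_flag[idx] = True

    host_tpm = host_mu / host_mu.sum() * 1e6
    graft_tpm = graft_mu / graft_mu.sum() * 1e6
    truth_pairs = pairs[["host_gene_id", "graft_gene_id"]].copy()
    truth_pairs["true_log2fc"] = true_fc
    truth_pairs["de_flag"] = de_flag
    return ExpressionTruth(host_tpm, graft_tpm, truth_pairs, effect_log2fc, seed)


def simulate_read_pairs(
    transcripts: list[TranscriptRecord],
    truth: ExpressionTruth,
    n_pairs: int,
    read_len: int,
    error_rate: float,
    host_fraction: float,
    seed: int,
    sample_id: str = "sample",
) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate a mixed-species paired-end sample with per-read truth.

    Each pair's species is Bernoulli(``host_fraction``); within the species
    the transcript is drawn proportional to true TPM times effective length
    (length - read_len + 1); the fragment start is uniform. R1 is the forward
    substring, R2 its reverse complement (fully overlapping mates).
    Substitution errors hit each base independently at ``error_rate``.

    Returns ``(r1_records, r2_records, read_truth)`` where records are
    ``(title, sequence, quality)`` FASTQ tuples with ``/1`` / ``/2`` suffixes.
    """
    if not transcripts:
        raise ValueError("empty transcript set")
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not (0.0 <= error_rate <= 1.0) or not (0.0 <= host_fraction <= 1.0):
        raise ValueError("error_rate and host_fraction must lie in [0, 1]")
    shortest = min(t.length for t in transcripts)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest transcript ({shortest} bp)")

    rng = np.random.default_rng(seed)
    by_species: dict[str, list[TranscriptRecord]] = {"host": [], "graft": []}
    for t in transcripts:
        by_species[t.species].append(t)

    weights: dict[str, np.ndarray] = {}
    for sp, recs in by_species.items():
        if not recs:
            continue
        tpm = truth.host_tpm if sp == "host" else truth.graft_tpm
        w = np.array(
            [tpm.get(r.gene_id, 0.0) * (r.length - read_len + 1) for r in recs], dtype=float
        )
        total = w.sum()
        weights[sp] = w / total if total > 0 else None

    is_host = rng.random(n_pairs) < host_fraction
    qual = "I" * read_len
    r1: list[tuple[str, str, str]] = []
    r2: list[tuple[str, str, str]] = []
    rows = []
    for i in range(n_pairs):
        sp = "host" if is_host[i] else "graft"
        recs = by_species[sp]
        if not recs or weights.get(sp) is None:
            raise ValueError(f"no expressed transcripts for species {sp!r}")
        rec = recs[rng.choice(len(recs), p=weights[sp])]
        start = int(rng.integers(0, rec.length - read_len + 1))
        frag = rec.sequence[start : start + read_len]
        seq1, e1 = _mutate(rng, frag, error_rate)
        seq2, e2 = _mutate(rng, reverse_complement(frag), error_rate)
        pid = f"{sample_id}:pair{i:07d}"
        r1.append((f"{pid}/1", seq1, qual))
        r2.append((f"{pid}/2", seq2, qual))
        rows.append((pid, sp, rec.transcript_id, start, e1 + e2))
    read_truth = pd.DataFrame(
        rows,
        columns=["read_pair_id", "origin_species", "origin_transcript", "start", "errors_introduced"],
    )
    return r1, r2, read_truth


@dataclass
class SimulatedExperiment:
    """On-disk layout of a full synthetic multi-sample xenograft experiment."""

    out_dir: Path
    host_fasta: Path
    graft_fasta: Path
    host_tx2gene: Path
    graft_tx2gene: Path
    ortholog_tsv: Path
    samples: list[str]
    fastq_r1: dict[str, Path]
    fastq_r2: dict[str, Path]
    truth: ExpressionTruth = field(repr=False)
    read_truth: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    manifest: Path | None = None


def simulate_experiment(
    out_dir: str | Path,
    seed: int,
    n_samples: int = 3,
    host_fractions: tuple[float, ...] = DEFAULT_HOST_FRACTIONS,
    n_genes_host: int = 80,
    n_genes_graft: int = 80,
    n_orthologs: int = 60,
    transcript_len_range: tuple[int, int] = (300, 500),
    divergence: float = 0.2,
    n_de: int | None = None,
    effect_log2fc: float = 3.0,
    n_pairs: int = 32000,
    read_len: int = 100,
    error_rate: float = 0.005,
    expression_sigma: float = DEFAULT_EXPR_SIGMA,
) -> SimulatedExperiment:
    """Generate the default three-sample xenograft experiment on disk.

    Defaults plant |log2FC| = 3 on 10% of orthologue pairs and give each
    sample 32,000 pairs (200 pairs per gene on average over the 160 genes),
    at 0.2 reference divergence and 0.005 per-base error.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if n_de is None:
        n_de = max(1, round(0.10 * n_orthologs))
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")

    host, graft, ortho = generate_reference_pair(
        n_genes_host, n_genes_graft, n_orthologs, transcript_len_range, divergence, seed
    )
    truth = assign_expression_profiles(
        ortho,
        n_de,
        effect_log2fc,
        seed + 1,
        host_genes=[t.gene_id for t in host],
        graft_genes=[t.gene_id for t in graft],
        sigma=expression_sigma,
    )

    host_fasta = out_dir / "host_transcripts.fasta"
    graft_fasta = out_dir / "graft_transcripts.fasta"
    write_fasta([(t.transcript_id, t.sequence) for t in host], host_fasta)
    write_fasta([(t.transcript_id, t.sequence) for t in graft], graft_fasta)
    host_t2g = out_dir / "host_tx2gene.tsv"
    graft_t2g = out_dir / "graft_tx2gene.tsv"
    pd.DataFrame(
        {"transcript_id": [t.transcript_id for t in host], "gene_id": [t.gene_id for t in host]}
    ).to_csv(host_t2g, sep="\t", index=False)
    pd.DataFrame(
        {"transcript_id": [t.transcript_id for t in graft], "gene_id": [t.gene_id for t in graft]}
    ).to_csv(graft_t2g, sep="\t", index=False)
    ortho_tsv = out_dir / "orthologs.tsv"
    ortho.to_csv(ortho_tsv, sep="\t", index=False)
    truth.pairs.to_csv(out_dir / "truth_pairs.tsv", sep="\t", index=False)
    truth.host_tpm.rename("true_tpm").to_csv(out_dir / "truth_host_tpm.tsv", sep="\t")
    truth.graft_tpm.rename("true_tpm").to_csv(out_dir / "truth_graft_tpm.tsv", sep="\t")

    samples, r1_paths, r2_paths, truths = [], {}, {}, {}
    all_transcripts = host + graft
    for s in range(n_samples):
        name = f"sample{s + 1}"
        hf = host_fractions[s % len(host_fractions)]
        r1, r2, rt = simulate_read_pairs(
            all_transcripts, truth, n_pairs, read_len, error_rate, hf, seed + 100 + s, sample_id=name
        )
        p1 = out_dir / f"{name}_R1.fastq"
        p2 = out_dir / f"{name}_R2.fastq"
        write_fastq(r1, p1)
        write_fastq(r2, p2)
        rt.to_csv(out_dir / f"{name}_read_truth.tsv", sep="\t", index=False)
        samples.append(name)
        r1_paths[name], r2_paths[name], truths[name] = p1, p2, rt

    manifest = out_dir / "manifest.json"
    manifest.write_text(
        json.dumps(
            {
                "seed": seed,
                "n_samples": n_samples,
                "host_fractions": list(host_fractions[:n_samples]),
                "n_genes_host": n_genes_host,
                "n_genes_graft": n_genes_graft,
                "n_orthologs": n_orthologs,
                "transcript_len_range": list(transcript_len_range),
                "divergence": divergence,
                "n_de": n_de,
                "effect_log2fc": effect_log2fc,
                "n_pairs": n_pairs,
                "read_len": read_len,
                "error_rate": error_rate,
                "expression_sigma": expression_sigma,
            },
            indent=2,
        )
        + "\n"
    )
    return SimulatedExperiment(
        out_dir=out_dir,
        host_fasta=host_fasta,
        graft_fasta=graft_fasta,
        host_tx2gene=host_t2g,
        graft_tx2gene=graft_t2g,
        ortholog_tsv=ortho_tsv,
        samples=samples,
        fastq_r1=r1_paths,
        fastq_r2=r2_paths,
        truth=truth,
        read_truth=truths,
        manifest=manifest,
    )
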