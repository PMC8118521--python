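"""Alignment-free gene-level quantification of species-classified reads.

Once a xenograft sample's reads are split by species, each species' reads
are assigned to genes by canonical k-mer voting against that species'
transcriptome (one transcript per gene): a pair's matching k-mers are
tallied per gene, the gene(s) with the most matches receive the pair, and a
tie splits the unit count equally. Counts are converted to transcripts per
million (TPM) with the standard effective-length correction

    efflen_g = max(L_g - read_len + 1, 1)
    rate_g   = count_g / efflen_g
    TPM_g    = rate_g / sum_g rate_g * 1e6

so that each column sums to one million whenever any count is positive.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._seqio import read_fasta, read_fastq
from .kmer import canonical_kmers
from .simulate import TranscriptRecord


def effective_lengths(lengths: pd.Series, read_len: int) -> pd.Series:
    """max(L - read_len + 1, 1) per gene."""
    return (lengths - read_len + 1).clip(lower=1).astype(float)


def compute_tpm(counts: pd.Series, eff_len: pd.Series) -> pd.Series:
    """Length-corrected counts rescaled to sum to 1e6; all-zero stays zero."""
    if (counts < 0).any():
        raise ValueError("negative counts")
    eff = eff_len.reindex(counts.index)
    if eff.isna().any() and (counts[eff.isna()] > 0).any():
        missing = counts.index[eff.isna() & (counts > 0)][:5].tolist()
        raise ValueError(f"missing effective length for genes with counts: {missing}")
    rate = counts / eff.fillna(1.0)
    total = rate.sum()
    if total == 0:
        return counts * 0.0
    return rate / total * 1e6


class KmerQuantifier(BaseEstimator, TransformerMixin):
    """Fit a k-mer -> gene map on one species' transcriptome, count read pairs.

    Parameters
    ----------
    k : int, default 25
        Canonical k-mer size; should match the classification k.

    Attributes
    ----------
    kmer_genes_ : dict[str, tuple[str, ...]]
        Canonical k-mer to the genes whose transcript contains it.
    gene_lengths_ : pandas.Series
        Transcript length per gene (one transcript per gene).
    genes_ : list[str]
        All genes of the fitted transcriptome, in input order.
    """

    def __init__(self, k: int = 25):
        self.k = k

    def fit(self, transcripts: Sequence[TranscriptRecord] | str | Path, y=None, tx2gene: pd.DataFrame | None = None):
        """Index a transcriptome given records, or a FASTA path plus tx2gene."""
        if isinstance(transcripts, (str, Path)):
            if tx2gene is None:
                raise ValueError("tx2gene table required when fitting from FASTA")
            t2g = dict(zip(tx2gene["transcript_id"], tx2gene["gene_id"]))
            records = [(t2g[name], seq) for name, seq in read_fasta(transcripts)]
        else:
            records = [(t.gene_id, t.sequence) for t in transcripts]
        if not records:
            raise ValueError("empty transcript set")

        kmer_genes: dict[str, set[str]] = {}
        lengths: dict[str, int] = {}
        for gene, seq in records:
            lengths[gene] = len(seq)
            for km in canonical_kmers(seq, self.k):
                kmer_genes.setdefault(km, set()).add(gene)
        self.kmer_genes_ = {km: tuple(sorted(gs)) for km, gs in kmer_genes.items()}
        self.gene_lengths_ = pd.Series(lengths, name="length")
        self.genes_ = list(lengths)
        return self

    def assign_pairs(self, pairs: Iterable[tuple[str, str]]) -> tuple[pd.Series, int]:
        """Vote each (R1, R2) pair onto genes; return (counts, n_dropped).

        Genes achieving the maximal number of matching k-mers for the pair
        split a unit count equally; pairs with no matching k-mer are dropped.
        """
        if not hasattr(self, "kmer_genes_"):
            raise ValueError("quantifier is not fitted; call fit() first")
        counts = {g: 0.0 for g in self.genes_}
        dropped = 0
        kmer_genes = self.kmer_genes_
        for r1, r2 in pairs:
            votes: Counter[str] = Counter()
            for mate in (r1, r2):
                for km in canonical_kmers(mate, self.k):
                    hit = kmer_genes.get(km)
                    if hit:
                        votes.update(hit)
            if not votes:
                dropped += 1
                continue
            top = max(votes.values())
            winners = [g for g, v in votes.items() if v == top]
            share = 1.0 / len(winners)
            for g in winners:
                counts[g] += share
        return pd.Series(counts, name="count"), dropped

    def transform(self, pairs: Iterable[tuple[str, str]]) -> pd.Series:
        counts, _ = self.assign_pairs(pairs)
        return counts


def quantify_fastq_pair(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    quantifier: KmerQuantifier,
    read_len: int | None = None,
) -> tuple[pd.Series, pd.Series, int]:
    """Count and TPM-normalize one classified FASTQ pair.

    Returns ``(counts, tpm, n_dropped)``. ``read_len`` defaults to the first
    read's length (reads are fixed-length in this pipeline).
    """
    seqs1 = [s for _, s, _ in read_fastq(fastq_r1)]
    seqs2 = [s for _, s, _ in read_fastq(fastq_r2)]
    if len(seqs1) != len(seqs2):
        raise ValueError("mismatched R1/R2 record counts")
    if not seqs1:
        zero = pd.Series(0.0, index=quantifier.genes_)
        return zero, zero.copy(), 0
    if read_len is None:
        read_len = len(seqs1[0])
    counts, dropped = quantifier.assign_pairs(zip(seqs1, seqs2))
    eff = effective_lengths(quantifier.gene_lengths_, read_len)
    return counts, compute_tpm(counts, eff), dropped


def expression_matrix(columns: dict[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample TPM (or count) columns into a gene x sample matrix."""
    mat = pd.DataFrame(columns)
    return mat.fillna(0.0)
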