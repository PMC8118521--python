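"""Species-based read-pair classification with canonical k-mers.

A read pair from a xenograft sample is assigned to one of five classes —
``host``, ``graft``, ``ambiguous``, ``both``, ``neither`` — by intersecting
its canonical k-mers with three disjoint sets built from the two reference
transcriptomes: k-mers unique to the host reference, k-mers unique to the
graft reference, and k-mers shared by both. The decision rule is:

=====  =====  ======  ==========
nH>0   nG>0   nB>0    class
=====  =====  ======  ==========
yes    no     any     host
no     yes    any     graft
yes    yes    any     ambiguous
no     no     yes     both
no     no     no      neither
=====  =====  ======  ==========

where nH, nG, nB count the pair's canonical k-mers found in the host-only,
graft-only and shared sets (summed over both mates; a pair has a single
origin). Canonical form — the lexicographic minimum of a k-mer and its
reverse complement — makes classification strand-agnostic; k must be odd so
no k-mer is its own reverse complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from ._seqio import read_fasta, read_fastq, strip_mate_suffix, write_fastq

CLASSES = ("host", "graft", "ambiguous", "both", "neither")
DEFAULT_K = 25

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def canonical_kmers(seq: str, k: int) -> Iterator[str]:
    """Yield the canonical form of every k-mer of ``seq``.

    K-mers containing characters outside {A,C,G,T} are skipped. Sequences
    shorter than k yield nothing.
    """
    seq = seq.upper()
    n = len(seq)
    if n < k:
        return
    rc = seq.translate(_COMPLEMENT)[::-1]
    clean = _VALID.issuperset(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if not clean and not _VALID.issuperset(fwd):
            continue
        rev = rc[n - k - i : n - i]
        yield fwd if fwd <= rev else rev


@dataclass
class KmerIndex:
    """Disjoint canonical k-mer partition of two reference transcriptomes."""

    k: int
    host_only: frozenset[str]
    graft_only: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        if self.host_only & self.graft_only or self.host_only & self.shared or self.graft_only & self.shared:
            raise ValueError("k-mer sets must be pairwise disjoint")

    def save(self, path: str | Path) -> None:
        with open(path, "w") as out:
            out.write(f"#xenosort-kmer-index\tv1\tk={self.k}\n")
            for tag, kmers in (("H", self.host_only), ("G", self.graft_only), ("S", self.shared)):
                for km in sorted(kmers):
                    out.write(f"{tag}\t{km}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerIndex":
        sets: dict[str, set[str]] = {"H": set(), "G": set(), "S": set()}
        with open(path) as handle:
            header = handle.readline().rstrip("\n").split("\t")
            if len(header) < 3 or header[0] != "#xenosort-kmer-index":
                raise ValueError(f"not a xenosort k-mer index: {path}")
            k = int(header[2].removeprefix("k="))
            for line in handle:
                tag, km = line.rstrip("\n").split("\t")
                sets[tag].add(km)
        return cls(k, frozenset(sets["H"]), frozenset(sets["G"]), frozenset(sets["S"]))


def _validate_k(k: int) -> None:
    if k % 2 == 0:
        raise ValueError("k must be odd (a palindromic k-mer has no unique canonical form)")
    if not (11 <= k <= 31):
        raise ValueError("k must lie in [11, 31]")


def build_kmer_index(
    host_fasta: str | Path | Sequence[str],
    graft_fasta: str | Path | Sequence[str],
    k: int = DEFAULT_K,
) -> KmerIndex:
    """Partition all reference k-mers into host-only / graft-only / shared.

    ``host_fasta`` / ``graft_fasta`` may be FASTA paths or in-memory sequence
    lists.
    """
    _validate_k(k)

    def collect(src) -> set[str]:
        if isinstance(src, (str, Path)):
            seqs = [s for _, s in read_fasta(src)]
        else:
            seqs = list(src)
        if not seqs:
            raise ValueError("empty reference")
        out: set[str] = set()
        for s in seqs:
            out.update(canonical_kmers(s, k))
        return out

    host_kmers = collect(host_fasta)
    graft_kmers = collect(graft_fasta)
    shared = host_kmers & graft_kmers
    return KmerIndex(
        k=k,
        host_only=frozenset(host_kmers - shared),
        graft_only=frozenset(graft_kmers - shared),
        shared=frozenset(shared),
    )


def classify_read_pair(r1: str, r2: str, index: KmerIndex) -> str:
    """Classify one read pair into host/graft/ambiguous/both/neither."""
    if not r1 or not r2:
        raise ValueError("empty read in pair")
    n_host = n_graft = n_both = 0
    host_only, graft_only, shared = index.host_only, index.graft_only, index.shared
    for mate in (r1, r2):
        for km in canonical_kmers(mate, index.k):
            if km in host_only:
                n_host += 1
            elif km in graft_only:
                n_graft += 1
            elif km in shared:
                n_both += 1
    if n_host and not n_graft:
        return "host"
    if n_graft and not n_host:
        return "graft"
    if n_host and n_graft:
        return "ambiguous"
    if n_both:
        return "both"
    return "neither"


class KmerReadClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn-style wrapper: fit on two references, predict read pairs.

    Parameters
    ----------
    k : int, default 25
        Odd k-mer size in [11, 31].

    Attributes
    ----------
    index_ : KmerIndex
        The disjoint canonical k-mer partition after :meth:`fit`.
    classes_ : ndarray of str
        The five class labels.
    """

    def __init__(self, k: int = DEFAULT_K):
        self.k = k

    def fit(self, host_fasta, graft_fasta=None, y=None):
        """Build the k-mer index. ``host_fasta`` may be a (host, graft) tuple."""
        if graft_fasta is None:
            host_fasta, graft_fasta = host_fasta
        self.index_ = build_kmer_index(host_fasta, graft_fasta, self.k)
        self.classes_ = np.asarray(CLASSES)
        return self

    def predict(self, X: Iterable[tuple[str, str]]) -> np.ndarray:
        """Classify an iterable of (R1, R2) sequence pairs."""
        if not hasattr(self, "index_"):
            raise ValueError("classifier is not fitted; call fit() first")
        return np.asarray([classify_read_pair(r1, r2, self.index_) for r1, r2 in X])


@dataclass
class ClassificationSummary:
    """Per-class read-pair counts and raw percentages for one sample."""

    sample_id: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            warnings.warn("empty input: percentages undefined, reported as 0")
            return {c: 0.0 for c in CLASSES}
        return {c: 100.0 * self.counts[c] / total for c in CLASSES}


def classify_dataset(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    index: KmerIndex,
    out_dir: str | Path,
    sample_id: str | None = None,
) -> ClassificationSummary:
    """Classify a paired FASTQ sample and split it into five FASTQ pairs.

    Writes ``{class}_1.fastq`` / ``{class}_2.fastq`` under ``out_dir``
    (input order preserved within each class) and returns the per-class
    summary. R1/R2 must be in matched order with equal record counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sample_id = sample_id or Path(fastq_r1).stem

    counts = {c: 0 for c in CLASSES}
    sinks: dict[str, tuple[list, list]] = {c: ([], []) for c in CLASSES}
    for idx, (rec1, rec2) in enumerate(
        zip_longest(read_fastq(fastq_r1), read_fastq(fastq_r2))
    ):
        if rec1 is None or rec2 is None:
            raise ValueError(f"mismatched R1/R2 record counts at record index {idx}")
        t1, s1, _ = rec1
        t2, s2, _ = rec2
        if strip_mate_suffix(t1) != strip_mate_suffix(t2):
            raise ValueError(f"unpaired records at index {idx}: {t1!r} vs {t2!r}")
        cls = classify_read_pair(s1, s2, index)
        counts[cls] += 1
        sinks[cls][0].append(rec1)
        sinks[cls][1].append(rec2)

    for cls in CLASSES:
        write_fastq(sinks[cls][0], out_dir / f"{cls}_1.fastq")
        write_fastq(sinks[cls][1], out_dir / f"{cls}_2.fastq")
    return ClassificationSummary(sample_id=sample_id, counts=counts)


#: printed precision per class in the summary table: the three major classes
#: at one decimal, the two minor ones at two decimals
SUMMARY_DECIMALS = {"host": 1, "graft": 1, "ambiguous": 1, "both": 2, "neither": 2}


def summarize_classification(
    summaries: Sequence[ClassificationSummary] | pd.DataFrame,
) -> pd.Series:
    """Average per-class percentages over samples, at table precision.

    Accepts a list of :class:`ClassificationSummary` or a DataFrame of
    per-sample percentage rows with the five class columns. Returns the
    per-class arithmetic mean, rounded to one decimal for host/graft/
    ambiguous and two decimals for both/neither.
    """
    if isinstance(summaries, pd.DataFrame):
        table = summaries[list(CLASSES)].astype(float)
    else:
        if len(summaries) == 0:
            raise ValueError("need at least one classification summary")
        table = pd.DataFrame([s.percentages for s in summaries])[list(CLASSES)]
    if table.empty:
        raise ValueError("need at least one classification summary")
    means = table.mean(axis=0)
    return pd.Series(
        {c: round(float(means[c]), SUMMARY_DECIMALS[c]) for c in CLASSES}, name="average_percent"
    )
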