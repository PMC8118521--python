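"""Shared fixtures: small synthetic references, a mini experiment on disk,
and independent oracles (exact hypergeometric tail, substring-search read
classification)."""

from __future__ import annotations

import math
from fractions import Fraction

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from xenosort.simulate import (
    assign_expression_profiles,
    generate_reference_pair,
    reverse_complement,
    simulate_experiment,
)
from xenosort.kmer import build_kmer_index


@pytest.fixture(scope="session")
def tiny_refs():
    """12+12 genes, 8 orthologue pairs, divergence 0.2."""
    return generate_reference_pair(12, 12, 8, (300, 400), 0.2, seed=11)


@pytest.fixture(scope="session")
def tiny_truth(tiny_refs):
    host, graft, table = tiny_refs
    return assign_expression_profiles(
        table,
        n_de=2,
        effect_log2fc=3.0,
        seed=12,
        host_genes=[t.gene_id for t in host],
        graft_genes=[t.gene_id for t in graft],
    )


@pytest.fixture(scope="session")
def tiny_index(tiny_refs):
    host, graft, _ = tiny_refs
    return build_kmer_index([t.sequence for t in host], [t.sequence for t in graft], k=25)


@pytest.fixture(scope="session")
def mini_experiment(tmp_path_factory):
    """A small but complete 3-sample experiment on disk."""
    out = tmp_path_factory.mktemp("mini_sim")
    return simulate_experiment(
        out,
        seed=123,
        n_genes_host=30,
        n_genes_graft=30,
        n_orthologs=20,
        transcript_len_range=(300, 400),
        divergence=0.2,
        n_de=2,
        effect_log2fc=3.0,
        n_pairs=4000,
        error_rate=0.005,
    )


@pytest.fixture(scope="session")
def hypergeom_exact():
    """Exact right-tail hypergeometric probability via rational arithmetic."""

    def tail(a: int, K: int, n: int, N: int) -> Fraction:
        denom = math.comb(N, n)
        num = 0
        for x in range(a, min(K, n) + 1):
            num += math.comb(K, x) * math.comb(N - K, n - x)
        return Fraction(num, denom)

    return tail


@pytest.fixture(scope="session")
def substring_oracle():
    """Classify an error-free read pair by substring search in full references.

    Returns host/graft/both/neither according to whether the pair (each mate
    forward or reverse-complemented) occurs verbatim in the host and/or the
    graft reference sequences.
    """

    def oracle(r1: str, r2: str, host_seqs: list[str], graft_seqs: list[str]) -> str:
        def pair_in(seqs: list[str]) -> bool:
            def mate_in(read: str) -> bool:
                rc = reverse_complement(read)
                return any(read in s or rc in s for s in seqs)

            return mate_in(r1) and mate_in(r2)

        in_host, in_graft = pair_in(host_seqs), pair_in(graft_seqs)
        if in_host and in_graft:
            return "both"
        if in_host:
            return "host"
        if in_graft:
            return "graft"
        return "neither"

    return oracle
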