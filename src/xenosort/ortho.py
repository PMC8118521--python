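"""Cross-species orthologue harmonization, fold change and DEG calling.

Expression can only be compared across species on one-to-one orthologues.
This module filters an orthologue table to strict one-to-one pairs, builds
the joint orthologue x sample matrix of log2(TPM + 0.01) values over both
species' samples (keeping pairs expressed — TPM > 0 — in at least one
sample), computes the cross-species statistic

    log2FC = log2((mean host TPM + c) / (mean graft TPM + c)),   c = 0.01

and calls differentially expressed genes with the inclusive |log2FC| >= 2.2
rule. The sign convention: positive log2FC means higher expression on the
host (microenvironment, "TME") side, negative means higher in the graft
tumor.

The pseudocount also appears inside the fold-change ratio so the statistic
stays finite when one species' mean is zero; pass ``fc_pseudocount=0`` to
reproduce the bare ratio where defined.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_FC_THRESHOLD = 2.2
ONE2ONE = "ortholog_one2one"

REQUIRED_COLUMNS = ("host_gene_id", "graft_gene_id", "homology_type")


def load_ortholog_map(source: str | Path | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter an orthologue table to strict one-to-one pairs.

    Rows whose ``homology_type`` is not one-to-one are dropped; if a gene
    still appears in more than one surviving row, all of its rows are
    dropped too (strict one-to-one). Returns ``(retained, dropped)`` where
    ``dropped`` carries a ``drop_reason`` column.
    """
    table = pd.read_csv(source, sep="\t") if isinstance(source, (str, Path)) else source.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"orthologue table missing columns: {missing}")
    table = table[list(REQUIRED_COLUMNS)].reset_index(drop=True)
    if table.empty:
        warnings.warn("orthologue table is empty")
        return table, table.assign(drop_reason=pd.Series(dtype=str))

    is_121 = table["homology_type"].str.contains("one2one|one-to-one", case=False, regex=True)
    dropped_type = table[~is_121].assign(drop_reason="not one-to-one")
    kept = table[is_121]
    dup_host = kept["host_gene_id"].duplicated(keep=False)
    dup_graft = kept["graft_gene_id"].duplicated(keep=False)
    dropped_dup = kept[dup_host | dup_graft].assign(drop_reason="gene in multiple pairs")
    retained = kept[~(dup_host | dup_graft)].reset_index(drop=True)
    dropped = pd.concat([dropped_type, dropped_dup], ignore_index=True)
    return retained, dropped


def _pair_index(omap: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(
        omap[["host_gene_id", "graft_gene_id"]], names=["host_gene_id", "graft_gene_id"]
    )


def build_ortho_matrix(
    host_tpm: pd.DataFrame,
    graft_tpm: pd.DataFrame,
    omap: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Joint orthologue x sample matrix of log2(TPM + pseudocount).

    Host sample columns come first, then graft sample columns (sample IDs
    must be disjoint between the two matrices). Orthologue pairs with zero
    TPM in every sample of both species are removed ("expressed in at least
    one sample" filter); mapped genes absent from a matrix are treated as
    all-zero with a warning.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    overlap = set(host_tpm.columns) & set(graft_tpm.columns)
    if overlap:
        raise ValueError(f"sample IDs shared between species matrices: {sorted(overlap)}")

    missing_h = [g for g in omap["host_gene_id"] if g not in host_tpm.index]
    missing_g = [g for g in omap["graft_gene_id"] if g not in graft_tpm.index]
    if missing_h or missing_g:
        warnings.warn(
            f"{len(missing_h)} host / {len(missing_g)} graft mapped genes absent from "
            "expression matrices; treated as zero"
        )
    h = host_tpm.reindex(omap["host_gene_id"]).fillna(0.0).to_numpy()
    g = graft_tpm.reindex(omap["graft_gene_id"]).fillna(0.0).to_numpy()
    raw = np.hstack([h, g])
    expressed = (raw > 0).any(axis=1)
    mat = pd.DataFrame(
        np.log2(raw[expressed] + pseudocount),
        index=_pair_index(omap)[expressed],
        columns=list(host_tpm.columns) + list(graft_tpm.columns),
    )
    mat.attrs["host_samples"] = list(host_tpm.columns)
    mat.attrs["graft_samples"] = list(graft_tpm.columns)
    mat.attrs["pseudocount"] = pseudocount
    return mat


def compute_log2fc(
    mean_host: pd.Series,
    mean_graft: pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2((mean_host + c) / (mean_graft + c)) on raw TPM means."""
    if (mean_host < 0).any() or (mean_graft < 0).any():
        raise ValueError("negative mean TPM")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    with np.errstate(divide="ignore"):
        fc = np.log2(mean_host + pseudocount) - np.log2(mean_graft.to_numpy() + pseudocount)
    return pd.Series(fc, index=mean_host.index, name="log2fc")


def call_degs(
    log2fc: pd.Series,
    mean_host: pd.Series | None = None,
    mean_graft: pd.Series | None = None,
    threshold: float = DEFAULT_FC_THRESHOLD,
    restrict_to=None,
) -> pd.DataFrame:
    """Flag DEGs with the inclusive |log2FC| >= threshold rule.

    ``restrict_to`` (e.g. the PCA-selected gene subset) is applied before
    thresholding. Direction ``tme_up`` means log2FC >= +threshold (higher on
    the host/microenvironment side), ``tumor_up`` means <= -threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fc = log2fc if restrict_to is None else log2fc.loc[log2fc.index.isin(list(restrict_to))]
    direction = pd.Series("none", index=fc.index, dtype=object)
    direction[fc >= threshold] = "tme_up"
    direction[fc <= -threshold] = "tumor_up"
    table = pd.DataFrame({"log2fc": fc, "direction": direction, "is_deg": direction != "none"})
    if mean_host is not None:
        table.insert(0, "mean_host_tpm", mean_host.reindex(fc.index).to_numpy())
    if mean_graft is not None:
        table.insert(1, "mean_graft_tpm", mean_graft.reindex(fc.index).to_numpy())
    return table


def deg_counts(table: pd.DataFrame) -> dict[str, int]:
    """Per-direction DEG counts plus the total (total = tme_up + tumor_up)."""
    tme = int((table["direction"] == "tme_up").sum())
    tumor = int((table["direction"] == "tumor_up").sum())
    return {"tme_up": tme, "tumor_up": tumor, "none": int(len(table)) - tme - tumor, "total_deg": tme + tumor}


def fold_change_table(
    host_tpm: pd.DataFrame,
    graft_tpm: pd.DataFrame,
    omap: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_FC_THRESHOLD,
    restrict_to=None,
) -> pd.DataFrame:
    """Means, fold change and DEG flags for every mapped orthologue pair.

    Convenience composition of :func:`compute_log2fc` and :func:`call_degs`
    with species means taken over each species' own sample columns.
    """
    idx = _pair_index(omap)
    mean_h = pd.Series(
        host_tpm.reindex(omap["host_gene_id"]).fillna(0.0).mean(axis=1).to_numpy(), index=idx
    )
    mean_g = pd.Series(
        graft_tpm.reindex(omap["graft_gene_id"]).fillna(0.0).mean(axis=1).to_numpy(), index=idx
    )
    fc = compute_log2fc(mean_h, mean_g, pseudocount)
    return call_degs(fc, mean_h, mean_g, threshold=threshold, restrict_to=restrict_to)
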