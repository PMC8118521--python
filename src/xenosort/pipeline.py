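"""End-to-end xenograft deconvolution pipeline.

Stage order (fixed): simulate (optional) -> k-mer index -> classify each
sample -> quantify host- and graft-classified reads separately -> TPM ->
orthologue harmonization (one-to-one filter, expressed-in->=1-sample
filter, log2(TPM+0.01)) -> PCA -> contribution selection per component ->
|log2FC| >= 2.2 DEG calling on the selected genes -> gene-set enrichment.
Only host- and graft-classified reads reach quantification; the
PCA-contribution filter is applied before the fold-change threshold.

Everything is deterministic given the seeds in the configuration, and every
resolved parameter is echoed into the machine-readable ``report.json``.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import enrich_sets, read_gmt
from .kmer import (
    CLASSES,
    KmerIndex,
    build_kmer_index,
    classify_dataset,
    summarize_classification,
)
from .ortho import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    build_ortho_matrix,
    deg_counts,
    fold_change_table,
    load_ortholog_map,
)
from .pca import gene_contributions, run_pca, select_contributing_genes
from .quantify import KmerQuantifier, expression_matrix, quantify_fastq_pair
from .simulate import simulate_experiment


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (defaults mirror the printed
    analysis constants: pseudocount 0.01, |log2FC| threshold 2.2, FDR 0.05)."""

    out_dir: str = "xenosort_run"
    host_fasta: str | None = None
    graft_fasta: str | None = None
    host_tx2gene: str | None = None
    graft_tx2gene: str | None = None
    ortholog_tsv: str | None = None
    gmt: str | None = None
    samples: dict[str, tuple[str, str]] = field(default_factory=dict)  # name -> (R1, R2)
    simulate: bool = False
    sim_params: dict = field(default_factory=dict)
    k: int = 25
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    fdr: float = 0.05
    scale: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if not self.simulate:
            needed = ["host_fasta", "graft_fasta", "host_tx2gene", "graft_tx2gene", "ortholog_tsv"]
            missing = [f for f in needed if getattr(self, f) is None]
            if missing:
                raise ValueError(f"missing inputs (or pass simulate=True): {missing}")
            if not self.samples:
                raise ValueError("no samples configured")
        if self.pseudocount <= 0 or self.fc_threshold <= 0 or not (0 < self.fdr < 1):
            raise ValueError("pseudocount and fc_threshold must be > 0; fdr in (0, 1)")


def _log(msg: str, quiet: bool) -> None:
    if not quiet:
        print(f"[xenosort] {msg}", file=sys.stderr)


def run_all(config: RunConfig, quiet: bool = True) -> dict:
    """Execute the full pipeline; returns the report dict (also on disk).

    On a stage failure, partial outputs are retained and a ``failed`` marker
    file naming the stage is written to the output directory before the
    error propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracker = ["setup"]
    try:
        return _run_all_stages(config, out, quiet, tracker)
    except Exception as exc:
        (out / "failed").write_text(f"{tracker[0]}\t{exc}\n")
        raise


def _run_all_stages(config: RunConfig, out: Path, quiet: bool, tracker: list[str]) -> dict:
    t0 = time.time()

    def mark(stage: str, msg: str) -> None:
        tracker[0] = stage
        _log(msg, quiet)
    report: dict = {
        "software": {"name": "xenosort", "version": __version__},
        "parameters": {
            "k": config.k,
            "pseudocount": config.pseudocount,
            "fc_threshold": config.fc_threshold,
            "fdr": config.fdr,
            "scale": config.scale,
            "seed": config.seed,
            "simulate": config.simulate,
        },
        "stages": {},
    }

    if config.simulate:
        mark("simulate", "simulating synthetic xenograft experiment")
        sim = simulate_experiment(out / "sim", seed=config.seed, **config.sim_params)
        config.host_fasta = str(sim.host_fasta)
        config.graft_fasta = str(sim.graft_fasta)
        config.host_tx2gene = str(sim.host_tx2gene)
        config.graft_tx2gene = str(sim.graft_tx2gene)
        config.ortholog_tsv = str(sim.ortholog_tsv)
        config.samples = {
            s: (str(sim.fastq_r1[s]), str(sim.fastq_r2[s])) for s in sim.samples
        }
        report["stages"]["simulate"] = {
            "n_samples": len(sim.samples),
            "manifest": str(sim.manifest),
        }
    else:
        sim = None

    mark("index", f"building k-mer index (k={config.k})")
    index: KmerIndex = build_kmer_index(config.host_fasta, config.graft_fasta, config.k)
    report["stages"]["index"] = {
        "k": index.k,
        "host_only": len(index.host_only),
        "graft_only": len(index.graft_only),
        "shared": len(index.shared),
    }

    host_t2g = pd.read_csv(config.host_tx2gene, sep="\t")
    graft_t2g = pd.read_csv(config.graft_tx2gene, sep="\t")
    host_quant = KmerQuantifier(k=config.k).fit(config.host_fasta, tx2gene=host_t2g)
    graft_quant = KmerQuantifier(k=config.k).fit(config.graft_fasta, tx2gene=graft_t2g)

    summaries = []
    host_tpm_cols: dict[str, pd.Series] = {}
    graft_tpm_cols: dict[str, pd.Series] = {}
    host_count_cols: dict[str, pd.Series] = {}
    graft_count_cols: dict[str, pd.Series] = {}
    class_block: dict[str, dict] = {}
    for name, (r1, r2) in config.samples.items():
        mark("classify", f"classifying {name}")
        sample_dir = out / "classified" / name
        summary = classify_dataset(r1, r2, index, sample_dir, sample_id=name)
        summaries.append(summary)
        class_block[name] = {
            "counts": summary.counts,
            "percent": {c: round(v, 4) for c, v in summary.percentages.items()},
        }
        mark("quantify", f"quantifying {name}")
        hc, ht, _ = quantify_fastq_pair(
            sample_dir / "host_1.fastq", sample_dir / "host_2.fastq", host_quant
        )
        gc, gt, _ = quantify_fastq_pair(
            sample_dir / "graft_1.fastq", sample_dir / "graft_2.fastq", graft_quant
        )
        host_count_cols[f"{name}_host"], host_tpm_cols[f"{name}_host"] = hc, ht
        graft_count_cols[f"{name}_graft"], graft_tpm_cols[f"{name}_graft"] = gc, gt

    averaged = summarize_classification(summaries)
    report["stages"]["classify"] = {
        "per_sample": class_block,
        "average_percent": {c: float(averaged[c]) for c in CLASSES},
    }

    host_tpm = expression_matrix(host_tpm_cols)
    graft_tpm = expression_matrix(graft_tpm_cols)
    expression_matrix(host_count_cols).to_csv(out / "host_counts.tsv", sep="\t")
    expression_matrix(graft_count_cols).to_csv(out / "graft_counts.tsv", sep="\t")
    host_tpm.to_csv(out / "host_tpm.tsv", sep="\t")
    graft_tpm.to_csv(out / "graft_tpm.tsv", sep="\t")

    mark("harmonize", "harmonizing orthologues")
    omap, dropped = load_ortholog_map(config.ortholog_tsv)
    ortho_matrix = build_ortho_matrix(host_tpm, graft_tpm, omap, config.pseudocount)
    ortho_matrix.to_csv(out / "ortho_matrix.tsv", sep="\t")
    report["stages"]["harmonize"] = {
        "input_pairs": len(omap) + len(dropped),
        "one_to_one_pairs": len(omap),
        "dropped_pairs": len(dropped),
        "expressed_pairs": int(ortho_matrix.shape[0]),
    }

    mark("pca", "running PCA")
    pca = run_pca(ortho_matrix, scale=config.scale)
    pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
    pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
    p = ortho_matrix.shape[0]
    selected: dict[str, list] = {}
    contrib_cols = {}
    for comp in (1, 2):
        if comp <= len(pca.components):
            contribs = gene_contributions(pca, comp)
            contrib_cols[f"PC{comp}"] = contribs
            selected[f"PC{comp}"] = select_contributing_genes(contribs, p)
    pd.DataFrame(contrib_cols).to_csv(out / "contributions.tsv", sep="\t")
    for comp, genes in selected.items():
        with open(out / f"selected_{comp.lower()}.txt", "w") as fh:
            for hg, gg in genes:
                fh.write(f"{hg}\t{gg}\n")
    report["stages"]["pca"] = {
        "variance_fractions": [round(float(v), 6) for v in pca.variance_fractions],
        "selected_genes": {comp: len(g) for comp, g in selected.items()},
    }

    mark("deg", "calling DEGs")
    expressed_map = omap.set_index(["host_gene_id", "graft_gene_id"]).loc[
        ortho_matrix.index
    ].reset_index()
    deg_block = {}
    fc_tables = {}
    full_fc = fold_change_table(
        host_tpm,
        graft_tpm,
        expressed_map,
        pseudocount=config.pseudocount,
        threshold=config.fc_threshold,
    )
    full_fc.to_csv(out / "fold_changes_all.tsv", sep="\t")
    deg_block["all_expressed"] = deg_counts(full_fc)
    for comp, genes in selected.items():
        table = fold_change_table(
            host_tpm,
            graft_tpm,
            expressed_map,
            pseudocount=config.pseudocount,
            threshold=config.fc_threshold,
            restrict_to=genes,
        )
        fc_tables[comp] = table
        table.to_csv(out / f"fold_changes_{comp.lower()}.tsv", sep="\t")
        deg_block[comp] = deg_counts(table)
    report["stages"]["deg"] = deg_block

    if config.gmt:
        mark("enrichment", "running enrichment")
        sets = read_gmt(config.gmt)
        universe = [hg for hg, _ in ortho_matrix.index]
        enr_block = {}
        for comp, table in fc_tables.items():
            host_indexed = table.copy()
            host_indexed.index = [hg for hg, _ in table.index]
            degs = list(host_indexed.index[host_indexed["is_deg"]])
            enr = enrich_sets(degs, universe, sets, host_indexed, fdr=config.fdr)
            enr.to_csv(out / f"enrichment_{comp.lower()}.tsv", sep="\t", index=False)
            enr_block[comp] = {
                "tested_sets": int(len(enr)),
                "significant": int(enr["significant"].sum()) if len(enr) else 0,
            }
        report["stages"]["enrichment"] = enr_block

    if sim is not None:
        scored = dict(fc_tables)
        scored["all_expressed"] = full_fc
        report["truth"] = _score_against_truth(sim, scored)

    report["elapsed_seconds"] = round(time.time() - t0, 3)
    write_report(report, out / "report.json")
    _log(f"done in {report['elapsed_seconds']}s -> {out / 'report.json'}", quiet)
    return report


def _score_against_truth(sim, fc_tables: dict[str, pd.DataFrame]) -> dict:
    """DEG sensitivity and direction agreement against the planted truth.

    Scored on the unrestricted fold-change table (all expressed orthologue
    pairs) so the score reflects the fold-change statistic itself.
    """
    truth_pairs = sim.truth.pairs.set_index(["host_gene_id", "graft_gene_id"])
    block: dict = {}
    planted = truth_pairs[truth_pairs["de_flag"]]
    for comp, table in fc_tables.items():
        hits = table.index.intersection(planted.index)
        recovered = table.loc[hits]
        recovered = recovered[recovered["is_deg"]]
        sens = len(recovered) / len(planted) if len(planted) else float("nan")
        agree = float("nan")
        if len(recovered):
            truth_sign = planted.loc[recovered.index, "true_log2fc"].to_numpy() > 0
            obs_sign = recovered["log2fc"].to_numpy() > 0
            agree = float((truth_sign == obs_sign).mean())
        block[comp] = {
            "planted_de": int(len(planted)),
            "recovered": int(len(recovered)),
            "sensitivity": round(sens, 4),
            "direction_agreement": None if np.isnan(agree) else round(agree, 4),
        }
    return block


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize the run report as stable-key-order JSON plus a TSV digest."""
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    digest = path.with_suffix(".tsv")
    rows = []

    def flatten(prefix: str, obj) -> None:
        if isinstance(obj, dict):
            for key, val in obj.items():
                flatten(f"{prefix}.{key}" if prefix else str(key), val)
        elif isinstance(obj, (list, tuple)):
            rows.append((prefix, ";".join(str(v) for v in obj)))
        else:
            rows.append((prefix, obj))

    flatten("", report)
    pd.DataFrame(rows, columns=["field", "value"]).to_csv(digest, sep="\t", index=False)
    return path
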