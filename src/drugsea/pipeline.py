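"""End-to-end orchestration: map, design, fit, permute, report.

Each disorder x predictor-mode cell runs independently; a failure in one
cell is logged and the others proceed. Every output TSV carries a header
comment with the config hash and seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import design as dz
from . import enrichment as ez
from . import io as dio
from . import mapping as mz
from . import permutation as pz
from .config import RunConfig

log = logging.getLogger("drugsea")


@dataclass
class RunSummary:
    results: list[ez.EnrichmentResult]
    permutations: list[pz.PermutationResult]
    pairing_counts: dict[tuple[str, str], int]
    errors: list[str] = field(default_factory=list)
    outdir: Optional[Path] = None


def run_pipeline(config: RunConfig) -> RunSummary:
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir, stamp)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, outdir: Path, stamp: str) -> RunSummary:
    log.info("start %s", stamp)
    genes_res = dio.read_gene_bed(config.genes)
    drugs_res = dio.read_drug_tables(config.targets, config.indications)
    genes, drugs = genes_res.records, drugs_res.drugs
    log.info("genes=%d (rejected %d); drugs=%d (excluded target-less %d)",
             len(genes), genes_res.n_rejected, len(drugs),
             drugs_res.n_excluded_no_targets)

    modes = [dz.PredictorMode.parse(m) for m in config.modes]
    all_results: list[ez.EnrichmentResult] = []
    permutations: list[pz.PermutationResult] = []
    pairing_counts: dict[tuple[str, str], int] = {}
    errors: list[str] = []

    per_mode: dict[str, list[ez.EnrichmentResult]] = {str(m): [] for m in modes}
    for disorder, inputs in sorted(config.disorders.items()):
        ss = dio.read_sumstats(inputs.sumstats, config.column_map)
        if ss.n_rejected:
            log.info("%s: rejected %d sumstat rows", disorder, ss.n_rejected)
        eqtls = dio.read_eqtl(inputs.eqtl).records if inputs.eqtl else None
        loops = dio.read_loops(inputs.loops).records if inputs.loops else None
        hits = mz.implicate_genes(
            ss.records, genes, gws_alpha=config.gws_alpha, flank=config.flank,
            clump_window=config.clump_window, eqtls=eqtls, loops=loops,
            promoter_flank=config.promoter_flank, sources=config.sources)
        mz.write_mapping_report(hits, outdir / f"mapping_{disorder}.tsv", stamp)
        log.info("%s: %d implicated genes", disorder, len(hits))

        for mode in modes:
            cell = f"{disorder}/{mode}"
            try:
                rows = dz.build_design(drugs, hits, disorder, mode)
                dz.write_design(rows, outdir / f"design_{disorder}_{mode.name}.tsv", stamp)
                edges = dz.summarize_pairings(rows)
                pairing_counts[(disorder, str(mode))] = len(edges)
                dz.write_sankey(edges, outdir / f"sankey_{disorder}_{mode.name}.tsv",
                                outdir / f"sankey_{disorder}_{mode.name}.json", stamp)
                if config.cluster_on_class:
                    res = ez.fit_enrichment_clustered(rows, disorder, str(mode))
                else:
                    res = ez.fit_enrichment(rows, disorder, str(mode))
                per_mode[str(mode)].append(res)
                if res.separation_flag:
                    log.info("%s: separation detected, Firth fit reported", cell)
                if config.n_perm > 0:
                    perm = pz.permutation_test(
                        drugs, genes, hits, disorder, mode,
                        n_perm=config.n_perm, seed=config.seed)
                    permutations.append(perm)
            except (dio.ValidationError, ez.DegenerateDataError, ValueError) as exc:
                msg = f"{cell}: {exc}"
                errors.append(msg)
                log.warning("cell skipped — %s", msg)

    for mode_name, results in per_mode.items():
        if results:
            adjusted = ez.bonferroni_adjust(results, config.alpha)
            ez.write_results(adjusted, outdir / f"results_{mode_name.replace(':', '-')}.tsv", stamp)
            all_results.extend(adjusted)
    if permutations:
        pz.write_permutation(permutations, outdir / "permutation.tsv", stamp)
    _write_summary(all_results, outdir / "summary.tsv", stamp)
    log.info("done: %d results, %d errors", len(all_results), len(errors))
    return RunSummary(results=all_results, permutations=permutations,
                      pairing_counts=pairing_counts, errors=errors, outdir=outdir)


def _write_summary(results: Sequence[ez.EnrichmentResult], path, stamp: str) -> None:
    ez.write_results(results, path, stamp)


def compare_modes(results: Sequence[ez.EnrichmentResult],
                  reference_mode: str = "binary") -> pd.DataFrame:
    """Per disorder: beta2 and CI per coding, flagged when a coding's CI
    excludes the reference (binary) coding's point estimate — the
    non-overlapping-interval criterion for a genuinely different signal."""
    rows = []
    by_disorder: dict[str, list[ez.EnrichmentResult]] = {}
    for r in results:
        by_disorder.setdefault(r.disorder_id, []).append(r)
    for disorder, group in sorted(by_disorder.items()):
        ref = next((r for r in group if r.mode == reference_mode), None)
        for r in group:
            flagged = False
            if ref is not None and r.mode != reference_mode:
                flagged = not (r.ci95[0] <= ref.or2 <= r.ci95[1])
            rows.append({
                "disorder_id": disorder, "mode": r.mode, "beta2": r.beta2,
                "or2": r.or2, "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "wald_p": r.wald_p, "fit_method": r.fit_method,
                "ci_excludes_reference": flagged,
            })
    return pd.DataFrame(rows)
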