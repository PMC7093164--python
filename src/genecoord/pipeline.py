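"""End-to-end orchestration of the coordination analysis.

Runs, in order: read inputs, high-expression filter against the reference
group, per-group pairwise correlation and coherence summaries, transcriptome
profiles, composite correlation per seed, ranking, correlated-set extraction
for the selected bottom/top seeds, over-representation, function comparison
(FRI/FAI), cross-seed common terms, and output writing. Each stage logs its
input/output cardinalities; a failure aborts with the stage name and removes
partial outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

import genecoord
from genecoord import coordination, enrichment as enrich, io, simulate as sim

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _unique(seq: Sequence[str]) -> list[str]:
    out: list[str] = []
    for x in seq:
        if x not in out:
            out.append(x)
    return out


def run_pipeline(
    counts_path: str | Path,
    design_path: str | Path,
    gmt_path: str | Path | None,
    config: io.AnalysisConfig,
    out_dir: str | Path,
    *,
    reference_label: str = "NOR",
    counts_dialect: str = "plain_tsv",
    with_enrichment: bool = True,
    save_matrices: bool = False,
) -> dict:
    """Execute the full analysis and write outputs under ``out_dir``.

    Returns the JSON-serialisable run report. ``gmt_path`` may be None only
    when ``with_enrichment`` is False. ``save_matrices`` additionally stores
    the per-group pairwise correlation matrices (needed for heatmap export;
    can be large).
    """
    out_dir = Path(out_dir)
    written: list[Path] = []

    def _track_write(path: Path) -> Path:
        written.append(path)
        return path

    try:
        return _run(counts_path, design_path, gmt_path, config, out_dir,
                    reference_label, counts_dialect, with_enrichment,
                    save_matrices, _track_write)
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _stage(name: str):
    """Decorator-free stage guard: re-raise any error tagged with the stage."""
    class _Guard:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Guard()


def _run(counts_path, design_path, gmt_path, config, out_dir, reference_label,
         counts_dialect, with_enrichment, save_matrices, track) -> dict:
    with _stage("read"):
        matrix = io.read_counts(counts_path, dialect=counts_dialect)
        design = io.read_design(design_path, reference_label=reference_label)
        logger.info("read %d genes x %d samples; groups %s",
                    matrix.n_genes, matrix.n_samples, design.group_sizes)

    annotation = None
    if with_enrichment:
        with _stage("enrichment"):
            if gmt_path is None:
                raise ValueError(
                    "enrichment is enabled but no GMT annotation path was given"
                )
            annotation = io.read_gmt(gmt_path)
            logger.info("annotation: %d terms, %d genes in universe",
                        len(annotation), len(annotation.universe))

    with _stage("filter_high_expression"):
        seeds = coordination.filter_high_expression(matrix, design, config)
        if not seeds:
            raise ValueError(
                f"no gene reaches {config.min_reads} "
                f"({config.read_aggregation}) in group {reference_label!r}"
            )

    group_keys = {"ref": design.reference_label, "cond": design.condition_label}
    corr_matrices: dict[str, coordination.CorrelationMatrix] = {}
    coherence: dict[str, dict[str, float]] = {}
    with _stage("pairwise_correlation"):
        for key, label in group_keys.items():
            cm = coordination.pairwise_correlation(matrix, seeds, design, label,
                                                   config)
            summary = coordination.coherence_summary(cm)
            corr_matrices[key] = cm
            coherence[label] = {
                "mean_r": summary.mean_r,
                "mean_abs_r": summary.mean_abs_r,
                "fraction_above_0.5": summary.fraction_above(0.5),
            }
            logger.info("group %s: mean R = %.4f over %d genes", label,
                        summary.mean_r, len(seeds))

    with _stage("transcriptome_profiles"):
        profiles = coordination.transcriptome_profiles(matrix, seeds, design,
                                                        config)

    with _stage("composite_correlation"):
        records = [
            coordination.composite_correlation(pair.ref, pair.cond, config)
            for pair in profiles.values()
        ]
        n_defined = sum(r.defined for r in records)
        logger.info("Pc defined for %d of %d seeds", n_defined, len(records))

    with _stage("rank_by_pc"):
        ranking = coordination.rank_by_pc(records, config)
        selected = _unique(
            [r.seed_gene for r in ranking.bottom] +
            [r.seed_gene for r in ranking.top]
        )
        logger.info("selected seeds: bottom %s, top %s",
                    [r.seed_gene for r in ranking.bottom],
                    [r.seed_gene for r in ranking.top])

    with _stage("extract_correlated_set"):
        correlated_sets: dict[str, list[coordination.GeneSet]] = {}
        for seed in selected:
            pair = profiles[seed]
            correlated_sets[seed] = [
                coordination.extract_correlated_set(pair.ref, config),
                coordination.extract_correlated_set(pair.cond, config),
            ]

    comparisons: list[enrich.FunctionComparison] = []
    common_terms: dict[str, list[tuple[str, str]]] = {}
    if with_enrichment:
        with _stage("overrepresentation"):
            terms_by_seed: dict[str, dict[str, frozenset[str]]] = {}
            for seed in selected:
                pair = profiles[seed]
                background = pair.ref.background_gene_ids
                terms_by_seed[seed] = {}
                for gs, key in zip(correlated_sets[seed], ("ref", "cond")):
                    results = enrich.overrepresentation(gs, background,
                                                        annotation, config)
                    terms_by_seed[seed][key] = enrich.significant_terms(results)
        with _stage("compare_functions"):
            for seed in selected:
                comparisons.append(enrich.compare_functions(
                    seed,
                    terms_by_seed[seed]["ref"],
                    terms_by_seed[seed]["cond"],
                ))
        with _stage("common_terms_across_seeds"):
            bottom_seeds = {r.seed_gene for r in ranking.bottom}
            bottom_cmp = [c for c in comparisons if c.seed_gene in bottom_seeds]
            if bottom_cmp:
                for grp in ("ref", "cond"):
                    common_terms[grp] = enrich.common_terms_across_seeds(
                        bottom_cmp, grp, annotation)

    with _stage("write_outputs"):
        report = io.write_outputs(
            ranking,
            comparisons,
            out_dir,
            config=config,
            correlated_sets=correlated_sets,
            common_terms=common_terms,
            report_extra={
                "version": genecoord.__version__,
                "rng_seed": config.rng_seed,
                "reference_label": design.reference_label,
                "condition_label": design.condition_label,
                "group_sizes": design.group_sizes,
                "n_genes": matrix.n_genes,
                "n_high_expression": len(seeds),
                "coherence": coherence,
                "selected_seeds": selected,
                "profile_files": {s: f"profile_{s}.tsv" for s in selected},
                "correlation_matrix_files": (
                    {key: f"correlation_{key}.tsv" for key in group_keys}
                    if save_matrices else {}
                ),
            },
        )
        for p in ("pc_ranking.tsv", "report.json"):
            track(out_dir / p)
        for seed in correlated_sets:
            track(out_dir / f"correlated_set_{seed}.tsv")
        for seed in selected:
            pair = profiles[seed]
            path = track(out_dir / f"profile_{seed}.tsv")
            with open(path, "w") as fh:
                fh.write("gene_id\tr_ref\tr_cond\n")
                for g, rr, rc in zip(pair.ref.background_gene_ids,
                                     pair.ref.r_values, pair.cond.r_values):
                    rr_s = "NA" if not np.isfinite(rr) else _FLOAT_FMT % rr
                    rc_s = "NA" if not np.isfinite(rc) else _FLOAT_FMT % rc
                    fh.write(f"{g}\t{rr_s}\t{rc_s}\n")
        if save_matrices:
            for key, cm in corr_matrices.items():
                path = track(out_dir / f"correlation_{key}.tsv")
                _write_matrix_tsv(cm, path)
    return report


def _write_matrix_tsv(cm: coordination.CorrelationMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(cm.gene_ids) + "\n")
        for g, row in zip(cm.gene_ids, cm.values):
            cells = ["NA" if not np.isfinite(v) else _FLOAT_FMT % v for v in row]
            fh.write(g + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# simulate subcommand backend
# ---------------------------------------------------------------------------


def simulate_to_dir(
    sim_config: sim.SimulationConfig,
    out_dir: str | Path,
    *,
    ref_label: str = "NOR",
    cond_label: str = "FRA",
    n_background_terms: int = 20,
) -> dict[str, Path]:
    """Write a simulated dataset as counts/design/truth/GMT files.

    The file set round-trips through :func:`run_pipeline`. Byte-identical for
    a fixed config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matrix_ref, matrix_cond, truth = sim.simulate_dataset(sim_config)
    combined, design = sim.combine_groups(matrix_ref, matrix_cond,
                                          ref_label=ref_label,
                                          cond_label=cond_label)
    annotation = sim.simulate_annotation(truth, n_background_terms,
                                         rng_seed=sim_config.rng_seed)
    paths = {
        "counts": out_dir / "counts.tsv",
        "design": out_dir / "design.tsv",
        "truth": out_dir / "truth.json",
        "gmt": out_dir / "annotation.gmt",
    }
    io.write_counts(combined, paths["counts"])
    io.write_design(design, paths["design"])
    io.write_gmt(annotation, paths["gmt"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "module_of": truth.module_of,
                "cond_module_of": truth.cond_module_of,
                "seed_genes": truth.seed_genes,
                "rewired": sorted(truth.rewired),
            },
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# figure export
# ---------------------------------------------------------------------------


def export_figures(report_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Render heatmaps, violin panels and the FRI/FAI bar chart from a run.

    Reads the run report and the intermediate TSVs it references (the run must
    have been executed with ``save_matrices=True`` for heatmaps). Every figure
    has a TSV twin so no number exists only in an image.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    report_path = Path(report_path)
    run_dir = report_path.parent
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = json.loads(report_path.read_text())
    produced: list[Path] = []

    cm_files = report.get("correlation_matrix_files") or {}
    if not cm_files:
        raise FileNotFoundError(
            "run report references no correlation matrices; re-run with "
            "save_matrices enabled to export heatmaps"
        )
    labels = {"ref": report.get("reference_label", "ref"),
              "cond": report.get("condition_label", "cond")}
    for key, fname in sorted(cm_files.items()):
        src = run_dir / fname
        if not src.exists():
            raise FileNotFoundError(f"missing intermediate table: {src}")
        df = pd.read_csv(src, sep="\t", index_col=0, na_values="NA")
        fig, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(df.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r",
                       interpolation="nearest")
        ax.set_title(f"Pairwise R, group {labels[key]}")
        fig.colorbar(im, ax=ax, label="Pearson R")
        path = out_dir / f"heatmap_{key}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        produced.append(path)

    selected = report.get("selected_seeds", [])
    if not selected:
        logger.warning("no selected seeds in report; skipping violin panels")
    for seed in selected:
        src = run_dir / f"profile_{seed}.tsv"
        if not src.exists():
            raise FileNotFoundError(f"missing intermediate table: {src}")
        df = pd.read_csv(src, sep="\t", na_values="NA")
        fig, ax = plt.subplots(figsize=(4, 4))
        data = [df["r_ref"].dropna().to_numpy(), df["r_cond"].dropna().to_numpy()]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks([1, 2],
                      [labels["ref"], labels["cond"]])
        ax.set_ylabel("R with transcriptome")
        ax.set_title(seed)
        path = out_dir / f"violin_{seed}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        produced.append(path)

    comparisons = report.get("function_comparison", [])
    if comparisons:
        twin = out_dir / "fri_fai.tsv"
        with open(twin, "w") as fh:
            fh.write("seed_gene\tfri\tfai\n")
            for c in comparisons:
                fri = "NA" if c["fri"] is None else _FLOAT_FMT % c["fri"]
                fai = "NA" if c["fai"] is None else _FLOAT_FMT % c["fai"]
                fh.write(f"{c['seed_gene']}\t{fri}\t{fai}\n")
        produced.append(twin)
        plotted = [c for c in comparisons if c["fri"] is not None]
        if plotted:
            fig, ax = plt.subplots(figsize=(1.2 * len(plotted) + 2, 4))
            xs = np.arange(len(plotted))
            ax.bar(xs - 0.2, [c["fri"] for c in plotted], width=0.4,
                   label="FRI")
            ax.bar(xs + 0.2, [c["fai"] for c in plotted], width=0.4,
                   label="FAI")
            ax.set_xticks(xs, [c["seed_gene"] for c in plotted], rotation=45,
                          ha="right")
            ax.set_ylim(0, 1)
            ax.legend()
            fig.tight_layout()
            path = out_dir / "fri_fai.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            produced.append(path)
    return produced
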