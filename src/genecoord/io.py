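"""Readers and writers for on-disk artifacts.

Handles count matrices (plain TSV or GEO series-matrix style), sample-design
tables, GMT annotation files, and the ranked/report outputs of a pipeline run.
All outputs are byte-stable for a fixed input and configuration.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd

from genecoord.enrichment import AnnotationCollection

if TYPE_CHECKING:  # pragma: no cover
    from genecoord.coordination import GeneSet, PcRanking
    from genecoord.enrichment import FunctionComparison

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Non-negative genes x samples expression values with unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # float64, shape (n_genes, n_samples)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} identifiers: {dupes}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def sample_index(self) -> dict[str, int]:
        return {s: j for j, s in enumerate(self.sample_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleDesign:
    """Assignment of each sample to one of exactly two groups."""

    assignments: dict[str, str]  # sample_id -> group label
    reference_label: str
    condition_label: str

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if labels != {self.reference_label, self.condition_label}:
            raise ValidationError(
                f"design labels {sorted(labels)} do not match the declared pair "
                f"({self.reference_label!r}, {self.condition_label!r})"
            )
        if self.reference_label == self.condition_label:
            raise ValidationError("reference and condition labels must differ")
        for label in (self.reference_label, self.condition_label):
            n = sum(1 for v in self.assignments.values() if v == label)
            if n < 3:
                raise ValidationError(
                    f"group {label!r} has {n} samples; at least 3 are required "
                    "for Pearson correlation"
                )

    def samples(self, label: str) -> list[str]:
        """Sample identifiers of one group, in assignment order."""
        if label not in (self.reference_label, self.condition_label):
            raise KeyError(f"unknown group label {label!r}")
        return [s for s, g in self.assignments.items() if g == label]

    @property
    def group_sizes(self) -> dict[str, int]:
        return {
            self.reference_label: len(self.samples(self.reference_label)),
            self.condition_label: len(self.samples(self.condition_label)),
        }


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the coordination analysis.

    Defaults mirror the published study: reads >= 70 in the reference group,
    correlated sets at R > 0.5, and three bottom/top-ranked seed genes.
    """

    min_reads: float = 70.0
    read_aggregation: str = "mean"  # over reference-group samples
    r_cutoff: float = 0.5
    pc_method: str = "pearson"
    transform: str = "none"
    bottom_k: int = 3
    top_k: int = 3
    fdr_alpha: float = 0.05
    min_term_size: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 0:
            raise ValidationError("min_reads must be non-negative")
        if self.read_aggregation not in ("mean", "min", "sum"):
            raise ValidationError(
                f"read_aggregation must be one of mean/min/sum, "
                f"got {self.read_aggregation!r}"
            )
        if not 0 < self.r_cutoff < 1:
            raise ValidationError("r_cutoff must lie in (0, 1)")
        if self.pc_method not in ("pearson", "spearman"):
            raise ValidationError(
                f"pc_method must be pearson or spearman, got {self.pc_method!r}"
            )
        if self.transform not in ("none", "log1p", "cpm_log1p"):
            raise ValidationError(
                f"transform must be one of none/log1p/cpm_log1p, "
                f"got {self.transform!r}"
            )
        if self.bottom_k < 1 or self.top_k < 1:
            raise ValidationError("bottom_k and top_k must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.min_term_size < 1:
            raise ValidationError("min_term_size must be positive")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_counts(path: str | Path, dialect: str = "plain_tsv") -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    ``dialect="series_matrix"`` additionally skips GEO-style metadata lines
    beginning with ``!`` and strips surrounding double quotes from fields.
    Duplicate gene rows are collapsed by summation (read counts are additive)
    with a logged warning; missing cells are imputed as 0 and logged.
    """
    path = Path(path)
    if dialect not in ("plain_tsv", "series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if dialect == "series_matrix":
        lines = [
            ln.replace('"', "")
            for ln in text.splitlines()
            if ln and not ln.startswith("!")
        ]
        text = "\n".join(lines) + "\n"
    header_line = text.splitlines()[0] if text.splitlines() else ""
    header_fields = header_line.rstrip("\n").split("\t")
    if len(header_fields) < 2:
        raise ParseError(
            f"{path}: malformed header line {header_line!r}: expected a gene "
            "identifier column followed by sample columns"
        )
    sample_fields = header_fields[1:]
    if len(set(sample_fields)) != len(sample_fields):
        dupes = sorted({s for s in sample_fields if sample_fields.count(s) > 1})
        raise ParseError(
            f"{path}: malformed header line: duplicate sample columns {dupes}"
        )
    try:
        df = pd.read_csv(_io.StringIO(text), sep="\t", header=0, index_col=0,
                         dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    try:
        values = df.astype(np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value: {exc}") from exc

    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%s: imputed %d missing cells as 0", path, n_missing)
        values = values.fillna(0.0)

    if values.index.duplicated().any():
        dupes = sorted(values.index[values.index.duplicated()].unique())
        logger.warning("%s: summed duplicate gene rows: %s", path, dupes)
        values = values.groupby(level=0, sort=False).sum()

    neg = values.to_numpy() < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValidationError(
            f"{path}: negative value {values.iat[i, j]} at gene "
            f"{values.index[i]!r}, sample {values.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=list(values.index.astype(str)),
        sample_ids=list(values.columns.astype(str)),
        values=values.to_numpy(),
    )


def read_design(path: str | Path, reference_label: str) -> SampleDesign:
    """Read a two-column ``sample_id<TAB>group`` table.

    A header line is tolerated (and skipped) when its second field is not one
    of the two group labels found in the body. Exactly two distinct labels are
    required; ``reference_label`` must be one of them.
    """
    path = Path(path)
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 tab-separated fields, "
                f"got {len(fields)}"
            )
        rows.append((fields[0].strip(), fields[1].strip()))
    if not rows:
        raise ParseError(f"{path}: empty design file")
    # drop a header row like "sample_id\tgroup"
    body_labels = {g for _, g in rows[1:]}
    if len(rows) > 1 and rows[0][1] not in body_labels:
        rows = rows[1:]

    seen: dict[str, str] = {}
    for sample, group in rows:
        if sample in seen:
            raise ValidationError(f"{path}: duplicate sample identifier {sample!r}")
        seen[sample] = group
    labels = sorted(set(seen.values()))
    if len(labels) != 2:
        raise ValidationError(
            f"{path}: expected exactly 2 group labels, found {len(labels)}: {labels}"
        )
    if reference_label not in labels:
        raise ValidationError(
            f"{path}: reference label {reference_label!r} not among group "
            f"labels {labels}"
        )
    condition_label = next(l for l in labels if l != reference_label)
    return SampleDesign(
        assignments=seen,
        reference_label=reference_label,
        condition_label=condition_label,
    )


def read_gmt(path: str | Path) -> AnnotationCollection:
    """Read a GMT file: ``term_id<TAB>description<TAB>gene...`` per line."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        n_lines += 1
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs term_id, description and "
                f"at least one gene (got {len(fields)} fields)"
            )
        term_id, description = fields[0], fields[1]
        genes = {g for g in fields[2:] if g}
        if term_id in terms:
            raise ParseError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        terms[term_id] = genes
        descriptions[term_id] = description
    if n_lines == 0:
        logger.warning("%s: empty GMT file, returning empty collection", path)
    return AnnotationCollection(terms=terms, descriptions=descriptions)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_counts(matrix: ExpressionMatrix, path: str | Path,
                 id_column: str = "gene_id") -> None:
    """Write a genes x samples TSV that round-trips through :func:`read_counts`."""
    df = matrix.to_frame()
    df.index.name = id_column
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in design.assignments.items():
            fh.write(f"{sample}\t{group}\n")


def write_gmt(annotation: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(annotation.terms):
            genes = "\t".join(sorted(annotation.terms[term_id]))
            fh.write(f"{term_id}\t{annotation.descriptions.get(term_id, '')}\t{genes}\n")


def _fmt(x: float | None) -> str:
    return "NA" if x is None else _FLOAT_FMT % x


def write_outputs(
    ranking: "PcRanking",
    comparisons: Sequence["FunctionComparison"],
    out_dir: str | Path,
    *,
    config: AnalysisConfig | None = None,
    correlated_sets: Mapping[str, Sequence["GeneSet"]] | None = None,
    common_terms: Mapping[str, Sequence[tuple[str, str]]] | None = None,
    report_extra: Mapping[str, object] | None = None,
) -> dict:
    """Write the ranked-Pc table, per-seed correlated-set TSVs and JSON report.

    Returns the report dict. Files are byte-stable for fixed inputs: floats use
    a fixed format and JSON keys are sorted. Seed genes are ordered by
    ascending Pc with lexicographic tie-breaks, undefined last.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        ranking_path = out_dir / "pc_ranking.tsv"
        with open(ranking_path, "w") as fh:
            fh.write("gene_id\tpc\tn_profile_genes\n")
            for rec in ranking.records:
                fh.write(f"{rec.seed_gene}\t{_fmt(rec.pc)}\t{rec.n_common_background}\n")
        written.append(ranking_path)

        set_files: dict[str, str] = {}
        for seed in sorted(correlated_sets or {}):
            sets = correlated_sets[seed]
            p = out_dir / f"correlated_set_{seed}.tsv"
            with open(p, "w") as fh:
                fh.write("group\tgene_id\tr\n")
                for gs in sets:
                    order = sorted(
                        zip(gs.gene_ids, gs.r_values),
                        key=lambda t: (-t[1], t[0]),
                    )
                    for gene, r in order:
                        fh.write(f"{gs.group}\t{gene}\t{_fmt(r)}\n")
            written.append(p)
            set_files[seed] = p.name

        report = {
            "config": asdict(config) if config is not None else None,
            "pc_ranking_file": ranking_path.name,
            "n_seed_genes": len(ranking.records),
            "bottom_k_seeds": [r.seed_gene for r in ranking.bottom],
            "top_k_seeds": [r.seed_gene for r in ranking.top],
            "correlated_set_files": set_files,
            "function_comparison": [
                {
                    "seed_gene": c.seed_gene,
                    "n_terms_ref": len(c.terms_ref),
                    "n_terms_cond": len(c.terms_cond),
                    "common": sorted(c.common),
                    "acquired": sorted(c.acquired),
                    "lost": sorted(c.lost),
                    "fri": c.fri,
                    "fai": c.fai,
                }
                for c in comparisons
            ],
            "common_terms": {
                grp: [{"term_id": t, "description": d} for t, d in terms]
                for grp, terms in (common_terms or {}).items()
            },
        }
        if report_extra:
            report.update(report_extra)
        report_path = out_dir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(report_path)
    except OSError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    return report
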