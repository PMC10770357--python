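"""Cohort analytics behind each conversational response.

Answers the questions the dialogue layer can reach: per-gene alteration
frequencies ("what fraction of breast-cancer samples carry a TP53
mutation?"), rankings of the most frequently mutated genes, expression
summaries, co-occurrence of two alteration types, and the split-by
analysis stratifying a gene's expression by another gene's mutation
status (two-sided Wilcoxon rank-sum by default, Welch t as an option).

Frequencies use as denominator the samples assayed for the relevant data
type — assays rarely cover identical sample subsets — and mutation
status always means post-consensus-filter records, since that is what
the knowledge base stores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import CNA_CATEGORIES, SampleManifest, load_sample_manifest


class ExplorerError(ValueError):
    pass


@dataclass
class CohortDataset:
    """One cancer type's harmonized tables, as written by the ingest layer."""

    cancer_type: str
    manifest: SampleManifest
    mutations: pd.DataFrame  # post-filter records
    cna: pd.DataFrame
    expression: pd.DataFrame  # gene x sample

    def __post_init__(self) -> None:
        bad = set(self.mutations["sample_id"]) - self.manifest.mutations
        if bad:
            raise ExplorerError(f"mutation records outside manifest: {sorted(bad)[:3]}")
        bad = set(self.cna["sample_id"]) - self.manifest.cna
        if bad:
            raise ExplorerError(f"CNA records outside manifest: {sorted(bad)[:3]}")
        bad = set(self.expression.columns) - self.manifest.expression
        if bad:
            raise ExplorerError(f"expression columns outside manifest: {sorted(bad)[:3]}")

    @classmethod
    def load(cls, kb_dir: str | Path, cancer_type: str) -> "CohortDataset":
        slug = cancer_type.lower().replace(" ", "_")
        cohort_dir = Path(kb_dir) / slug
        if not cohort_dir.is_dir():
            raise ExplorerError(
                f"no cohort {cancer_type!r} under {kb_dir} (expected {cohort_dir})"
            )
        name_file = cohort_dir / "cohort.txt"
        name = name_file.read_text().strip() if name_file.exists() else cancer_type
        return cls(
            cancer_type=name,
            manifest=load_sample_manifest(cohort_dir / "manifest.tsv"),
            mutations=pd.read_csv(
                cohort_dir / "mutations.tsv", sep="\t", dtype=str, keep_default_na=False
            ),
            cna=pd.read_csv(cohort_dir / "cna.tsv", sep="\t", dtype=str, keep_default_na=False),
            expression=pd.read_csv(cohort_dir / "expression.tsv", sep="\t", index_col="gene"),
        )

    def mutated_samples(self, gene: str) -> set[str]:
        """Samples with >=1 post-filter mutation in `gene` (multiple hits
        in one sample count once)."""
        hits = self.mutations.loc[self.mutations["gene"] == gene, "sample_id"]
        return set(hits)


@dataclass(frozen=True)
class GeneStats:
    gene: str
    cancer_type: str
    altered_sample_count: int
    cohort_size: int

    @property
    def frequency(self) -> float:
        return self.altered_sample_count / self.cohort_size

    def __post_init__(self) -> None:
        if not 0 <= self.altered_sample_count <= self.cohort_size:
            raise ExplorerError("altered count outside [0, cohort size]")


def mutation_frequency(dataset: CohortDataset, gene: str) -> GeneStats:
    """Fraction of mutation-assayed samples with >=1 qualifying mutation."""
    cohort = dataset.manifest.mutations
    if not cohort:
        raise ExplorerError("cohort has no mutation-assayed samples")
    altered = dataset.mutated_samples(gene) & cohort
    return GeneStats(gene, dataset.cancer_type, len(altered), len(cohort))


def top_mutated_genes(dataset: CohortDataset, k: int) -> list[GeneStats]:
    """Genes ranked by mutation frequency, ties broken alphabetically."""
    if k < 1:
        raise ExplorerError("k must be >= 1")
    genes = sorted(set(dataset.mutations["gene"]))
    ranked = sorted(
        (mutation_frequency(dataset, g) for g in genes),
        key=lambda s: (-s.frequency, s.gene),
    )
    return ranked[:k]


def cna_frequency(dataset: CohortDataset, gene: str) -> tuple[GeneStats, GeneStats]:
    """(amplification, deletion) frequencies over CNA-assayed samples."""
    cohort = dataset.manifest.cna
    if not cohort:
        raise ExplorerError("cohort has no CNA-assayed samples")
    bad = set(dataset.cna["category"]) - CNA_CATEGORIES
    if bad:
        raise ExplorerError(f"unknown CNA categories: {sorted(bad)}")
    sub = dataset.cna[dataset.cna["gene"] == gene]
    amp = set(sub.loc[sub["category"] == "amplification", "sample_id"]) & cohort
    dele = set(sub.loc[sub["category"] == "deletion", "sample_id"]) & cohort
    n = len(cohort)
    return (
        GeneStats(gene, dataset.cancer_type, len(amp), n),
        GeneStats(gene, dataset.cancer_type, len(dele), n),
    )


def cna_altered_samples(dataset: CohortDataset, gene: str) -> set[str]:
    sub = dataset.cna[(dataset.cna["gene"] == gene) & (dataset.cna["category"] != "neutral")]
    return set(sub["sample_id"])


@dataclass(frozen=True)
class ExpressionSummary:
    gene: str
    cancer_type: str
    n: int
    mean: float
    median: float
    sd: float
    min: float
    max: float


def expression_summary(dataset: CohortDataset, gene: str) -> ExpressionSummary:
    """Summary statistics of one gene's expression over non-missing samples."""
    if gene not in dataset.expression.index:
        raise ExplorerError(f"gene {gene!r} not in expression matrix")
    values = dataset.expression.loc[gene].astype(float).dropna()
    if values.empty:
        raise ExplorerError(f"gene {gene!r} has no non-missing expression values")
    return ExpressionSummary(
        gene=gene,
        cancer_type=dataset.cancer_type,
        n=int(values.size),
        mean=float(values.mean()),
        median=float(values.median()),
        sd=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        min=float(values.min()),
        max=float(values.max()),
    )


@dataclass
class CompareResult:
    attribute_type: str
    value_a: str
    value_b: str
    #: DATA_TYPE comparison: {"a_only", "b_only", "both", "neither"} counts
    #: over samples assayed for both; GENE / CANCER_TYPE comparison: paired
    #: frequency table.
    contingency: dict[str, int] | None = None
    frequencies: pd.DataFrame | None = None


def compare_data_types(dataset: CohortDataset, gene: str, value_a: str, value_b: str) -> CompareResult:
    """Co-occurrence of two alteration types for one gene, as a 2x2 table
    over samples assayed for both data types."""
    def altered(data_type: str) -> tuple[set[str], set[str]]:
        if data_type == "mutations":
            return dataset.mutated_samples(gene), dataset.manifest.mutations
        if data_type == "copy number alterations":
            return cna_altered_samples(dataset, gene), dataset.manifest.cna
        raise ExplorerError(f"cannot compare data type {data_type!r} by alteration status")

    set_a, cohort_a = altered(value_a)
    set_b, cohort_b = altered(value_b)
    shared = cohort_a & cohort_b
    if not shared:
        raise ExplorerError("no samples assayed for both data types")
    a, b = set_a & shared, set_b & shared
    table = {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "both": len(a & b),
        "neither": len(shared - a - b),
    }
    return CompareResult("DATA_TYPE", value_a, value_b, contingency=table)


def compare_genes(dataset: CohortDataset, gene_a: str, gene_b: str) -> CompareResult:
    """Mutation frequencies of two genes plus their co-mutated sample count."""
    stats_a = mutation_frequency(dataset, gene_a)
    stats_b = mutation_frequency(dataset, gene_b)
    co = len(dataset.mutated_samples(gene_a) & dataset.mutated_samples(gene_b)
             & dataset.manifest.mutations)
    freq = pd.DataFrame(
        {
            "value": [gene_a, gene_b],
            "altered_sample_count": [stats_a.altered_sample_count, stats_b.altered_sample_count],
            "cohort_size": [stats_a.cohort_size, stats_b.cohort_size],
            "frequency": [stats_a.frequency, stats_b.frequency],
        }
    )
    result = CompareResult("GENE", gene_a, gene_b, frequencies=freq)
    result.contingency = {"both": co}
    return result


def compare_cancer_types(
    dataset_a: CohortDataset, dataset_b: CohortDataset, gene: str
) -> CompareResult:
    """One gene's mutation frequency in each of two cohorts."""
    stats_a = mutation_frequency(dataset_a, gene)
    stats_b = mutation_frequency(dataset_b, gene)
    freq = pd.DataFrame(
        {
            "value": [dataset_a.cancer_type, dataset_b.cancer_type],
            "altered_sample_count": [stats_a.altered_sample_count, stats_b.altered_sample_count],
            "cohort_size": [stats_a.cohort_size, stats_b.cohort_size],
            "frequency": [stats_a.frequency, stats_b.frequency],
        }
    )
    return CompareResult("CANCER_TYPE", dataset_a.cancer_type, dataset_b.cancer_type, frequencies=freq)


@dataclass
class GroupSummary:
    n: int
    mean: float
    median: float
    sd: float


@dataclass
class SplitByResult:
    quant_gene: str
    partition_gene: str
    group_mutant: GroupSummary
    group_wildtype: GroupSummary
    statistic: float | None
    p_value: float | None
    test: str
    warning: str | None = None


def _summarize(values: np.ndarray) -> GroupSummary:
    if values.size == 0:
        return GroupSummary(0, float("nan"), float("nan"), float("nan"))
    return GroupSummary(
        n=int(values.size),
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        sd=float(np.std(values, ddof=1)) if values.size > 1 else 0.0,
    )


def split_by(
    dataset: CohortDataset,
    quant_gene: str,
    partition_gene: str,
    test: Literal["ranksum", "welch"] = "ranksum",
) -> SplitByResult:
    """Stratify `quant_gene` expression by `partition_gene` mutation status.

    Eligible samples are those with both an expression value and mutation
    assay coverage.  Returns group summaries plus a two-sided test; if a
    group is empty the result is descriptive-only with a warning.
    """
    if quant_gene not in dataset.expression.index:
        raise ExplorerError(f"gene {quant_gene!r} not in expression matrix")
    expr = dataset.expression.loc[quant_gene].astype(float).dropna()
    eligible = [s for s in expr.index if s in dataset.manifest.mutations]
    mutated = dataset.mutated_samples(partition_gene)
    mut_vals = expr[[s for s in eligible if s in mutated]].to_numpy()
    wt_vals = expr[[s for s in eligible if s not in mutated]].to_numpy()
    summary_mut, summary_wt = _summarize(mut_vals), _summarize(wt_vals)
    if mut_vals.size == 0 or wt_vals.size == 0:
        return SplitByResult(
            quant_gene, partition_gene, summary_mut, summary_wt, None, None, test,
            warning="one group is empty; no test performed",
        )
    if test == "ranksum":
        res = stats.ranksums(mut_vals, wt_vals)
    elif test == "welch":
        res = stats.ttest_ind(mut_vals, wt_vals, equal_var=False)
    else:
        raise ExplorerError(f"unknown test {test!r}")
    return SplitByResult(
        quant_gene, partition_gene, summary_mut, summary_wt,
        float(res.statistic), float(res.pvalue), test,
    )


# ---------------------------------------------------------------------------
# Rendering


def render_result(result, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write `<prefix>.tsv` and `<prefix>.png` for any analytic result.

    Tables are written with fixed column order and no floating environment
    dependence, so re-rendering identical input is byte-identical.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    tsv_path = out_prefix.with_suffix(".tsv")
    png_path = out_prefix.with_suffix(".png")

    fig, ax = plt.subplots(figsize=(5, 3.2))
    if isinstance(result, GeneStats):
        df = pd.DataFrame(
            [{
                "gene": result.gene,
                "cancer_type": result.cancer_type,
                "altered_sample_count": result.altered_sample_count,
                "cohort_size": result.cohort_size,
                "frequency": f"{result.frequency:.6f}",
            }]
        )
        ax.bar(["altered", "not altered"],
               [result.altered_sample_count, result.cohort_size - result.altered_sample_count])
        ax.set_title(f"{result.gene} in {result.cancer_type}")
    elif isinstance(result, list) and result and isinstance(result[0], GeneStats):
        df = pd.DataFrame(
            [{
                "gene": s.gene,
                "altered_sample_count": s.altered_sample_count,
                "cohort_size": s.cohort_size,
                "frequency": f"{s.frequency:.6f}",
            } for s in result]
        )
        ax.barh([s.gene for s in reversed(result)], [s.frequency for s in reversed(result)])
        ax.set_xlabel("mutation frequency")
    elif isinstance(result, ExpressionSummary):
        df = pd.DataFrame([{
            "gene": result.gene, "cancer_type": result.cancer_type, "n": result.n,
            "mean": f"{result.mean:.6f}", "median": f"{result.median:.6f}",
            "sd": f"{result.sd:.6f}", "min": f"{result.min:.6f}", "max": f"{result.max:.6f}",
        }])
        ax.bar(["mean", "median"], [result.mean, result.median])
        ax.set_title(f"{result.gene} expression in {result.cancer_type}")
    elif isinstance(result, CompareResult):
        if result.contingency is not None and result.frequencies is None:
            df = pd.DataFrame([{"cell": k, "count": v} for k, v in result.contingency.items()])
            ax.bar(list(result.contingency), list(result.contingency.values()))
        else:
            df = result.frequencies.copy()
            df["frequency"] = df["frequency"].map(lambda v: f"{v:.6f}")
            ax.bar(result.frequencies["value"], result.frequencies["frequency"])
        ax.set_title(f"{result.value_a} vs {result.value_b}")
    elif isinstance(result, SplitByResult):
        df = pd.DataFrame([
            {"group": "mutant", "n": result.group_mutant.n,
             "mean": f"{result.group_mutant.mean:.6f}",
             "median": f"{result.group_mutant.median:.6f}",
             "sd": f"{result.group_mutant.sd:.6f}",
             "statistic": "" if result.statistic is None else f"{result.statistic:.6f}",
             "p_value": "" if result.p_value is None else f"{result.p_value:.6g}",
             "test": result.test},
            {"group": "wildtype", "n": result.group_wildtype.n,
             "mean": f"{result.group_wildtype.mean:.6f}",
             "median": f"{result.group_wildtype.median:.6f}",
             "sd": f"{result.group_wildtype.sd:.6f}",
             "statistic": "", "p_value": "", "test": result.test},
        ])
        ax.bar(
            [f"{result.partition_gene} mutant", f"{result.partition_gene} wildtype"],
            [result.group_mutant.mean, result.group_wildtype.mean],
        )
        ax.set_ylabel(f"{result.quant_gene} expression (mean)")
    else:
        raise ExplorerError(f"cannot render result of type {type(result).__name__}")
    df.to_csv(tsv_path, sep="\t", index=False)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return png_path, tsv_path
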