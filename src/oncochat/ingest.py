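"""Build the cohort knowledge base from raw TSVs.

Raw somatic calls arrive with per-caller evidence and a precomputed
functional-impact class.  Harmonization applies, in either order (the
filters commute):

* a **consensus filter** — in majority mode an SNV is kept when called by
  at least ``snv_min_callers`` of the configured SNV callers (default 2 of
  MuTect2, SomaticSniper, VarScan, MuSE) and an indel only when called by
  *every* configured indel caller (MuTect2 and VarScan); in union mode any
  single configured caller suffices — followed by an impact gate keeping
  MODERATE and HIGH calls;
* a **gene whitelist** restricting all assays to a consensus coding
  sequence (CCDS-style) gene set.

Copy-number input is already categorical per (sample, gene):
amplification / neutral / deletion.  Expression is a gene x sample matrix
taken as-is (assumed normalized upstream).  Optionally the sample
manifest is restricted to samples present in both the mutation and
copy-number assays, mirroring cohorts distributed only for samples with
complete DNA data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VARIANT_CLASSES = {"SNV", "INS", "DEL"}
IMPACT_LEVELS = {"HIGH", "MODERATE", "LOW", "MODIFIER"}
CNA_CATEGORIES = {"amplification", "neutral", "deletion"}

TCGA_CALLERS = frozenset({"mutect2", "somaticsniper", "varscan", "muse"})
TCGA_INDEL_CALLERS = frozenset({"mutect2", "varscan"})
BASIS_SNV_CALLERS = frozenset({"caveman", "pcawg_consensus_snv"})
BASIS_INDEL_CALLERS = frozenset({"pindel", "pcawg_consensus_indel"})


class ConsensusMode(str, Enum):
    MAJORITY = "MAJORITY"
    UNION = "UNION"


@dataclass(frozen=True)
class RawMutationRecord:
    sample_id: str
    gene: str
    variant_class: str  # SNV | INS | DEL
    impact: str  # HIGH | MODERATE | LOW | MODIFIER
    callers: frozenset[str]


@dataclass(frozen=True)
class RawCnaRecord:
    sample_id: str
    gene: str
    category: str  # amplification | neutral | deletion


@dataclass(frozen=True)
class ConsensusPolicy:
    """Caller-consensus and impact rules for one data source."""

    mode: ConsensusMode = ConsensusMode.MAJORITY
    snv_caller_set: frozenset[str] = TCGA_CALLERS
    snv_min_callers: int = 2
    indel_caller_set: frozenset[str] = TCGA_INDEL_CALLERS
    impact_keep: frozenset[str] = frozenset({"MODERATE", "HIGH"})

    def __post_init__(self) -> None:
        if self.snv_min_callers > len(self.snv_caller_set):
            raise ValueError("snv_min_callers exceeds the SNV caller set size")

    @classmethod
    def tcga_default(cls) -> "ConsensusPolicy":
        """>=2-of-4 SNV consensus, both-of-2 indel rule, MODERATE/HIGH gate."""
        return cls()

    @classmethod
    def basis_default(cls) -> "ConsensusPolicy":
        """Union-of-callers rule used for externally harmonized cohorts."""
        return cls(
            mode=ConsensusMode.UNION,
            snv_caller_set=BASIS_SNV_CALLERS,
            snv_min_callers=1,
            indel_caller_set=BASIS_INDEL_CALLERS,
        )

    @property
    def all_callers(self) -> frozenset[str]:
        return self.snv_caller_set | self.indel_caller_set


class IngestError(ValueError):
    """Malformed raw input."""


def load_mutations(path: str | Path, caller_set: Iterable[str]) -> list[RawMutationRecord]:
    """Read the minimal mutation dialect: sample_id / gene / variant_class /
    impact / callers (semicolon-separated).  Unknown tokens are load errors
    naming the offending row."""
    caller_set = set(caller_set)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "variant_class", "impact", "callers"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"mutation TSV missing columns: {sorted(missing)}")
    if df.empty:
        raise IngestError(f"mutation TSV is empty: {path}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        if row.variant_class not in VARIANT_CLASSES:
            raise IngestError(f"row {i}: unknown variant_class {row.variant_class!r}")
        if row.impact not in IMPACT_LEVELS:
            raise IngestError(f"row {i}: unknown impact {row.impact!r}")
        callers = frozenset(c for c in row.callers.split(";") if c)
        if not callers:
            raise IngestError(f"row {i}: empty caller evidence")
        unknown = callers - caller_set
        if unknown:
            raise IngestError(f"row {i}: unknown callers {sorted(unknown)}")
        records.append(
            RawMutationRecord(
                row.sample_id, _canonical_gene(row.gene), row.variant_class, row.impact, callers
            )
        )
    return records


def _canonical_gene(symbol: str) -> str:
    upper = symbol.upper()
    if upper != symbol:
        warnings.warn(f"gene symbol {symbol!r} uppercased to {upper!r}", stacklevel=3)
    return upper


def apply_consensus_filter(
    records: Iterable[RawMutationRecord], policy: ConsensusPolicy
) -> list[RawMutationRecord]:
    """Keep records passing the caller-consensus rule and the impact gate."""
    kept = []
    for rec in records:
        if rec.variant_class == "SNV":
            support = len(rec.callers & policy.snv_caller_set)
            ok = support >= (1 if policy.mode is ConsensusMode.UNION else policy.snv_min_callers)
        else:  # INS / DEL
            if policy.mode is ConsensusMode.UNION:
                ok = bool(rec.callers & policy.indel_caller_set)
            else:
                ok = policy.indel_caller_set <= rec.callers
        if ok and rec.impact in policy.impact_keep:
            kept.append(rec)
    return kept


def apply_gene_whitelist(
    records: Sequence[RawMutationRecord | RawCnaRecord], whitelist: Iterable[str]
) -> list:
    """Keep records whose gene symbol is in the (case-sensitive) whitelist."""
    wl = set(whitelist)
    if not wl:
        raise IngestError("empty gene whitelist")
    return [r for r in records if r.gene in wl]


def load_whitelist(path: str | Path) -> set[str]:
    symbols = {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}
    if not symbols:
        raise IngestError(f"whitelist file has no symbols: {path}")
    return symbols


def load_cna(path: str | Path) -> list[RawCnaRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "gene", "category"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"CNA TSV missing columns: {sorted(missing)}")
    bad = set(df["category"]) - CNA_CATEGORIES
    if bad:
        raise IngestError(f"unknown CNA categories: {sorted(bad)}")
    if df.duplicated(["sample_id", "gene"]).any():
        dupes = df[df.duplicated(["sample_id", "gene"])].iloc[0]
        raise IngestError(f"duplicate CNA row for ({dupes.sample_id}, {dupes.gene})")
    return [
        RawCnaRecord(r.sample_id, _canonical_gene(r.gene), r.category)
        for r in df.itertuples(index=False)
    ]


def load_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: first column `gene`, remaining columns sample ids;
    returns a float gene x sample DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise IngestError(f"non-numeric expression value in {path}: {exc}") from exc
    df.index = [_canonical_gene(g) for g in df.index]
    return df


@dataclass
class SampleManifest:
    """Per-assay sample availability for one cohort."""

    mutations: set[str] = field(default_factory=set)
    cna: set[str] = field(default_factory=set)
    expression: set[str] = field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        samples = sorted(self.mutations | self.cna | self.expression)
        return pd.DataFrame(
            {
                "sample_id": samples,
                "has_mutations": [int(s in self.mutations) for s in samples],
                "has_cna": [int(s in self.cna) for s in samples],
                "has_expression": [int(s in self.expression) for s in samples],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleManifest":
        return cls(
            mutations=set(df.loc[df["has_mutations"] == 1, "sample_id"]),
            cna=set(df.loc[df["has_cna"] == 1, "sample_id"]),
            expression=set(df.loc[df["has_expression"] == 1, "sample_id"]),
        )


def load_sample_manifest(path: str | Path) -> SampleManifest:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "has_mutations", "has_cna", "has_expression"}
    missing = required - set(df.columns)
    if missing:
        raise IngestError(f"sample manifest missing columns: {sorted(missing)}")
    return SampleManifest.from_frame(df)


def mutations_to_frame(records: Sequence[RawMutationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "gene": r.gene,
                "variant_class": r.variant_class,
                "impact": r.impact,
                "callers": ";".join(sorted(r.callers)),
            }
            for r in records
        ],
        columns=["sample_id", "gene", "variant_class", "impact", "callers"],
    )


def cna_to_frame(records: Sequence[RawCnaRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": r.sample_id, "gene": r.gene, "category": r.category} for r in records],
        columns=["sample_id", "gene", "category"],
    )


def build_knowledge_base(
    mutations: Sequence[RawMutationRecord],
    cna: Sequence[RawCnaRecord],
    expression: pd.DataFrame,
    policy: ConsensusPolicy,
    whitelist: Iterable[str],
    out_dir: str | Path,
    cancer_type: str,
    require_both: bool = False,
    manifest: SampleManifest | None = None,
) -> Path:
    """Filter one cohort's raw inputs and write the knowledge-base layout.

    Writes ``<out_dir>/<slug>/{mutations,cna,expression,manifest}.tsv``.
    When no explicit manifest is given, each assay's manifest is inferred
    from the samples present in its raw input.  With ``require_both`` the
    manifest (all assays) is restricted to samples having both mutation
    and copy-number data.
    """
    wl = set(whitelist)
    filtered_mut = apply_gene_whitelist(apply_consensus_filter(mutations, policy), wl)
    filtered_cna = apply_gene_whitelist(cna, wl)
    expr = expression.loc[[g for g in expression.index if g in wl]]

    if manifest is None:
        manifest = SampleManifest(
            mutations={r.sample_id for r in mutations},
            cna={r.sample_id for r in cna},
            expression=set(expression.columns),
        )
    if require_both:
        both = manifest.mutations & manifest.cna
        if not both:
            raise IngestError("no samples with both mutation and CNA data")
        manifest = SampleManifest(
            mutations=both, cna=both, expression=manifest.expression & both
        )
        filtered_mut = [r for r in filtered_mut if r.sample_id in both]
        filtered_cna = [r for r in filtered_cna if r.sample_id in both]
        expr = expr[[s for s in expr.columns if s in both]]
    if not (manifest.mutations | manifest.cna | manifest.expression):
        raise IngestError("zero surviving samples")

    slug = cancer_type.lower().replace(" ", "_")
    cohort_dir = Path(out_dir) / slug
    cohort_dir.mkdir(parents=True, exist_ok=True)
    mutations_to_frame(filtered_mut).to_csv(cohort_dir / "mutations.tsv", sep="\t", index=False)
    cna_to_frame(filtered_cna).to_csv(cohort_dir / "cna.tsv", sep="\t", index=False)
    expr.to_csv(cohort_dir / "expression.tsv", sep="\t", index_label="gene")
    manifest.to_frame().to_csv(cohort_dir / "manifest.tsv", sep="\t", index=False)
    (cohort_dir / "cohort.txt").write_text(cancer_type + "\n")
    return cohort_dir
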