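import pytest

from oncochat import (
    AttributeType,
    CohortSpec,
    Lexicon,
    TermEntry,
)
from oncochat.ingest import (
    ConsensusPolicy,
    build_knowledge_base,
    load_cna,
    load_expression,
    load_mutations,
    load_sample_manifest,
)
from oncochat.explorer import CohortDataset
from oncochat.synthetic import generate_cohort


@pytest.fixture(scope="session")
def tiny_lexicon() -> Lexicon:
    return Lexicon(
        [
            TermEntry("TP53", AttributeType.GENE),
            TermEntry("PIK3CA", AttributeType.GENE),
            TermEntry("KRAS", AttributeType.GENE),
            TermEntry("MYC", AttributeType.GENE),
            TermEntry("BRCA1", AttributeType.GENE),
            TermEntry("breast cancer", AttributeType.CANCER_TYPE, ("breast",)),
            TermEntry("lung cancer", AttributeType.CANCER_TYPE, ("lung",)),
            TermEntry("mutations", AttributeType.DATA_TYPE, ("mutation",)),
            TermEntry(
                "copy number alterations",
                AttributeType.DATA_TYPE,
                ("copy number", "cnas"),
            ),
            TermEntry("gene expression", AttributeType.DATA_TYPE, ("expression",)),
        ]
    )


@pytest.fixture(scope="session")
def fixture_cohort_spec() -> CohortSpec:
    return CohortSpec(
        cancer_type="breast cancer",
        n_samples=200,
        genes=("TP53", "PIK3CA", "KRAS", "MYC", "BRCA1"),
        mutation_rates={"TP53": 0.4, "PIK3CA": 0.3, "KRAS": 0.1},
        amp_rates={"MYC": 0.3},
        del_rates={"BRCA1": 0.2},
        expression_shifts={("PIK3CA", "TP53"): 2.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_kb(tmp_path_factory, fixture_cohort_spec):
    """Raw synthetic cohort written to disk, ingested into a knowledge base."""
    root = tmp_path_factory.mktemp("kb_fixture")
    tables = generate_cohort(fixture_cohort_spec)
    raw_dir = tables.write(root / "raw")
    policy = ConsensusPolicy.tcga_default()
    records = load_mutations(raw_dir / "mutations.tsv", policy.all_callers)
    cna = load_cna(raw_dir / "cna.tsv")
    expression = load_expression(raw_dir / "expression.tsv")
    manifest = load_sample_manifest(raw_dir / "samples.tsv")
    kb_dir = root / "kb"
    build_knowledge_base(
        records,
        cna,
        expression,
        policy,
        set(fixture_cohort_spec.genes),
        out_dir=kb_dir,
        cancer_type=fixture_cohort_spec.cancer_type,
        manifest=manifest,
    )
    return {"kb_dir": kb_dir, "raw_dir": raw_dir, "tables": tables, "records": records}


@pytest.fixture(scope="session")
def fixture_dataset(fixture_kb) -> CohortDataset:
    return CohortDataset.load(fixture_kb["kb_dir"], "breast cancer")
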