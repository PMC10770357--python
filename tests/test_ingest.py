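"""Harmonization rules: consensus filter, whitelist, knowledge-base build."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncochat.explorer import CohortDataset, mutation_frequency
from oncochat.ingest import (
    TCGA_CALLERS,
    TCGA_INDEL_CALLERS,
    ConsensusMode,
    ConsensusPolicy,
    IngestError,
    RawCnaRecord,
    RawMutationRecord,
    apply_consensus_filter,
    apply_gene_whitelist,
    build_knowledge_base,
    load_cna,
    load_expression,
    load_mutations,
)


def mrec(sample="S1", gene="TP53", vc="SNV", impact="MODERATE", callers=("mutect2", "muse")):
    return RawMutationRecord(sample, gene, vc, impact, frozenset(callers))


def brute_force_keep(record: RawMutationRecord, policy: ConsensusPolicy) -> bool:
    """Independent restatement of the consensus rule, record by record."""
    if record.impact not in policy.impact_keep:
        return False
    if policy.mode is ConsensusMode.UNION:
        pool = policy.snv_caller_set if record.variant_class == "SNV" else policy.indel_caller_set
        return any(c in pool for c in record.callers)
    if record.variant_class == "SNV":
        return sum(c in policy.snv_caller_set for c in record.callers) >= policy.snv_min_callers
    return all(c in record.callers for c in policy.indel_caller_set)


def random_records(n, rng):
    callers = sorted(TCGA_CALLERS)
    records = []
    for i in range(n):
        vc = ["SNV", "INS", "DEL"][int(rng.integers(3))]
        impact = ["HIGH", "MODERATE", "LOW", "MODIFIER"][int(rng.integers(4))]
        k = int(rng.integers(1, 5))
        chosen = frozenset(rng.choice(callers, size=k, replace=False))
        records.append(
            RawMutationRecord(f"S{int(rng.integers(50))}", f"G{int(rng.integers(30))}", vc, impact, chosen)
        )
    return records


class TestConsensusFilter:
    def test_snv_two_of_four_rule(self):
        policy = ConsensusPolicy.tcga_default()
        kept = apply_consensus_filter(
            [mrec(callers=("mutect2", "muse")), mrec(callers=("mutect2",))], policy
        )
        assert [len(r.callers) for r in kept] == [2]

    def test_indel_requires_both_designated_callers(self):
        policy = ConsensusPolicy.tcga_default()
        only_varscan = mrec(vc="DEL", callers=("varscan",))
        both = mrec(vc="DEL", callers=("mutect2", "varscan"))
        assert apply_consensus_filter([only_varscan, both], policy) == [both]

    def test_impact_gate(self):
        policy = ConsensusPolicy.tcga_default()
        high = mrec(impact="HIGH")
        low = mrec(impact="LOW", callers=("mutect2", "muse", "varscan"))
        assert apply_consensus_filter([high, low], policy) == [high]

    def test_union_mode_single_caller_suffices(self):
        policy = ConsensusPolicy.basis_default()
        snv = mrec(callers=("caveman",))
        indel = mrec(vc="INS", callers=("pindel",))
        assert apply_consensus_filter([snv, indel], policy) == [snv, indel]

    def test_matches_brute_force_on_generated_table(self):
        rng = np.random.default_rng(42)
        records = random_records(1000, rng)
        policy = ConsensusPolicy.tcga_default()
        kept = apply_consensus_filter(records, policy)
        expected = [r for r in records if brute_force_keep(r, policy)]
        assert kept == expected

    def test_adding_a_caller_never_removes(self):
        rng = np.random.default_rng(7)
        policy = ConsensusPolicy.tcga_default()
        for record in random_records(200, rng):
            missing = sorted(TCGA_CALLERS - record.callers)
            if not missing:
                continue
            richer = RawMutationRecord(
                record.sample_id, record.gene, record.variant_class, record.impact,
                record.callers | {missing[0]},
            )
            if apply_consensus_filter([record], policy):
                assert apply_consensus_filter([richer], policy)

    @settings(max_examples=50, deadline=None)
    @given(min_callers=st.integers(min_value=1, max_value=4), seed=st.integers(0, 1000))
    def test_raising_min_callers_never_adds(self, min_callers, seed):
        rng = np.random.default_rng(seed)
        records = random_records(100, rng)
        loose = ConsensusPolicy(snv_min_callers=min_callers)
        if min_callers < 4:
            strict = ConsensusPolicy(snv_min_callers=min_callers + 1)
            assert set(apply_consensus_filter(records, strict)) <= set(
                apply_consensus_filter(records, loose)
            )

    def test_filters_commute_with_whitelist(self):
        rng = np.random.default_rng(13)
        records = random_records(300, rng)
        policy = ConsensusPolicy.tcga_default()
        whitelist = {f"G{i}" for i in range(15)}
        a = apply_gene_whitelist(apply_consensus_filter(records, policy), whitelist)
        b = apply_consensus_filter(apply_gene_whitelist(records, whitelist), policy)
        assert a == b


class TestWhitelist:
    def test_membership_filtering(self):
        records = [mrec(gene=g) for g in ["TP53", "KRAS", "ZZZ9", "QQQ1"]]
        kept = apply_gene_whitelist(records, {"TP53", "KRAS", "MYC"})
        assert [r.gene for r in kept] == ["TP53", "KRAS"]

    def test_superset_is_identity(self):
        records = [mrec(gene=g) for g in ["TP53", "KRAS"]]
        assert apply_gene_whitelist(records, {"TP53", "KRAS", "MYC"}) == records

    def test_empty_whitelist_rejected(self):
        with pytest.raises(IngestError):
            apply_gene_whitelist([mrec()], set())

    def test_symbol_match_is_case_sensitive(self):
        assert apply_gene_whitelist([mrec(gene="TP53")], {"tp53"}) == []


class TestLoaders:
    def test_mutation_loader_round_trip(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample_id\tgene\tvariant_class\timpact\tcallers\n"
            "S1\tTP53\tSNV\tHIGH\tmutect2;muse\n"
            "S2\tKRAS\tDEL\tMODERATE\tmutect2;varscan\n"
        )
        records = load_mutations(path, TCGA_CALLERS)
        assert len(records) == 2
        assert records[0].callers == frozenset({"mutect2", "muse"})

    def test_unknown_caller_errors_with_row(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample_id\tgene\tvariant_class\timpact\tcallers\nS1\tTP53\tSNV\tHIGH\tsamtools\n"
        )
        with pytest.raises(IngestError, match="row 0"):
            load_mutations(path, TCGA_CALLERS)

    def test_bad_impact_errors(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "sample_id\tgene\tvariant_class\timpact\tcallers\nS1\tTP53\tSNV\tSEVERE\tmuse\n"
        )
        with pytest.raises(IngestError, match="impact"):
            load_mutations(path, TCGA_CALLERS)

    def test_duplicate_cna_row_errors(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text(
            "sample_id\tgene\tcategory\nS1\tTP53\tneutral\nS1\tTP53\tdeletion\n"
        )
        with pytest.raises(IngestError, match="duplicate"):
            load_cna(path)

    def test_unknown_cna_category_errors(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tgene\tcategory\nS1\tTP53\tgained\n")
        with pytest.raises(IngestError, match="categories"):
            load_cna(path)

    def test_expression_loader_shape_and_type_error(self, tmp_path):
        good = tmp_path / "e.tsv"
        good.write_text("gene\tS1\tS2\tS3\tS4\nTP53\t1\t2\t3\t4\nKRAS\t5\t6\t7\t8\nMYC\t0\t0\t0\t1\n")
        matrix = load_expression(good)
        assert matrix.shape == (3, 4)
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\tS1\nTP53\thigh\n")
        with pytest.raises(IngestError, match="non-numeric"):
            load_expression(bad)


class TestBuildKnowledgeBase:
    def test_require_both_intersects_manifests(self, tmp_path):
        mut_samples = [f"S{i}" for i in range(10)]
        cna_samples = [f"S{i}" for i in range(4, 12)]  # overlap S4..S9 (6 samples)
        mutations = [mrec(sample=s) for s in mut_samples]
        cna = [RawCnaRecord(s, "TP53", "neutral") for s in cna_samples]
        import pandas as pd

        expression = pd.DataFrame({s: [1.0] for s in mut_samples}, index=["TP53"])
        cohort_dir = build_knowledge_base(
            mutations, cna, expression, ConsensusPolicy.tcga_default(), {"TP53"},
            out_dir=tmp_path / "kb", cancer_type="breast cancer", require_both=True,
        )
        ds = CohortDataset.load(tmp_path / "kb", "breast cancer")
        assert ds.manifest.mutations == set(mut_samples) & set(cna_samples)
        assert len(ds.manifest.mutations) == 6
        assert cohort_dir.name == "breast_cancer"

    def test_round_trip_preserves_frequencies(self, fixture_kb, fixture_dataset):
        """Counts recomputed from the knowledge base match a brute-force scan
        of the raw fixture table."""
        policy = ConsensusPolicy.tcga_default()
        raw = fixture_kb["records"]
        for gene in ["TP53", "PIK3CA", "KRAS"]:
            expected = len(
                {r.sample_id for r in raw if r.gene == gene and brute_force_keep(r, policy)}
            )
            assert mutation_frequency(fixture_dataset, gene).altered_sample_count == expected

    def test_zero_overlap_with_require_both_errors(self, tmp_path):
        import pandas as pd

        mutations = [mrec(sample="S1")]
        cna = [RawCnaRecord("S2", "TP53", "neutral")]
        expression = pd.DataFrame({"S1": [1.0]}, index=["TP53"])
        with pytest.raises(IngestError, match="both"):
            build_knowledge_base(
                mutations, cna, expression, ConsensusPolicy.tcga_default(), {"TP53"},
                out_dir=tmp_path / "kb", cancer_type="x", require_both=True,
            )
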