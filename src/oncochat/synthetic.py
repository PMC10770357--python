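"""Seeded synthetic cohorts and pronunciation corpora with known truth.

Everything downstream is testable against planted structure, without any
external download:

* **Lexicons** of gene-like symbols (letters + digits), multiword cancer
  type names, and the three standard genomic data types with synonyms.
* **Utterance corpora** that emulate crowdsourced pronunciations: each
  term yields several transcriptions perturbed by speech-to-text-like
  operations (digit spell-out, letter naming, sound-alike substitutions,
  token splits/joins, character drops) at a configurable noise level.
  Noise 0 reproduces each term verbatim.
* **Cohorts** with per-gene mutation rates, a per-caller evidence model
  (so the consensus filter is genuinely exercised), amplification and
  deletion rates, and Gaussian per-gene expression with an additive shift
  in carriers of a chosen partition gene.

Every generator is a deterministic function of its spec (including the
seed); truth files record the planted parameters, and for mutation rates
also the expected post-filter detection rate implied by the caller model,
which is the quantity a consensus-filtered pipeline can recover.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import TCGA_CALLERS, TCGA_INDEL_CALLERS
from .oov_mapper import AttributeType, Lexicon, TermEntry, UtteranceRecord

# The three data types every lexicon carries, with conversational synonyms.
STANDARD_DATA_TYPES: list[TermEntry] = [
    TermEntry("mutations", AttributeType.DATA_TYPE, ("mutation", "snvs and indels")),
    TermEntry(
        "copy number alterations",
        AttributeType.DATA_TYPE,
        ("copy number", "copy number alteration", "cnas"),
    ),
    TermEntry("gene expression", AttributeType.DATA_TYPE, ("expression", "rna expression")),
]

_TISSUES = [
    "breast", "lung", "colon", "liver", "skin", "brain", "kidney", "ovarian",
    "prostate", "gastric", "bladder", "thyroid", "pancreatic", "cervical",
    "endometrial", "esophageal", "rectal", "testicular", "adrenal", "bone",
]
_QUALIFIERS = ["", "invasive ", "metastatic ", "early ", "advanced "]


def generate_lexicon(
    n_genes: int, n_cancer_types: int, n_data_types: int, seed: int
) -> Lexicon:
    """Synthetic lexicon: `n_genes` unique gene-like symbols, `n_cancer_types`
    multiword cancer names, and at least the three standard data types."""
    if min(n_genes, n_cancer_types, n_data_types) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    genes: set[str] = set()
    while len(genes) < n_genes:
        stem = "".join(rng.choice(list(letters), size=int(rng.integers(2, 5))))
        symbol = stem + str(int(rng.integers(1, 100)))
        genes.add(symbol)
    entries = [TermEntry(g, AttributeType.GENE) for g in sorted(genes)]

    if n_cancer_types > len(_TISSUES) * len(_QUALIFIERS):
        raise ValueError("n_cancer_types too large for the name inventory")
    names: list[str] = []
    for qualifier in _QUALIFIERS:
        for tissue in _TISSUES:
            names.append(f"{qualifier}{tissue} cancer")
    for name in names[:n_cancer_types]:
        short = name.replace(" cancer", "")
        syns = (short,) if short != name and " " not in short else ()
        entries.append(TermEntry(name, AttributeType.CANCER_TYPE, syns))

    data_types = list(STANDARD_DATA_TYPES)
    for i in range(3, n_data_types):
        data_types.append(TermEntry(f"assay type {i - 2}", AttributeType.DATA_TYPE))
    entries.extend(data_types[: max(3, n_data_types)] if n_data_types >= 3 else data_types[:3])
    return Lexicon(entries)


def mean_pronunciations_per_expert_per_term(
    n_utterances: int, n_experts: int, n_terms: int
) -> float:
    """Average number of pronunciations each contributor supplied per term,
    given a corpus's bookkeeping counts."""
    if min(n_utterances, n_experts, n_terms) < 1:
        raise ValueError("all counts must be >= 1")
    return n_utterances / (n_experts * n_terms)


# ---------------------------------------------------------------------------
# Pronunciation perturbation


@dataclass(frozen=True)
class PerturbationSpec:
    """How hard to distort each term, and how many variants to emit.

    `noise_level` is the per-token probability of applying one distortion
    operation; 0 reproduces the term verbatim.  `variants_per_term`
    defaults to 27 — nine speakers contributing on average three
    pronunciations per term, matching a realistic crowdsourcing yield.
    """

    noise_level: float = 0.3
    variants_per_term: int = 27
    n_speakers: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise_level <= 1:
            raise ValueError("noise_level must be in [0, 1]")
        if self.variants_per_term < 1 or self.n_speakers < 1:
            raise ValueError("variants_per_term and n_speakers must be >= 1")


_DIGIT_NAMES = {
    "0": "zero", "1": "one", "2": "two", "3": "three", "4": "four",
    "5": "five", "6": "six", "7": "seven", "8": "eight", "9": "nine",
}
_LETTER_NAMES = {
    "a": "ay", "b": "bee", "c": "see", "d": "dee", "e": "ee", "f": "eff",
    "g": "gee", "h": "aitch", "i": "eye", "j": "jay", "k": "kay", "l": "ell",
    "m": "em", "n": "en", "o": "oh", "p": "pee", "q": "cue", "r": "are",
    "s": "ess", "t": "tee", "u": "you", "v": "vee", "w": "double you",
    "x": "ex", "y": "why", "z": "zee",
}
_SOUND_SUBS = [
    ("ph", "f"), ("c", "k"), ("k", "c"), ("i", "ee"), ("y", "i"),
    ("s", "ss"), ("z", "s"), ("er", "a"), ("oo", "u"), ("ght", "t"),
]


def _perturb_token(token: str, rng: np.random.Generator) -> str:
    """Apply one randomly chosen applicable distortion to a token."""
    ops = []
    if any(ch.isdigit() for ch in token):
        ops.append("spell_digits")
    if any(ch.isalpha() for ch in token):
        ops.append("letter_names")
        ops.append("sound_sub")
    if len(token) > 3:
        ops.append("char_drop")
        ops.append("split")
    if not ops:
        return token
    op = ops[int(rng.integers(len(ops)))]
    if op == "spell_digits":
        return " ".join(
            _DIGIT_NAMES[ch] if ch.isdigit() else ch for ch in token
        ).replace("  ", " ")
    if op == "letter_names":
        # speak the leading consonant cluster letter by letter (tp53 -> "tee pee 53")
        head = ""
        for ch in token:
            if ch.isalpha():
                head += ch
            else:
                break
        if not head:
            return token
        spoken = " ".join(_LETTER_NAMES[ch.lower()] for ch in head)
        return (spoken + " " + token[len(head):]).strip()
    if op == "sound_sub":
        lowered = token.lower()
        candidates = [(a, b) for a, b in _SOUND_SUBS if a in lowered]
        if not candidates:
            return token
        a, b = candidates[int(rng.integers(len(candidates)))]
        return lowered.replace(a, b, 1)
    if op == "char_drop":
        pos = int(rng.integers(len(token)))
        return token[:pos] + token[pos + 1:]
    # split: insert a space mid-token
    pos = int(rng.integers(1, len(token)))
    return token[:pos] + " " + token[pos:]


def perturb_term(term: str, noise_level: float, rng: np.random.Generator) -> str:
    """One speech-to-text-like distortion of a term; verbatim at noise 0."""
    if noise_level == 0:
        return term
    tokens = term.split()
    out = []
    for token in tokens:
        if rng.random() < noise_level:
            out.append(_perturb_token(token, rng))
        else:
            out.append(token)
    # occasionally join two tokens, as recognizers do with unfamiliar phrases
    if len(out) > 1 and rng.random() < noise_level / 2:
        j = int(rng.integers(len(out) - 1))
        out[j : j + 2] = [out[j] + out[j + 1]]
    return " ".join(out)


def generate_utterance_corpus(
    lexicon: Lexicon, spec: PerturbationSpec
) -> list[UtteranceRecord]:
    """`variants_per_term` perturbed transcriptions per lexicon term, each
    labeled with its true target and a rotating synthetic speaker id."""
    rng = np.random.default_rng(spec.seed)
    records = []
    for entry in lexicon.entries:
        for v in range(spec.variants_per_term):
            transcription = perturb_term(entry.value, spec.noise_level, rng)
            if not transcription.strip():
                transcription = entry.value
            records.append(
                UtteranceRecord(
                    transcription=transcription,
                    target_value=entry.value,
                    attribute_type=entry.attribute_type,
                    speaker_id=f"speaker{v % spec.n_speakers + 1:02d}",
                )
            )
    return records


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortSpec:
    """Planted structure of one synthetic cohort.

    Caller sensitivities default to 0.95 per caller, firing independently
    given a true variant; the truth file records the resulting expected
    post-filter detection rate per gene.  A fraction of samples also
    receive low-impact single-caller artifact calls, which the consensus
    and impact filters must reject.
    """

    cancer_type: str = "breast cancer"
    n_samples: int = 500
    genes: tuple[str, ...] = ("TP53", "PIK3CA", "KRAS", "MYC", "BRCA1")
    mutation_rates: dict[str, float] = field(default_factory=dict)
    amp_rates: dict[str, float] = field(default_factory=dict)
    del_rates: dict[str, float] = field(default_factory=dict)
    expression_mean: float = 8.0
    expression_sd: float = 1.0
    #: (quant_gene, partition_gene) -> shift in sd units added to carriers.
    expression_shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    caller_sensitivity: float = 0.95
    indel_fraction: float = 0.15
    artifact_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for table in (self.mutation_rates, self.amp_rates, self.del_rates):
            for gene, rate in table.items():
                if not 0 <= rate <= 1:
                    raise ValueError(f"rate for {gene} outside [0, 1]")

    def rate(self, gene: str) -> float:
        return self.mutation_rates.get(gene, 0.0)

    def expected_detected_rate(self, gene: str) -> float:
        """Planted rate times the probability a true variant survives the
        >=2-of-4 SNV / both-of-2 indel consensus rule."""
        p = self.caller_sensitivity
        p_snv = sum(
            math.comb(4, k) * p**k * (1 - p) ** (4 - k) for k in range(2, 5)
        )
        p_indel = p * p
        keep = (1 - self.indel_fraction) * p_snv + self.indel_fraction * p_indel
        return self.rate(gene) * keep


@dataclass
class CohortTables:
    """In-memory raw cohort, writable in the ingest dialect."""

    spec: CohortSpec
    samples: list[str]
    mutations: pd.DataFrame
    cna: pd.DataFrame
    expression: pd.DataFrame
    truth: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
        self.cna.to_csv(out / "cna.tsv", sep="\t", index=False)
        self.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene")
        manifest = pd.DataFrame(
            {
                "sample_id": self.samples,
                "has_mutations": 1,
                "has_cna": 1,
                "has_expression": 1,
            }
        )
        manifest.to_csv(out / "samples.tsv", sep="\t", index=False)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return out


def generate_cohort(spec: CohortSpec) -> CohortTables:
    """Draw one cohort from the spec's generative model.

    True variants: per sample and gene, Bernoulli(rate); class SNV with
    probability 1 - indel_fraction, else an insertion or deletion; impact
    MODERATE or HIGH (1:1).  Each relevant caller fires independently with
    `caller_sensitivity`; a variant seen by no caller is reported by one
    random caller (call records always carry evidence) and will fail the
    consensus rule.  Artifacts: per sample/gene, Bernoulli(artifact_rate)
    single-caller LOW/MODIFIER calls.
    """
    rng = np.random.default_rng(spec.seed)
    samples = [f"SAMPLE{i + 1:04d}" for i in range(spec.n_samples)]
    snv_callers = sorted(TCGA_CALLERS)
    indel_callers = sorted(TCGA_INDEL_CALLERS)

    mut_rows = []
    true_carriers: dict[str, set[str]] = {g: set() for g in spec.genes}
    for gene in spec.genes:
        rate = spec.rate(gene)
        for sample in samples:
            if rate > 0 and rng.random() < rate:
                true_carriers[gene].add(sample)
                is_indel = rng.random() < spec.indel_fraction
                if is_indel:
                    variant_class = "INS" if rng.random() < 0.5 else "DEL"
                    pool = indel_callers
                else:
                    variant_class = "SNV"
                    pool = snv_callers
                fired = [c for c in pool if rng.random() < spec.caller_sensitivity]
                if not fired:
                    fired = [pool[int(rng.integers(len(pool)))]]
                impact = "MODERATE" if rng.random() < 0.5 else "HIGH"
                mut_rows.append(
                    (sample, gene, variant_class, impact, ";".join(fired))
                )
            if spec.artifact_rate > 0 and rng.random() < spec.artifact_rate:
                caller = snv_callers[int(rng.integers(len(snv_callers)))]
                impact = "LOW" if rng.random() < 0.5 else "MODIFIER"
                mut_rows.append((sample, gene, "SNV", impact, caller))
    mutations = pd.DataFrame(
        mut_rows, columns=["sample_id", "gene", "variant_class", "impact", "callers"]
    )

    cna_rows = []
    for gene in spec.genes:
        amp = spec.amp_rates.get(gene, 0.0)
        dele = spec.del_rates.get(gene, 0.0)
        for sample in samples:
            u = rng.random()
            if u < amp:
                category = "amplification"
            elif u < amp + dele:
                category = "deletion"
            else:
                category = "neutral"
            cna_rows.append((sample, gene, category))
    cna = pd.DataFrame(cna_rows, columns=["sample_id", "gene", "category"])

    expr = pd.DataFrame(
        rng.normal(spec.expression_mean, spec.expression_sd, size=(len(spec.genes), len(samples))),
        index=list(spec.genes),
        columns=samples,
    )
    for (quant_gene, partition_gene), shift_sd in spec.expression_shifts.items():
        carriers = [s for s in samples if s in true_carriers.get(partition_gene, set())]
        expr.loc[quant_gene, carriers] += shift_sd * spec.expression_sd

    truth = {
        "cancer_type": spec.cancer_type,
        "n_samples": spec.n_samples,
        "seed": spec.seed,
        "mutation_rates": {g: spec.rate(g) for g in spec.genes},
        "expected_detected_rates": {g: spec.expected_detected_rate(g) for g in spec.genes},
        "true_carrier_counts": {g: len(true_carriers[g]) for g in spec.genes},
        "amp_rates": {g: spec.amp_rates.get(g, 0.0) for g in spec.genes},
        "del_rates": {g: spec.del_rates.get(g, 0.0) for g in spec.genes},
        "expression_shifts": {
            f"{q}|{p}": s for (q, p), s in spec.expression_shifts.items()
        },
    }
    return CohortTables(spec, samples, mutations, cna, expr, truth)
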