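# Methods

This note documents the models, rules and numerical choices behind
`oncochat`, what the synthetic generators do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Term normalization

Queries and lexicon terms are compared after one shared normalization:
lowercase, punctuation → whitespace, whitespace collapse, token-wise
lemmatization. The lemmatizer is a rule-based English suffix stripper
(plural and a few inflectional endings, a small irregular table) with two
guards: tokens containing digits are never touched (gene symbols such as
`tp53`), and no token is reduced below four characters (protecting short
symbols spoken as words — `ras`, `myc`). Because both sides of every
lookup pass through the same function, any residual lemmatizer quirk is
symmetric and cannot break the identity property (every supported term
maps to itself). An input that is empty after cleaning yields a distinct
empty signal, which every downstream stage treats as unresolvable.

## Phonetic encoding

Phonetic keys use the classic Metaphone rule set (consonant-class
reduction of English spelling: silent-letter handling, digraphs, vowels
kept only word-initially), implemented in `oncochat.phonetics` and applied
per whitespace token. Metaphone was chosen because sound-alike
transcriptions of gene symbols are exactly its use case — `"kay rass"`
and `kras` both reduce to `K RS` / `KRS` — and the algorithm is compact
enough to state and test rule by rule. Digits carry no phonetic key;
digit content is captured by the syllable and length features instead.
The syllable heuristic counts vowel groups per token (silent-final-`e`
adjusted), one per all-consonant token, plus one per digit (digits in
symbols are spoken individually).

## The out-of-vocabulary matching chain

Resolution stages, in order; the first stage that resolves wins:

1. **Personal pronunciations** — per-user overrides keyed by
   (user, normalized transcription), upsert semantics, JSON-persisted.
   They exist to repair mappings the shared stages get wrong for one
   speaker, so they precede everything for the owning user.
2. **Exact matching** — normalized lookup against canonical values and
   synonyms. Lexicon loading rejects collisions (same normalized key for
   two different targets) rather than guessing.
3. **Crowdsourced matching** — lookup in the pronunciation corpus,
   resolving only when every matching record agrees on a single target.
   An ambiguous transcription falls through to prediction instead of
   erroring, since a lookup that cannot name one target has not resolved.
4. **Predicted matching** — a random forest (scikit-learn, 200 trees,
   default depth) over: TF-IDF of character 2–4-grams with word-boundary
   padding; TF-IDF of character 1–3-grams of the per-token Metaphone
   keys; character, token and syllable counts; optionally (off by
   default) a 64-dimensional hashed character embedding as a cheap
   stand-in for pluggable distributed representations. The featurizer is
   fitted on the training partition only. The predicted class is the
   majority vote of tree-level predictions; a k-way tie is broken by a
   seeded uniform draw among the tied classes, and the reported
   confidence is the winning class's vote fraction. Lookup stages report
   confidence 1.

Training uses a seeded shuffle split with |train| = ⌊f·N⌋ (f = 0.9 by
default). Evaluation replays the *full* chain on held-out records with
the crowdsourced index restricted to the training partition, and reports
an exact-only baseline alongside; the chain can therefore never score
below the baseline on the same records, and the tests assert that
dominance as an invariant.

Model artifacts serialize the classifier, fitted featurizer, label index
and training seed with a format version; loading any other version is an
error rather than a silent misread.

## Dialogue model

The session state is the triple (GENE, CANCER TYPE, DATA TYPE); state is
a pure value, and each accepted navigation utterance replaces exactly one
slot. This gives order-independence (any arrival order of distinct
attributes yields the same state) and context retention (switching one
value never touches the other two) by construction. Response dispatch is
a total function of the fill pattern and intent kind: data type + cancer
type without a gene → overview ranking; all three → gene-level summary;
anything less → a prompt for the first unfilled attribute in the fixed
order DATA TYPE → CANCER TYPE → GENE (an arbitrary but documented
choice — prompting for the analysis type first keeps the next prompt
specific). Compare requires the second value to share an attribute type
with an already-filled slot; split-by requires all three slots plus a
quantitative data type (gene expression), otherwise an explanatory error
response. Comparing two cancer types is permitted with the gene slot
taken from the state.

Intents are detected from fixed keyword triggers (`compare … with …`,
`split by <gene>`, `reset`, `help`) and conversational carrier prefixes
("tell me about …", "show me …") are stripped before term resolution —
this replaces a voice platform's interaction model, which is out of
scope. Trigger payloads are resolved through the same matching chain as
plain navigation utterances.

## Harmonization rules (ingest)

The mutation dialect is a minimal 5-column TSV (`sample_id`, `gene`,
`variant_class` ∈ {SNV, INS, DEL}, `impact` ∈ {HIGH, MODERATE, LOW,
MODIFIER}, `callers` semicolon-separated); functional impact is taken as
a precomputed input column, since running an annotation engine is out of
scope. Consensus policies:

* **majority** (default, four-caller cohorts): an SNV is kept with ≥ 2
  of {MuTect2, SomaticSniper, VarScan, MuSE}; an indel only with *both*
  of {MuTect2, VarScan}, the two callers that report indels;
* **union** (externally harmonized cohorts): any one configured caller
  suffices, with separate SNV and indel caller pairs.

Both are followed by the MODERATE/HIGH impact gate and a case-sensitive
coding-gene whitelist (symbols are uppercased at load with a warning).
The filters commute, and the tests check that plus two monotonicity
properties (adding a caller never removes a record; raising the SNV
threshold never adds one). Multiple qualifying records per (sample,
gene) count once toward frequencies. Copy-number input is categorical
per (sample, gene) — amplification / neutral / deletion — with duplicate
rows rejected. Expression matrices are taken as-is (assumed upstream
normalized, e.g. log-scale); no re-normalization is applied.

Frequency denominators are per-assay: the samples listed for that assay
in the cohort manifest, not the union across assays, because assays
cover different sample subsets. The manifest is taken from an explicit
per-assay sample table when provided, else inferred from the samples
present in each raw input (which undercounts wild-type-only samples in
sparse mutation tables — hence the explicit option, which the synthetic
generator always writes). The `require_both` switch restricts the whole
manifest to samples having both mutation and copy-number data, mirroring
cohorts distributed only with complete DNA-level data.

## Analytics

* Mutation/CNA frequency: distinct altered samples over the assay
  denominator; rankings sort by descending frequency with alphabetical
  tie-break for reproducible output.
* Data-type comparison: 2×2 contingency (a-only, b-only, both, neither)
  over samples assayed for both types; cells sum to the shared-sample
  count. Gene and cancer-type comparisons report paired frequencies (plus
  the co-mutated count for genes).
* Split-by: eligible samples are those with an expression value and
  mutation-assay coverage; groups are post-filter mutation carriers
  versus the rest. The default test is the two-sided Wilcoxon rank-sum
  (robust to the unknown expression scale); Welch's t is available as an
  option. An empty group yields a descriptive-only result with a warning
  instead of a test.
* Rendering writes a TSV (fixed column order, fixed float formatting, so
  identical input is byte-identical) and a PNG bar chart per result.

## Synthetic generators

The generators define the study conditions under which the stack is
validated:

* **Lexicon**: gene-like symbols (2–4 letters + 1–2 digits), multiword
  cancer-type names, and always the three standard data types with
  synonyms. Default corpus shape for matcher experiments: 50 genes, 10
  cancer types, 3 data types (63 terms).
* **Utterance corpus**: per term, `variants_per_term` transcriptions
  (default 27 = 9 synthetic speakers × 3 pronunciations each, a
  realistic crowdsourcing yield; matcher experiments use 10 per term).
  Each token is perturbed with probability `noise_level` (default 0.3)
  by one operation drawn from: digit spell-out ("53" → "five three"),
  letter-naming of leading consonant clusters ("tp53" → "tee pee 53"),
  sound-alike substitutions (c↔k, ph→f, …), character drop, token split;
  multiword terms are occasionally joined. Noise 0 reproduces the term
  verbatim. This emulates the *kinds* of ASR distortion (phonetic
  confusion, spelled-out symbols) but not accent structure, speaker
  idiolects, or correlated recognizer errors — so matcher accuracies on
  this corpus validate the machinery, not performance on human speech.
* **Cohort**: per sample and gene, a true variant with the planted rate;
  15% indels; impact MODERATE/HIGH (1:1). Each relevant caller fires
  independently with sensitivity 0.95; a variant seen by no caller is
  assigned one random caller and will fail consensus. Artifact calls
  (rate 0.05 per sample/gene) are single-caller LOW/MODIFIER records, so
  the filters always have something to reject. The truth file records
  both the planted rate and the *expected detected rate* — the planted
  rate times the analytic probability that a true variant survives the
  consensus rule (≥2-of-4 at sensitivity p for SNVs, both-of-2 for
  indels) — which is the recoverable quantity for a post-filter pipeline
  and the reference for the binomial recovery checks. Expression is
  per-gene Gaussian (default mean 8, sd 1, log-like scale) with an
  additive shift, in sd units, in true carriers of a chosen partition
  gene.

## Validation scales and numerical choices

Test and acceptance problem sizes are chosen so the whole suite runs in
seconds while keeping the statistics meaningful: rate recovery at
n = 1000 samples against exact (Clopper–Pearson) 99% binomial intervals;
split-by power at ~100 carriers per group with a 2 sd shift (p < 0.01);
split-by null calibration over 200 permuted replicates of 25/25 samples
(rejection rate at α = 0.05 required to lie in [0.01, 0.10]); matcher
evaluation on a 630-utterance corpus with a 90/10 split. Corpus-split
bookkeeping is additionally exercised at the full 24,093-record scale,
where a 90/10 split yields 21,683 / 2,410.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical (inputs, model file, seed)
reproduce identical matches, splits and generated files byte for byte.

## Known limitations

* The matcher treats all three attribute types jointly; no upstream slot
  elicitation narrows the candidate set.
* The lemmatizer and perturbation inventory are English-only.
* The random forest cannot predict a class absent from its training
  partition (such classes are permitted but unreachable).
* Transcript-level annotation (e.g. selecting each gene's longest
  transcript) is not represented; impact is a per-record input fact.
* Copy-number categories are taken as input facts; no thresholds or
  segmentation are computed.
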