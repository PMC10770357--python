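"""Orchestration of one conversational turn: map, parse, update, answer.

The engine glues the term mapper, the dialogue state machine and the
explorer together.  Each typed utterance (standing in for a speech
transcription) is resolved to a supported term, turned into an intent,
applied to the session state, and answered with speech text backed by a
cohort computation.  Turns are recorded so a session is replayable:
feeding the same utterances back reproduces the same final state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from . import dialogue, explorer
from .dialogue import (
    Intent,
    IntentKind,
    NavigationState,
    ResponseClass,
    ResponseSpec,
)
from .oov_mapper import (
    AttributeType,
    Lexicon,
    MatcherModel,
    MatchResult,
    PersonalStore,
    UNRESOLVED,
    build_corpus_index,
    map_utterance,
)


@dataclass
class Turn:
    user_text: str
    match: MatchResult
    state: NavigationState
    response: ResponseSpec


@dataclass
class ChatEngine:
    lexicon: Lexicon
    kb_dir: str | Path | None = None
    corpus_index: dict | None = None
    model: MatcherModel | None = None
    personal_store: PersonalStore | None = None
    user_id: str | None = None
    seed: int = 0
    plots_dir: str | Path | None = None
    state: NavigationState = field(default_factory=dialogue.new_session)
    transcript: list[Turn] = field(default_factory=list)
    _datasets: dict = field(default_factory=dict, repr=False)

    @classmethod
    def create(
        cls,
        lexicon: Lexicon,
        corpus=None,
        kb_dir=None,
        model=None,
        personal_store=None,
        user_id=None,
        seed: int = 0,
        plots_dir=None,
        session_id: str = "default",
    ) -> "ChatEngine":
        return cls(
            lexicon=lexicon,
            kb_dir=kb_dir,
            corpus_index=build_corpus_index(corpus) if corpus else None,
            model=model,
            personal_store=personal_store,
            user_id=user_id,
            seed=seed,
            plots_dir=plots_dir,
            state=dialogue.new_session(session_id),
        )

    # -- data access -------------------------------------------------------

    def dataset(self, cancer_type: str) -> explorer.CohortDataset:
        if cancer_type not in self._datasets:
            if self.kb_dir is None:
                raise explorer.ExplorerError("no knowledge base configured")
            self._datasets[cancer_type] = explorer.CohortDataset.load(self.kb_dir, cancer_type)
        return self._datasets[cancer_type]

    # -- one turn ----------------------------------------------------------

    #: Conversational carrier phrases preceding the actual term ("tell me
    #: about mutations"); stripped before term resolution.
    _CARRIER_RE = re.compile(
        r"^\s*(?:please\s+)?(?:tell me about|show me|what about|how about|"
        r"give me|switch to|navigate to|go to|tell me)\b[\s,]*",
        re.IGNORECASE,
    )

    def _map(self, text: str) -> MatchResult:
        text = self._CARRIER_RE.sub("", text) or text
        return map_utterance(
            text,
            self.lexicon,
            self.corpus_index,
            self.model,
            self.personal_store,
            self.user_id,
            seed=self.seed,
        )

    def handle(self, text: str) -> Turn:
        """Process one utterance and return the completed turn."""
        trigger = dialogue.scan_triggers(text)
        if trigger is not None and trigger.payload_text is not None:
            match = self._map(trigger.payload_text)
        elif trigger is not None:
            match = UNRESOLVED
        else:
            match = self._map(text)
        intent = dialogue.parse_intent(match, self.state, text)

        if intent.kind is IntentKind.RESET:
            self.state = dialogue.reset_session(self.state)
        elif intent.kind is IntentKind.NAVIGATE:
            attr, value = intent.payload
            self.state = dialogue.apply_attribute(self.state, attr, value)

        response = dialogue.resolve_response(self.state, intent)
        response = self._execute(response)
        turn = Turn(text, match, self.state, response)
        self.transcript.append(turn)
        return turn

    # -- analytics backing the speech -------------------------------------

    def _execute(self, response: ResponseSpec) -> ResponseSpec:
        """Run the explorer request named in the response payload and fold
        the numbers into the speech text."""
        op = response.payload.get("op")
        if op == "none" or self.kb_dir is None:
            return response
        try:
            if op == "gene_summary":
                self._fill_gene_summary(response)
            elif op == "overview":
                self._fill_overview(response)
            elif op == "compare":
                self._fill_compare(response)
            elif op == "split_by":
                self._fill_split_by(response)
        except explorer.ExplorerError as exc:
            response.response_class = ResponseClass.ERROR_TEXT
            response.speech_text = f"I could not compute that: {exc}"
        return response

    def _render(self, result, stem: str) -> None:
        if self.plots_dir is not None:
            explorer.render_result(result, Path(self.plots_dir) / stem)

    def _fill_gene_summary(self, response: ResponseSpec) -> None:
        state = self.state
        ds = self.dataset(state.cancer_type)
        if state.data_type == "mutations":
            stats = explorer.mutation_frequency(ds, state.gene)
            response.speech_text = (
                f"{stats.frequency:.1%} of {ds.cancer_type} samples "
                f"({stats.altered_sample_count} of {stats.cohort_size}) carry a "
                f"{state.gene} mutation."
            )
            response.payload["result"] = stats
            self._render(stats, f"{state.gene}_mutations")
        elif state.data_type == "copy number alterations":
            amp, dele = explorer.cna_frequency(ds, state.gene)
            response.speech_text = (
                f"In {ds.cancer_type}, {state.gene} is amplified in {amp.frequency:.1%} "
                f"and deleted in {dele.frequency:.1%} of samples."
            )
            response.payload["result"] = (amp, dele)
            self._render(amp, f"{state.gene}_cna")
        else:
            summary = explorer.expression_summary(ds, state.gene)
            response.speech_text = (
                f"{state.gene} expression in {ds.cancer_type}: mean {summary.mean:.2f}, "
                f"median {summary.median:.2f} across {summary.n} samples."
            )
            response.payload["result"] = summary
            self._render(summary, f"{state.gene}_expression")

    def _fill_overview(self, response: ResponseSpec, k: int = 5) -> None:
        state = self.state
        ds = self.dataset(state.cancer_type)
        if state.data_type != "mutations":
            return  # generic speech text already set
        ranked = explorer.top_mutated_genes(ds, k)
        listing = ", ".join(f"{s.gene} ({s.frequency:.1%})" for s in ranked)
        response.speech_text = (
            f"The most frequently mutated genes in {ds.cancer_type} are: {listing}."
        )
        response.payload["result"] = ranked
        self._render(ranked, "top_mutated_genes")

    def _fill_compare(self, response: ResponseSpec) -> None:
        attr = AttributeType(response.payload["attribute_type"])
        value_a = response.payload["value_a"]
        value_b = response.payload["value_b"]
        state = self.state
        if attr is AttributeType.DATA_TYPE:
            ds = self.dataset(state.cancer_type)
            result = explorer.compare_data_types(ds, state.gene, value_a, value_b)
            c = result.contingency
            response.speech_text = (
                f"For {state.gene} in {ds.cancer_type}: {c['both']} samples have both "
                f"{value_a} and {value_b}, {c['a_only']} only {value_a}, "
                f"{c['b_only']} only {value_b}, and {c['neither']} neither."
            )
        elif attr is AttributeType.GENE:
            ds = self.dataset(state.cancer_type)
            result = explorer.compare_genes(ds, value_a, value_b)
            fa, fb = result.frequencies["frequency"]
            response.speech_text = (
                f"In {ds.cancer_type}, {value_a} is mutated in {fa:.1%} and "
                f"{value_b} in {fb:.1%} of samples; "
                f"{result.contingency['both']} samples carry both."
            )
        else:
            ds_a = self.dataset(value_a)
            ds_b = self.dataset(value_b)
            result = explorer.compare_cancer_types(ds_a, ds_b, state.gene)
            fa, fb = result.frequencies["frequency"]
            response.speech_text = (
                f"{state.gene} is mutated in {fa:.1%} of {value_a} and "
                f"{fb:.1%} of {value_b} samples."
            )
        response.payload["result"] = result
        self._render(result, "compare")

    def _fill_split_by(self, response: ResponseSpec) -> None:
        state = self.state
        ds = self.dataset(state.cancer_type)
        result = explorer.split_by(ds, state.gene, response.payload["partition_gene"])
        if result.p_value is None:
            response.speech_text = (
                f"Every eligible sample falls in one {response.payload['partition_gene']} "
                f"group; no test performed."
            )
        else:
            response.speech_text = (
                f"{state.gene} expression in {ds.cancer_type}: mean "
                f"{result.group_mutant.mean:.2f} in {response.payload['partition_gene']}-mutant "
                f"samples (n={result.group_mutant.n}) versus {result.group_wildtype.mean:.2f} "
                f"in wildtype (n={result.group_wildtype.n}); rank-sum p = {result.p_value:.2g}."
            )
        response.payload["result"] = result
        self._render(result, "split_by")

    # -- persistence -------------------------------------------------------

    def save_session(self, path: str | Path) -> None:
        self.state.save(path)

    def load_session(self, path: str | Path) -> None:
        if Path(path).exists():
            self.state = NavigationState.load(path)
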