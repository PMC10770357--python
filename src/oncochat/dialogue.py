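"""Three-slot conversational navigation state and intent handling.

The conversation is modelled as a finite state machine over three
attributes — GENE, CANCER TYPE and DATA TYPE.  A fresh session starts
with all slots empty; each accepted utterance updates exactly one slot,
in any order, and the filled pattern of the state (plus the intent kind)
fully determines the class of response: prompt for a missing attribute,
an overview ranking when the gene is still open, a gene-level summary
when all three are set, or the compare / split-by analytic views.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Any

from .oov_mapper import AttributeType, MatchResult, MatchStage


@dataclass(frozen=True)
class NavigationState:
    """Pure-value session state; update operations return new states."""

    gene: str | None = None
    cancer_type: str | None = None
    data_type: str | None = None
    session_id: str = "default"

    _SLOTS = {
        AttributeType.GENE: "gene",
        AttributeType.CANCER_TYPE: "cancer_type",
        AttributeType.DATA_TYPE: "data_type",
    }

    def get(self, attribute_type: AttributeType) -> str | None:
        return getattr(self, self._SLOTS[AttributeType(attribute_type)])

    def filled(self) -> set[AttributeType]:
        return {a for a, slot in self._SLOTS.items() if getattr(self, slot) is not None}

    def to_dict(self) -> dict[str, Any]:
        return {
            "gene": self.gene,
            "cancer_type": self.cancer_type,
            "data_type": self.data_type,
            "session_id": self.session_id,
        }

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "NavigationState":
        return cls(**payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NavigationState":
        return cls.from_dict(json.loads(Path(path).read_text()))


def new_session(session_id: str = "default") -> NavigationState:
    """All-empty state for a fresh session."""
    return NavigationState(session_id=session_id)


def apply_attribute(
    state: NavigationState, attribute_type: AttributeType, value: str
) -> NavigationState:
    """Replace one slot with a canonical value, leaving the others intact.

    This is what makes "How about PIK3CA?" work mid-conversation: the gene
    slot switches while cancer type and data type are retained.
    """
    slot = NavigationState._SLOTS.get(AttributeType(attribute_type))
    if slot is None:  # pragma: no cover - enum coercion raises first
        raise ValueError(f"unknown attribute type: {attribute_type!r}")
    return replace(state, **{slot: value})


def reset_session(state: NavigationState) -> NavigationState:
    return new_session(state.session_id)


class IntentKind(str, Enum):
    NAVIGATE = "NAVIGATE"
    COMPARE = "COMPARE"
    SPLIT_BY = "SPLIT_BY"
    RESET = "RESET"
    HELP = "HELP"


@dataclass(frozen=True)
class Intent:
    kind: IntentKind
    #: NAVIGATE: (attribute_type, value); COMPARE: (attribute_type, value_b);
    #: SPLIT_BY: partition gene symbol; RESET/HELP: None.
    payload: Any = None


class ResponseClass(str, Enum):
    PROMPT_MISSING = "PROMPT_MISSING"
    OVERVIEW_LIST = "OVERVIEW_LIST"
    GENE_SUMMARY = "GENE_SUMMARY"
    COMPARE_VIEW = "COMPARE_VIEW"
    SPLITBY_VIEW = "SPLITBY_VIEW"
    ERROR_TEXT = "ERROR_TEXT"


@dataclass
class ResponseSpec:
    response_class: ResponseClass
    speech_text: str
    #: Analysis request descriptor consumed by the explorer layer.
    payload: dict[str, Any] = field(default_factory=dict)


# Keyword triggers standing in for a voice platform's interaction model.
_COMPARE_RE = re.compile(r"\bcompare\b(?:.*?\bwith\b\s*(?P<b>.+))?", re.IGNORECASE)
_SPLIT_RE = re.compile(r"\bsplit\s+by\b\s*(?P<g>.+)?", re.IGNORECASE)
_RESET_RE = re.compile(r"^\s*(reset|start over)\s*$", re.IGNORECASE)
_HELP_RE = re.compile(r"^\s*help\s*$", re.IGNORECASE)

#: Quantitative data types eligible as the split-by response variable.
QUANTITATIVE_DATA_TYPES = {"gene expression"}

#: Prompting order for unfilled attributes.
PROMPT_ORDER = (AttributeType.DATA_TYPE, AttributeType.CANCER_TYPE, AttributeType.GENE)

_PROMPT_TEXT = {
    AttributeType.DATA_TYPE: 'Which data type? For example, say "mutations".',
    AttributeType.CANCER_TYPE: 'Which cancer type? For example, say "breast cancer".',
    AttributeType.GENE: 'Which gene? For example, say "TP53".',
}


@dataclass(frozen=True)
class RawIntent:
    """Trigger-phrase scan result; payload text still needs term resolution."""

    kind: IntentKind
    payload_text: str | None = None


def scan_triggers(raw_text: str) -> RawIntent | None:
    """Detect compare / split-by / reset / help trigger phrases."""
    if _RESET_RE.match(raw_text):
        return RawIntent(IntentKind.RESET)
    if _HELP_RE.match(raw_text):
        return RawIntent(IntentKind.HELP)
    m = _SPLIT_RE.search(raw_text)
    if m:
        return RawIntent(IntentKind.SPLIT_BY, (m.group("g") or "").strip() or None)
    m = _COMPARE_RE.search(raw_text)
    if m:
        return RawIntent(IntentKind.COMPARE, (m.group("b") or "").strip() or None)
    return None


def parse_intent(match: MatchResult, state: NavigationState, raw_text: str) -> Intent:
    """Turn a trigger scan plus a term-resolution result into an intent.

    `match` is the mapper's resolution of the trigger payload (for compare
    and split-by) or of the whole utterance (for navigation).
    """
    trigger = scan_triggers(raw_text)
    if trigger is not None:
        if trigger.kind is IntentKind.RESET:
            return Intent(IntentKind.RESET)
        if trigger.kind is IntentKind.HELP:
            return Intent(IntentKind.HELP)
        if not match.resolved:
            return Intent(IntentKind.HELP)
        if trigger.kind is IntentKind.SPLIT_BY:
            return Intent(IntentKind.SPLIT_BY, match.value)
        return Intent(IntentKind.COMPARE, (match.attribute_type, match.value))
    if match.stage is MatchStage.UNRESOLVED:
        return Intent(IntentKind.HELP)
    return Intent(IntentKind.NAVIGATE, (match.attribute_type, match.value))


def resolve_response(state: NavigationState, intent: Intent) -> ResponseSpec:
    """Select the response class for the current state and intent.

    Total over all eight fill patterns and every intent kind; analytic
    payloads are descriptors executed by the explorer layer.
    """
    kind = IntentKind(intent.kind)
    if kind is IntentKind.RESET:
        return ResponseSpec(
            ResponseClass.PROMPT_MISSING,
            "Starting over. " + _PROMPT_TEXT[PROMPT_ORDER[0]],
            {"op": "none"},
        )
    if kind is IntentKind.HELP:
        return ResponseSpec(
            ResponseClass.ERROR_TEXT,
            "I did not catch a supported gene, cancer type or data type. "
            'You can also say "compare ... with ...", "split by <gene>", or "reset".',
            {"op": "none"},
        )
    if kind is IntentKind.COMPARE:
        if intent.payload is None:
            return ResponseSpec(
                ResponseClass.ERROR_TEXT,
                'To compare, name the second value: e.g. "compare with mutations".',
                {"op": "none"},
            )
        attr, value_b = intent.payload
        attr = AttributeType(attr)
        value_a = state.get(attr)
        if value_a is None:
            return ResponseSpec(
                ResponseClass.ERROR_TEXT,
                f"Set a {attr.value.replace('_', ' ').lower()} first, then compare against {value_b}.",
                {"op": "none"},
            )
        return ResponseSpec(
            ResponseClass.COMPARE_VIEW,
            f"Comparing {value_a} with {value_b}.",
            {
                "op": "compare",
                "attribute_type": attr.value,
                "value_a": value_a,
                "value_b": value_b,
                "state": state.to_dict(),
            },
        )
    if kind is IntentKind.SPLIT_BY:
        missing = [a for a in (AttributeType.GENE, AttributeType.CANCER_TYPE, AttributeType.DATA_TYPE) if state.get(a) is None]
        if intent.payload is None or missing:
            return ResponseSpec(
                ResponseClass.ERROR_TEXT,
                "Split-by needs a gene, a cancer type and a quantitative data "
                'type set, plus a partition gene: e.g. "split by TP53".',
                {"op": "none"},
            )
        if state.data_type not in QUANTITATIVE_DATA_TYPES:
            return ResponseSpec(
                ResponseClass.ERROR_TEXT,
                f'Split-by needs a quantitative data type such as "gene expression"; '
                f"the current data type is {state.data_type}.",
                {"op": "none"},
            )
        return ResponseSpec(
            ResponseClass.SPLITBY_VIEW,
            f"Splitting {state.gene} {state.data_type} by {intent.payload} mutation status.",
            {
                "op": "split_by",
                "quant_gene": state.gene,
                "partition_gene": intent.payload,
                "state": state.to_dict(),
            },
        )
    # NAVIGATE (or any future kind defaulting to state-driven dispatch)
    filled = state.filled()
    if AttributeType.DATA_TYPE in filled and AttributeType.CANCER_TYPE in filled:
        if AttributeType.GENE in filled:
            return ResponseSpec(
                ResponseClass.GENE_SUMMARY,
                f"Here is the {state.gene} {state.data_type} summary for {state.cancer_type}.",
                {"op": "gene_summary", "state": state.to_dict()},
            )
        return ResponseSpec(
            ResponseClass.OVERVIEW_LIST,
            f"Top genes by {state.data_type} in {state.cancer_type}.",
            {"op": "overview", "state": state.to_dict()},
        )
    for attr in PROMPT_ORDER:
        if attr not in filled:
            return ResponseSpec(
                ResponseClass.PROMPT_MISSING, _PROMPT_TEXT[attr], {"op": "none"}
            )
    # gene-only / gene+data-type states fall through to the cancer-type prompt
    return ResponseSpec(  # pragma: no cover - PROMPT_ORDER covers all gaps
        ResponseClass.PROMPT_MISSING, _PROMPT_TEXT[AttributeType.GENE], {"op": "none"}
    )
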