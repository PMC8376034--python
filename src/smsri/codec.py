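"""Coded-SMS message grammar: WK / FS / OS messages.

Health workers summarise each vaccination session as a short coded text:
a message-type prefix (``WK`` weekly plan, ``FS`` fixed-post session,
``OS`` outreach session) followed by letter+number tokens, e.g. ``a15``
meaning 15 children received BCG and ``f30`` meaning 30 received measles
vaccine. The code table maps each letter to a semantic field (measure +
antigen); it is a configuration artifact so alternative tables can be
dropped in from YAML/JSON.

Decoding is total: any text yields either a :class:`CodedReport` (possibly
with issues attached) or a hard reject when the message type itself cannot
be recognised.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

MESSAGE_TYPES = ("WK", "FS", "OS")

ANTIGENS = (
    "BCG",
    "OPV",
    "PENTA1",
    "PENTA2",
    "PENTA3",
    "IPV",
    "MEASLES",
    "YELLOW_FEVER",
)

#: Shared-vial pseudo-antigen: pentavalent doses travel in one vial while
#: children counts are recorded per dose number (PENTA1..3).
PENTA_SHARED = "PENTA"

MEASURES = (
    "children_vaccinated",
    "doses_opened",
    "planned_sessions",
    "conducted_sessions",
)

SESSION_TYPES = ("fixed_post", "outreach")

#: Values above this cap are flagged out-of-range by validate/decode.
MAX_VALUE = 9999


class CodecError(ValueError):
    pass


class UnclassifiableMessage(CodecError):
    """The message type prefix cannot be recognised: hard reject."""


@dataclass(frozen=True)
class CodeField:
    """Semantic meaning of one letter within one message type."""

    measure: str
    antigen: str | None = None
    session_type: str | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise CodecError(f"unknown measure {self.measure!r}")
        if self.antigen is not None and self.antigen not in ANTIGENS + (PENTA_SHARED,):
            raise CodecError(f"unknown antigen {self.antigen!r}")


@dataclass
class CodeTable:
    """Ordered letter -> field maps, one per message type."""

    field_map: dict[str, dict[str, CodeField]]

    def __post_init__(self) -> None:
        for mtype, letters in self.field_map.items():
            if mtype not in MESSAGE_TYPES:
                raise CodecError(f"unknown message type {mtype!r}")
            for letter in letters:
                if not (len(letter) == 1 and letter.isalpha()):
                    raise CodecError(f"{mtype}: bad letter {letter!r}")
                if letter != letter.lower():
                    raise CodecError(f"{mtype}: letters must be lowercase: {letter!r}")
        n_wk = len(self.field_map.get("WK", {}))
        if n_wk != 2:
            raise CodecError(f"WK must carry exactly 2 fields, got {n_wk}")
        for mtype in ("FS", "OS"):
            n = len(self.field_map.get(mtype, {}))
            if n != 15:
                raise CodecError(f"{mtype} must carry exactly 15 fields, got {n}")

    def letters(self, message_type: str) -> list[str]:
        return list(self.field_map[message_type])

    def field(self, message_type: str, letter: str) -> CodeField:
        return self.field_map[message_type][letter]


def _session_fields() -> dict[str, CodeField]:
    """15 fields per session message: 8 children counts, 6 doses counts
    (penta shares one vial code), and the conducted-session count."""
    children_order = ["BCG", "OPV", "PENTA1", "PENTA2", "PENTA3", "MEASLES",
                      "YELLOW_FEVER", "IPV"]
    doses_order = ["BCG", "OPV", PENTA_SHARED, "MEASLES", "YELLOW_FEVER", "IPV"]
    fields: dict[str, CodeField] = {}
    for letter, antigen in zip("abcdefgh", children_order):
        fields[letter] = CodeField("children_vaccinated", antigen)
    for letter, antigen in zip("ijklmn", doses_order):
        fields[letter] = CodeField("doses_opened", antigen)
    fields["o"] = CodeField("conducted_sessions")
    return fields


def default_code_table() -> CodeTable:
    """The packaged default table.

    Letter ``a`` is BCG children and ``f`` is measles children; the WK
    message carries the planned fixed-post and outreach session counts.
    """
    return CodeTable(
        field_map={
            "WK": {
                "a": CodeField("planned_sessions", session_type="fixed_post"),
                "b": CodeField("planned_sessions", session_type="outreach"),
            },
            "FS": _session_fields(),
            "OS": _session_fields(),
        }
    )


def load_code_table(path: str | Path) -> CodeTable:
    """Load a code table from YAML or JSON.

    Schema: ``{message_type: {letter: {measure, antigen?, session_type?}}}``.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    field_map = {
        mtype: {
            letter: CodeField(
                measure=entry["measure"],
                antigen=entry.get("antigen"),
                session_type=entry.get("session_type"),
            )
            for letter, entry in letters.items()
        }
        for mtype, letters in raw.items()
    }
    return CodeTable(field_map)


def dump_code_table(table: CodeTable, path: str | Path) -> None:
    raw = {
        mtype: {
            letter: {
                k: v
                for k, v in (
                    ("measure", f.measure),
                    ("antigen", f.antigen),
                    ("session_type", f.session_type),
                )
                if v is not None
            }
            for letter, f in letters.items()
        }
        for mtype, letters in table.field_map.items()
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(raw, indent=2))
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass(frozen=True)
class Issue:
    """One decoding/validation problem; never fatal except hard rejects."""

    kind: str  # malformed_token | unknown_letter | duplicate_letter |
               # missing_letter | extra_letter | out_of_range | empty_payload
    detail: str = ""


@dataclass
class CodedReport:
    message_type: str
    values: dict[str, int] = field(default_factory=dict)
    raw_text: str = ""

    def value_for(self, table: CodeTable, measure: str,
                  antigen: str | None = None) -> int | None:
        """Look up the value of the (measure, antigen) field; None if absent."""
        for letter, f in table.field_map[self.message_type].items():
            if f.measure == measure and f.antigen == antigen:
                return self.values.get(letter)
        return None


_TOKEN_RE = re.compile(r"^([A-Za-z])(\d+)$")
_PREFIX_RE = re.compile(r"^(wk|fs|os)\b", re.IGNORECASE)


def decode_message(text: str, table: CodeTable) -> tuple[CodedReport, list[Issue]]:
    """Parse SMS text into a :class:`CodedReport` plus an issue list.

    The message type is recognised from a case-insensitive WK/FS/OS prefix
    token; unknown letters, duplicate letters (last occurrence wins), and
    non-numeric payloads are reported as issues. Missing expected letters
    decode as *absent*, not zero, and are listed as ``missing_letter``
    issues.

    Raises :class:`UnclassifiableMessage` when no prefix matches.
    """
    stripped = text.strip()
    m = _PREFIX_RE.match(stripped)
    if not m:
        raise UnclassifiableMessage(f"no WK/FS/OS prefix in {text[:40]!r}")
    mtype = m.group(1).upper()
    body = stripped[m.end():]
    tokens = [t for t in re.split(r"[\s,;]+", body) if t]
    letters = table.field_map[mtype]
    values: dict[str, int] = {}
    issues: list[Issue] = []
    for token in tokens:
        tm = _TOKEN_RE.match(token)
        if not tm:
            issues.append(Issue("malformed_token", token))
            continue
        letter, payload = tm.group(1).lower(), tm.group(2)
        if letter not in letters:
            issues.append(Issue("unknown_letter", token))
            continue
        value = int(payload)
        if value > MAX_VALUE:
            issues.append(Issue("out_of_range", f"{letter}={value}"))
            value = MAX_VALUE
        if letter in values:
            # Latest correction wins within one message.
            issues.append(Issue("duplicate_letter", letter))
        values[letter] = value
    for letter in letters:
        if letter not in values:
            issues.append(Issue("missing_letter", letter))
    if not values and not tokens:
        issues.append(Issue("empty_payload"))
    return CodedReport(message_type=mtype, values=values, raw_text=text), issues


def encode_report(report: CodedReport, table: CodeTable) -> str:
    """Canonical SMS text: type prefix, then letter tokens in table order.

    Lowercase letters, space-separated, no leading zeros. Raises on letters
    unknown to the table (use :func:`validate_report` for soft checking).
    """
    letters = table.field_map[report.message_type]
    for letter in report.values:
        if letter not in letters:
            raise CodecError(
                f"letter {letter!r} not in {report.message_type} code table"
            )
    tokens = [report.message_type] + [
        f"{letter}{report.values[letter]}"
        for letter in letters
        if letter in report.values
    ]
    return " ".join(tokens)


def validate_report(report: CodedReport, table: CodeTable) -> list[Issue]:
    """Conformance issues: missing/extra letters, out-of-range values.

    Returns an empty list iff the report is fully conformant.
    """
    issues: list[Issue] = []
    expected = table.field_map[report.message_type]
    for letter in expected:
        if letter not in report.values:
            issues.append(Issue("missing_letter", letter))
    for letter, value in report.values.items():
        if letter not in expected:
            issues.append(Issue("extra_letter", letter))
        elif value < 0 or value > MAX_VALUE:
            issues.append(Issue("out_of_range", f"{letter}={value}"))
    return issues
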