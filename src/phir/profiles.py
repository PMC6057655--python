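"""Patient profiles and the preference database.

A profile holds the patient's self-logged medical conditions as free-form
named fields.  Textual field values pass through the same lemma+similarity
concept matcher as documents at entry time; values that parse as numbers
(optionally with a small unit suffix: mm, cm, kg, mg, %) are never
annotated.  The preference database accumulates explicit feedback (1-5 star
ratings, latest rating per user/document wins) and implicit feedback
(clicks, counted), which the recommender turns into ranking boosts.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

from .annotator import Annotation, annotate_document
from .config import DEFAULT_CONFIG, PhirConfig, SUPPORTED_LANGUAGES
from .ontology import OntologyIndex

EVENT_KINDS = ("click", "rating")

_UNIT_SUFFIXES = ("mm", "cm", "kg", "mg", "%", "ml", "g")
_NUMBER_RE = re.compile(r"^[+-]?(\d+([.,]\d+)?|[.,]\d+)$")


class ValidationError(ValueError):
    pass


def is_numeric_field(value: str) -> bool:
    """True when the value is a number, optionally followed by a small unit
    suffix — such fields carry measurements, not annotatable text."""
    v = value.strip().lower()
    if not v:
        return False
    for unit in _UNIT_SUFFIXES:
        if v.endswith(unit):
            v = v[: -len(unit)].strip()
            break
    return bool(_NUMBER_RE.match(v))


@dataclass(frozen=True)
class MedicalCondition:
    """One condition entry: the raw named fields as typed by the patient and
    the concept annotations derived from the textual fields."""

    raw_fields: dict[str, str]
    annotations: tuple[Annotation, ...] = ()


@dataclass
class PatientProfile:
    user_id: str
    language: str = "en"
    conditions: list[MedicalCondition] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.language not in SUPPORTED_LANGUAGES:
            raise ValidationError(f"unsupported language {self.language!r}")

    def concept_annotations(self) -> list[Annotation]:
        return [a for c in self.conditions for a in c.annotations]

    def concept_ids(self) -> list[str]:
        return sorted({a.concept_id for a in self.concept_annotations()})


def add_condition(
    profile: PatientProfile,
    fields: dict[str, str],
    ontology: OntologyIndex,
    threshold: float | None = None,
    config: PhirConfig = DEFAULT_CONFIG,
) -> MedicalCondition:
    """Annotate and append a condition entry to the profile.

    Textual values are concatenated and matched like document content;
    numeric values (with or without unit suffixes) are skipped.  Raises
    :class:`ValidationError` when every field is empty.
    """
    if not fields or all(not str(v).strip() for v in fields.values()):
        raise ValidationError("condition requires at least one non-empty field")
    if threshold is not None:
        config = PhirConfig(**{**config.to_dict(), "similarity_threshold": threshold})
    textual = [
        str(v).strip()
        for v in fields.values()
        if str(v).strip() and not is_numeric_field(str(v))
    ]
    annotations = annotate_document(
        ". ".join(textual), (), ontology, profile.language, config=config
    ) if textual else ()
    condition = MedicalCondition(
        raw_fields={k: str(v) for k, v in fields.items()}, annotations=tuple(annotations)
    )
    profile.conditions.append(condition)
    return condition


@dataclass(frozen=True)
class PreferenceEvent:
    """A click or a 1-5 star rating by a user on a document."""

    user_id: str
    doc_id: str
    kind: str
    rating_value: int | None = None
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"kind {self.kind!r} not in {EVENT_KINDS}")
        if self.kind == "rating":
            if self.rating_value is None or not 1 <= self.rating_value <= 5:
                raise ValidationError("rating_value must be an int in [1, 5]")
        elif self.rating_value is not None:
            raise ValidationError("rating_value only valid for kind='rating'")


class PreferenceStore:
    """Append-only event log with derived per-user state: click counts
    accumulate; a new rating on the same (user, doc) supersedes the old."""

    def __init__(self) -> None:
        self.events: list[PreferenceEvent] = []
        self._clicks: dict[tuple[str, str], int] = {}
        self._ratings: dict[tuple[str, str], int] = {}

    def record_event(self, event: PreferenceEvent) -> None:
        self.events.append(event)
        key = (event.user_id, event.doc_id)
        if event.kind == "click":
            self._clicks[key] = self._clicks.get(key, 0) + 1
        else:
            self._ratings[key] = event.rating_value  # supersede

    def click_count(self, user_id: str, doc_id: str) -> int:
        return self._clicks.get((user_id, doc_id), 0)

    def rating(self, user_id: str, doc_id: str) -> int | None:
        return self._ratings.get((user_id, doc_id))

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.events:
                fh.write(
                    json.dumps(
                        {
                            "user_id": e.user_id,
                            "doc_id": e.doc_id,
                            "kind": e.kind,
                            "rating_value": e.rating_value,
                            "timestamp": e.timestamp,
                        }
                    )
                    + "\n"
                )

    @classmethod
    def load(cls, path: str | Path) -> "PreferenceStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if line.strip():
                    d = json.loads(line)
                    store.record_event(PreferenceEvent(**d))
        return store


class ProfileStore:
    """user_id-keyed profile collection with JSON round-trip."""

    def __init__(self) -> None:
        self._profiles: dict[str, PatientProfile] = {}

    def __contains__(self, user_id: str) -> bool:
        return user_id in self._profiles

    def get(self, user_id: str) -> PatientProfile | None:
        return self._profiles.get(user_id)

    def put(self, profile: PatientProfile) -> None:
        self._profiles[profile.user_id] = profile

    def get_or_create(self, user_id: str, language: str = "en") -> PatientProfile:
        if user_id not in self._profiles:
            self._profiles[user_id] = PatientProfile(user_id=user_id, language=language)
        return self._profiles[user_id]

    def save(self, path: str | Path) -> None:
        payload = {
            uid: {
                "user_id": p.user_id,
                "language": p.language,
                "conditions": [
                    {
                        "raw_fields": c.raw_fields,
                        "annotations": [
                            {
                                "concept_id": a.concept_id,
                                "matched_term": a.matched_term,
                                "source_text": a.source_text,
                                "similarity": a.similarity,
                                "origin": a.origin,
                            }
                            for a in c.annotations
                        ],
                    }
                    for c in p.conditions
                ],
            }
            for uid, p in sorted(self._profiles.items())
        }
        Path(path).write_text(
            json.dumps(payload, ensure_ascii=False, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "ProfileStore":
        store = cls()
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        for uid, d in payload.items():
            profile = PatientProfile(user_id=d["user_id"], language=d["language"])
            for c in d.get("conditions", []):
                profile.conditions.append(
                    MedicalCondition(
                        raw_fields=dict(c["raw_fields"]),
                        annotations=tuple(
                            Annotation(**a) for a in c.get("annotations", [])
                        ),
                    )
                )
            store.put(profile)
        return store


def record_event(store: PreferenceStore, event: PreferenceEvent) -> dict:
    """Module-level convenience: validate (already done by the event's own
    invariants), record, acknowledge."""
    store.record_event(event)
    return {"status": "ok"}


def make_event(
    user_id: str,
    doc_id: str,
    kind: str,
    rating_value: int | None = None,
    timestamp: float | None = None,
) -> PreferenceEvent:
    return PreferenceEvent(
        user_id=user_id,
        doc_id=doc_id,
        kind=kind,
        rating_value=rating_value,
        timestamp=time.time() if timestamp is None else timestamp,
    )
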