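"""Text extraction and linguistic preprocessing.

Two responsibilities: (1) turn raw HTML/plain-text bytes into visible text,
dropping script/style/nav boilerplate while preserving reading order;
(2) tokenize, tag parts of speech, and lemmatize, keeping the noun lemmas
that drive concept matching.

The tagger is pluggable.  The shipped backend is a deterministic rule-based
tagger/lemmatizer for English, German, and Italian: a small closed-class
stopword list marks function words, suffix heuristics separate verbs and
adjectives, and plural endings are stripped to form lemmas.  It is crude
compared to a statistical model but hermetic and versionless, which keeps
every downstream result reproducible.  Statistical backends can be
registered under a name via :func:`register_tagger`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Protocol

from .config import POS_TAGS, SUPPORTED_LANGUAGES, logger


class UnsupportedContentError(ValueError):
    """MIME type the extractor cannot handle."""


@dataclass(frozen=True)
class LemmaRecord:
    """One token the tagger kept: surface form, dictionary lemma, coarse POS
    tag, and character offset into the source text."""

    surface: str
    lemma: str
    pos: str
    offset: int

    def __post_init__(self) -> None:
        if not self.lemma:
            raise ValueError("lemma must be non-empty")
        if self.pos not in POS_TAGS:
            raise ValueError(f"pos {self.pos!r} not in {POS_TAGS}")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


# ---------------------------------------------------------------------------
# text extraction
# ---------------------------------------------------------------------------

_NONTEXT_TAGS = ("script", "style", "noscript", "nav", "header", "footer", "aside")


def extract_text(raw: bytes | str, content_type: str = "text/html") -> str:
    """Visible text of a document, in reading order.

    Supports ``text/html`` and ``text/plain``.  Script, style and
    navigation elements are removed.  Returns "" for pages with no text.

    Raises
    ------
    UnsupportedContentError
        For any other MIME type; callers register the resource but skip
        concept annotation of its body.
    """
    mime = content_type.split(";")[0].strip().lower()
    if isinstance(raw, bytes):
        text_in = raw.decode("utf-8", errors="replace")
    else:
        text_in = raw

    if mime == "text/plain":
        return text_in.strip()
    if mime != "text/html":
        raise UnsupportedContentError(f"cannot extract text from {content_type!r}")

    if not text_in.strip():
        return ""
    import lxml.html

    try:
        doc = lxml.html.fromstring(text_in)
    except lxml.etree.ParserError:
        return ""
    for tag in _NONTEXT_TAGS:
        for el in doc.iter(tag):
            el.drop_tree()
    text = doc.text_content()
    # collapse intra-line whitespace but keep block separation as single spaces
    return " ".join(text.split())


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[^\W\d_]+(?:['’-][^\W\d_]+)*", re.UNICODE)


def tokenize(text: str) -> list[tuple[str, int]]:
    """Word tokens with character offsets; alphabetic tokens only."""
    return [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(text)]


# ---------------------------------------------------------------------------
# taggers
# ---------------------------------------------------------------------------


class Tagger(Protocol):
    """Backend contract: tag and lemmatize a text in one language."""

    def tag(self, text: str, language: str) -> list[LemmaRecord]:
        ...  # pragma: no cover


# Function words per language; membership => OTHER.  Small closed classes
# are enough here because only NOUN survives into matching.
_STOPWORDS: dict[str, frozenset[str]] = {
    "en": frozenset(
        """a an the and or but if then than of in on at to for from with without
        by as is are was were be been being am do does did done have has had
        having will would shall should can could may might must not no nor it
        its this that these those there here he she they them his her their my
        your our me you we i who whom whose which what when where why how all
        any both each few more most other some such only own same so too very
        just about into over under again further once during before after
        above below up down out off while because until against between
        through also yet etc""".split()
    ),
    "de": frozenset(
        """der die das den dem des ein eine einen einem einer eines und oder
        aber wenn dann als von in auf an zu für aus mit ohne bei durch ist
        sind war waren sein gewesen werden wird wurde wurden haben hat hatte
        hatten nicht kein keine keinen keinem keiner ich du er sie es wir ihr
        man mein dein sein unser euer dieser diese dieses jener welche was wer
        wo wann warum wie alle viele einige mehr sehr nur auch noch schon so
        dass da weil bis gegen zwischen über unter nach vor seit um am im zum
        zur beim vom""".split()
    ),
    "it": frozenset(
        """il lo la i gli le un uno una e o ma se poi che di a da in con su
        per tra fra è sono era erano essere stato essere avere ha hanno aveva
        avevano non nessun nessuna io tu lui lei noi voi loro mio tuo suo
        nostro vostro questo questa questi queste quello quella chi cosa dove
        quando perché come tutti molti alcuni più molto solo anche ancora già
        così dal del della delle degli dei al alla alle agli ai nel nella
        nelle negli nei sul sulla""".split()
    ),
}

# Suffixes that signal verbs / adjectives in each language (surface, lowercase).
_VERB_SUFFIXES = {
    "en": ("ing", "ized", "ised", "ate", "ify"),
    "de": ("ieren", "iert", "elt", "eln"),
    "it": ("are", "ere", "ire", "ando", "endo", "ato", "uto", "ito"),
}
_ADJ_SUFFIXES = {
    "en": ("ous", "ful", "less", "able", "ible", "ive", "ic", "al", "ary"),
    "de": ("isch", "lich", "bar", "sam", "haft", "ig"),
    "it": ("oso", "osa", "ale", "ile", "ivo", "iva", "ico", "ica"),
}
# Past-tense -ed words that are usually verbs in running text.
_EN_VERB_PAST = ("ed",)


def _lemmatize_noun(token: str, language: str) -> str:
    """Strip plural endings to approximate the dictionary form."""
    t = token.lower()
    if language == "en":
        if t.endswith("ies") and len(t) > 4:
            return t[:-3] + "y"
        if t.endswith(("ses", "xes", "zes", "ches", "shes")) and len(t) > 4:
            return t[:-2]
        if t.endswith("s") and not t.endswith(("ss", "us", "is")) and len(t) > 3:
            return t[:-1]
        return t
    if language == "de":
        for suf in ("nen", "en", "er", "n", "e", "s"):
            if t.endswith(suf) and len(t) - len(suf) >= 4:
                return t[: -len(suf)]
        return t
    if language == "it":
        if len(t) > 4 and t.endswith(("i", "e")):
            # ragazzi -> ragazzo, infezioni -> infezione is ambiguous; map
            # masculine plural -i -> -o, feminine/plural -e kept as-is when
            # the singular is not recoverable
            if t.endswith("hi"):
                return t[:-2] + "o"
            if t.endswith("i"):
                return t[:-1] + "o"
        return t
    return t


class RuleBasedTagger:
    """Deterministic suffix-heuristic tagger/lemmatizer for en/de/it."""

    def tag(self, text: str, language: str) -> list[LemmaRecord]:
        if language not in SUPPORTED_LANGUAGES:
            raise ValueError(f"unsupported language {language!r}")
        records: list[LemmaRecord] = []
        stop = _STOPWORDS[language]
        for surface, offset in tokenize(text):
            low = surface.lower()
            if low in stop or len(low) < 2:
                pos = "OTHER"
                lemma = low
            elif low.endswith(_VERB_SUFFIXES[language]) or (
                language == "en" and low.endswith(_EN_VERB_PAST) and len(low) > 4
            ):
                pos = "VERB"
                lemma = low
            elif low.endswith(_ADJ_SUFFIXES[language]):
                pos = "ADJ"
                lemma = low
            else:
                pos = "NOUN"
                lemma = _lemmatize_noun(surface, language)
            records.append(LemmaRecord(surface=surface, lemma=lemma, pos=pos, offset=offset))
        return records


class DegradedWhitespaceTagger:
    """Fallback for unsupported languages: every alphabetic token of length
    >= 3 is treated as a candidate noun, lowercased as its own lemma."""

    def tag(self, text: str, language: str) -> list[LemmaRecord]:
        return [
            LemmaRecord(surface=s, lemma=s.lower(), pos="NOUN", offset=o)
            for s, o in tokenize(text)
            if len(s) >= 3
        ]


_TAGGERS: dict[str, Callable[[], Tagger]] = {
    "rule": RuleBasedTagger,
    "degraded": DegradedWhitespaceTagger,
}
_DEFAULT_TAGGER = "rule"


def register_tagger(name: str, factory: Callable[[], Tagger]) -> None:
    """Register an alternative tagger backend (e.g. a statistical model)."""
    _TAGGERS[name] = factory


def get_tagger(name: str | None = None) -> Tagger:
    return _TAGGERS[name or _DEFAULT_TAGGER]()


def lemmatize_nouns(
    text: str, language: str, tagger: Tagger | None = None
) -> list[LemmaRecord]:
    """Noun lemma records in document order.

    Unsupported languages fall back to whitespace tokenization with every
    alphabetic token >= 3 chars treated as a candidate noun (logged as
    degraded mode).
    """
    if not text:
        return []
    if tagger is None:
        if language in SUPPORTED_LANGUAGES:
            tagger = get_tagger()
        else:
            logger.warning(
                "language %r unsupported by tagger; degraded whitespace mode", language
            )
            tagger = DegradedWhitespaceTagger()
    return [r for r in tagger.tag(text, language) if r.pos == "NOUN"]
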