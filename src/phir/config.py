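"""Tunable settings for the recommender pipeline.

Every knob that affects matching, scoring, or crawling lives here so a run
is fully described by one :class:`PhirConfig` value.  Defaults follow the
package's declared choices: normalized-Levenshtein threshold 0.85, standard
BM25 constants, title-boosted field weights, bounded multiplicative
feedback coefficients, and polite single-threaded crawling caps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

logger = logging.getLogger("phir")

SUPPORTED_LANGUAGES = ("en", "de", "it")

#: Closed coarse part-of-speech tag set used throughout the pipeline.
POS_TAGS = ("NOUN", "VERB", "ADJ", "OTHER")


@dataclass(frozen=True)
class PhirConfig:
    # concept matching
    similarity_threshold: float = 0.85  # tau: min normalized-Levenshtein similarity
    max_annotations_per_doc: int = 50

    # BM25
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    field_weights: dict[str, float] = field(
        default_factory=lambda: {
            "title": 2.0,
            "content": 1.0,
            "tags": 1.5,
            "concepts": 1.5,
        }
    )

    # preference boosting
    rating_coefficient: float = 0.1   # boost = 1 + coeff * (rating - 3)
    click_coefficient: float = 0.05   # boost = 1 + coeff * min(clicks, click_cap)
    click_cap: int = 4

    # crawler
    max_pages: int = 500
    max_depth: int = 5
    crawl_delay_seconds: float = 1.0

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhirConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PhirConfig":
        """Load overrides from a YAML (or JSON) config file."""
        import json

        text = Path(path).read_text(encoding="utf-8")
        try:
            import yaml  # type: ignore

            data = yaml.safe_load(text)
        except ImportError:  # pragma: no cover - yaml is normally present
            data = json.loads(text)
        return cls.from_dict(data or {})


DEFAULT_CONFIG = PhirConfig()
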