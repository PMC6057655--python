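"""JSON search service.

Exposes the recommender to external applications over HTTP:

  GET  /health                           liveness probe
  GET  /search?q=...&user=...&lang=...&type=...&top_k=...
  POST /feedback   {"user": ..., "doc": ..., "kind": "click"|"rating", "stars": 1-5}
  POST /register   {"url": ..., "title": ..., "type": ..., "lang": ..., "tags": [...]}

Responses are stable-field JSON documents (see ``schemas/`` for the
published result schema); each search hit carries the document's metadata,
its concept ids, the relevance score, its tier in the personalization
hierarchy, and its rank.  The app is a plain WSGI callable, so it can be
served by any WSGI server or exercised in-process without sockets.
"""

from __future__ import annotations

import json
import urllib.parse
from typing import Any, Callable, Iterable

from pydantic import BaseModel, Field, ValidationError as PydanticValidationError

from .annotator import (
    DocumentStore,
    RegistrationEntry,
    RegistrationError,
    register,
)
from .config import DEFAULT_CONFIG, PhirConfig, SUPPORTED_LANGUAGES, logger
from .crawler import Fetcher
from .ontology import OntologyIndex
from .profiles import PreferenceStore, ProfileStore, ValidationError, make_event
from .recommender import Recommender, TieredResult
from .search_index import BlankQueryError, SearchIndex


class ResultDocumentJSON(BaseModel):
    """One search result as served to external applications; all fields are
    always present, lists may be empty."""

    doc_id: str
    url: str
    title: str
    type: str = Field(pattern="^(text|video)$")
    language: str
    tags: list[str]
    concepts: list[str]
    score: float
    tier: int = Field(ge=1, le=3)
    rank: int = Field(ge=1)


class FeedbackRequest(BaseModel):
    user: str
    doc: str
    kind: str = Field(pattern="^(click|rating)$")
    stars: int | None = Field(default=None, ge=1, le=5)


class RegisterRequest(BaseModel):
    url: str
    title: str
    type: str = Field(pattern="^(text|video)$")
    lang: str
    tags: list[str] = Field(default_factory=list)


def canonical_json(payload: Any) -> bytes:
    """Canonical serialized form: sorted keys, no insignificant whitespace."""
    return json.dumps(
        payload, sort_keys=True, separators=(",", ":"), ensure_ascii=False
    ).encode("utf-8")


def result_to_json(result: TieredResult, store: DocumentStore) -> dict:
    doc = store.get(result.doc_id)
    return ResultDocumentJSON(
        doc_id=result.doc_id,
        url=doc.entry.url if doc else "",
        title=doc.entry.title if doc else "",
        type=doc.entry.doc_type if doc else "text",
        language=doc.entry.language if doc else "en",
        tags=list(doc.entry.tags) if doc else [],
        concepts=doc.concept_ids() if doc else [],
        score=result.boosted_score,
        tier=int(result.tier),
        rank=result.final_rank,
    ).model_dump()


class PhirService:
    """WSGI application wrapping a recommender, a document store, and (for
    the register endpoint) the vocabulary."""

    def __init__(
        self,
        recommender: Recommender,
        store: DocumentStore,
        ontology: OntologyIndex | None = None,
        fetcher: Fetcher | None = None,
        config: PhirConfig = DEFAULT_CONFIG,
    ):
        self.recommender = recommender
        self.store = store
        self.ontology = ontology
        self.fetcher = fetcher
        self.config = config

    # -- endpoint logic (framework-free, used directly by tests) -----------

    def http_search(
        self,
        q: str,
        user: str | None = None,
        lang: str = "en",
        type_filter: str | None = None,
        top_k: int = 20,
    ) -> list[dict]:
        """Recommend + serialize.  The type filter (the app's text/video
        tabs) is applied after ranking, preserving relative order and ranks."""
        if lang not in SUPPORTED_LANGUAGES:
            raise ValidationError(f"unsupported language {lang!r}")
        if type_filter is not None and type_filter not in ("text", "video"):
            raise ValidationError(f"invalid type filter {type_filter!r}")
        results = self.recommender.recommend(user, q, language=lang, top_k=top_k)
        payload = [result_to_json(r, self.store) for r in results]
        if type_filter is not None:
            payload = [p for p in payload if p["type"] == type_filter]
        return payload

    def http_feedback(self, body: FeedbackRequest) -> dict:
        event = make_event(
            user_id=body.user,
            doc_id=body.doc,
            kind=body.kind,
            rating_value=body.stars if body.kind == "rating" else None,
        )
        self.recommender.prefs.record_event(event)
        return {"status": "ok"}

    def http_register(self, body: RegisterRequest) -> dict:
        if self.ontology is None:
            raise ValidationError("registration endpoint requires a loaded vocabulary")
        entry = RegistrationEntry(
            url=body.url,
            title=body.title,
            doc_type=body.type,
            language=body.lang,
            tags=tuple(body.tags),
        )
        docs = register(
            entry,
            self.ontology,
            self.store,
            config=self.config,
            fetcher=self.fetcher,
        )
        for doc in docs:
            self.recommender.index.add_document(doc)
        return {"status": "ok", "registered": [d.doc_id for d in docs]}

    # -- WSGI plumbing ------------------------------------------------------

    def __call__(
        self, environ: dict, start_response: Callable
    ) -> Iterable[bytes]:
        method = environ.get("REQUEST_METHOD", "GET")
        path = environ.get("PATH_INFO", "/")
        try:
            if method == "GET" and path == "/health":
                return self._respond(start_response, 200, {"status": "ok"})
            if method == "GET" and path == "/search":
                params = dict(
                    urllib.parse.parse_qsl(environ.get("QUERY_STRING", ""))
                )
                q = params.get("q", "")
                if not q.strip():
                    return self._respond(
                        start_response, 400, {"error": "blank query"}
                    )
                body = self.http_search(
                    q=q,
                    user=params.get("user") or None,
                    lang=params.get("lang", "en"),
                    type_filter=params.get("type") or None,
                    top_k=int(params.get("top_k", "20")),
                )
                return self._respond(start_response, 200, body)
            if method == "POST" and path == "/feedback":
                body = FeedbackRequest.model_validate_json(self._read_body(environ))
                return self._respond(start_response, 200, self.http_feedback(body))
            if method == "POST" and path == "/register":
                body = RegisterRequest.model_validate_json(self._read_body(environ))
                return self._respond(start_response, 200, self.http_register(body))
            return self._respond(start_response, 404, {"error": "not found"})
        except (PydanticValidationError, ValidationError, BlankQueryError, ValueError) as exc:
            return self._respond(start_response, 400, {"error": str(exc)})
        except RegistrationError as exc:
            return self._respond(start_response, 502, {"error": str(exc)})
        except Exception as exc:  # pragma: no cover - last-resort guard
            logger.exception("internal error")
            return self._respond(start_response, 500, {"error": str(exc)})

    @staticmethod
    def _read_body(environ: dict) -> bytes:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        return environ["wsgi.input"].read(length) if length else b"{}"

    @staticmethod
    def _respond(
        start_response: Callable, status: int, payload: Any
    ) -> Iterable[bytes]:
        body = canonical_json(payload)
        reason = {200: "OK", 400: "Bad Request", 404: "Not Found", 500: "Internal Server Error", 502: "Bad Gateway"}.get(status, "")
        start_response(
            f"{status} {reason}",
            [
                ("Content-Type", "application/json; charset=utf-8"),
                ("Content-Length", str(len(body))),
            ],
        )
        return [body]

    def serve(self, port: int = 8080, host: str = "127.0.0.1") -> None:  # pragma: no cover
        from wsgiref.simple_server import make_server

        with make_server(host, port, self) as httpd:
            logger.info("phir service listening on %s:%d", host, port)
            httpd.serve_forever()


class TestClient:
    """Minimal in-process WSGI client (no sockets)."""

    __test__ = False  # not a pytest collection target

    def __init__(self, app: Callable):
        self.app = app

    def request(
        self, method: str, path: str, query: dict | None = None, body: dict | None = None
    ) -> tuple[int, Any, bytes]:
        import io

        raw = json.dumps(body).encode("utf-8") if body is not None else b""
        environ = {
            "REQUEST_METHOD": method,
            "PATH_INFO": path,
            "QUERY_STRING": urllib.parse.urlencode(query or {}),
            "CONTENT_LENGTH": str(len(raw)),
            "wsgi.input": io.BytesIO(raw),
        }
        captured: dict = {}

        def start_response(status: str, headers: list) -> None:
            captured["status"] = int(status.split()[0])
            captured["headers"] = headers

        chunks = b"".join(self.app(environ, start_response))
        return captured["status"], json.loads(chunks or b"null"), chunks

    def get(self, path: str, **query: Any) -> tuple[int, Any, bytes]:
        return self.request("GET", path, query={k: v for k, v in query.items() if v is not None})

    def post(self, path: str, body: dict) -> tuple[int, Any, bytes]:
        return self.request("POST", path, body=body)
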