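"""Same-domain breadth-first crawler.

Starting from a registered seed URL, discovers and fetches every reachable
page on the same host, breadth-first, respecting page and depth caps.  Links
to other domains are recorded but never fetched — the curation boundary is
the registering expert's chosen site.

Transport is injected through the :class:`Fetcher` protocol: HTTP(S) via
urllib for live sites (robots.txt respected), or a local-directory fetcher
mapping paths to files for hermetic tests.
"""

from __future__ import annotations

import time
import urllib.parse
import urllib.request
import urllib.robotparser
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from .config import DEFAULT_CONFIG, logger


class CrawlError(RuntimeError):
    """Seed could not be fetched; nothing was crawled."""


@dataclass(frozen=True)
class FetchedPage:
    """One fetched page: canonical URL, BFS depth from the seed, raw bytes,
    MIME type, and all absolute links discovered in it (on- and off-domain)."""

    url: str
    depth: int
    content: bytes
    content_type: str
    discovered_links: tuple[str, ...] = field(default_factory=tuple)


def normalize_url(url: str, base: str | None = None) -> str | None:
    """Canonical absolute URL: resolve against ``base``, lowercase scheme and
    host, drop default ports and fragments.  Returns None for non-fetchable
    schemes (mailto:, javascript:) or unparsable input."""
    try:
        if base:
            url = urllib.parse.urljoin(base, url)
        parts = urllib.parse.urlsplit(url)
    except ValueError:
        logger.warning("unparsable URL %r", url)
        return None
    scheme = parts.scheme.lower()
    if scheme not in ("http", "https", "file"):
        return None
    host = (parts.hostname or "").lower()
    port = parts.port
    if port and not (
        (scheme == "http" and port == 80) or (scheme == "https" and port == 443)
    ):
        netloc = f"{host}:{port}"
    else:
        netloc = host
    path = parts.path or "/"
    return urllib.parse.urlunsplit((scheme, netloc, path, parts.query, ""))


def _registrable_host(url: str) -> str | None:
    norm = normalize_url(url)
    if norm is None:
        return None
    host = urllib.parse.urlsplit(norm).hostname or ""
    return host[4:] if host.startswith("www.") else host


def same_domain(seed_url: str, candidate_url: str) -> bool:
    """True iff both URLs live on the same registrable host (``www.`` is
    stripped before comparison).  Unparsable URLs compare False."""
    a, b = _registrable_host(seed_url), _registrable_host(candidate_url)
    if a is None or b is None or not a or not b:
        return False
    return a == b


def extract_links(content: bytes, content_type: str, base_url: str) -> list[str]:
    """Absolute, normalized link targets of an HTML page; [] otherwise."""
    if content_type.split(";")[0].strip().lower() != "text/html":
        return []
    import lxml.html

    try:
        doc = lxml.html.fromstring(content.decode("utf-8", errors="replace"))
    except Exception:
        return []
    links: list[str] = []
    seen: set[str] = set()
    for el in doc.iter("a"):
        href = el.get("href")
        if not href:
            continue
        norm = normalize_url(href, base=base_url)
        if norm and norm not in seen:
            seen.add(norm)
            links.append(norm)
    return links


class Fetcher(Protocol):
    def fetch(self, url: str) -> tuple[bytes, str]:
        """Return (content bytes, MIME type) or raise on failure."""
        ...  # pragma: no cover


class HttpFetcher:
    """urllib-based transport; honours robots.txt per host."""

    user_agent = "phir-crawler/0.1"

    def __init__(self, timeout: float = 10.0, respect_robots: bool = True):
        self.timeout = timeout
        self.respect_robots = respect_robots
        self._robots: dict[str, urllib.robotparser.RobotFileParser] = {}

    def _allowed(self, url: str) -> bool:
        if not self.respect_robots:
            return True
        parts = urllib.parse.urlsplit(url)
        root = f"{parts.scheme}://{parts.netloc}"
        if root not in self._robots:
            rp = urllib.robotparser.RobotFileParser(root + "/robots.txt")
            try:
                rp.read()
            except OSError:
                rp.allow_all = True  # unreachable robots.txt => permissive
            self._robots[root] = rp
        return self._robots[root].can_fetch(self.user_agent, url)

    def fetch(self, url: str) -> tuple[bytes, str]:
        if not self._allowed(url):
            raise PermissionError(f"disallowed by robots.txt: {url}")
        req = urllib.request.Request(url, headers={"User-Agent": self.user_agent})
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            ctype = resp.headers.get("Content-Type", "text/html")
            return resp.read(), ctype


class LocalDirectoryFetcher:
    """Maps a fake host to a directory of files, for tests and fixtures.

    ``http://<host>/page.html`` resolves to ``<root>/page.html``; bare ``/``
    resolves to ``index.html``.  No robots handling — the fixture is ours.
    """

    def __init__(self, root: str | Path, host: str = "example.org"):
        self.root = Path(root)
        self.host = host

    def url_for(self, relative_path: str) -> str:
        return f"http://{self.host}/{relative_path.lstrip('/')}"

    def fetch(self, url: str) -> tuple[bytes, str]:
        parts = urllib.parse.urlsplit(url)
        host = (parts.hostname or "").lower()
        if host.removeprefix("www.") != self.host.removeprefix("www."):
            raise FileNotFoundError(f"host {host!r} not served by this fixture")
        rel = parts.path.lstrip("/") or "index.html"
        path = self.root / rel
        if not path.is_file():
            raise FileNotFoundError(path)
        suffix = path.suffix.lower()
        mime = {
            ".html": "text/html",
            ".htm": "text/html",
            ".txt": "text/plain",
        }.get(suffix, "application/octet-stream")
        return path.read_bytes(), mime


def crawl(
    seed_url: str,
    fetcher: Fetcher | None = None,
    max_pages: int = DEFAULT_CONFIG.max_pages,
    max_depth: int = DEFAULT_CONFIG.max_depth,
    delay_seconds: float = 0.0,
) -> list[FetchedPage]:
    """Breadth-first, same-domain crawl from ``seed_url``.

    Every returned page is on the seed's domain; no URL is fetched twice;
    at most ``max_pages`` pages at most ``max_depth`` hops from the seed.
    Off-domain links appear in ``discovered_links`` but are never fetched.
    Individual page failures after the seed are logged and skipped.

    Raises
    ------
    CrawlError
        If the seed itself cannot be fetched.
    """
    if max_pages < 1:
        raise ValueError("max_pages must be >= 1")
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    if fetcher is None:
        fetcher = HttpFetcher()

    seed = normalize_url(seed_url)
    if seed is None:
        raise CrawlError(f"invalid seed URL {seed_url!r}")

    pages: list[FetchedPage] = []
    visited: set[str] = {seed}
    queue: deque[tuple[str, int]] = deque([(seed, 0)])
    first = True

    while queue and len(pages) < max_pages:
        url, depth = queue.popleft()
        try:
            content, ctype = fetcher.fetch(url)
        except Exception as exc:
            if first:
                raise CrawlError(f"seed unreachable: {url} ({exc})") from exc
            logger.warning("skipping unreachable page %s: %s", url, exc)
            continue
        finally:
            first = False
        links = extract_links(content, ctype, base_url=url)
        pages.append(
            FetchedPage(
                url=url,
                depth=depth,
                content=content,
                content_type=ctype,
                discovered_links=tuple(links),
            )
        )
        if depth < max_depth:
            for link in links:
                if link not in visited and same_domain(seed, link):
                    visited.add(link)
                    queue.append((link, depth + 1))
        if delay_seconds and queue:
            time.sleep(delay_seconds)
    return pages
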