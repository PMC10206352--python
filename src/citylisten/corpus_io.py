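"""Reading, filtering and preprocessing of tweet-like records.

The collection stage mirrors a keyword + geo-radius scrape: a record is kept
when any query keyword occurs in its text (case-insensitive substring) and it
lies within a configured great-circle radius of a city point.  The cleaning
stage lowercases, strips URLs and special characters, removes stopwords and
drops documents left with fewer than three tokens, producing a tokenized
corpus with an integer-id vocabulary.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

__all__ = [
    "TweetRecord",
    "CityPoint",
    "TokenizedDoc",
    "PreprocessReport",
    "Vocabulary",
    "EARTH_RADIUS_MILES",
    "default_stopwords",
    "load_stopwords",
    "filter_keyword",
    "haversine_miles",
    "filter_radius",
    "preprocess_text",
    "collect_records",
    "build_corpus",
    "read_records",
    "write_records",
    "write_tokenized_corpus",
    "read_tokenized_corpus",
    "write_vocabulary",
    "read_vocabulary",
    "write_report",
]

#: Mean Earth radius in statute miles (IUGG mean radius 6371.0088 km).
EARTH_RADIUS_MILES = 3958.7613


@dataclass(frozen=True)
class TweetRecord:
    """One raw document: text plus posting time and geo metadata."""

    id: str
    text: str
    timestamp: datetime
    city: str
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat!r}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon!r}")
        if not self.text:
            raise ValueError("record text must be non-empty")


@dataclass(frozen=True)
class CityPoint:
    """A named point of interest with a collection radius in statute miles."""

    name: str
    lat: float
    lon: float
    radius_miles: float = 20.0

    def __post_init__(self) -> None:
        if self.radius_miles <= 0:
            raise ValueError("radius_miles must be positive")


@dataclass(frozen=True)
class TokenizedDoc:
    """A cleaned document: ordered lowercase tokens plus carried metadata."""

    id: str
    tokens: tuple[str, ...]
    timestamp: datetime
    city: str


@dataclass(frozen=True)
class PreprocessReport:
    """Raw/kept counts for the cleaning stage.

    ``deduplicated`` is always False: no duplicate/retweet removal is
    performed, and the report surfaces that explicitly.
    """

    n_raw: int
    n_kept: int
    deduplicated: bool = False

    @property
    def loss_fraction(self) -> float:
        if self.n_raw == 0:
            return 0.0
        return (self.n_raw - self.n_kept) / self.n_raw


class Vocabulary:
    """Bijection between surviving tokens and ids 0..V-1, sorted by token."""

    def __init__(self, tokens: Iterable[str]):
        self._tokens: list[str] = sorted(set(tokens))
        self._index: dict[str, int] = {t: i for i, t in enumerate(self._tokens)}

    def __len__(self) -> int:
        return len(self._tokens)

    def __contains__(self, token: str) -> bool:
        return token in self._index

    def __iter__(self):
        return iter(self._tokens)

    def id_of(self, token: str) -> int:
        return self._index[token]

    def token_of(self, idx: int) -> str:
        return self._tokens[idx]

    @property
    def tokens(self) -> list[str]:
        return list(self._tokens)

    def encode(self, tokens: Sequence[str], skip_oov: bool = True) -> list[int]:
        if skip_oov:
            return [self._index[t] for t in tokens if t in self._index]
        return [self._index[t] for t in tokens]


def default_stopwords() -> frozenset[str]:
    """The fixed English stopword list shipped with the package."""
    text = resources.files("citylisten.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a one-word-per-line stopword file (UTF-8, lowercase)."""
    words = Path(path).read_text("utf-8").split()
    return frozenset(w.lower() for w in words if w)


def filter_keyword(record: TweetRecord, keywords: Sequence[str]) -> bool:
    """True iff any keyword occurs case-insensitively as a substring."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    text = record.text.casefold()
    return any(k.casefold() in text for k in keywords)


def haversine_miles(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance between two (lat, lon) points in statute miles."""
    for lat, lon in (a, b):
        if not -90.0 <= lat <= 90.0 or not -180.0 <= lon <= 180.0:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_MILES * math.asin(min(1.0, math.sqrt(h)))


def filter_radius(record: TweetRecord, city: CityPoint) -> bool:
    """True iff the record lies within the city's collection radius."""
    return haversine_miles((record.lat, record.lon), (city.lat, city.lon)) <= city.radius_miles


# URLs are removed before punctuation stripping: any scheme://... span, or a
# bare t.co/... shortener, up to the next whitespace.
_URL_RE = re.compile(r"(?:[a-z][a-z0-9+.-]*://\S+|\bt\.co/\S+)")
_NON_WORD_RE = re.compile(r"[^a-z0-9']+")


def preprocess_text(text: str, stopwords: frozenset[str] | set[str]) -> list[str]:
    """Clean one text into ordered lowercase tokens.

    Rules, in order: lowercase; delete URL spans; replace every character
    outside ``[a-z0-9']`` with whitespace; split on whitespace; drop
    stopwords.  Apostrophes are kept so contractions survive intact.
    """
    lowered = text.lower()
    no_urls = _URL_RE.sub(" ", lowered)
    words = _NON_WORD_RE.sub(" ", no_urls).split()
    return [w for w in words if w not in stopwords]


def collect_records(
    records: Iterable[TweetRecord],
    keywords: Sequence[str] | None = None,
    cities: Sequence[CityPoint] | None = None,
    window: tuple[datetime, datetime] | None = None,
    language_filter: Callable[[TweetRecord], bool] | None = None,
) -> list[TweetRecord]:
    """Apply the collection filters: keyword, geo-radius, study window.

    ``language_filter`` is a pluggable predicate hook; by default no language
    identification is performed (records are assumed pre-filtered upstream).
    Each filter is skipped when its argument is None.
    """
    by_city = {c.name: c for c in cities} if cities else None
    kept = []
    for rec in records:
        if keywords is not None and not filter_keyword(rec, keywords):
            continue
        if by_city is not None:
            city = by_city.get(rec.city)
            if city is None or not filter_radius(rec, city):
                continue
        if window is not None and not (window[0] <= rec.timestamp <= window[1]):
            continue
        if language_filter is not None and not language_filter(rec):
            continue
        kept.append(rec)
    return kept


def build_corpus(
    records: Sequence[TweetRecord],
    stopwords: frozenset[str] | set[str] | None = None,
    min_tokens: int = 3,
) -> tuple[list[TokenizedDoc], PreprocessReport, Vocabulary]:
    """Clean records into a tokenized corpus, dropping near-empty documents.

    Documents left with fewer than ``min_tokens`` tokens after cleaning and
    stopword removal are discarded (default: single- or double-word tweets).
    The vocabulary covers exactly the tokens of the kept documents.

    Raises ``ValueError`` if no document survives.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    docs: list[TokenizedDoc] = []
    for rec in records:
        tokens = preprocess_text(rec.text, stopwords)
        if len(tokens) >= min_tokens:
            docs.append(TokenizedDoc(rec.id, tuple(tokens), rec.timestamp, rec.city))
    if not docs:
        raise ValueError("no documents survived preprocessing")
    report = PreprocessReport(n_raw=len(records), n_kept=len(docs))
    vocab = Vocabulary(t for d in docs for t in d.tokens)
    return docs, report, vocab


# ---------------------------------------------------------------------------
# File formats: JSONL records, TSV/CSV tables, key-value reports.  UTF-8.
# ---------------------------------------------------------------------------

_RECORD_FIELDS = ("id", "text", "timestamp", "city", "lat", "lon")


def _parse_ts(value: str) -> datetime:
    ts = datetime.fromisoformat(value)
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    return ts


def read_records(path: str | Path) -> list[TweetRecord]:
    """Read records from JSON-lines (``.jsonl``) or delimited (``.csv``/``.tsv``)."""
    path = Path(path)
    records = []
    if path.suffix == ".jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                records.append(_record_from_row(obj))
    else:
        delim = "\t" if path.suffix == ".tsv" else ","
        with path.open("r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh, delimiter=delim):
                records.append(_record_from_row(row))
    return records


def _record_from_row(row: dict) -> TweetRecord:
    return TweetRecord(
        id=str(row["id"]),
        text=str(row["text"]),
        timestamp=_parse_ts(str(row["timestamp"])),
        city=str(row["city"]),
        lat=float(row["lat"]),
        lon=float(row["lon"]),
    )


def write_records(records: Iterable[TweetRecord], path: str | Path) -> None:
    """Write records as JSON-lines with ISO-8601 timestamps."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "id": rec.id,
                "text": rec.text,
                "timestamp": rec.timestamp.isoformat(),
                "city": rec.city,
                "lat": rec.lat,
                "lon": rec.lon,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def write_tokenized_corpus(docs: Iterable[TokenizedDoc], path: str | Path) -> None:
    """One doc per line: id, ISO timestamp, city, space-joined tokens (TSV)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(f"{d.id}\t{d.timestamp.isoformat()}\t{d.city}\t{' '.join(d.tokens)}\n")


def read_tokenized_corpus(path: str | Path) -> list[TokenizedDoc]:
    docs = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            doc_id, ts, city, toks = line.split("\t")
            docs.append(TokenizedDoc(doc_id, tuple(toks.split()), _parse_ts(ts), city))
    return docs


def write_vocabulary(vocab: Vocabulary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, tok in enumerate(vocab):
            fh.write(f"{i}\t{tok}\n")


def read_vocabulary(path: str | Path) -> Vocabulary:
    tokens = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                _, tok = line.rstrip("\n").split("\t")
                tokens.append(tok)
    return Vocabulary(tokens)


def write_report(report: PreprocessReport, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"n_raw={report.n_raw}\n")
        fh.write(f"n_kept={report.n_kept}\n")
        fh.write(f"loss_fraction={report.loss_fraction!r}\n")
        fh.write("deduplication=none\n")
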