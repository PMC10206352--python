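"""Synthetic tweet-corpus generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes: a
Dirichlet-multinomial topic model over a symbolic vocabulary, multi-city
sampling with city-specific topic prevalence, an 18-month study window with
time-varying tweet volume and per-(city, month) emotion mixtures, plus
injected junk (URLs, punctuation runs, stopwords) and emotion marker tokens.
Every draw flows from one seeded generator, so a seed fixes the corpus
byte-for-byte.

Tokens are symbolic (``w0000`` ...); no natural language is generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Sequence

import numpy as np

from .corpus_io import EARTH_RADIUS_MILES, CityPoint, TweetRecord

__all__ = [
    "EMOTIONS",
    "GeneratorConfig",
    "GroundTruth",
    "default_cities",
    "default_city_weights",
    "default_month_weights",
    "default_emotion_mixtures",
    "study_months",
    "emotion_wordlists",
    "junk_pool",
    "generate_corpus",
]

#: The four emotion labels, in fixed alphabetical order.
EMOTIONS = ("anger", "joy", "optimism", "sadness")

# Junk drawn by the noise process.  Every entry vanishes entirely under
# default preprocessing: URLs are deleted as spans, punctuation runs reduce
# to nothing, and the word entries are in the shipped stopword list.
_JUNK_POOL = (
    "https://t.co/x8fk2q",
    "http://example.com/page?q=1",
    "ftp://mirror.net/a.bin",
    "t.co/abc123",
    "!!!",
    "$$$",
    "%%%%",
    "&&&",
    "===>",
    "~~~",
    "the",
    "and",
    "of",
    "no",
    "i",
    "did",
)


def junk_pool() -> tuple[str, ...]:
    """The fixed pool of junk tokens the noise process injects."""
    return _JUNK_POOL


def default_cities() -> list[CityPoint]:
    """The four mid-sized study markets, 20-mile collection radius each."""
    return [
        CityPoint("Kansas City", 39.0997, -94.5786, 20.0),
        CityPoint("Long Beach", 33.7701, -118.1937, 20.0),
        CityPoint("Omaha", 41.2565, -95.9345, 20.0),
        CityPoint("Raleigh", 35.7796, -78.6382, 20.0),
    ]


def default_city_weights() -> dict[str, float]:
    """Per-city sampling shares, proportional to the study's tweet volumes
    (Long Beach dominates, Omaha is smallest)."""
    counts = {"Long Beach": 133844, "Omaha": 8291, "Kansas City": 18332, "Raleigh": 19661}
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


def study_months() -> list[str]:
    """The 18 calendar months Jan 2020 .. Jun 2021 as ``YYYY-MM`` strings."""
    months = []
    for year in (2020, 2021):
        last = 12 if year == 2020 else 6
        months += [f"{year}-{m:02d}" for m in range(1, last + 1)]
    return months


def default_month_weights() -> dict[str, float]:
    """Relative tweet volume per month: a sharp surge in Feb 2020, a drop in
    Mar 2020 with partial recovery in April, a slow decline through late
    2020, a second surge in May 2021 and a sharp fall in June 2021."""
    months = study_months()
    w = dict.fromkeys(months, 1.0)
    w["2020-01"] = 0.4
    w["2020-02"] = 3.0
    w["2020-03"] = 1.0
    w["2020-04"] = 1.6
    w["2020-05"] = 1.4
    w["2020-09"] = 0.7
    w["2020-10"] = 0.9
    w["2020-11"] = 0.9
    w["2020-12"] = 0.9
    w["2021-01"] = 0.8
    w["2021-02"] = 0.8
    w["2021-03"] = 0.8
    w["2021-04"] = 1.2
    w["2021-05"] = 2.6
    w["2021-06"] = 0.6
    return w


# Baseline mood regimes.  2020 skews negative; each city has a positivity
# surge month in 2021 (Feb for Long Beach, Apr elsewhere) followed by an
# anger spike in May 2021.
_MIX_NEGATIVE = {"anger": 0.33, "joy": 0.18, "optimism": 0.17, "sadness": 0.32}
_MIX_POSITIVE = {"anger": 0.17, "joy": 0.30, "optimism": 0.35, "sadness": 0.18}
_MIX_ANGRY = {"anger": 0.50, "joy": 0.15, "optimism": 0.15, "sadness": 0.20}


def default_emotion_mixtures(
    cities: Sequence[str], months: Sequence[str]
) -> dict[tuple[str, str], dict[str, float]]:
    surge = {c: "2021-04" for c in cities}
    if "Long Beach" in surge:
        surge["Long Beach"] = "2021-02"
    mixtures = {}
    for c in cities:
        for m in months:
            if m == "2021-05":
                mix = _MIX_ANGRY
            elif surge[c] <= m <= "2021-04" and m.startswith("2021"):
                mix = _MIX_POSITIVE
            else:
                mix = _MIX_NEGATIVE
            mixtures[(c, m)] = dict(mix)
    return mixtures


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``alpha`` is the per-document topic-mixture concentration (small values
    give near-single-topic tweets), ``beta`` the within-block topic-word
    concentration.  Topic word distributions are "disjoint-leaning": each
    topic places ``block_mass`` of its probability on its own vocabulary
    block and spreads the remainder over the other blocks.
    """

    k_true: int = 4
    V: int = 500
    D: int = 2000
    alpha: float = 0.1
    beta: float = 0.1
    block_mass: float = 0.95
    doc_length_mean: float = 12.0
    doc_length_dispersion: float = 5.0  # negative-binomial shape; larger = tighter
    min_doc_length: int = 3
    cities: list[CityPoint] = field(default_factory=default_cities)
    city_weights: dict[str, float] | None = None
    topic_weights: Sequence[float] | None = None  # global prevalence tilt
    prevalence_concentration: float = 50.0  # mild per-city Dirichlet perturbation
    months: list[str] = field(default_factory=study_months)
    month_weights: dict[str, float] | None = None
    emotion_mixtures: dict[tuple[str, str], dict[str, float]] | None = None
    noise_rate: float = 0.05
    marker_rate: float = 0.1
    n_markers_per_emotion: int = 8
    keyword: str | None = "covid"
    seed: int = 0

    def validate(self) -> None:
        if self.D < 1:
            raise ValueError("D must be >= 1")
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        n_reserved = 4 * self.n_markers_per_emotion
        if self.V - n_reserved < self.k_true:
            raise ValueError(
                f"V={self.V} too small for k_true={self.k_true} topics "
                f"plus {n_reserved} reserved marker words"
            )
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 0.0 <= self.marker_rate < 1.0:
            raise ValueError("marker_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Latent state of a generated corpus.

    ``phi_true`` (k x V) and ``theta_true`` (D x k) are the row-stochastic
    topic-word and document-topic matrices; ``vocab_tokens`` maps column ids
    to token strings (marker words occupy the last columns and carry zero
    topic mass).
    """

    phi_true: np.ndarray
    theta_true: np.ndarray
    topic_label: np.ndarray  # per-doc argmax of theta_true
    emotion_label: list[str]
    city: list[str]
    month: list[str]
    injected_junk: list[list[str]]
    vocab_tokens: list[str]
    marker_words: dict[str, list[str]]


def _vocab_tokens(config: GeneratorConfig) -> tuple[list[str], dict[str, list[str]]]:
    n_res = 4 * config.n_markers_per_emotion
    n_plain = config.V - n_res
    tokens = [f"w{i:04d}" for i in range(n_plain)]
    markers: dict[str, list[str]] = {}
    for emo in EMOTIONS:
        markers[emo] = [f"{emo}mark{j:02d}" for j in range(config.n_markers_per_emotion)]
        tokens.extend(markers[emo])
    return tokens, markers


def emotion_wordlists(config: GeneratorConfig) -> dict[str, set[str]]:
    """Four disjoint marker-token sets, one per emotion label."""
    config.validate()
    _, markers = _vocab_tokens(config)
    return {emo: set(words) for emo, words in markers.items()}


def _draw_phi(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Disjoint-leaning topic-word matrix over the non-marker vocabulary."""
    k, V = config.k_true, config.V
    n_plain = V - 4 * config.n_markers_per_emotion
    blocks = np.array_split(np.arange(n_plain), k)
    phi = np.zeros((k, V))
    for t in range(k):
        own = blocks[t]
        others = np.setdiff1d(np.arange(n_plain), own)
        phi[t, own] = config.block_mass * rng.dirichlet(np.full(len(own), config.beta))
        if len(others) and config.block_mass < 1.0:
            phi[t, others] = (1.0 - config.block_mass) * rng.dirichlet(
                np.full(len(others), config.beta)
            )
        phi[t] /= phi[t].sum()
    return phi


def _city_prevalence(config: GeneratorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    base = np.ones(config.k_true)
    if config.topic_weights is not None:
        base = np.asarray(config.topic_weights, dtype=float)
        if len(base) != config.k_true or np.any(base <= 0):
            raise ValueError("topic_weights must be k_true positive values")
    base = base / base.sum()
    prev = {}
    for city in config.cities:
        tilt = rng.dirichlet(config.prevalence_concentration * config.k_true * base)
        prev[city.name] = tilt / tilt.sum()
    return prev


def _point_in_radius(city: CityPoint, rng: np.random.Generator) -> tuple[float, float]:
    # Uniform over the disc: r ~ R*sqrt(u).  Small-angle planar approximation
    # is adequate for a 20-mile radius.
    r = city.radius_miles * np.sqrt(rng.random()) * 0.999
    ang = rng.random() * 2 * np.pi
    dlat = (r * np.cos(ang) / EARTH_RADIUS_MILES) * (180.0 / np.pi)
    dlon = (r * np.sin(ang) / (EARTH_RADIUS_MILES * np.cos(np.radians(city.lat)))) * (
        180.0 / np.pi
    )
    return city.lat + dlat, city.lon + dlon


def _timestamp_in_month(month: str, rng: np.random.Generator) -> datetime:
    year, mon = int(month[:4]), int(month[5:7])
    start = datetime(year, mon, 1, tzinfo=timezone.utc)
    nxt = datetime(year + (mon == 12), mon % 12 + 1, 1, tzinfo=timezone.utc)
    span = (nxt - start).total_seconds()
    return start + timedelta(seconds=float(rng.random()) * span)


def _doc_length(config: GeneratorConfig, rng: np.random.Generator) -> int:
    # Negative-binomial count distribution truncated (by rejection) to the
    # minimum real-token length, mimicking short tweets.
    shape = config.doc_length_dispersion
    p = shape / (shape + config.doc_length_mean)
    while True:
        n = int(rng.negative_binomial(shape, p))
        if n >= config.min_doc_length:
            return n


def generate_corpus(config: GeneratorConfig) -> tuple[list[TweetRecord], GroundTruth]:
    """Generate a corpus of tweet-like records plus its latent ground truth.

    Per document: a city and month are sampled from the configured weights,
    the topic mixture theta_d ~ Dirichlet(alpha * city prevalence), tokens
    from the mixture distribution sum_t theta_dt phi_t, the emotion label
    from the (city, month) mixture.  Noise replaces tokens with junk at
    ``noise_rate``; emotion markers are salted in at ``marker_rate``; the
    query keyword, when set, is prepended so collection filters pass.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    vocab_tokens, markers = _vocab_tokens(config)
    phi = _draw_phi(config, rng)
    prevalence = _city_prevalence(config, rng)

    city_names = [c.name for c in config.cities]
    cw = config.city_weights or default_city_weights()
    city_p = np.array([cw.get(c, 0.0) for c in city_names], dtype=float)
    if city_p.sum() <= 0:
        city_p = np.ones(len(city_names))
    city_p /= city_p.sum()

    mw = config.month_weights or default_month_weights()
    month_p = np.array([mw.get(m, 1.0) for m in config.months], dtype=float)
    month_p /= month_p.sum()

    mixtures = config.emotion_mixtures or default_emotion_mixtures(city_names, config.months)
    cities_by_name = {c.name: c for c in config.cities}

    D, k = config.D, config.k_true
    theta = np.empty((D, k))
    records: list[TweetRecord] = []
    emotion_label: list[str] = []
    doc_city: list[str] = []
    doc_month: list[str] = []
    injected: list[list[str]] = []

    for d in range(D):
        ci = int(rng.choice(len(city_names), p=city_p))
        city = city_names[ci]
        month = config.months[int(rng.choice(len(config.months), p=month_p))]
        theta[d] = rng.dirichlet(config.alpha * k * prevalence[city])
        n_d = _doc_length(config, rng)
        mix = theta[d] @ phi
        word_ids = rng.choice(config.V, size=n_d, p=mix)
        tokens = [vocab_tokens[w] for w in word_ids]

        junk_d: list[str] = []
        if config.noise_rate > 0:
            for pos in range(n_d):
                if rng.random() < config.noise_rate:
                    j = _JUNK_POOL[int(rng.integers(len(_JUNK_POOL)))]
                    tokens[pos] = j
                    junk_d.append(j)

        mix_emo = mixtures[(city, month)]
        emo = str(rng.choice(EMOTIONS, p=[mix_emo[e] for e in EMOTIONS]))
        if config.marker_rate > 0:
            n_mark = int(rng.binomial(n_d, config.marker_rate))
            for _ in range(n_mark):
                m_tok = markers[emo][int(rng.integers(len(markers[emo])))]
                tokens.insert(int(rng.integers(len(tokens) + 1)), m_tok)

        if config.keyword:
            tokens.insert(0, config.keyword)

        lat, lon = _point_in_radius(cities_by_name[city], rng)
        ts = _timestamp_in_month(month, rng)
        records.append(
            TweetRecord(
                id=f"d{d:06d}",
                text=" ".join(tokens),
                timestamp=ts,
                city=city,
                lat=float(lat),
                lon=float(lon),
            )
        )
        emotion_label.append(emo)
        doc_city.append(city)
        doc_month.append(month)
        injected.append(junk_d)

    truth = GroundTruth(
        phi_true=phi,
        theta_true=theta,
        topic_label=np.argmax(theta, axis=1),
        emotion_label=emotion_label,
        city=doc_city,
        month=doc_month,
        injected_junk=injected,
        vocab_tokens=vocab_tokens,
        marker_words=markers,
    )
    return records, truth
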