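"""Boolean keyword queries and the term-mining step that builds them.

A query is a conjunction of OR-groups ("clauses") of words and quoted
phrases, e.g. ``(bogong OR bogan) AND moth``.  Three query types are
distinguished by how they name the species: *taxonomic* (scientific name),
*common_name* (vernacular name), and *symptomatic* (descriptive words that
indicate presence without naming the species).  Symptomatic queries are
built by mining frequent terms from the hits of a common-name search.

Matching semantics are exact-token: a word term matches a whole token of
the text (tokens are maximal Unicode-letter runs after URL removal and
stripping of ``#``/``@``), and a phrase matches consecutive tokens.  No
stemming is applied at match time unless ``stem_match=True`` — "moth" does
not match "moths" by default, and "#mothapocalypse" tokenizes to the single
token "mothapocalypse" so it matches neither.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from ._porter import stem
from .tweetstore import CoveragePeriod, TweetRecord

__all__ = [
    "Term",
    "Clause",
    "Query",
    "QueryParseError",
    "PreprocessConfig",
    "parse_query",
    "match",
    "run_query",
    "tokenize",
    "preprocess",
    "term_frequencies",
    "frequent_terms",
    "build_symptomatic_query",
    "default_stopwords",
    "read_query_file",
]

QUERY_TYPES = ("taxonomic", "common_name", "symptomatic")


class QueryParseError(ValueError):
    """Raised on malformed query text; carries the character position."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


@dataclass(frozen=True)
class Term:
    """A single lowercase word, or a quoted phrase of >= 2 tokens."""

    kind: str  # "word" | "phrase"
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("word", "phrase"):
            raise ValueError(f"bad term kind {self.kind!r}")
        if not self.tokens or any(not t for t in self.tokens):
            raise ValueError("term tokens must be non-empty")
        if any(t != t.lower() for t in self.tokens):
            raise ValueError("term tokens must be lowercase")
        if self.kind == "word" and len(self.tokens) != 1:
            raise ValueError("word terms have exactly one token")

    def serialize(self) -> str:
        if self.kind == "phrase":
            return '"' + " ".join(self.tokens) + '"'
        return self.tokens[0]


@dataclass(frozen=True)
class Clause:
    """Terms combined by OR."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("clause must have at least one term")

    def serialize(self) -> str:
        inner = " OR ".join(t.serialize() for t in self.terms)
        return f"({inner})" if len(self.terms) > 1 else inner


@dataclass(frozen=True)
class Query:
    """Conjunction of clauses, tagged with how the query names the species."""

    clauses: tuple[Clause, ...]
    query_type: str = "common_name"
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("query must have at least one clause")
        if self.query_type not in QUERY_TYPES:
            raise ValueError(f"bad query type {self.query_type!r}")

    def serialize(self) -> str:
        return " AND ".join(c.serialize() for c in self.clauses)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Query):
            return NotImplemented
        return self.clauses == other.clauses and self.query_type == other.query_type

    def __hash__(self) -> int:
        return hash((self.clauses, self.query_type))


# --- parsing -----------------------------------------------------------

_QUOTE_OPEN = "\"“‘'"
_QUOTE_CLOSE = {'"': '"', "“": "”", "‘": "’", "'": "'"}

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()\"“”‘’']+|.)")


def _lex(text: str) -> list[tuple[str, str, int]]:
    """Tokens: (kind, value, position); kinds: lparen rparen word phrase and or."""
    out: list[tuple[str, str, int]] = []
    i = 0
    n = len(text)
    while i < n:
        while i < n and text[i].isspace():
            i += 1
        if i >= n:
            break
        ch = text[i]
        if ch == "(":
            out.append(("lparen", ch, i)); i += 1
        elif ch == ")":
            out.append(("rparen", ch, i)); i += 1
        elif ch in _QUOTE_OPEN:
            close = _QUOTE_CLOSE[ch]
            j = text.find(close, i + 1)
            if j < 0:
                raise QueryParseError("unbalanced quote", i)
            out.append(("phrase", text[i + 1 : j], i)); i = j + 1
        else:
            m = _TOKEN_RE.match(text, i)
            word = m.group(1)
            i = m.end()
            lowered = word.lower()
            if lowered == "and":
                out.append(("and", word, m.start(1)))
            elif lowered == "or":
                out.append(("or", word, m.start(1)))
            else:
                out.append(("word", lowered, m.start(1)))
    return out


class _Parser:
    """Recursive-descent parser for conjunctions of OR-groups.

    OR binds tighter than AND, so ``a OR b AND c`` reads ``(a OR b) AND c``;
    parentheses are only needed to make OR-groups explicit in serialized
    form.  AND nested inside an OR-group is rejected: queries are kept in
    conjunction-of-disjunctions shape so they serialize canonically.
    """

    def __init__(self, tokens: list[tuple[str, str, int]], text: str):
        self.tokens = tokens
        self.text = text
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str, int]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> tuple[Clause, ...]:
        clauses = self.conjunction()
        if self.peek() is not None:
            kind, val, at = self.peek()
            raise QueryParseError(f"unexpected {val!r}", at)
        return clauses

    def conjunction(self) -> tuple[Clause, ...]:
        clauses = list(self.disjunction())
        while self.peek() and self.peek()[0] == "and":
            self.take()
            clauses.extend(self.disjunction())
        return tuple(clauses)

    def disjunction(self) -> tuple[Clause, ...]:
        first = self.atom()
        if not (self.peek() and self.peek()[0] == "or"):
            return first
        terms: list[Term] = list(self._as_single_clause(first).terms)
        while self.peek() and self.peek()[0] == "or":
            _, _, at = self.take()
            nxt = self.atom()
            clause = self._as_single_clause(nxt, at)
            terms.extend(clause.terms)
        return (Clause(tuple(terms)),)

    def _as_single_clause(self, clauses: tuple[Clause, ...], at: int = 0) -> Clause:
        if len(clauses) != 1:
            raise QueryParseError("AND is not allowed inside an OR group", at)
        return clauses[0]

    def atom(self) -> tuple[Clause, ...]:
        tok = self.peek()
        if tok is None:
            raise QueryParseError("unexpected end of query", len(self.text))
        kind, val, at = tok
        if kind == "word":
            self.take()
            self._reject_adjacent(at)
            return (Clause((Term("word", (val,)),)),)
        if kind == "phrase":
            self.take()
            tokens = tuple(tokenize(val))
            if not tokens:
                raise QueryParseError("empty phrase", at)
            term = (
                Term("phrase", tokens) if len(tokens) > 1 else Term("word", tokens)
            )
            self._reject_adjacent(at)
            return (Clause((term,)),)
        if kind == "lparen":
            self.take()
            inner = self.conjunction()
            nxt = self.peek()
            if nxt is None or nxt[0] != "rparen":
                raise QueryParseError("unbalanced parenthesis", at)
            self.take()
            self._reject_adjacent(at)
            return inner
        raise QueryParseError(f"unexpected {val!r}", at)

    def _reject_adjacent(self, at: int) -> None:
        nxt = self.peek()
        if nxt and nxt[0] in ("word", "phrase", "lparen"):
            raise QueryParseError(
                "terms must be joined by AND or OR", nxt[2]
            )


def parse_query(text: str, query_type: str = "common_name") -> Query:
    """Parse query text such as ``(bogong OR bogan) AND moth``."""
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    clauses = _Parser(_lex(text), text).parse()
    return Query(clauses=clauses, query_type=query_type, source_text=text)


# --- matching ----------------------------------------------------------

_URL_RE = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_LETTER_RUN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Case-folded maximal letter runs, after URL removal and #/@ stripping.

    Stripping "#" and "@" (rather than treating them as boundaries) keeps
    hashtags and usernames as single opaque tokens, so "#mothapocalypse"
    never matches the word "moth".
    """
    text = _URL_RE.sub(" ", text)
    text = text.replace("#", "").replace("@", "")
    return _LETTER_RUN_RE.findall(text.casefold())


def _term_matches(term: Term, tokens: Sequence[str]) -> bool:
    if term.kind == "word":
        return term.tokens[0] in tokens
    k = len(term.tokens)
    target = tuple(term.tokens)
    return any(tuple(tokens[i : i + k]) == target for i in range(len(tokens) - k + 1))


def match(query: Query, text: str, stem_match: bool = False) -> bool:
    """True iff every clause has at least one term present in the text.

    With ``stem_match=True`` both query words and text tokens are stemmed
    before comparison (phrases still require adjacency).
    """
    tokens = tokenize(text)
    if stem_match:
        tokens = [stem(t) for t in tokens]
        query = Query(
            clauses=tuple(
                Clause(tuple(Term(t.kind, tuple(stem(w) for w in t.tokens)) for t in c.terms))
                for c in query.clauses
            ),
            query_type=query.query_type,
        )
    return all(any(_term_matches(t, tokens) for t in c.terms) for c in query.clauses)


def run_query(
    query: Query,
    records: Iterable[TweetRecord],
    period: CoveragePeriod | None = None,
    stem_match: bool = False,
) -> list[TweetRecord]:
    """Records whose text matches, in input order; optionally period-checked."""
    hits = []
    for rec in records:
        if period is not None and not period.contains(rec.timestamp):
            raise ValueError(f"record {rec.id} outside coverage period")
        if match(query, rec.text, stem_match=stem_match):
            hits.append(rec)
    return hits


# --- term mining -------------------------------------------------------


def default_stopwords() -> frozenset[str]:
    raw = (
        resources.files("seasonwatch").joinpath("data/stopwords_en.txt").read_text()
    )
    return frozenset(
        line.strip()
        for line in raw.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Corpus preprocessing switches, applied in a fixed order:

    lowercase -> remove numbers -> remove punctuation -> tokenize on
    whitespace -> drop stopwords -> stem.
    """

    lowercase: bool = True
    strip_numbers: bool = True
    strip_punctuation: bool = True
    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    stem: bool = True

    def __post_init__(self) -> None:
        if any(w != w.lower() for w in self.stopword_list):
            raise ValueError("stopword list must be lowercase")


_NUMBER_RE = re.compile(r"\d+")
_PUNCT_RE = re.compile(r"[^\w\s]|_", re.UNICODE)


def preprocess(text: str, config: PreprocessConfig | None = None) -> list[str]:
    """Normalize one document to a token list for term mining."""
    config = config or PreprocessConfig()
    text = _URL_RE.sub(" ", text)
    if config.lowercase:
        text = text.lower()
    if config.strip_numbers:
        text = _NUMBER_RE.sub("", text)
    if config.strip_punctuation:
        text = _PUNCT_RE.sub("", text)
    tokens = text.split()
    tokens = [t for t in tokens if t not in config.stopword_list]
    if config.stem:
        tokens = [stem(t) for t in tokens]
    return tokens


def term_frequencies(
    texts: Iterable[str], config: PreprocessConfig | None = None
) -> dict[str, int]:
    """Occurrence count per preprocessed term, summed over all documents."""
    config = config or PreprocessConfig()
    counts: Counter[str] = Counter()
    for text in texts:
        counts.update(preprocess(text, config))
    return dict(counts)


def frequent_terms(table: dict[str, int], min_count: int = 5) -> list[str]:
    """Terms occurring at least ``min_count`` times, by descending count then
    lexicographically.  The default threshold of 5 is the conventional floor
    for calling a term characteristic of a small seed corpus."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    keep = [(term, n) for term, n in table.items() if n >= min_count]
    keep.sort(key=lambda kv: (-kv[1], kv[0]))
    return [term for term, _ in keep]


def build_symptomatic_query(
    anchor_terms: Clause | Sequence[str],
    descriptor_terms: Sequence[str] = (),
    grouping: Sequence[Sequence[str]] | None = None,
) -> Query:
    """Assemble a symptomatic query: anchor AND one clause per descriptor group.

    ``anchor_terms`` names the broad category (e.g. {moth} or {bird, cuckoo});
    descriptors are the mined or hand-grouped presence words.  When
    ``grouping`` is given it supersedes the flat descriptor list.
    """
    if isinstance(anchor_terms, Clause):
        anchor = anchor_terms
    else:
        if not anchor_terms:
            raise ValueError("anchor terms must be non-empty")
        anchor = Clause(tuple(_make_term(w) for w in anchor_terms))
    groups: list[Sequence[str]]
    if grouping is not None:
        groups = list(grouping)
    elif descriptor_terms:
        groups = [list(descriptor_terms)]
    else:
        groups = []
    clauses = [anchor]
    for group in groups:
        if not group:
            raise ValueError("descriptor group must be non-empty")
        clauses.append(Clause(tuple(_make_term(w) for w in group)))
    return Query(clauses=tuple(clauses), query_type="symptomatic")


def _make_term(word: str) -> Term:
    tokens = tuple(tokenize(word))
    if not tokens:
        raise ValueError(f"term {word!r} has no letters")
    return Term("phrase", tokens) if len(tokens) > 1 else Term("word", tokens)


def read_query_file(path) -> list[Query]:
    """Query file: one query per line, ``type: text`` (blank / # lines skipped)."""
    queries = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"line {line_no}: missing 'type:' tag")
            tag, text = line.split(":", 1)
            tag = tag.strip().lower()
            if tag not in QUERY_TYPES:
                raise ValueError(f"line {line_no}: unknown query type {tag!r}")
            queries.append(parse_query(text.strip(), query_type=tag))
    return queries
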