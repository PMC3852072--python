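"""Text preprocessing chain for abstract classification.

The pipeline mirrors the standard text-mining preparation of MEDLINE
abstracts: lowercase, strip punctuation, tokenize on whitespace, optionally
drop numeric tokens, remove stopwords, consolidate synonyms against a flat
lexicon, then Porter-stem.  Numbers are kept by default because tokens such
as HLA allele designations ("hla", "a", "0201") and CD receptor numbers are
informative for immunology triage.

Punctuation is replaced by spaces rather than deleted in place, so
"HLA-A*0201" yields the tokens "hla", "a", "0201" instead of a single merged
blob.
"""

from __future__ import annotations

import string
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

from ._porter import porter_stem
from .corpus_io import Document

_PUNCT_TABLE = {ord(c): " " for c in string.punctuation}

STEMMER_PORTER = "porter"
STEMMER_NONE = "none"


class ConfigError(ValueError):
    """Raised for invalid preprocessing configuration."""


def default_stopwords() -> frozenset[str]:
    """The bundled standard English stopword list (lowercase, no punctuation)."""
    text = (
        resources.files("littriage").joinpath("data/stopwords_en.txt").read_text("utf-8")
    )
    return frozenset(w for w in text.split() if w)


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Load a one-word-per-line stopword file."""
    return frozenset(
        w.strip().lower() for w in Path(path).read_text("utf-8").split() if w.strip()
    )


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV lexicon (variant <tab> canonical)."""
    mapping: dict[str, str] = {}
    for line_num, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ConfigError(f"synonym file line {line_num}: expected 2 columns")
        mapping[parts[0].strip().lower()] = parts[1].strip().lower()
    _check_no_chains(mapping)
    return mapping


def _check_no_chains(mapping: Mapping[str, str]) -> None:
    chained = sorted(v for v in mapping.values() if v in mapping)
    if chained:
        raise ConfigError(
            f"synonym map contains chains: canonical form(s) {chained} are also keys"
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the token pipeline.

    Parameters
    ----------
    stopword_list:
        Lowercase, punctuation-free words to drop.  Defaults to the bundled
        standard English list.
    remove_numbers:
        Drop tokens consisting solely of digits.  Off by default so that HLA
        allele and CD receptor designators survive.
    synonym_map:
        Flat variant -> canonical replacement applied before stemming (so
        lexicon keys can be surface forms).  No chains allowed.
    stemmer:
        ``"porter"`` (default) or ``"none"``.
    """

    stopword_list: frozenset[str] = field(default_factory=default_stopwords)
    remove_numbers: bool = False
    synonym_map: Mapping[str, str] = field(default_factory=dict)
    stemmer: str = STEMMER_PORTER

    def __post_init__(self) -> None:
        if self.stemmer not in (STEMMER_PORTER, STEMMER_NONE):
            raise ConfigError(f"unknown stemmer {self.stemmer!r}")
        bad = [
            w
            for w in self.stopword_list
            if w != w.lower() or any(c in string.punctuation for c in w)
        ]
        if bad:
            raise ConfigError(
                f"stopwords must be lowercase and punctuation-free: {sorted(bad)[:5]}"
            )
        _check_no_chains(self.synonym_map)

    def to_dict(self) -> dict:
        return {
            "stopword_list": sorted(self.stopword_list),
            "remove_numbers": self.remove_numbers,
            "synonym_map": dict(self.synonym_map),
            "stemmer": self.stemmer,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PreprocessConfig":
        return cls(
            stopword_list=frozenset(d["stopword_list"]),
            remove_numbers=bool(d["remove_numbers"]),
            synonym_map=dict(d["synonym_map"]),
            stemmer=d["stemmer"],
        )


@dataclass(frozen=True)
class TokenizedDocument:
    doc_id: str
    tokens: tuple[str, ...]


def apply_synonyms(
    tokens: Sequence[str], synonym_map: Mapping[str, str]
) -> list[str]:
    """Replace each token by its canonical form if mapped; idempotent."""
    _check_no_chains(synonym_map)
    return [synonym_map.get(t, t) for t in tokens]


def tokenize_text(text: str, cfg: Optional[PreprocessConfig] = None) -> list[str]:
    """Run the full pipeline on raw text and return the token list.

    Fixed stage order: lowercase -> punctuation-to-space -> whitespace split
    -> optional number removal -> stopword removal -> synonym consolidation
    -> stemming -> drop empties.  Deterministic.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    text = unicodedata.normalize("NFKC", text).lower()
    text = text.translate(_PUNCT_TABLE)
    tokens = text.split()
    if cfg.remove_numbers:
        tokens = [t for t in tokens if not t.isdigit()]
    tokens = [t for t in tokens if t not in cfg.stopword_list]
    tokens = [cfg.synonym_map.get(t, t) for t in tokens]
    if cfg.stemmer == STEMMER_PORTER:
        tokens = [porter_stem(t) for t in tokens]
    return [t for t in tokens if t]


def preprocess_document(
    doc: Document, cfg: Optional[PreprocessConfig] = None
) -> TokenizedDocument:
    """Preprocess one document's classification text (title + abstract + MeSH)."""
    return TokenizedDocument(
        doc_id=doc.doc_id, tokens=tuple(tokenize_text(doc.classification_text, cfg))
    )


def preprocess_corpus(
    documents, cfg: Optional[PreprocessConfig] = None
) -> list[TokenizedDocument]:
    return [preprocess_document(d, cfg) for d in documents]
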