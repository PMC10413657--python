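"""Keyword-based classification of dominant disease mechanisms.

Free-text evidence (abstracts, database entries) is tokenized into
sentences and screened for mechanism keywords:

* dominant-negative (DN): "dominant negative"
* gain-of-function (GOF): "gain of function", "activating mutation"
* loss-of-function (LOF): "haploinsufficiency", "haploinsufficient",
  "dosage sensitivity", "dosage sensitive", "heterozygous loss of function"

Matching is case-insensitive and normalizes hyphens to spaces, so
"dominant-negative" and "Dominant  Negative" both match.  A sentence can
support several classes.  Manual curation is modelled as an explicit
accept/reject map over evidence sentences; after filtering, a gene's final
class follows the precedence DN > GOF > LOF (a gene with any accepted DN
evidence is DN regardless of other hits), and genes with no accepted
evidence stay unclassified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

KEYWORDS: dict[str, tuple[str, ...]] = {
    "DN": ("dominant negative",),
    "GOF": ("gain of function", "activating mutation"),
    "LOF": (
        "haploinsufficiency",
        "haploinsufficient",
        "dosage sensitivity",
        "dosage sensitive",
        "heterozygous loss of function",
    ),
}

#: Precedence used to resolve genes matching several classes.
HIERARCHY: tuple[str, ...] = ("DN", "GOF", "LOF")

_SENTENCE_SPLIT = re.compile(r"(?<=[.!?])\s+")
_HYPHENS = re.compile(r"[-‐‑‒–—]")
_WHITESPACE = re.compile(r"\s+")


@dataclass
class MechanismEvidence:
    """One keyword-bearing sentence supporting a mechanism class."""

    gene_id: str
    mechanism_class: str
    sentence: str
    source_id: str = ""
    accepted: bool = True


def normalize(text: str) -> str:
    """Lowercase, hyphen→space, collapsed whitespace."""
    return _WHITESPACE.sub(" ", _HYPHENS.sub(" ", text.lower())).strip()


def split_sentences(text: str) -> list[str]:
    """Split on terminal punctuation followed by whitespace.

    Deliberately simple — abbreviation-induced oversplits are handled by the
    curation step, not the tokenizer.
    """
    return [s for s in _SENTENCE_SPLIT.split(text) if s.strip()]


def extract_evidence(
    gene_id: str,
    documents: Sequence[str],
    source_ids: Sequence[str] | None = None,
) -> list[MechanismEvidence]:
    """Collect keyword-bearing sentences for one gene.

    Every retained sentence is a verbatim substring of its source document.
    A sentence matching keywords of several classes yields one evidence
    entry per class.  An empty corpus yields an empty list.
    """
    if source_ids is not None and len(source_ids) != len(documents):
        raise ValueError("source_ids must align with documents")
    evidence: list[MechanismEvidence] = []
    for i, doc in enumerate(documents):
        src = source_ids[i] if source_ids is not None else f"doc{i}"
        for sentence in split_sentences(doc):
            norm = normalize(sentence)
            for cls, words in KEYWORDS.items():
                if any(w in norm for w in words):
                    evidence.append(
                        MechanismEvidence(
                            gene_id=gene_id,
                            mechanism_class=cls,
                            sentence=sentence,
                            source_id=src,
                        )
                    )
    return evidence


def resolve_class(
    evidence: Iterable[MechanismEvidence],
    curation: Mapping[str, bool] | None = None,
) -> str | None:
    """Final mechanism class for a gene's evidence, or None if unclassified.

    ``curation`` maps sentence text to accept (True) / reject (False);
    sentences absent from the map keep their own ``accepted`` flag.  The
    result is independent of evidence ordering.
    """
    accepted_classes = set()
    for ev in evidence:
        accepted = ev.accepted
        if curation is not None and ev.sentence in curation:
            accepted = curation[ev.sentence]
        if accepted:
            accepted_classes.add(ev.mechanism_class)
    for cls in HIERARCHY:
        if cls in accepted_classes:
            return cls
    return None


@dataclass
class GeneClassification:
    gene_id: str
    mechanism: str | None
    evidence: list[MechanismEvidence] = field(default_factory=list)


def classify_genes(
    corpus: Mapping[str, Sequence[str]],
    curation: Mapping[str, bool] | None = None,
) -> dict[str, GeneClassification]:
    """Classify every gene of a corpus ``{gene_id: [document, ...]}``."""
    out: dict[str, GeneClassification] = {}
    for gene_id in sorted(corpus):
        ev = extract_evidence(gene_id, list(corpus[gene_id]))
        out[gene_id] = GeneClassification(
            gene_id=gene_id, mechanism=resolve_class(ev, curation), evidence=ev
        )
    return out
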