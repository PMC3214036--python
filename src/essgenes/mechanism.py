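"""Disease-mechanism classification of free-text records: gain / loss / other.

Two independent methods are applied to each record and cross-checked:

* a lexicon word-score — count tokens matching category-specific word stems
  (prefix match, so "activat" hits "activation" and "activating") and take
  the argmax category; and
* a multinomial naive-Bayes classifier trained on labeled records, with two
  vocabulary exclusions: words present in a large fraction of training
  documents, and (optionally) words shared by training documents of every
  class, neither of which can discriminate between mechanisms.

"neutral" covers mechanisms that are neither gain nor loss of function
(chromosomal translocations, chimeric proteins) and is reported as "other".
Ties and all-zero scores yield "unclassified", which is excluded from
proportion denominators.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .classify import ClassifiedGeneTable, Group, DISEASE_GROUPS
from .io import DiseaseAssociation, TextRecord, MECHANISM_LABELS

CATEGORIES = MECHANISM_LABELS  # ("gain", "loss", "neutral")
UNCLASSIFIED = "unclassified"

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase tokens split on non-alphanumeric runs."""
    return _TOKEN_RE.findall(text.lower())


@dataclass
class Lexicon:
    """Category → set of lowercase word stems, matched by token prefix."""

    stems: dict[str, set[str]]

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            self.stems.setdefault(cat, set())
        for cat, words in self.stems.items():
            if any(not w for w in words):
                raise ValueError(f"empty stem in category '{cat}'")
            self.stems[cat] = {w.lower() for w in words}
        shared = set.intersection(*(self.stems[c] for c in CATEGORIES))
        for cat in CATEGORIES:
            self.stems[cat] -= shared

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls({cat: set(words or []) for cat, words in raw.items()})


def default_lexicon() -> Lexicon:
    """The lexicon shipped with the package (data/lexicon.yaml)."""
    return Lexicon.from_yaml(Path(__file__).parent / "data" / "lexicon.yaml")


def word_score_classify(text: str, lexicon: Lexicon) -> str:
    """Argmax of per-category stem-match counts; ties or no match → unclassified.

    Returns "gain", "loss", "other" (for the neutral category) or
    "unclassified". Deterministic and insensitive to token order.
    """
    tokens = tokenize(text)
    scores = {
        cat: sum(1 for t in tokens if any(t.startswith(stem) for stem in lexicon.stems[cat]))
        for cat in CATEGORIES
    }
    best = max(scores.values())
    if best == 0:
        return UNCLASSIFIED
    winners = [c for c, s in scores.items() if s == best]
    if len(winners) > 1:
        return UNCLASSIFIED
    return "other" if winners[0] == "neutral" else winners[0]


@dataclass
class NaiveBayesModel:
    """Multinomial naive Bayes over a filtered vocabulary.

    Word likelihoods interpolate the class's empirical word frequencies with
    the uniform distribution: p(w|c) = (f(w|c) + α/V) / (1 + α). Because the
    likelihood depends on frequencies only, replicating the training corpus
    leaves the model exactly unchanged.
    """

    priors: dict[str, float]
    log_likelihoods: dict[str, dict[str, float]]
    vocabulary: set[str]
    excluded_words: set[str]
    alpha: float


def train_nb(
    records: Sequence[TextRecord],
    alpha: float = 1.0,
    frequent_df_cutoff: float = 0.5,
    exclude_shared: bool = True,
) -> NaiveBayesModel:
    """Train the mechanism classifier on labeled records.

    Words with document frequency ≥ ``frequent_df_cutoff`` (fraction of all
    training documents) are excluded; with ``exclude_shared``, so is any word
    occurring in at least one training document of every class. Class priors
    come from label frequencies; token likelihoods mix each class's word
    frequencies with the uniform distribution at weight ``alpha`` (α = 1
    weighs data and uniform equally; larger α smooths harder).
    """
    if alpha <= 0:
        raise ValueError("smoothing alpha must be positive")
    labeled = [r for r in records if r.known_label in CATEGORIES]
    by_class: dict[str, list[list[str]]] = {c: [] for c in CATEGORIES}
    for r in labeled:
        by_class[r.known_label].append(tokenize(r.text))
    for cat, docs in by_class.items():
        if not docs:
            raise ValueError(f"no training records for class '{cat}'")

    n_docs = len(labeled)
    doc_freq: Counter[str] = Counter()
    class_presence: dict[str, set[str]] = {}
    for cat, docs in by_class.items():
        present: set[str] = set()
        for toks in docs:
            words = set(toks)
            doc_freq.update(words)
            present |= words
        class_presence[cat] = present

    excluded = {w for w, df in doc_freq.items() if df / n_docs >= frequent_df_cutoff}
    if exclude_shared:
        excluded |= set.intersection(*class_presence.values())
    vocabulary = set(doc_freq) - excluded

    priors = {cat: len(docs) / n_docs for cat, docs in by_class.items()}
    log_lik: dict[str, dict[str, float]] = {}
    v = len(vocabulary)
    for cat, docs in by_class.items():
        counts: Counter[str] = Counter()
        for toks in docs:
            counts.update(t for t in toks if t in vocabulary)
        total = sum(counts.values())
        log_lik[cat] = {
            w: math.log(((counts[w] / total if total else 0.0) + alpha / v) / (1.0 + alpha))
            for w in vocabulary
        }
    return NaiveBayesModel(priors, log_lik, vocabulary, excluded, alpha)


def nb_classify(model: NaiveBayesModel, text: str) -> tuple[str, dict[str, float]]:
    """Posterior over mechanism classes; argmax call, exact tie → unclassified.

    Out-of-vocabulary and excluded tokens are ignored, so a document with no
    informative token gets the prior as its posterior.
    """
    tokens = [t for t in tokenize(text) if t in model.vocabulary]
    log_post = {
        cat: math.log(model.priors[cat]) + sum(model.log_likelihoods[cat][t] for t in tokens)
        for cat in CATEGORIES
    }
    mx = max(log_post.values())
    unnorm = {c: math.exp(lp - mx) for c, lp in log_post.items()}
    z = sum(unnorm.values())
    posterior = {c: p / z for c, p in unnorm.items()}
    best = max(posterior.values())
    winners = [c for c, p in posterior.items() if p == best]
    call = winners[0] if len(winners) == 1 else UNCLASSIFIED
    return call, posterior


@dataclass
class MechanismCall:
    record_id: str
    gene_id: str
    group: str
    wordscore_call: str
    nb_call: str
    nb_posterior: dict[str, float]
    final_call: str


@dataclass
class CorpusResult:
    """Per-group mechanism proportions by each method, plus their agreement."""

    calls: list[MechanismCall]
    proportions: "object"  # DataFrame: group × (method, category) fractions
    agreement_rate: float  # simple agreement of the two methods on mutually classified records


def _as_other(call: str) -> str:
    return "other" if call == "neutral" else call


def classify_corpus(
    records: Sequence[TextRecord],
    lexicon: Lexicon,
    model: NaiveBayesModel,
    classified: ClassifiedGeneTable,
    associations: Sequence[DiseaseAssociation] = (),
    genicity_filter: str = "monogenic_only",
) -> CorpusResult:
    """Classify a record corpus and tabulate mechanism proportions per group.

    With ``genicity_filter="monogenic_only"`` every record whose gene carries
    a polygenic disease association is dropped before tabulation. The final
    call is the word-score call, falling back to naive Bayes when the word
    score is unclassified. Proportions are over classified records only.
    """
    import pandas as pd

    if genicity_filter not in ("monogenic_only", "all"):
        raise ValueError(f"unknown genicity filter '{genicity_filter}'")
    polygenic_genes = {a.gene_id for a in associations if a.genicity == "polygenic"}

    calls: list[MechanismCall] = []
    for rec in records:
        if genicity_filter == "monogenic_only" and rec.gene_id in polygenic_genes:
            continue
        group = classified.groups.get(rec.gene_id)
        ws = word_score_classify(rec.text, lexicon)
        nb_raw, post = nb_classify(model, rec.text)
        nb = _as_other(nb_raw) if nb_raw != UNCLASSIFIED else UNCLASSIFIED
        final = ws if ws != UNCLASSIFIED else nb
        calls.append(
            MechanismCall(
                record_id=rec.record_id,
                gene_id=rec.gene_id,
                group=group.value if group is not None else "",
                wordscore_call=ws,
                nb_call=nb,
                nb_posterior=post,
                final_call=final,
            )
        )

    rows = []
    group_labels = [g.value for g in DISEASE_GROUPS] + ["D"]
    for label in group_labels:
        subset = [
            c
            for c in calls
            if c.group == label or (label == "D" and c.group in {g.value for g in DISEASE_GROUPS})
        ]
        row: dict[str, float | str | int] = {"group": label, "n_records": len(subset)}
        for method in ("wordscore", "nb", "final"):
            picked = [getattr(c, f"{method}_call") for c in subset]
            classified_calls = [p for p in picked if p != UNCLASSIFIED]
            for cat in ("gain", "loss", "other"):
                key = f"{method}_{cat}"
                row[key] = (
                    classified_calls.count(cat) / len(classified_calls) if classified_calls else math.nan
                )
        rows.append(row)

    both = [c for c in calls if UNCLASSIFIED not in (c.wordscore_call, c.nb_call)]
    agreement = (
        sum(1 for c in both if c.wordscore_call == c.nb_call) / len(both) if both else math.nan
    )
    return CorpusResult(calls, pd.DataFrame(rows), agreement)


def calls_frame(result: CorpusResult):
    """Per-record calls as a DataFrame in the report column order."""
    import pandas as pd

    return pd.DataFrame(
        {
            "record_id": [c.record_id for c in result.calls],
            "gene_id": [c.gene_id for c in result.calls],
            "group": [c.group for c in result.calls],
            "wordscore_call": [c.wordscore_call for c in result.calls],
            "nb_call": [c.nb_call for c in result.calls],
            "nb_posterior_gain": [c.nb_posterior["gain"] for c in result.calls],
            "nb_posterior_loss": [c.nb_posterior["loss"] for c in result.calls],
            "nb_posterior_neutral": [c.nb_posterior["neutral"] for c in result.calls],
            "final_call": [c.final_call for c in result.calls],
        }
    )
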