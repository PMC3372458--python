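"""GO-term log-odds tables and per-protein GO-scores.

For each GO sub-ontology (Cellular Component C, Molecular Function F,
Biological Process P) a training partition defines, per term t,

    logodds(t) = ln[(c_t + k) / (n_c + 2k)] - ln[(o_t + k) / (n_o + 2k)]

where c_t (o_t) counts the cancer-labelled (other-labelled) variations
whose protein is annotated with t, n_c and n_o the class totals and
k a Laplace pseudocount (default 1) that keeps the ratio finite for
terms seen in one class only.  A protein's GO-score per aspect is the
sum of the log-odds of its table-resident terms; a positive score marks
the cancer class.  Tables are always fitted inside cross-validation on
the training folds only, so a test protein never contributes to the
frequencies that score it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mutgo.dataset_io import ASPECTS, GoAnnotationSet, Label, VariantRecord
from mutgo.metrics import UNPREDICTED

GO_CLASSIFY_MODES = ("C", "F", "P", "CFP_AVG")


@dataclass
class TermLogOddsTable:
    """Per-term cancer-vs-other log-odds for one aspect and training fold."""

    aspect: str
    fold_id: int = -1
    kappa: float = 1.0
    n_cancer: int = 0
    n_other: int = 0
    entries: dict[str, tuple[int, int, float]] = field(default_factory=dict)
    #: proteins of the training partition; used by leakage assertions
    training_proteins: frozenset[str] = frozenset()

    def logodds(self, term: str) -> float | None:
        entry = self.entries.get(term)
        return entry[2] if entry is not None else None


@dataclass(frozen=True)
class GoScore:
    """Per-aspect GO-scores of one protein against one fold's tables."""

    protein_id: str
    scores: dict[str, float]
    n_terms_seen: dict[str, int]

    def covered(self, aspect: str) -> bool:
        return self.n_terms_seen[aspect] > 0

    def as_vector(self) -> list[float]:
        """[C, F, P] scores, uncovered aspects contributing 0."""
        return [self.scores[a] for a in ASPECTS]


def _term_logodds(
    count_cancer: int, count_other: int, n_cancer: int, n_other: int, kappa: float
) -> float:
    return math.log((count_cancer + kappa) / (n_cancer + 2 * kappa)) - math.log(
        (count_other + kappa) / (n_other + 2 * kappa)
    )


def fit_term_logodds(
    variants: Sequence[VariantRecord],
    annotations: Iterable[GoAnnotationSet],
    aspect: str,
    kappa: float = 1.0,
    fold_id: int = -1,
    per_protein: bool = False,
) -> TermLogOddsTable:
    """Estimate the term log-odds table for one aspect.

    Occurrences are counted at the variation level: every labelled
    variation contributes its protein's terms once, so a protein with
    many variations weighs proportionally.  ``per_protein=True`` counts
    each protein once per class instead.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"unknown aspect {aspect!r}")
    ann_by_protein = {a.protein_id: a for a in annotations}
    labelled = [v for v in variants if v.label in (Label.CANCER, Label.OTHER)]
    if per_protein:
        units: list[tuple[str, Label]] = sorted(
            {(v.protein_id, v.label) for v in labelled}
        )
    else:
        units = [(v.protein_id, v.label) for v in labelled]
    n_cancer = sum(1 for _, lab in units if lab == Label.CANCER)
    n_other = len(units) - n_cancer
    if n_cancer == 0 or n_other == 0:
        raise ValueError(
            "term log-odds require both classes in the training partition "
            f"(got {n_cancer} cancer, {n_other} other)"
        )
    counts: dict[str, list[int]] = {}
    for pid, lab in units:
        annset = ann_by_protein.get(pid)
        if annset is None:
            continue
        idx = 0 if lab == Label.CANCER else 1
        for term in annset.terms_by_aspect[aspect]:
            counts.setdefault(term, [0, 0])[idx] += 1
    table = TermLogOddsTable(
        aspect=aspect,
        fold_id=fold_id,
        kappa=kappa,
        n_cancer=n_cancer,
        n_other=n_other,
        training_proteins=frozenset(pid for pid, _ in units),
    )
    for term in sorted(counts):
        c, o = counts[term]
        table.entries[term] = (c, o, _term_logodds(c, o, n_cancer, n_other, kappa))
    return table


def score_protein(
    annotations: GoAnnotationSet,
    tables: Mapping[str, TermLogOddsTable],
) -> GoScore:
    """Sum per-aspect term log-odds for one protein.

    ``tables`` maps each aspect to the table fitted on the same training
    partition.  Terms absent from a table contribute nothing and do not
    count toward coverage; an aspect with no table-resident term scores
    exactly 0 and is flagged uncovered.
    """
    scores: dict[str, float] = {}
    n_seen: dict[str, int] = {}
    for aspect in ASPECTS:
        table = tables[aspect]
        total = 0.0
        seen = 0
        for term in annotations.terms_by_aspect[aspect]:
            lo = table.logodds(term)
            if lo is not None:
                total += lo
                seen += 1
        scores[aspect] = total if seen else 0.0
        n_seen[aspect] = seen
    return GoScore(
        protein_id=annotations.protein_id, scores=scores, n_terms_seen=n_seen
    )


def classify_by_go(score: GoScore, mode: str) -> Label | str:
    """Sign-rule classification from GO-scores.

    Single-aspect modes return UNPREDICTED for an uncovered aspect
    (this is why per-aspect coverage stays below 100%); otherwise the
    variant's protein is called CANCER iff the score is strictly
    positive, ties going to the majority class OTHER.  ``CFP_AVG``
    averages the covered aspects only, so any annotated protein gets a
    prediction and coverage is total.
    """
    if mode not in GO_CLASSIFY_MODES:
        raise ValueError(f"unknown GO classification mode {mode!r}")
    if mode in ASPECTS:
        if not score.covered(mode):
            return UNPREDICTED
        value = score.scores[mode]
    else:
        covered = [score.scores[a] for a in ASPECTS if score.covered(a)]
        value = sum(covered) / len(covered) if covered else 0.0
    return Label.CANCER if value > 0 else Label.OTHER


def rank_discriminative_terms(
    table: TermLogOddsTable, k: int
) -> list[tuple[str, float]]:
    """Top-k terms by descending log-odds (most cancer-discriminative first).

    Ties break on the term identifier for determinism; k beyond the
    table size returns every entry.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.entries.items(), key=lambda kv: (-kv[1][2], kv[0]))
    return [(term, entry[2]) for term, entry in ranked[:k]]


def write_logodds_table(path, table: TermLogOddsTable) -> None:
    """TSV dump: term, count_cancer, count_other, logodds."""
    with open(path, "w") as fh:
        fh.write("term\tcount_cancer\tcount_other\tlogodds\n")
        for term in sorted(table.entries):
            c, o, lo = table.entries[term]
            fh.write(f"{term}\t{c}\t{o}\t{lo:.6f}\n")
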