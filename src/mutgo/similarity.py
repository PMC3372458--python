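"""Pairwise identity, identity-aware fold splitting and the transfer baseline.

Identity between two proteins is computed over the best local alignment
(BLOSUM62, affine gap open 11 / extend 1) as identical columns divided
by aligned columns.  Significance is a Karlin–Altschul E-value with the
standard gapped BLOSUM62 parameters; any engine honouring the same
contract may be substituted behind :func:`pairwise_identity`.

Cross-validation folds keep single-linkage components of the >=25%
identity graph intact, so no test protein shares detectable similarity
with a training protein — the split that makes homology-based leakage
impossible.  The same machinery drives the annotation-transfer
baseline: each query inherits the majority variant label of its best
dataset hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from mutgo.dataset_io import Label, VariantRecord
from mutgo.metrics import UNPREDICTED, ConfusionSummary, confusion_counts

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap costs 11/1.
_LAMBDA = 0.267
_K = 0.041

IDENTITY_THRESHOLD = 25.0
EVALUE_THRESHOLD = 1e-3


@dataclass(frozen=True)
class IdentityEdge:
    """Significant similarity between an unordered protein pair."""

    protein_a: str
    protein_b: str
    identity_pct: float
    evalue: float

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class BaselineReport:
    """One row of the annotation-transfer sweep."""

    threshold_pct: float
    coverage_pct: float  # proteins with a usable best hit
    metrics: ConfusionSummary


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(
    seq_a: str, seq_b: str, max_evalue: float = 100.0
) -> tuple[float, float] | None:
    """Identity percentage and E-value of the best local alignment.

    Returns ``None`` when no alignment scores above zero or the
    E-value exceeds ``max_evalue`` (the reporting threshold).  Identity
    is matches / aligned columns * 100, gap columns excluded.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    # X is outside BLOSUM62's alphabet here; mask it to the most neutral row.
    seq_a = seq_a.replace("X", "S")
    seq_b = seq_b.replace("X", "S")
    alignments = _ALIGNER.align(seq_a, seq_b)
    try:
        best = alignments[0]
    except IndexError:
        return None
    if best.score <= 0:
        return None
    evalue = _K * len(seq_a) * len(seq_b) * math.exp(-_LAMBDA * best.score)
    if evalue > max_evalue:
        return None
    counts = best.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return None
    identity = 100.0 * counts.identities / aligned
    return identity, evalue


def all_pairs_identity(
    sequences: Mapping[str, str], max_evalue: float = 100.0
) -> list[IdentityEdge]:
    """All-against-all edge list over the dataset proteins.

    Quadratic in the number of proteins; intended for dataset-scale
    (hundreds) inputs, not proteome scans.
    """
    ids = sorted(sequences)
    edges: list[IdentityEdge] = []
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            hit = pairwise_identity(sequences[pa], sequences[pb], max_evalue)
            if hit is None:
                continue
            identity, evalue = hit
            edges.append(
                IdentityEdge(
                    protein_a=pa, protein_b=pb, identity_pct=identity, evalue=evalue
                )
            )
    return edges


def _components(
    proteins: Iterable[str], edges: Iterable[IdentityEdge]
) -> list[list[str]]:
    """Single-linkage components over the significant-similarity graph."""
    parent: dict[str, str] = {p: p for p in proteins}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        if e.protein_a in parent and e.protein_b in parent:
            ra, rb = find(e.protein_a), find(e.protein_b)
            if ra != rb:
                parent[ra] = rb
    groups: dict[str, list[str]] = {}
    for p in parent:
        groups.setdefault(find(p), []).append(p)
    return [sorted(g) for g in groups.values()]


def cluster_into_folds(
    edges: Sequence[IdentityEdge],
    proteins: Iterable[str],
    k: int = 10,
    seed: int = 0,
    weights: Mapping[str, int] | None = None,
    identity_threshold: float = IDENTITY_THRESHOLD,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> dict[str, int]:
    """Partition proteins into k folds with no similar cross-fold pair.

    Edges with identity >= ``identity_threshold`` and E-value below
    ``evalue_threshold`` bind their endpoints into the same fold
    (single-linkage closure).  Components are then dealt greedily,
    heaviest first, onto the currently lightest fold, balancing the
    per-fold variation counts given by ``weights`` (default: one per
    protein).  ``seed`` shuffles equal-weight components so different
    seeds explore different balanced splits.
    """
    proteins = sorted(set(proteins))
    if k < 2:
        raise ValueError("k must be >= 2")
    significant = [
        e
        for e in edges
        if e.identity_pct >= identity_threshold and e.evalue < evalue_threshold
    ]
    comps = _components(proteins, significant)
    w = weights or {}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(comps))
    comps = [comps[i] for i in order]
    comps.sort(key=lambda c: -sum(w.get(p, 1) for p in c))  # stable: keeps shuffle
    fold_load = [0] * k
    assignment: dict[str, int] = {}
    for comp in comps:
        target = int(np.argmin(fold_load))
        for p in comp:
            assignment[p] = target
        fold_load[target] += sum(w.get(p, 1) for p in comp)
    return assignment


def check_fold_validity(
    assignment: Mapping[str, int],
    edges: Iterable[IdentityEdge],
    identity_threshold: float = IDENTITY_THRESHOLD,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> list[IdentityEdge]:
    """Exhaustively list significant edges that cross folds (must be empty)."""
    return [
        e
        for e in edges
        if e.identity_pct >= identity_threshold
        and e.evalue < evalue_threshold
        and e.protein_a in assignment
        and e.protein_b in assignment
        and assignment[e.protein_a] != assignment[e.protein_b]
    ]


def write_folds(path, assignment: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfold\n")
        for pid in sorted(assignment):
            fh.write(f"{pid}\t{assignment[pid]}\n")


def read_folds(path) -> dict[str, int]:
    assignment: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError(f"{path}: expected a 'protein_id\\tfold' header")
        for line in fh:
            if not line.strip():
                continue
            pid, fold = line.rstrip("\n").split("\t")
            assignment[pid] = int(fold)
    return assignment


def _best_hits(
    sequences: Mapping[str, str],
    edges: Sequence[IdentityEdge] | None,
    max_evalue: float,
) -> dict[str, list[tuple[float, float, str]]]:
    """Per-protein hit lists as (evalue, identity, hit_id), sorted."""
    if edges is None:
        edges = all_pairs_identity(sequences, max_evalue=max_evalue)
    hits: dict[str, list[tuple[float, float, str]]] = {p: [] for p in sequences}
    for e in edges:
        hits[e.protein_a].append((e.evalue, e.identity_pct, e.protein_b))
        hits[e.protein_b].append((e.evalue, e.identity_pct, e.protein_a))
    for p in hits:
        # ascending evalue, then higher identity, then lexicographic id
        hits[p].sort(key=lambda h: (h[0], -h[1], h[2]))
    return hits


def similarity_transfer_baseline(
    dataset: Sequence[VariantRecord],
    sequences: Mapping[str, str],
    threshold_pct: float,
    edges: Sequence[IdentityEdge] | None = None,
    max_evalue: float = 100.0,
    first_under_threshold: bool = False,
) -> BaselineReport:
    """Annotate every query protein from its best dataset hit.

    The hit list of a query excludes the query itself and is sorted by
    ascending E-value.  By default the single best hit is retained only
    when its identity does not exceed ``threshold_pct``; with
    ``first_under_threshold`` the first hit satisfying the bound is
    used instead.  A retained hit transfers its majority variant label:
    the query's variations are all predicted CANCER when the hit
    carries strictly more cancer- than other-labelled variations,
    OTHER otherwise (ties go to the majority class).  Queries without a
    retained hit are unpredicted and lower the protein coverage.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must be in (0, 100]")
    labelled = [v for v in dataset if v.label in (Label.CANCER, Label.OTHER)]
    proteins = sorted({v.protein_id for v in labelled})
    missing = [p for p in proteins if p not in sequences]
    if missing:
        raise ValueError(f"no sequence for dataset proteins {missing[:5]}")
    counts: dict[str, list[int]] = {p: [0, 0] for p in proteins}
    for v in labelled:
        counts[v.protein_id][0 if v.label == Label.CANCER else 1] += 1
    hits = _best_hits({p: sequences[p] for p in proteins}, edges, max_evalue)
    predictions: dict[str, object] = {}
    covered = 0
    for query in proteins:
        hit_id = None
        for _, identity, candidate in hits[query]:
            if identity <= threshold_pct:
                hit_id = candidate
                break
            if not first_under_threshold:
                break  # overall best hit exceeds the bound: query uncovered
        if hit_id is None:
            continue
        covered += 1
        n_cancer, n_other = counts[hit_id]
        predictions[query] = Label.CANCER if n_cancer > n_other else Label.OTHER
    predicted = [predictions.get(v.protein_id, UNPREDICTED) for v in labelled]
    observed = [v.label for v in labelled]
    metrics = confusion_counts(predicted, observed)
    coverage_pct = 100.0 * covered / len(proteins) if proteins else 0.0
    return BaselineReport(
        threshold_pct=threshold_pct, coverage_pct=coverage_pct, metrics=metrics
    )
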