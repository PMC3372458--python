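"""RBF-kernel SVM training, prediction and identity-aware cross-validation.

The classifier is a support vector machine with a radial basis function
kernel on standardised feature vectors.  The class imbalance (roughly
one cancer variation per five others) is handled with class weights
inversely proportional to the training class frequencies.  Decision
threshold is 0: positive decision values are called CANCER.

Cross-validation follows the identity-aware protocol: the outer folds
come from <25%-identity clustering, the GO log-odds tables are fitted
only on the nine training folds of each round, and (C, gamma) are
selected by an inner stratified 5-fold search on the training partition
maximising MCC.  A leakage assertion verifies that no test protein
contributed to the GO tables that score it.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from mutgo.dataset_io import ASPECTS, GoAnnotationSet, Label, PssmProfile, VariantRecord
from mutgo.features import EncodingConfig, build_design_matrix
from mutgo.go_scoring import GoScore, TermLogOddsTable, fit_term_logodds, score_protein
from mutgo.metrics import ConfusionSummary, confusion_counts

DEFAULT_C_GRID = (0.5, 1.0, 2.0, 4.0, 8.0)
DEFAULT_GAMMA_GRID = (0.01, 0.05, 0.1, 0.5, 1.0)

BUNDLE_FORMAT_VERSION = 1


@dataclass
class ModelBundle:
    """A trained model plus every fitted quantity its predictions need.

    A bundle predicts only with its own GO tables and standardisation
    parameters; mixing folds would leak test information.
    """

    config: EncodingConfig
    svc: SVC
    scaler: StandardScaler
    tables: dict[str, TermLogOddsTable]
    C: float
    gamma: float
    fold_id: int = -1

    @property
    def training_proteins(self) -> frozenset[str]:
        if not self.tables:
            return frozenset()
        return next(iter(self.tables.values())).training_proteins

    def save(self, path) -> None:
        payload = {
            "format": "mutgo-model-bundle",
            "version": BUNDLE_FORMAT_VERSION,
            "bundle": self,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "mutgo-model-bundle":
            raise ValueError(f"{path} is not a model bundle")
        if payload.get("version") != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"bundle version {payload.get('version')} unsupported"
            )
        return payload["bundle"]


@dataclass
class CvResult:
    """Per-fold and pooled outcome of one cross-validation run."""

    fold_summaries: dict[int, ConfusionSummary]
    predictions: list[tuple[VariantRecord, Label, float]]
    chosen_params: dict[int, tuple[float, float]] = field(default_factory=dict)

    @property
    def pooled(self) -> ConfusionSummary:
        total = ConfusionSummary(0, 0, 0, 0)
        for s in self.fold_summaries.values():
            total = total + s
        return total


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    seed: int = 0,
    class_weight: Mapping[int, float] | str | None = "balanced",
) -> tuple[SVC, StandardScaler]:
    """Fit the scaler and RBF SVM on training rows only."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    scaler = StandardScaler().fit(X)
    svc = SVC(
        kernel="rbf",
        C=C,
        gamma=gamma,
        class_weight=class_weight,
        random_state=seed,
        cache_size=200,
    )
    svc.fit(scaler.transform(X), y)
    return svc, scaler


def train(
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    profiles: Mapping[str, PssmProfile] | None,
    config: EncodingConfig,
    C: float,
    gamma: float,
    seed: int = 0,
    kappa: float = 1.0,
    fold_id: int = -1,
) -> ModelBundle:
    """Fit GO tables, scaler and SVM on one training partition."""
    tables = {
        a: fit_term_logodds(variants, annotations, a, kappa=kappa, fold_id=fold_id)
        for a in ASPECTS
    }
    goscores = _score_proteins(variants, annotations, tables)
    X, y = build_design_matrix(variants, config, profiles=profiles, goscores=goscores)
    svc, scaler = train_svm(X, y, C=C, gamma=gamma, seed=seed)
    return ModelBundle(
        config=config,
        svc=svc,
        scaler=scaler,
        tables=tables,
        C=C,
        gamma=gamma,
        fold_id=fold_id,
    )


def _score_proteins(
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    tables: Mapping[str, TermLogOddsTable],
) -> dict[str, GoScore]:
    ann_by_protein = {a.protein_id: a for a in annotations}
    scores: dict[str, GoScore] = {}
    for pid in {v.protein_id for v in variants}:
        annset = ann_by_protein.get(pid, GoAnnotationSet(protein_id=pid))
        scores[pid] = score_protein(annset, tables)
    return scores


def predict(
    bundle: ModelBundle,
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    profiles: Mapping[str, PssmProfile] | None = None,
) -> list[tuple[VariantRecord, Label, float]]:
    """Per-variant predicted label and SVM decision value.

    GO-scores are computed from the bundle's own tables, so predictions
    are reproducible bit-exactly for a fixed bundle.
    """
    if not variants:
        return []
    goscores = (
        _score_proteins(variants, annotations, bundle.tables)
        if bundle.config.use_go
        else None
    )
    X, _ = build_design_matrix(
        variants, bundle.config, profiles=profiles, goscores=goscores
    )
    values = bundle.svc.decision_function(bundle.scaler.transform(X))
    return [
        (v, Label.CANCER if d > 0 else Label.OTHER, float(d))
        for v, d in zip(variants, values)
    ]


def _inner_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[tuple[float, float]],
    seed: int,
    n_inner: int = 5,
) -> tuple[float, float]:
    """Select (C, gamma) by stratified inner CV maximising pooled MCC."""
    if len(grid) == 1:
        return grid[0]
    n_inner = min(n_inner, int(np.bincount(y).min()))
    skf = StratifiedKFold(n_splits=n_inner, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best: tuple[float, tuple[float, float]] | None = None
    for C, gamma in grid:
        tp = tn = fp = fn = 0
        for tr_idx, te_idx in splits:
            if np.unique(y[tr_idx]).size < 2:
                continue
            svc, scaler = train_svm(X[tr_idx], y[tr_idx], C=C, gamma=gamma, seed=seed)
            pred = svc.predict(scaler.transform(X[te_idx]))
            tp += int(np.sum((pred == 1) & (y[te_idx] == 1)))
            tn += int(np.sum((pred == 0) & (y[te_idx] == 0)))
            fp += int(np.sum((pred == 1) & (y[te_idx] == 0)))
            fn += int(np.sum((pred == 0) & (y[te_idx] == 1)))
        mcc = ConfusionSummary(tp=tp, tn=tn, fp=fp, fn=fn).mcc
        key = (mcc, (C, gamma))
        # deterministic tie-break: first grid entry wins on equal MCC
        if best is None or key[0] > best[0]:
            best = key
    assert best is not None
    return best[1]


def cross_validate(
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    profiles: Mapping[str, PssmProfile] | None,
    config: EncodingConfig,
    folds: Mapping[str, int],
    seed: int = 0,
    grid: Sequence[tuple[float, float]] | None = None,
    kappa: float = 1.0,
) -> CvResult:
    """Identity-aware k-fold cross-validation with fold-wise GO tables.

    For each test fold the GO tables, standardisation and SVM are
    fitted exclusively on the complementary folds; hyperparameters come
    from an inner stratified 5-fold search on that training partition.
    """
    labelled = [v for v in variants if v.label in (Label.CANCER, Label.OTHER)]
    unassigned = sorted({v.protein_id for v in labelled} - set(folds))
    if unassigned:
        raise ValueError(f"no fold assignment for proteins {unassigned[:5]}")
    if grid is None:
        grid = [(C, g) for C in DEFAULT_C_GRID for g in DEFAULT_GAMMA_GRID]
    fold_ids = sorted(set(folds[v.protein_id] for v in labelled))
    fold_summaries: dict[int, ConfusionSummary] = {}
    predictions: list[tuple[VariantRecord, Label, float]] = []
    chosen: dict[int, tuple[float, float]] = {}
    for f in fold_ids:
        test = [v for v in labelled if folds[v.protein_id] == f]
        training = [v for v in labelled if folds[v.protein_id] != f]
        if not test:
            continue
        tables = {
            a: fit_term_logodds(training, annotations, a, kappa=kappa, fold_id=f)
            for a in ASPECTS
        }
        # leakage guard: no test protein may sit in the GO training partition
        test_proteins = {v.protein_id for v in test}
        for table in tables.values():
            overlap = test_proteins & table.training_proteins
            assert not overlap, f"GO-table leakage for fold {f}: {sorted(overlap)[:3]}"
        goscores = _score_proteins(labelled, annotations, tables)
        X_tr, y_tr = build_design_matrix(
            training, config, profiles=profiles, goscores=goscores
        )
        X_te, y_te = build_design_matrix(
            test, config, profiles=profiles, goscores=goscores
        )
        C, gamma = _inner_search(X_tr, y_tr, grid, seed=seed + f)
        chosen[f] = (C, gamma)
        svc, scaler = train_svm(X_tr, y_tr, C=C, gamma=gamma, seed=seed)
        values = svc.decision_function(scaler.transform(X_te))
        pred_labels = [Label.CANCER if d > 0 else Label.OTHER for d in values]
        fold_summaries[f] = confusion_counts(pred_labels, [v.label for v in test])
        predictions.extend(
            (v, lab, float(d)) for v, lab, d in zip(test, pred_labels, values)
        )
    return CvResult(
        fold_summaries=fold_summaries, predictions=predictions, chosen_params=chosen
    )
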