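"""End-to-end experiment orchestration.

`run_full_evaluation` reproduces the three evaluation surfaces on one
dataset: the transfer-by-similarity threshold sweep, the cross-validated
GO-only classification per sub-ontology, and the SVM cross-validation
for each requested feature encoding.  All stages share one fold
assignment and one seed, and every report row carries its coverage
denominator, so reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from mutgo import dataset_io
from mutgo.dataset_io import (
    GoAnnotationSet,
    Label,
    PssmProfile,
    VariantRecord,
)
from mutgo.features import get_encoding
from mutgo.go_scoring import (
    GO_CLASSIFY_MODES,
    classify_by_go,
    fit_term_logodds,
    score_protein,
)
from mutgo.metrics import ConfusionSummary, confusion_counts
from mutgo.similarity import (
    all_pairs_identity,
    cluster_into_folds,
    similarity_transfer_baseline,
)
from mutgo.svm import CvResult, ModelBundle, cross_validate

logger = logging.getLogger("mutgo")

DEFAULT_THRESHOLDS = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)


@dataclass
class ExperimentConfig:
    variants_path: str
    fasta_path: str
    go_path: str
    pssm_dir: str | None = None
    go_dialect: str = "TSV"
    encodings: tuple[str, ...] = ("mut_GO",)
    n_folds: int = 10
    seed: int = 0
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    cascade_path: str | None = None
    grid: tuple[tuple[float, float], ...] | None = None
    outdir: str = "mutgo_run"


def cross_validate_go_only(
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    folds: Mapping[str, int],
    kappa: float = 1.0,
) -> dict[str, ConfusionSummary]:
    """Cross-validated sign-rule classification from GO-scores alone.

    For each fold, term log-odds tables are fitted on the complementary
    folds and every test variant is classified per mode (C, F, P and
    the covered-aspect average CFP_AVG).  Uncovered single-aspect
    predictions count as unpredicted, which is what keeps per-aspect
    coverage below 100%.
    """
    labelled = [v for v in variants if v.label in (Label.CANCER, Label.OTHER)]
    ann_by_protein = {a.protein_id: a for a in annotations}
    predicted: dict[str, list] = {mode: [] for mode in GO_CLASSIFY_MODES}
    observed: list[Label] = []
    for f in sorted(set(folds[v.protein_id] for v in labelled)):
        test = [v for v in labelled if folds[v.protein_id] == f]
        training = [v for v in labelled if folds[v.protein_id] != f]
        if not test:
            continue
        tables = {
            a: fit_term_logodds(training, annotations, a, kappa=kappa, fold_id=f)
            for a in ("C", "F", "P")
        }
        scores = {
            pid: score_protein(
                ann_by_protein.get(pid, GoAnnotationSet(protein_id=pid)), tables
            )
            for pid in {v.protein_id for v in test}
        }
        for v in test:
            observed.append(v.label)
            for mode in GO_CLASSIFY_MODES:
                predicted[mode].append(classify_by_go(scores[v.protein_id], mode))
    return {
        mode: confusion_counts(predicted[mode], observed)
        for mode in GO_CLASSIFY_MODES
    }


def _write_metrics_table(path: Path, rows: list[tuple[str, ConfusionSummary]]) -> None:
    cols = ("n", "coverage", "Q", "MCC", "Sp(C)", "Sn(C)", "Sp(O)", "Sn(O)")
    with path.open("w") as fh:
        fh.write("row\t" + "\t".join(cols) + "\n")
        for name, summary in rows:
            r = summary.as_row()
            fh.write(
                name
                + "\t"
                + "\t".join(
                    f"{r[c]:.4f}" if c != "n" else str(int(r[c])) for c in cols
                )
                + "\n"
            )


def run_full_evaluation(config: ExperimentConfig) -> dict[str, Path]:
    """Run baseline, GO-only and SVM evaluations; return report paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    variants = dataset_io.parse_variant_table(config.variants_path)
    sequences = dataset_io.parse_fasta(config.fasta_path)
    annotations = dataset_io.parse_go_annotations(config.go_path, config.go_dialect)
    variants, problems = dataset_io.check_consistency(variants, sequences)
    for p in problems:
        logger.warning("excluded inconsistent variant: %s", p)
    if config.cascade_path:
        upstream = read_upstream_calls(config.cascade_path)
        variants, retention = apply_cascade_filter(variants, upstream)
        logger.info("cascade filter retained %.1f%% of variants", 100 * retention)
    labelled = [v for v in variants if v.label in (Label.CANCER, Label.OTHER)]
    proteins = sorted({v.protein_id for v in labelled})
    logger.info(
        "dataset: %d labelled variants on %d proteins", len(labelled), len(proteins)
    )
    edges = all_pairs_identity({p: sequences[p] for p in proteins})
    weights: dict[str, int] = {}
    for v in labelled:
        weights[v.protein_id] = weights.get(v.protein_id, 0) + 1
    folds = cluster_into_folds(
        edges, proteins, k=config.n_folds, seed=config.seed, weights=weights
    )
    reports: dict[str, Path] = {}

    folds_path = outdir / "folds.tsv"
    from mutgo.similarity import write_folds

    write_folds(folds_path, folds)
    reports["folds"] = folds_path

    baseline_rows = []
    for t in config.thresholds:
        rep = similarity_transfer_baseline(labelled, sequences, t, edges=edges)
        row = rep.metrics.as_row()
        baseline_rows.append((t, rep.coverage_pct, row))
    baseline_path = outdir / "baseline.tsv"
    with baseline_path.open("w") as fh:
        fh.write("threshold\tpct_prot\tQ\tMCC\tSp(C)\tSn(C)\tSp(O)\tSn(O)\n")
        for t, cov, row in baseline_rows:
            fh.write(
                f"{t:.0f}\t{cov:.1f}\t"
                + "\t".join(
                    f"{row[c]:.4f}"
                    for c in ("Q", "MCC", "Sp(C)", "Sn(C)", "Sp(O)", "Sn(O)")
                )
                + "\n"
            )
    reports["baseline"] = baseline_path

    go_rows = cross_validate_go_only(labelled, annotations, folds)
    go_path = outdir / "go_only.tsv"
    _write_metrics_table(go_path, [(m, go_rows[m]) for m in GO_CLASSIFY_MODES])
    reports["go_only"] = go_path

    profiles = None
    if any(get_encoding(e).needs_profile for e in config.encodings):
        if config.pssm_dir is None:
            raise ValueError("profile-based encodings need --pssm-dir")
        profiles = dataset_io.load_pssm_dir(config.pssm_dir, proteins)
    svm_rows = []
    for name in config.encodings:
        enc = get_encoding(name)
        result = cross_validate(
            labelled,
            annotations,
            profiles if enc.needs_profile else None,
            enc,
            folds,
            seed=config.seed,
            grid=list(config.grid) if config.grid else None,
        )
        svm_rows.append((name, result.pooled))
        logger.info("encoding %s: %s", name, result.pooled.as_row())
    svm_path = outdir / "svm.tsv"
    _write_metrics_table(svm_path, svm_rows)
    reports["svm"] = svm_path

    log_path = outdir / "run_log.txt"
    with log_path.open("w") as fh:
        fh.write(f"seed\t{config.seed}\n")
        fh.write(f"n_folds\t{config.n_folds}\n")
        fh.write(f"n_variants\t{len(labelled)}\n")
        fh.write(f"n_proteins\t{len(proteins)}\n")
        fh.write(f"n_excluded_inconsistent\t{len(problems)}\n")
        fh.write(f"encodings\t{','.join(config.encodings)}\n")
    reports["log"] = log_path
    return reports


def screen_external_set(
    bundle: ModelBundle,
    variants: Sequence[VariantRecord],
    annotations: Sequence[GoAnnotationSet],
    profiles: Mapping[str, PssmProfile] | None = None,
    expected_label: Label = Label.OTHER,
) -> tuple[float, list[tuple[VariantRecord, Label, float]]]:
    """Predict an external set and report the fraction matching expectation.

    The screened proteins must be disjoint from the bundle's training
    proteins (checked by identifier); overlap is an error because a
    screening figure on training proteins is meaningless.
    """
    if not variants:
        raise ValueError("nothing to screen: empty variant list")
    overlap = {v.protein_id for v in variants} & bundle.training_proteins
    if overlap:
        raise ValueError(
            f"screened proteins overlap the training set: {sorted(overlap)[:5]}"
        )
    from mutgo.svm import predict

    preds = predict(bundle, variants, annotations, profiles=profiles)
    n_expected = sum(1 for _, lab, _ in preds if lab == expected_label)
    return n_expected / len(preds), preds


def read_upstream_calls(path) -> dict[tuple[str, int, str], str]:
    """Read an upstream disease/neutral prediction table.

    TSV columns: protein_id, position, mut_aa, call in {DISEASE, NEUTRAL}.
    """
    calls: dict[tuple[str, int, str], str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            call = row["call"].upper()
            if call not in {"DISEASE", "NEUTRAL"}:
                raise ValueError(f"{path}:{lineno}: call must be DISEASE or NEUTRAL")
            calls[(row["protein_id"], int(row["position"]), row["mut_aa"])] = call
    return calls


def apply_cascade_filter(
    variants: Sequence[VariantRecord],
    upstream: Mapping[tuple[str, int, str], str],
    missing: str = "drop",
) -> tuple[list[VariantRecord], float]:
    """Keep only variants an upstream method calls disease-related.

    Returns the retained list and the retention rate.  ``missing``
    controls variants absent from the upstream table: ``drop`` removes
    them with a warning, ``error`` raises.
    """
    if missing not in {"drop", "error"}:
        raise ValueError("missing must be 'drop' or 'error'")
    retained: list[VariantRecord] = []
    n_missing = 0
    for v in variants:
        call = upstream.get(v.key)
        if call is None:
            if missing == "error":
                raise ValueError(f"variant {v.key} absent from the upstream table")
            n_missing += 1
            continue
        if call == "DISEASE":
            retained.append(v)
    if n_missing:
        logger.warning("%d variants missing from the upstream table", n_missing)
    rate = len(retained) / len(variants) if variants else 0.0
    return retained, rate
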