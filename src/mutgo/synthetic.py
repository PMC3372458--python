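"""Synthetic benchmark generator with controllable class-conditional GO signal.

The generator emulates the structure of a curated germline-variant set:
proteins carry batches of labelled substitutions, most proteins are
single-class, a small fraction carries variations of both classes, and
the discriminative signal lives in the proteins' GO annotations.

Per aspect, a vocabulary of ``vocab_size_per_aspect`` terms is split in
half.  The first half is cancer-informative: under the cancer class a
term slot lands in the informative half with probability
sigma(delta) = 1/(1+exp(-delta)) and uniformly within the half; under
the other class the probability is sigma(-delta).  Every informative
term therefore has a true cancer-vs-other log-odds of exactly +delta
and every remaining term -delta, which makes the Bayes-optimal
accuracy of a GO-only classifier a closed-form binomial expression
(:func:`bayes_accuracy`).  delta = 0 produces a pure-noise dataset.

Sequences are i.i.d. uniform over the 20 residues and carry no class
signal, so substitution-only encodings have chance-level ground truth
by construction.  Profiles favour the wild-type residue with a
Dirichlet concentration, emitted in the legacy PSI-BLAST ``-Q``
dialect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import binom

from mutgo.dataset_io import (
    AA_ALPHABET,
    ASPECTS,
    GoAnnotationSet,
    Label,
    Origin,
    PssmProfile,
    VariantRecord,
    write_fasta,
    write_go_annotations,
    write_pssm,
    write_variant_table,
)

#: Cancer share of variations on dual-class proteins (mixed-label carriers).
DUAL_CANCER_SHARE = 0.47


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of one synthetic dataset.

    Defaults mirror a curated germline set: ~600 proteins averaging
    ~11 variations each, a 16% cancer class, and 3.4% of proteins
    carrying variations of both classes.  ``effect_size`` (delta) is
    the true per-term log-odds separating the class-conditional GO-term
    distributions; per-aspect annotation coverage defaults to the
    89/98/96% (C/F/P) pattern typical of well-annotated proteomes.
    """

    n_proteins: int = 592
    variants_per_protein: tuple[int, int] = (2, 20)
    cancer_protein_fraction: float = 0.16
    dual_class_fraction: float = 0.034
    terms_per_aspect: int = 5
    vocab_size_per_aspect: int = 60
    effect_size: float = 2.0
    aspect_coverage: tuple[float, float, float] = (0.89, 0.98, 0.96)
    sequence_length: tuple[int, int] = (100, 400)
    profile_concentration: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cancer_protein_fraction <= 1:
            raise ValueError("cancer_protein_fraction must be in [0, 1]")
        if not 0 <= self.dual_class_fraction < 1:
            raise ValueError("dual_class_fraction must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.vocab_size_per_aspect % 2:
            raise ValueError("vocab_size_per_aspect must be even")
        if self.terms_per_aspect > self.vocab_size_per_aspect // 2:
            raise ValueError(
                "terms_per_aspect cannot exceed half the vocabulary "
                "(terms are drawn without replacement within each half)"
            )
        lo, hi = self.variants_per_protein
        if not 1 <= lo <= hi:
            raise ValueError("variants_per_protein must be a valid range")
        lo, hi = self.sequence_length
        if not 10 <= lo <= hi:
            raise ValueError("sequence_length must be a range with min >= 10")
        for c in self.aspect_coverage:
            if not 0 <= c <= 1:
                raise ValueError("aspect coverages must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """Everything one benchmark run needs, plus the generating truth."""

    config: GeneratorConfig
    variants: list[VariantRecord]
    sequences: dict[str, str]
    annotations: list[GoAnnotationSet]
    profiles: dict[str, PssmProfile]
    #: aspect -> term -> true log-odds (+delta informative, -delta rest)
    true_term_logodds: dict[str, dict[str, float]] = field(default_factory=dict)
    #: protein -> "CANCER" | "OTHER" | "DUAL"
    protein_class: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Emit the dataset in the package's text dialects (reproducible)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_variant_table(outdir / "variants.tsv", self.variants)
        write_fasta(outdir / "sequences.fasta", self.sequences)
        write_go_annotations(outdir / "annotations.tsv", self.annotations)
        pssm_dir = outdir / "pssm"
        pssm_dir.mkdir(exist_ok=True)
        for pid, profile in self.profiles.items():
            write_pssm(pssm_dir / f"{pid}.pssm", profile)


def _aspect_vocab(aspect: str, vocab_size: int) -> list[str]:
    offset = {"C": 0, "F": 1, "P": 2}[aspect] * 1_000_000
    return [f"GO:{offset + i + 1:07d}" for i in range(vocab_size)]


def _sigma(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _draw_terms(
    rng: np.random.Generator,
    vocab: list[str],
    m: int,
    p_informative: float,
) -> set[str]:
    """m distinct terms: Binomial(m, p) from the informative half, rest from the other."""
    half = len(vocab) // 2
    k = int(rng.binomial(m, p_informative))
    inf = rng.choice(half, size=k, replace=False) if k else np.array([], dtype=int)
    rest = (
        rng.choice(half, size=m - k, replace=False) + half
        if m - k
        else np.array([], dtype=int)
    )
    return {vocab[i] for i in np.concatenate([inf, rest]).astype(int)}


def _make_profile(
    rng: np.random.Generator, pid: str, sequence: str, concentration: float
) -> PssmProfile:
    n = len(sequence)
    alpha = np.ones((n, 20))
    wt_idx = np.fromiter((AA_ALPHABET.index(c) for c in sequence), dtype=int, count=n)
    alpha[np.arange(n), wt_idx] = concentration
    # Dirichlet rows via normalised gammas, vectorised over positions
    g = rng.standard_gamma(alpha)
    p = g / g.sum(axis=1, keepdims=True)
    f = np.floor(p * 100).astype(int)
    # pseudocounted log-odds against the uniform background, PSSM-like scale
    q = (f + 1) / (f.sum(axis=1, keepdims=True) + 20)
    lo = np.clip(np.round(2 * np.log2(q / 0.05)), -15, 15).astype(int)
    return PssmProfile(
        protein_id=pid,
        residues=sequence,
        logodds=[[int(x) for x in row] for row in lo],
        freqs=[[float(x) for x in row] for row in f],
    )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Draw a fully reproducible dataset from the configured conditions."""
    rng = np.random.default_rng(config.seed)
    delta = config.effect_size
    vocabs = {a: _aspect_vocab(a, config.vocab_size_per_aspect) for a in ASPECTS}
    true_lo = {
        a: {
            t: (delta if i < config.vocab_size_per_aspect // 2 else -delta)
            for i, t in enumerate(vocabs[a])
        }
        for a in ASPECTS
    }
    variants: list[VariantRecord] = []
    sequences: dict[str, str] = {}
    annotations: list[GoAnnotationSet] = []
    profiles: dict[str, PssmProfile] = {}
    protein_class: dict[str, str] = {}
    m = config.terms_per_aspect
    lo_v, hi_v = config.variants_per_protein
    lo_s, hi_s = config.sequence_length
    for i in range(config.n_proteins):
        pid = f"SYN{i:05d}"
        if rng.random() < config.dual_class_fraction:
            cls = "DUAL"
        elif rng.random() < config.cancer_protein_fraction:
            cls = "CANCER"
        else:
            cls = "OTHER"
        protein_class[pid] = cls
        p_inf = {
            "CANCER": _sigma(delta),
            "OTHER": _sigma(-delta),
            "DUAL": 0.5,
        }[cls]
        annset = GoAnnotationSet(protein_id=pid)
        for aspect, cov in zip(ASPECTS, config.aspect_coverage):
            if rng.random() < cov:
                for term in sorted(_draw_terms(rng, vocabs[aspect], m, p_inf)):
                    annset.add(term, aspect)
        annotations.append(annset)
        length = int(rng.integers(lo_s, hi_s + 1))
        seq = "".join(AA_ALPHABET[j] for j in rng.integers(0, 20, size=length))
        sequences[pid] = seq
        profiles[pid] = _make_profile(rng, pid, seq, config.profile_concentration)
        n_var = int(rng.integers(lo_v, hi_v + 1))
        if cls == "DUAL":
            n_var = max(n_var, 2)
        positions = rng.choice(length, size=min(n_var, length), replace=False) + 1
        if cls == "DUAL":
            # guarantee both classes on a dual protein, rest Bernoulli
            labels = [Label.CANCER, Label.OTHER] + [
                Label.CANCER if rng.random() < DUAL_CANCER_SHARE else Label.OTHER
                for _ in range(len(positions) - 2)
            ]
        else:
            labels = [Label(cls)] * len(positions)
        for pos, lab in zip(sorted(int(p) for p in positions), labels):
            wt = seq[pos - 1]
            mut = AA_ALPHABET[
                (AA_ALPHABET.index(wt) + 1 + int(rng.integers(0, 19))) % 20
            ]
            variants.append(
                VariantRecord(
                    protein_id=pid,
                    position=pos,
                    wt_aa=wt,
                    mut_aa=mut,
                    label=lab,
                    origin=Origin.GERMLINE,
                )
            )
    return SyntheticDataset(
        config=config,
        variants=variants,
        sequences=sequences,
        annotations=annotations,
        profiles=profiles,
        true_term_logodds=true_lo,
        protein_class=protein_class,
    )


def bayes_accuracy(config: GeneratorConfig) -> float:
    """Bayes-optimal variant-level accuracy of a GO-only classifier.

    With all terms in the informative half at true log-odds +delta and
    the rest at -delta, the log-likelihood ratio of a protein given K
    informative terms out of M observed slots is

        logit(pi) + delta * (2K - M),

    pi being the variant-level cancer prior, so the optimal rule
    thresholds the binomial count K.  The expectation enumerates the 8
    aspect-coverage patterns.  Only defined for single-class datasets
    (``dual_class_fraction = 0``): dual proteins break the clean
    class-conditional term model.
    """
    if config.dual_class_fraction != 0:
        raise ValueError("bayes_accuracy requires dual_class_fraction = 0")
    if config.effect_size == 0:
        return max(config.cancer_protein_fraction, 1 - config.cancer_protein_fraction)
    pi = config.cancer_protein_fraction
    delta = config.effect_size
    m = config.terms_per_aspect
    logit = math.log(pi / (1 - pi))
    p_c = _sigma(delta)
    p_o = _sigma(-delta)
    acc = 0.0
    for pattern in range(8):
        covered = [(pattern >> j) & 1 for j in range(3)]
        w = 1.0
        for cov, bit in zip(config.aspect_coverage, covered):
            w *= cov if bit else (1 - cov)
        M = m * sum(covered)
        if M == 0:
            acc += w * max(pi, 1 - pi)
            continue
        # predict cancer iff K > t
        t = M / 2 - logit / (2 * delta)
        k_min = math.floor(t) + 1  # smallest K called cancer
        p_cancer_correct = binom.sf(k_min - 1, M, p_c)
        p_other_correct = binom.cdf(k_min - 1, M, p_o)
        acc += w * (pi * p_cancer_correct + (1 - pi) * p_other_correct)
    return acc


def expected_cancer_fraction(config: GeneratorConfig) -> float:
    """Expected variant-level cancer prevalence under the configured conditions."""
    d = config.dual_class_fraction
    return (1 - d) * config.cancer_protein_fraction + d * DUAL_CANCER_SHARE


def generate_external_other_set(
    config: GeneratorConfig, n_proteins: int, seed: int
) -> SyntheticDataset:
    """A disjoint all-OTHER screening set (somatic-like negative control).

    Proteins are freshly drawn from the other-disease generator with
    identifiers that never collide with the training set's.
    """
    cfg = GeneratorConfig(
        n_proteins=n_proteins,
        variants_per_protein=config.variants_per_protein,
        cancer_protein_fraction=0.0,
        dual_class_fraction=0.0,
        terms_per_aspect=config.terms_per_aspect,
        vocab_size_per_aspect=config.vocab_size_per_aspect,
        effect_size=config.effect_size,
        aspect_coverage=config.aspect_coverage,
        sequence_length=config.sequence_length,
        profile_concentration=config.profile_concentration,
        seed=seed,
    )
    data = generate_dataset(cfg)
    renamed_variants = [
        VariantRecord(
            protein_id="EXT" + v.protein_id[3:],
            position=v.position,
            wt_aa=v.wt_aa,
            mut_aa=v.mut_aa,
            label=v.label,
            origin=Origin.SOMATIC,
        )
        for v in data.variants
    ]
    rename = lambda pid: "EXT" + pid[3:]  # noqa: E731
    data.variants = renamed_variants
    data.sequences = {rename(p): s for p, s in data.sequences.items()}
    for a in data.annotations:
        a.protein_id = rename(a.protein_id)
    for p in list(data.profiles):
        prof = data.profiles.pop(p)
        prof.protein_id = rename(p)
        data.profiles[prof.protein_id] = prof
    data.protein_class = {rename(p): c for p, c in data.protein_class.items()}
    return data


def table1_like_composition(
    variants: list[VariantRecord],
) -> dict[str, int]:
    """Bookkeeping summary of a labelled dataset.

    Returns the counts a dataset-composition table reports: total
    variations and proteins, per-class variation counts, and the
    single-class / dual-class protein breakdown with their variation
    loads.
    """
    by_protein: dict[str, list[Label]] = {}
    for v in variants:
        by_protein.setdefault(v.protein_id, []).append(v.label)
    n_cancer_only = n_other_only = n_dual = 0
    var_cancer_only = var_other_only = dual_cancer = dual_other = 0
    for labels in by_protein.values():
        has_c = Label.CANCER in labels
        has_o = Label.OTHER in labels
        if has_c and has_o:
            n_dual += 1
            dual_cancer += sum(1 for l in labels if l == Label.CANCER)
            dual_other += sum(1 for l in labels if l == Label.OTHER)
        elif has_c:
            n_cancer_only += 1
            var_cancer_only += len(labels)
        elif has_o:
            n_other_only += 1
            var_other_only += len(labels)
    return {
        "n_variations": len(variants),
        "n_proteins": len(by_protein),
        "n_cancer_variations": sum(
            1 for v in variants if v.label == Label.CANCER
        ),
        "n_other_variations": sum(1 for v in variants if v.label == Label.OTHER),
        "proteins_cancer_only": n_cancer_only,
        "proteins_other_only": n_other_only,
        "proteins_dual": n_dual,
        "variations_cancer_only_proteins": var_cancer_only,
        "variations_other_only_proteins": var_other_only,
        "variations_dual_cancer": dual_cancer,
        "variations_dual_other": dual_other,
    }
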