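"""Pairwise identity, fold clustering and the transfer baseline."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from mutgo.dataset_io import AA_ALPHABET, Label, VariantRecord
from mutgo.similarity import (
    BaselineReport,
    IdentityEdge,
    check_fold_validity,
    cluster_into_folds,
    pairwise_identity,
    similarity_transfer_baseline,
)

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_identity(a, b, gap_open=11, gap_extend=1):
    """Brute-force affine-gap Smith-Waterman oracle with traceback.

    Returns (best score, identity over the best local alignment).
    Quadratic DP written for clarity, usable only at tiny n.
    """
    n, m = len(a), len(b)
    NEG = -1e9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best, best_pos = 0.0, None
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(0.0, M[i - 1, j - 1] + s, X[i - 1, j - 1] + s, Y[i - 1, j - 1] + s)
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
            if M[i, j] > best:
                best, best_pos = M[i, j], (i, j)
    if best_pos is None:
        return 0.0, None
    # traceback through match states only for identity counting
    i, j = best_pos
    matches = aligned = 0
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i, j] == 0:
                break
            s = BLOSUM62[a[i - 1], b[j - 1]]
            aligned += 1
            if a[i - 1] == b[j - 1]:
                matches += 1
            prev = M[i, j] - s
            if abs(prev - M[i - 1, j - 1]) < 1e-9 or abs(prev) < 1e-9:
                state = "M"
            elif abs(prev - X[i - 1, j - 1]) < 1e-9:
                state = "X"
            else:
                state = "Y"
            i, j = i - 1, j - 1
        elif state == "X":
            if abs(X[i, j] - (M[i - 1, j] - gap_open)) < 1e-9:
                state = "M"
            i -= 1
        else:
            if abs(Y[i, j] - (M[i, j - 1] - gap_open)) < 1e-9:
                state = "M"
            j -= 1
    return best, 100.0 * matches / aligned if aligned else None


class TestPairwiseIdentity:
    def test_self_identity(self):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        identity, evalue = pairwise_identity(seq, seq)
        assert identity == 100.0
        assert evalue < 1e-10

    def test_single_substitution_matches_oracle(self):
        a, b = "ACDEFGHIK", "ACDEFGHIR"
        identity, _ = pairwise_identity(a, b)
        assert identity == pytest.approx(100 * 8 / 9)
        score, oracle_identity = sw_identity(a, b)
        assert identity == pytest.approx(oracle_identity)

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 25))
            b = list(a)
            # mutate a few positions so alignments stay near-global
            for pos in rng.choice(25, size=5, replace=False):
                b[pos] = AA_ALPHABET[int(rng.integers(0, 20))]
            b = "".join(b)
            hit = pairwise_identity(a, b)
            score, oracle_identity = sw_identity(a, b)
            assert hit is not None
            assert hit[0] == pytest.approx(oracle_identity)

    def test_unrelated_random_sequences_not_significant(self):
        rng = np.random.default_rng(7)
        a = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 30))
        b = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 30))
        # at the clustering significance cutoff random 30-mers must not hit
        assert pairwise_identity(a, b, max_evalue=1e-3) is None

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")


def edge(a, b, identity, evalue=1e-6):
    return IdentityEdge(protein_a=a, protein_b=b, identity_pct=identity, evalue=evalue)


class TestFoldClustering:
    def test_no_edges_balanced(self):
        proteins = [f"P{i}" for i in range(20)]
        folds = cluster_into_folds([], proteins, k=10, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=10)
        assert set(folds) == set(proteins)
        assert all(s == 2 for s in sizes)

    def test_single_linkage_closure(self):
        edges = [edge("A", "B", 30.0), edge("B", "C", 40.0)]
        folds = cluster_into_folds(edges, ["A", "B", "C", "D"], k=2, seed=1)
        assert folds["A"] == folds["B"] == folds["C"]

    def test_insignificant_edges_do_not_bind(self):
        edges = [edge("A", "B", 24.9), edge("C", "D", 80.0, evalue=0.5)]
        folds = cluster_into_folds(edges, ["A", "B", "C", "D"], k=2, seed=0)
        sizes = np.bincount(list(folds.values()), minlength=2)
        assert all(s == 2 for s in sizes)  # nothing bound, perfectly balanced

    def test_fixture_graph_exhaustive_validity(self):
        # 3 components sized 5 / 3 / 2
        comp1 = [edge(f"A{i}", f"A{i+1}", 50.0) for i in range(4)]
        comp2 = [edge(f"B{i}", f"B{i+1}", 30.0) for i in range(2)]
        comp3 = [edge("C0", "C1", 99.0)]
        edges = comp1 + comp2 + comp3
        proteins = [f"A{i}" for i in range(5)] + [f"B{i}" for i in range(3)] + ["C0", "C1"]
        folds = cluster_into_folds(edges, proteins, k=2, seed=3)
        assert check_fold_validity(folds, edges) == []

    def test_validity_over_seeds(self):
        rng = np.random.default_rng(0)
        proteins = [f"P{i}" for i in range(30)]
        edges = []
        for _ in range(25):
            i, j = rng.choice(30, size=2, replace=False)
            edges.append(edge(f"P{min(i,j)}", f"P{max(i,j)}", float(rng.uniform(10, 90))))
        for seed in range(5):
            folds = cluster_into_folds(edges, proteins, k=4, seed=seed)
            assert check_fold_validity(folds, edges) == []

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cluster_into_folds([], ["A", "B"], k=1, seed=0)

    def test_weights_balance_variation_counts(self):
        proteins = [f"P{i}" for i in range(6)]
        weights = {"P0": 10, "P1": 10, "P2": 1, "P3": 1, "P4": 1, "P5": 1}
        folds = cluster_into_folds([], proteins, k=2, seed=0, weights=weights)
        load = [0, 0]
        for p, f in folds.items():
            load[f] += weights[p]
        assert abs(load[0] - load[1]) <= 2


def make_baseline_fixture():
    """Two similar pairs plus an isolated protein.

    Q1's best hit H1 carries 3 cancer / 1 other variations; Q2's best
    hit H2 carries 2 / 2 (tie).  The isolated protein Z has no hit.
    """
    rng = np.random.default_rng(11)
    base1 = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 80))
    base2 = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 80))
    zseq = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, 80))

    def mutate(seq, n):
        s = list(seq)
        for pos in rng.choice(len(s), size=n, replace=False):
            s[pos] = AA_ALPHABET[int(rng.integers(0, 20))]
        return "".join(s)

    sequences = {
        "Q1": base1,
        "H1": mutate(base1, 8),
        "Q2": base2,
        "H2": mutate(base2, 8),
        "Z": zseq,
    }
    variants = []

    def add(pid, labels):
        for i, lab in enumerate(labels):
            wt = sequences[pid][i]
            mut = "A" if wt != "A" else "C"
            variants.append(VariantRecord(pid, i + 1, wt, mut, lab))

    add("Q1", [Label.OTHER] * 2)
    add("H1", [Label.CANCER] * 3 + [Label.OTHER])
    add("Q2", [Label.CANCER] * 2)
    add("H2", [Label.CANCER] * 2 + [Label.OTHER] * 2)
    add("Z", [Label.OTHER])
    return variants, sequences


class TestTransferBaseline:
    def test_majority_and_tie_rules(self):
        variants, sequences = make_baseline_fixture()
        # strict reporting threshold: only the two engineered pairs hit
        report = similarity_transfer_baseline(
            variants, sequences, threshold_pct=100.0, max_evalue=1e-3
        )
        # Q1 <- H1 (3C/1O, majority CANCER): Q1's 2 OTHER variants -> FP
        # H1 <- Q1 (0C/2O): H1's 3 CANCER -> FN, 1 OTHER -> TN
        # Q2 <- H2 (2C/2O, tie -> OTHER): Q2's 2 CANCER -> FN
        # H2 <- Q2 (2C/0O): H2's 2 CANCER -> TP, 2 OTHER -> FP
        m = report.metrics
        assert (m.tp, m.tn, m.fp, m.fn) == (2, 1, 4, 5)
        # Z has no significant hit -> unpredicted
        assert m.n_unpredicted == 1
        assert report.coverage_pct == pytest.approx(100 * 4 / 5)

    def test_coverage_monotone_in_threshold(self):
        variants, sequences = make_baseline_fixture()
        coverages = [
            similarity_transfer_baseline(variants, sequences, t).coverage_pct
            for t in (30.0, 60.0, 90.0, 100.0)
        ]
        assert coverages == sorted(coverages)

    def test_deterministic(self):
        variants, sequences = make_baseline_fixture()
        r1 = similarity_transfer_baseline(variants, sequences, 80.0)
        r2 = similarity_transfer_baseline(variants, sequences, 80.0)
        assert r1 == r2

    def test_threshold_validation(self):
        variants, sequences = make_baseline_fixture()
        with pytest.raises(ValueError):
            similarity_transfer_baseline(variants, sequences, 0.0)
        with pytest.raises(ValueError):
            similarity_transfer_baseline(variants, sequences, 101.0)
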