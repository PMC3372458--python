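"""Parsers, writers and cross-file validation."""

import pytest

from mutgo import dataset_io
from mutgo.dataset_io import (
    GoAnnotationSet,
    Label,
    Origin,
    ParseError,
    PssmProfile,
    ValidationError,
    VariantRecord,
)

VARIANT_HEADER = "protein_id\tposition\twt_aa\tmut_aa\tlabel\torigin\n"


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestVariantTable:
    def test_parse_and_filter_origins(self, tmp_path):
        p = write(
            tmp_path,
            "v.tsv",
            VARIANT_HEADER
            + "P1\t5\tA\tC\tCANCER\tGERMLINE\n"
            + "P1\t9\tG\tV\tOTHER\tSOMATIC\n"
            + "P2\t2\tL\tM\tOTHER\tGERMLINE\n",
        )
        all_recs = dataset_io.parse_variant_table(p)
        assert len(all_recs) == 3
        germline = dataset_io.parse_variant_table(p, exclude_origins={Origin.SOMATIC})
        assert [r.protein_id for r in germline] == ["P1", "P2"]
        # filter monotonicity: stricter exclusion yields a subset
        assert set(r.key for r in germline) <= set(r.key for r in all_recs)

    def test_empty_file_with_header(self, tmp_path):
        p = write(tmp_path, "v.tsv", VARIANT_HEADER)
        assert dataset_io.parse_variant_table(p) == []

    def test_duplicate_triple_rejected(self, tmp_path):
        p = write(
            tmp_path,
            "v.tsv",
            VARIANT_HEADER
            + "P1\t5\tA\tC\tCANCER\tGERMLINE\n"
            + "P1\t5\tA\tC\tOTHER\tGERMLINE\n",
        )
        with pytest.raises(ValidationError, match="duplicate"):
            dataset_io.parse_variant_table(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = write(tmp_path, "v.tsv", VARIANT_HEADER + "P1\t5\tA\n")
        with pytest.raises(ParseError, match=":2"):
            dataset_io.parse_variant_table(p)

    def test_silent_mutation_rejected(self, tmp_path):
        p = write(tmp_path, "v.tsv", VARIANT_HEADER + "P1\t5\tA\tA\tCANCER\tGERMLINE\n")
        with pytest.raises((ParseError, ValidationError)):
            dataset_io.parse_variant_table(p)

    def test_round_trip(self, tmp_path):
        records = [
            VariantRecord("P1", 5, "A", "C", Label.CANCER, Origin.GERMLINE),
            VariantRecord("P2", 1, "W", "R", Label.OTHER, Origin.UNKNOWN),
        ]
        p = tmp_path / "v.tsv"
        dataset_io.write_variant_table(p, records)
        assert dataset_io.parse_variant_table(p) == records

    def test_row_adapter_converts_other_layouts(self, tmp_path):
        p = write(
            tmp_path,
            "v.tsv",
            "acc\tpos\tsub\tdisease\n" + "P1\t5\tA/C\tcancer\n",
        )

        def adapt(row):
            wt, mut = row["sub"].split("/")
            return {
                "protein_id": row["acc"],
                "position": row["pos"],
                "wt_aa": wt,
                "mut_aa": mut,
                "label": row["disease"].upper(),
            }

        recs = dataset_io.parse_variant_table(p, row_adapter=adapt)
        assert recs == [VariantRecord("P1", 5, "A", "C", Label.CANCER)]


class TestGoAnnotations:
    def test_tsv_duplicates_collapse(self, tmp_path):
        p = write(
            tmp_path,
            "go.tsv",
            "P1\tGO:0006298\tP\nP1\tGO:0006298\tP\n",
        )
        sets = dataset_io.parse_go_annotations(p, "TSV")
        assert len(sets) == 1
        assert sets[0].terms_by_aspect["P"] == {"GO:0006298"}
        assert sets[0].terms_by_aspect["C"] == set()

    def test_gaf_one_per_aspect(self, tmp_path):
        def gaf_line(term, aspect):
            cols = ["UniProtKB", "P1", "GENE", "", term, "PMID:1", "IDA", "", aspect]
            cols += [""] * 8
            return "\t".join(cols)

        p = write(
            tmp_path,
            "a.gaf",
            "!gaf-version: 2.2\n"
            + gaf_line("GO:0000001", "C")
            + "\n"
            + gaf_line("GO:1000001", "F")
            + "\n"
            + gaf_line("GO:2000001", "P")
            + "\n",
        )
        sets = dataset_io.parse_go_annotations(p, "GAF")
        assert len(sets) == 1
        assert all(len(sets[0].terms_by_aspect[a]) == 1 for a in "CFP")

    def test_bad_aspect_rejected(self, tmp_path):
        p = write(tmp_path, "go.tsv", "P1\tGO:0006298\tQ\n")
        with pytest.raises(ValidationError, match="aspect"):
            dataset_io.parse_go_annotations(p, "TSV")

    def test_bad_term_rejected(self, tmp_path):
        p = write(tmp_path, "go.tsv", "P1\tGO:12\tP\n")
        with pytest.raises(ValidationError, match="GO identifier"):
            dataset_io.parse_go_annotations(p, "TSV")

    def test_term_under_two_aspects_rejected(self):
        s = GoAnnotationSet(protein_id="P1")
        s.add("GO:0000001", "C")
        with pytest.raises(ValidationError):
            s.add("GO:0000001", "F")

    def test_round_trip(self, tmp_path):
        s = GoAnnotationSet(protein_id="P1")
        s.add("GO:0000002", "C")
        s.add("GO:2000001", "P")
        p = tmp_path / "go.tsv"
        dataset_io.write_go_annotations(p, [s])
        back = dataset_io.parse_go_annotations(p, "TSV")
        assert back[0].terms_by_aspect == s.terms_by_aspect


class TestFasta:
    def test_basic(self, tmp_path):
        p = write(tmp_path, "s.fa", ">P1\nACDE\n")
        assert dataset_io.parse_fasta(p) == {"P1": "ACDE"}

    def test_wrapped_record_concatenated(self, tmp_path):
        p = write(tmp_path, "s.fa", ">P1\nACDE\n>P2 desc\nAC\nDE\nFG\n")
        assert dataset_io.parse_fasta(p)["P2"] == "ACDEFG"

    def test_duplicate_identifier_rejected(self, tmp_path):
        p = write(tmp_path, "s.fa", ">P1\nACDE\n>P1\nACDF\n")
        with pytest.raises(ValidationError, match="duplicate"):
            dataset_io.parse_fasta(p)

    def test_fasta_round_trip(self, tmp_path):
        seqs = {"P1": "ACDEFGHIKLMNPQRSTVWY" * 5, "P2": "WWWW"}
        p = tmp_path / "s.fa"
        dataset_io.write_fasta(p, seqs)
        assert dataset_io.parse_fasta(p) == seqs


class TestPssm:
    def make_profile(self, n=10):
        import numpy as np

        rng = np.random.default_rng(0)
        residues = "".join(
            dataset_io.AA_ALPHABET[i] for i in rng.integers(0, 20, size=n)
        )
        logodds = [[int(x) for x in rng.integers(-9, 10, size=20)] for _ in range(n)]
        freqs = [[0.0] * 20 for _ in range(n)]
        for i in range(n):
            freqs[i][int(rng.integers(0, 20))] = 90.0
            freqs[i][int(rng.integers(0, 20))] = 10.0
        return PssmProfile(
            protein_id="P1", residues=residues, logodds=logodds, freqs=freqs
        )

    def test_round_trip_numeric_fields(self, tmp_path):
        profile = self.make_profile()
        p = tmp_path / "P1.pssm"
        dataset_io.write_pssm(p, profile)
        back = dataset_io.parse_pssm(p, protein_id="P1")
        assert back.residues == profile.residues
        assert back.logodds == profile.logodds
        assert back.freqs == profile.freqs
        # re-emitting yields byte-identical files
        p2 = tmp_path / "P1b.pssm"
        dataset_io.write_pssm(p2, back)
        assert p.read_bytes() == p2.read_bytes()

    def test_written_value_read_back(self, tmp_path):
        profile = self.make_profile()
        profile.freqs[3] = [0.0] * 20
        profile.freqs[3][dataset_io.AA_INDEX["D"]] = 90.0
        p = tmp_path / "P1.pssm"
        dataset_io.write_pssm(p, profile)
        assert dataset_io.parse_pssm(p).freq_at(4, "D") == 90.0

    def test_short_row_rejected(self, tmp_path):
        profile = self.make_profile(3)
        p = tmp_path / "P1.pssm"
        dataset_io.write_pssm(p, profile)
        lines = p.read_text().splitlines()
        lines[3] = " ".join(lines[3].split()[:-1])  # drop one numeric field
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="42 fields"):
            dataset_io.parse_pssm(p)

    def test_non_monotonic_index_rejected(self, tmp_path):
        profile = self.make_profile(3)
        p = tmp_path / "P1.pssm"
        dataset_io.write_pssm(p, profile)
        text = p.read_text().replace("\n    2 ", "\n    7 ")
        p.write_text(text)
        with pytest.raises(ParseError, match="non-monotonic"):
            dataset_io.parse_pssm(p)


class TestConsistency:
    def test_mismatch_reported_not_dropped_silently(self):
        variants = [
            VariantRecord("P1", 2, "C", "D", Label.CANCER),
            VariantRecord("P1", 3, "W", "R", Label.OTHER),  # sequence has D
            VariantRecord("P1", 99, "A", "C", Label.OTHER),  # beyond end
            VariantRecord("P2", 1, "A", "C", Label.OTHER),  # no sequence: kept
        ]
        valid, problems = dataset_io.check_consistency(variants, {"P1": "ACDE"})
        assert [v.position for v in valid] == [2, 1]
        assert len(problems) == 2

    def test_x_position_excluded(self):
        variants = [VariantRecord("P1", 2, "C", "D", Label.CANCER)]
        valid, problems = dataset_io.check_consistency(variants, {"P1": "AXDE"})
        assert valid == [] and len(problems) == 1
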