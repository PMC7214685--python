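import gemmi
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisym import (
    Conformer,
    Ensemble,
    NumberingMap,
    RegionSpan,
    detect_gaps,
    map_numbering,
    parse_span,
    read_structure,
    span_length,
    write_structure,
)
from trisym.structure_io import NumberingError, StructureParseError, TopologyError

from conftest import protomer_from_points

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CA  GLY A   2      12.758   7.092  -4.973  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_minimal_single_model(self):
        ens = read_structure(MINIMAL_PDB)
        assert len(ens) == 1
        (prot,) = ens.conformers[0].protomers
        assert list(prot.residue_numbers) == [1, 2]
        np.testing.assert_allclose(prot.ca[0], [11.639, 6.071, -5.147])
        # the backbone N rode along with residue 1
        assert set(prot.atoms[0]) == {"N", "CA"}

    def test_roundtrip_coordinates_stable(self, bundle):
        ens = Ensemble([bundle.as_conformer()])
        again = read_structure(write_structure(ens))
        a = again.conformers[0].protomers[0].ca
        b = bundle.protomers[0].ca
        assert np.abs(a - b).max() < 1e-3
        # a second write/read cycle changes nothing further
        twice = read_structure(write_structure(again))
        assert np.abs(twice.conformers[0].protomers[0].ca - a).max() == 0

    def test_multi_model_policy(self, bundle):
        ens = Ensemble([bundle.as_conformer(), bundle.as_conformer()])
        text = write_structure(ens)
        assert len(read_structure(text, model_policy="all")) == 2
        assert len(read_structure(text, model_policy="first")) == 1
        with pytest.raises(ValueError, match="model_policy"):
            read_structure(text, model_policy="best")

    def test_mmcif_source(self, bundle):
        st_ = gemmi.read_pdb_string(write_structure(Ensemble([bundle.as_conformer()])))
        st_.setup_entities()
        cif_text = st_.make_mmcif_document().as_string()
        ens = read_structure(cif_text)
        assert ens.conformers[0].chain_ids == ["A", "B", "C"]

    def test_malformed_source_raises(self):
        with pytest.raises(StructureParseError):
            read_structure("this is not a structure at all\n")

    def test_mixed_topology_rejected(self, bundle, helix):
        with pytest.raises(TopologyError):
            Ensemble([bundle.as_conformer(), Conformer([helix])])

    def test_altloc_highest_occupancy_kept(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   0.000   0.000  0.70  0.00           C\n"
            "ATOM      3  CA AGLY A   2       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      4  CA BGLY A   2       6.000   0.000   0.000  0.50  0.00           C\n"
            "END\n"
        )
        prot = read_structure(text).conformers[0].protomers[0]
        assert prot.ca[0, 0] == 9.0  # higher occupancy wins
        assert prot.ca[1, 0] == 5.0  # tie goes to the first listed

    def test_residue_without_ca_dropped(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N\n"
            "ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        prot = read_structure(text).conformers[0].protomers[0]
        assert list(prot.residue_numbers) == [1, 3]


class TestWriteStructure:
    def test_trimer_has_three_chains(self, bundle):
        text = write_structure(Ensemble([bundle.as_conformer()]))
        chains = {line[21] for line in text.splitlines() if line.startswith("ATOM")}
        assert chains == {"A", "B", "C"}

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            Ensemble([])

    def test_chain_capacity(self):
        protomers = [
            protomer_from_points([[i, 0, 0], [i, 0, 3.8], [i, 0, 7.6]], chain_id=f"c{i}")
            for i in range(63)
        ]
        with pytest.raises(ValueError, match="62"):
            write_structure(Ensemble([Conformer(protomers)]))


class TestNumbering:
    CD95 = NumberingMap(signal_peptide_length=16)

    @pytest.mark.parametrize(
        "position,src,dst,expected",
        [
            (59, "precursor", "mature", 43),
            (1, "mature", "precursor", 17),
            (102, "precursor", "precursor", 102),
            (171, "file", "precursor", 171),  # identity offset
        ],
    )
    def test_known_conversions(self, position, src, dst, expected):
        assert map_numbering(position, src, dst, self.CD95) == expected

    def test_signal_peptide_has_no_mature_position(self):
        with pytest.raises(NumberingError):
            map_numbering(16, "precursor", "mature", self.CD95)

    @given(st.integers(min_value=17, max_value=500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_roundtrip_is_identity(self, position):
        m = map_numbering(position, "precursor", "mature", self.CD95)
        assert map_numbering(m, "mature", "precursor", self.CD95) == position

    def test_file_offset(self):
        nm = NumberingMap(signal_peptide_length=16, file_to_precursor_offset=5)
        assert map_numbering(100, "file", "precursor", nm) == 105
        assert map_numbering(105, "precursor", "file", nm) == 100


class TestSpans:
    @pytest.mark.parametrize(
        "start,end,expected", [(191, 226, 36), (5, 5, 1), (17, 82, 66)]
    )
    def test_span_length(self, start, end, expected):
        assert span_length(RegionSpan(start, end, "precursor")) == expected

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            RegionSpan(10, 9, "file")

    def test_parse_span(self):
        s = parse_span("17-47:precursor")
        assert (s.start, s.end, s.scheme) == (17, 47, "precursor")
        with pytest.raises(ValueError, match="scheme"):
            parse_span("17-47")

    def test_span_scheme_conversion(self):
        nm = NumberingMap(signal_peptide_length=16)
        s = RegionSpan(59, 82, "precursor").in_scheme("mature", nm)
        assert (s.start, s.end) == (43, 66)


class TestDetectGaps:
    def test_contiguous_has_no_gaps(self):
        prot = protomer_from_points(np.outer(np.arange(10), [3.8, 0, 0]))
        assert detect_gaps(prot) == []

    def test_ecd_tm_junction_gap(self):
        # chain resolved up to 167 and resuming at 171: three missing residues
        from trisym import Protomer

        nums = [n for n in range(160, 180) if not 168 <= n <= 170]
        pts = np.outer(nums, [3.8, 0, 0])
        prot = Protomer("A", np.array(nums), ["ALA"] * len(nums),
                        [{"CA": p} for p in pts], NumberingMap())
        (gap,) = detect_gaps(prot)
        assert (gap.start, gap.end) == (168, 170)
        assert span_length(gap) == 3

    def test_multiple_gaps_sorted_and_cover_interval(self):
        from trisym import Protomer

        nums = [1, 2, 3, 7, 8, 9, 10, 15]
        pts = np.outer(nums, [3.8, 0, 0])
        prot = Protomer("A", np.array(nums), ["ALA"] * len(nums),
                        [{"CA": p} for p in pts], NumberingMap())
        gaps = detect_gaps(prot)
        assert [(g.start, g.end) for g in gaps] == [(4, 6), (11, 14)]
        covered = set(nums) | {n for g in gaps for n in range(g.start, g.end + 1)}
        assert covered == set(range(1, 16))
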