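import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_force_peak_matches
from cystmine.ms_match import (
    PeakList,
    PeakListParseError,
    build_presence_matrix,
    match_ions,
    presence_call,
    read_peak_list,
)
from cystmine.peptide_mass import TheoreticalIonSet, ion_table


def ion_set(name, seq, n_ss=0):
    return ion_table([(name, seq, n_ss)])[0]


@pytest.fixture
def ref_ion(barrettide_c):
    return ion_set(barrettide_c.name, barrettide_c.sequence, 2)


class TestReadPeakList:
    def test_csv_single_peak(self, tmp_path):
        p = tmp_path / "s1.csv"
        p.write_text("1619.681,1000\n")
        pl = read_peak_list(p)
        assert pl.sample == "s1"
        assert pl.peaks == ((1619.681, 1000.0),)

    def test_csv_header_skipped(self, tmp_path):
        p = tmp_path / "s1.csv"
        p.write_text("mz,intensity\n100.5,10\n")
        assert read_peak_list(p).peaks == ((100.5, 10.0),)

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "s1.csv"
        p.write_text("500.0,1\n100.0,2\n300.0,3\n")
        assert read_peak_list(p).mz_values == [100.0, 300.0, 500.0]

    def test_non_numeric_mz_names_line(self, tmp_path):
        p = tmp_path / "s1.csv"
        p.write_text("100.0,1\noops,2\n")
        with pytest.raises(PeakListParseError, match="line 2"):
            read_peak_list(p)

    def test_mgf_block(self, tmp_path):
        p = tmp_path / "s1.mgf"
        p.write_text(
            "BEGIN IONS\nTITLE=x\nPEPMASS=100\n"
            "100.5 10\n200.5 20\nEND IONS\n"
        )
        pl = read_peak_list(p)
        assert pl.peaks == ((100.5, 10.0), (200.5, 20.0))

    def test_rejects_nonpositive_mz(self):
        with pytest.raises(ValueError):
            PeakList(sample="x", peaks=((0.0, 1.0),))


class TestMatchIons:
    def test_match_within_tolerance(self, ref_ion):
        pl = PeakList(sample="s", peaks=((1619.681, 1000.0),))
        matches = match_ions([ref_ion], pl, tolerance=0.05)
        m = next(m for m in matches if m.charge == 2)
        assert m.error_da == pytest.approx(0.0002, abs=1e-4)

    def test_no_match_outside_tolerance(self, ref_ion):
        pl = PeakList(sample="s", peaks=((1620.5, 1000.0),))
        assert match_ions([ref_ion], pl, tolerance=0.05) == []

    def test_isobaric_pair_mutually_ambiguous(self):
        a = ion_set("pep-L", "NLVPKWFCGH")
        b = ion_set("pep-I", "NIVPKWFCGH")
        pl = PeakList(sample="s", peaks=((a.mz_at(2), 500.0),))
        matches = match_ions([a, b], pl, tolerance=0.05)
        by_name = {m.peptide_name: m for m in matches if m.charge == 2}
        assert by_name["pep-L"].ambiguous_with == ("pep-I",)
        assert by_name["pep-I"].ambiguous_with == ("pep-L",)

    def test_nearest_peak_tie_prefers_lower_mz(self, ref_ion):
        t = ref_ion.mz_at(2)
        pl = PeakList(sample="s", peaks=((t - 0.01, 1.0), (t + 0.01, 2.0)))
        m = next(m for m in match_ions([ref_ion], pl, tolerance=0.05)
                 if m.charge == 2)
        assert m.observed_mz == t - 0.01

    def test_ppm_mode(self, ref_ion):
        t = ref_ion.mz_at(1)
        pl = PeakList(sample="s", peaks=((t * (1 + 5e-6), 1.0),))
        assert match_ions([ref_ion], pl, tolerance=10, mode="ppm")
        assert not match_ions([ref_ion], pl, tolerance=1, mode="ppm")

    @given(
        mz_values=st.lists(st.floats(min_value=100, max_value=1500),
                           min_size=1, max_size=30),
        tol=st.floats(min_value=0.001, max_value=1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_against_all_pairs_scan(self, mz_values, tol, barrettide_c):
        ion = ion_set(barrettide_c.name, barrettide_c.sequence, 2)
        pl = PeakList(sample="s",
                      peaks=tuple((v, 1.0) for v in mz_values))
        got = {(m.peptide_name, m.charge)
               for m in match_ions([ion], pl, tolerance=tol)}
        want = brute_force_peak_matches(
            [(ion.peptide_name, z, ion.mz_at(z)) for z in (1, 2, 3, 4)],
            list(mz_values), tol,
        )
        assert got == want


class TestPresenceCall:
    def _matches(self, ion, charges, ambiguous=()):
        pl_peaks = tuple((ion.mz_at(z), 1.0) for z in charges)
        pl = PeakList(sample="s", peaks=pl_peaks)
        return match_ions([ion], pl, tolerance=0.05)

    def test_two_charges_present(self, ref_ion):
        matches = self._matches(ref_ion, (2, 3))
        calls = presence_call(matches, [ref_ion.peptide_name], min_charges=2)
        assert calls[0].present and not calls[0].ambiguous
        assert calls[0].charges == (2, 3)

    def test_single_ambiguous_match_flagged(self):
        a = ion_set("pep-L", "NLVPKWFCGH")
        b = ion_set("pep-I", "NIVPKWFCGH")
        pl = PeakList(sample="s", peaks=((a.mz_at(2), 1.0),))
        matches = match_ions([a, b], pl, tolerance=0.05)
        calls = presence_call(matches, ["pep-L", "pep-I"], min_charges=1)
        assert all(c.present and c.ambiguous for c in calls)

    def test_no_matches_absent(self, ref_ion):
        calls = presence_call([], [ref_ion.peptide_name])
        assert not calls[0].present
        assert calls[0].charges == ()

    def test_insufficient_charges(self, ref_ion):
        matches = self._matches(ref_ion, (2,))
        calls = presence_call(matches, [ref_ion.peptide_name], min_charges=2)
        assert not calls[0].present


class TestPresenceMatrix:
    def test_merged_flags(self, ref_ion):
        pl = PeakList(sample="Gb01", peaks=((ref_ion.mz_at(2), 1.0),))
        calls = presence_call(
            match_ions([ref_ion], pl, tolerance=0.05),
            [ref_ion.peptide_name],
        )
        matrix = build_presence_matrix(
            sequence_evidence={"Gb01": {ref_ion.peptide_name}},
            ms_calls={"Gb01": calls},
            peptides=[ref_ion.peptide_name],
            samples=["Gb01"],
        )
        flags = matrix.flags_at("Gb01", ref_ion.peptide_name)
        assert flags == {"sequence_evidence", "ms_evidence"}

    def test_genome_only_evidence_tagged_separately(self, ref_ion):
        matrix = build_presence_matrix(
            sequence_evidence={},
            ms_calls={},
            peptides=[ref_ion.peptide_name],
            samples=["genome"],
            genome_evidence={"genome": {ref_ion.peptide_name}},
        )
        assert matrix.flags_at("genome", ref_ion.peptide_name) == {
            "genome_evidence"
        }

    def test_unknown_sample_raises(self, ref_ion):
        with pytest.raises(ValueError, match="unknown sample"):
            build_presence_matrix(
                sequence_evidence={"nope": {ref_ion.peptide_name}},
                ms_calls={},
                peptides=[ref_ion.peptide_name],
                samples=["Gb01"],
            )

    def test_empty_inputs(self):
        matrix = build_presence_matrix({}, {}, peptides=[], samples=[])
        assert matrix.cells == {}

    def test_tsv_rendering(self, tmp_path, ref_ion):
        matrix = build_presence_matrix(
            sequence_evidence={"Gb01": {ref_ion.peptide_name}},
            ms_calls={},
            peptides=[ref_ion.peptide_name],
            samples=["Gb01"],
        )
        out = tmp_path / "m.tsv"
        matrix.write_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0].startswith("sample\tpeptide")
        assert lines[1].split("\t")[2] == "1"
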