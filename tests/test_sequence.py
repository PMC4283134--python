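"""Unit and property tests for FG-domain sequence analytics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgphase import sequence as sq

from conftest import AA20, brute_force_classify, random_fg_rich_sequence


class TestFindFGDipeptides:
    @pytest.mark.parametrize("seq,expected", [
        ("", []),
        ("FGFG", [1, 3]),
        ("AFGGFGQ", [2, 5]),
        ("MAAA", []),
        ("FG", [1]),
    ])
    def test_examples(self, seq, expected):
        assert sq.find_fg_dipeptides(seq) == expected

    def test_invalid_character_names_position(self):
        with pytest.raises(sq.SequenceError, match="position 3"):
            sq.find_fg_dipeptides("AFBG")

    @given(st.text(alphabet=AA20, max_size=300))
    @settings(max_examples=200, derandomize=True)
    def test_matches_naive_2mer_scan(self, seq):
        expected = [i + 1 for i in range(len(seq) - 1)
                    if seq[i : i + 2] == "FG"]
        assert sq.find_fg_dipeptides(seq) == expected


class TestMotifClassification:
    @pytest.mark.parametrize("seq,expected_class", [
        ("GLFG", "GLFG"),
        ("PAFGQ", "PAFG"),   # PA context outranks the contained AFG
        ("GFGQ", "GFGQ"),    # suffix-Q context outranks GFG
        ("SLFG", "SLFG"),
        ("APFGA", "PFG"),
        ("AGFGA", "(G/A)FG"),
        ("ATFGA", "(S/T)FG"),
        ("ANFGA", "other FG"),
        ("FG", "other FG"),  # no context at sequence start
    ])
    def test_precedence(self, seq, expected_class):
        rec = sq.FGDomainRecord(id="t", residues=seq)
        counts = sq.classify_fg_motifs(rec)
        assert counts.counts[expected_class] == 1
        assert counts.total_fg == 1

    def test_counts_partition_total(self, rng):
        for _ in range(300):
            seq = random_fg_rich_sequence(rng, int(rng.integers(2, 400)))
            rec = sq.FGDomainRecord(id="t", residues=seq)
            counts = sq.classify_fg_motifs(rec)
            assert sum(counts.counts.values()) == counts.total_fg
            assert counts.total_fg == len(sq.find_fg_dipeptides(seq))

    def test_agrees_with_brute_force_on_long_sequences(self, rng):
        for _ in range(200):
            seq = random_fg_rich_sequence(rng, int(rng.integers(2, 2000)))
            rec = sq.FGDomainRecord(id="t", residues=seq)
            assert sq.classify_fg_motifs(rec).counts == \
                brute_force_classify(seq)

    def test_glebs_not_excluded_from_motif_count(self):
        rec = sq.FGDomainRecord(id="t", residues="GLFGAAAGLFG",
                                glebs_interval=(5, 11))
        assert sq.classify_fg_motifs(rec).total_fg == 2


class TestMotifDensity:
    @pytest.mark.parametrize("total,length,expected", [
        (39, 500, 7.8),
        (47, 737, 6.4),
        (0, 123, 0.0),
    ])
    def test_printed_density_pairs(self, total, length, expected):
        counts = sq.MotifCounts(
            counts={"other FG": total,
                    **{n: 0 for n in sq.MOTIF_CLASS_NAMES
                       if n != "other FG"}},
            total_fg=total, domain_length=length)
        dens = sq.motif_density(counts)
        assert round(dens["All FG dipeptides"], 1) == expected

    def test_zero_length_rejected(self):
        counts = sq.MotifCounts(
            counts={n: 0 for n in sq.MOTIF_CLASS_NAMES},
            total_fg=0, domain_length=0)
        with pytest.raises(ValueError):
            sq.motif_density(counts)


class TestComposition:
    def test_nq_content(self):
        rec = sq.FGDomainRecord(id="t", residues="NQNQ")
        prof = sq.composition_profile(rec, "full_domain")
        assert prof.nq_content == pytest.approx(1.0)

    def test_uncharged_homopolymer(self):
        rec = sq.FGDomainRecord(id="t", residues="GGGG")
        prof = sq.composition_profile(rec, "full_domain")
        assert prof.charged_fraction == 0.0
        assert prof.fractions["G"] == pytest.approx(1.0)

    def test_matches_letter_count_oracle(self, rng):
        seq = "".join(rng.choice(list(AA20), size=1000))
        prof = sq.composition_profile(
            sq.FGDomainRecord(id="t", residues=seq), "full_domain")
        for aa in AA20:
            assert prof.fractions[aa] == pytest.approx(seq.count(aa) / 1000)
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_spacers_exclude_glebs_and_motif_spans(self):
        # GLFG motif (span 4) + GLEBS (6..8) removed => spacers = "AA"+"TT"
        rec = sq.FGDomainRecord(id="t", residues="AAGLFGEKRTT",
                                glebs_interval=(7, 9))
        prof = sq.composition_profile(rec, "spacers")
        assert prof.n_residues == 4
        assert prof.fractions["A"] == pytest.approx(0.5)
        assert prof.fractions["T"] == pytest.approx(0.5)

    def test_dipeptide_only_spacer_masking(self):
        rec = sq.FGDomainRecord(id="t", residues="AAGLFGTT")
        full = sq.composition_profile(rec, "spacers",
                                      full_context_spacers=True)
        dipep = sq.composition_profile(rec, "spacers",
                                       full_context_spacers=False)
        assert full.n_residues == 4      # AA + TT
        assert dipep.n_residues == 6     # AAGL + TT

    def test_empty_region_errors(self):
        rec = sq.FGDomainRecord(id="t", residues="GLFG")
        with pytest.raises(sq.SequenceError, match="no residues"):
            sq.composition_profile(rec, "spacers")


class TestHydrophobicity:
    @pytest.mark.parametrize("seq,expected", [
        ("W", 1.0),
        ("R", 0.0),
        ("G", 0.31),
        ("FILVM", np.mean([0.859, 0.862, 0.831, 0.684, 0.687])),
    ])
    def test_scale_values(self, seq, expected):
        assert sq.mean_hydrophobicity(seq) == pytest.approx(expected)

    def test_scale_has_20_entries_in_unit_interval(self):
        assert len(sq.DEFAULT_HYDROPHOBICITY) == 20
        assert all(0 <= v <= 1
                   for v in sq.DEFAULT_HYDROPHOBICITY.values())

    def test_x_excluded(self):
        assert sq.mean_hydrophobicity("WXX") == pytest.approx(1.0)
        with pytest.raises(sq.SequenceError):
            sq.mean_hydrophobicity("XX")

    @given(st.text(alphabet=AA20, min_size=1, max_size=100))
    @settings(max_examples=100, derandomize=True)
    def test_mean_bounded_by_residue_extremes(self, seq):
        vals = [sq.DEFAULT_HYDROPHOBICITY[c] for c in seq]
        mean = sq.mean_hydrophobicity(seq)
        assert min(vals) - 1e-12 <= mean <= max(vals) + 1e-12


class TestChargeHydropathy:
    def test_fully_charged(self):
        rec = sq.FGDomainRecord(id="t", residues="DEKR")
        assert sq.charge_hydropathy_point(rec).charged_fraction == 1.0

    def test_glycine_point(self):
        rec = sq.FGDomainRecord(id="t", residues="GGGG")
        pt = sq.charge_hydropathy_point(rec)
        assert pt.charged_fraction == 0.0
        assert pt.mean_hydrophobicity == pytest.approx(0.31)

    def test_glebs_excluded_before_counting(self):
        # without exclusion charged fraction would be 4/8
        rec = sq.FGDomainRecord(id="t", residues="GGGGDEKR",
                                glebs_interval=(5, 8))
        assert sq.charge_hydropathy_point(rec).charged_fraction == 0.0

    def test_charged_plus_uncharged_is_one(self, rng):
        seq = "".join(rng.choice(list(AA20), size=500))
        pt = sq.charge_hydropathy_point(
            sq.FGDomainRecord(id="t", residues=seq))
        uncharged = sum(1 for c in seq if c not in "DEKR") / len(seq)
        assert pt.charged_fraction + uncharged == pytest.approx(1.0)


class TestDelimitation:
    def test_domain_ends_at_last_fg_inclusive(self, rng):
        body = "".join(rng.choice(list("ASTGNQP"), size=478))
        seq = body + "FG" + "".join(rng.choice(list("ASTNQP"), size=120))
        rec = sq.delimit_fg_domain(seq, "t")
        assert rec.length == 480
        assert rec.residues.endswith("FG")

    def test_no_fg_is_an_error(self):
        with pytest.raises(sq.SequenceError, match="not an FG domain"):
            sq.delimit_fg_domain("MAAA", "t")

    @pytest.mark.parametrize("length,ok", [(399, False), (400, True),
                                           (1000, True), (1001, False)])
    def test_length_filter_window(self, length, ok):
        seq = "A" * (length - 2) + "FG"
        rec = sq.delimit_fg_domain(seq, "t")
        assert rec.length == length
        assert rec.length_ok is ok


class TestCohortSummary:
    def _record_with_motifs(self, n_motifs, length, idx):
        spacer_len = (length - 2 * n_motifs) // n_motifs
        parts = [("A" * spacer_len) + "FG"] * n_motifs
        seq = "".join(parts)
        seq = seq + "A" * (length - len(seq))
        rec = sq.FGDomainRecord(id=f"r{idx}", residues=seq)
        rec.length_ok = True
        return rec

    def test_median_of_three(self):
        recs = [self._record_with_motifs(n, 520, i)
                for i, n in enumerate([40, 43, 50])]
        summary = sq.cohort_summary(recs)
        assert summary.median_fg_motifs == 43
        assert summary.n_domains == 3

    def test_single_record_zero_dispersion(self):
        recs = [self._record_with_motifs(40, 520, 0)]
        summary = sq.cohort_summary(recs)
        assert summary.mad_fg_motifs == 0.0
        assert summary.sd_fg_motifs == 0.0

    def test_empty_cohort_errors(self):
        with pytest.raises(sq.SequenceError):
            sq.cohort_summary([])


class TestMolecularWeight:
    def test_glycine_masses(self):
        assert sq.molecular_weight("G") * 1000 == pytest.approx(75.07,
                                                                abs=0.05)
        assert sq.molecular_weight("GG") * 1000 == pytest.approx(132.12,
                                                                 abs=0.05)

    def test_x_rejected(self):
        with pytest.raises(sq.SequenceError, match="X"):
            sq.molecular_weight("GXG")


class TestHeatmapBins:
    def test_single_point_single_bin(self):
        pt = sq.ChargeHydropathyPoint("p", 0.5, 0.5)
        assert sq.heatmap_bins([pt], 1).tolist() == [[1]]

    def test_identical_points_occupy_one_cell(self):
        pts = [sq.ChargeHydropathyPoint(f"p{i}", 0.25, 0.75)
               for i in range(4)]
        grid = sq.heatmap_bins(pts, 2)
        assert grid.sum() == 4
        assert grid[0, 1] == 4

    def test_boundary_point_counted(self):
        pt = sq.ChargeHydropathyPoint("p", 1.0, 1.0)
        grid = sq.heatmap_bins([pt], 10)
        assert grid[9, 9] == 1

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sq.heatmap_bins(np.array([[1.2, 0.5]]), 10)

    def test_uniform_points_near_uniform_counts(self, rng):
        pts = rng.uniform(0, 1, size=(10000, 2))
        grid = sq.heatmap_bins(pts, 10)
        assert grid.sum() == 10000
        bound = 4 * np.sqrt(100 * 0.99)
        assert np.all(np.abs(grid - 100) <= bound)
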