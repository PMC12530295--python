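"""Chromosome painting: windows, assignment, calibration, backbone QC."""

import math

import numpy as np
import pytest

from oakpop.paint import (
    BackbonePanel,
    CalibrationResult,
    PaintingConfig,
    PaintingProfile,
    WindowCall,
    assigned_tracts,
    calibrate_threshold,
    classify_admixture,
    paint_genome,
    panel_from_cohort,
    tile_windows,
    validate_backbone,
    window_divergence,
)
from oakpop.seqs import MISSING, StrainGenome


class TestWindows:
    @pytest.mark.parametrize(
        "length, expected",
        [
            (90_000, [(0, 30_000), (30_000, 60_000), (60_000, 90_000)]),
            # 15 kb remainder is exactly half a window: kept
            (75_000, [(0, 30_000), (30_000, 60_000), (60_000, 75_000)]),
            # 10 kb remainder is under half a window: merged into previous
            (70_000, [(0, 30_000), (30_000, 70_000)]),
            (20_000, [(0, 20_000)]),  # single short chromosome
        ],
    )
    def test_trailing_window_rules(self, length, expected):
        assert tile_windows(length, 30_000) == expected

    def test_windows_tile_without_overlap(self):
        for length in (31_000, 59_999, 123_456, 300_000):
            wins = tile_windows(length, 30_000)
            assert wins[0][0] == 0 and wins[-1][1] == length
            assert all(w[1] == v[0] for w, v in zip(wins, wins[1:]))
            assert sum(e - s for s, e in wins) == length


class TestWindowDivergence:
    def test_identical_windows(self):
        seq = np.zeros(30_000, dtype=np.uint8)
        assert window_divergence(seq, seq, 0, 30_000) == (0.0, 30_000)

    def test_ninety_mismatches_is_exactly_the_threshold(self):
        a = np.zeros(30_000, dtype=np.uint8)
        b = a.copy()
        b[:90] = 1
        d, n = window_divergence(a, b, 0, 30_000)
        assert (d, n) == (0.003, 30_000)

    def test_all_n_query_has_zero_compared_sites(self):
        a = np.full(30_000, MISSING, dtype=np.uint8)
        b = np.zeros(30_000, dtype=np.uint8)
        _, n = window_divergence(a, b, 0, 30_000)
        assert n == 0


class TestPaintGenome:
    def test_self_painting_identity(self, paperlike_cohort, paperlike_panel):
        """Painting a panel strain against a panel containing it assigns
        every window to its own clade at zero divergence."""
        for strain in ("AsiaA_s01", "WineEuropean_s03"):
            profile = paint_genome(paperlike_cohort.genome(strain), paperlike_panel)
            clade = paperlike_cohort.truth_clades[strain]
            assert profile.composition == {clade: 1.0}
            assert all(w.min_prop_diff == 0.0 for w in profile.windows)
            assert not profile.admixed

    def test_mosaic_recovers_truth_tracts_to_window_resolution(
        self, paperlike_cohort, paperlike_panel
    ):
        profile = paint_genome(paperlike_cohort.genome("mosaic_EU1"), paperlike_panel)
        window = 30_000
        for chrom, start, end, donor in paperlike_cohort.truth_tracts["mosaic_EU1"]:
            runs = [
                t
                for t in assigned_tracts(profile)
                if t[0] == chrom and t[3] == donor and t[1] < end and start < t[2]
            ]
            assert len(runs) == 1, f"tract {chrom}:{start}-{end} not recovered"
            _, rs, re, _ = runs[0]
            assert abs(rs - start) <= window and abs(re - end) <= window
        assert profile.admixed  # three-lineage mosaic is under 90% primary

    def test_query_from_unrepresented_clade_is_all_white(
        self, paperlike_cohort, paperlike_panel
    ):
        reduced = BackbonePanel(
            {
                c: gs
                for c, gs in paperlike_panel.clades.items()
                if c != "AsiaA"
            }
        )
        profile = paint_genome(paperlike_cohort.genome("AsiaA_s01"), reduced)
        assert profile.diverged_fraction == 1.0
        assert profile.composition == {}

    def test_missing_chromosome_in_panel_is_an_error(self, paperlike_panel):
        rogue = StrainGenome("rogue", {"chr99": np.zeros(60_000, dtype=np.uint8)})
        with pytest.raises(ValueError, match="chr99"):
            paint_genome(rogue, paperlike_panel)

    def test_all_n_query_is_low_coverage(self, paperlike_panel):
        chroms = {
            c: np.full(l, MISSING, dtype=np.uint8)
            for c, l in next(
                iter(paperlike_panel.clades.values())
            )[0].chrom_lengths().items()
        }
        profile = paint_genome(StrainGenome("blank", chroms), paperlike_panel)
        assert profile.low_coverage_fraction == 1.0

    def test_raising_threshold_never_unassigns_windows(
        self, paperlike_cohort, paperlike_panel
    ):
        q = paperlike_cohort.genome("mosaic_EU1")
        counts = [
            paint_genome(q, paperlike_panel, PaintingConfig(divergence_threshold=t)).n_assigned
            for t in (0.0005, 0.003, 0.01)
        ]
        assert counts == sorted(counts)

    def test_tie_assigned_to_lexicographically_smallest_clade(self):
        seq = np.zeros(60_000, dtype=np.uint8)
        panel = BackbonePanel(
            {
                "zeta": [StrainGenome("z1", {"chr01": seq.copy()})],
                "alpha": [StrainGenome("a1", {"chr01": seq.copy()})],
            }
        )
        profile = paint_genome(StrainGenome("q", {"chr01": seq.copy()}), panel)
        assert all(w.tie for w in profile.windows)
        assert profile.composition == {"alpha": 1.0}


class TestClassifyAdmixture:
    def _profile(self, composition):
        return PaintingProfile("s", [], composition, 0.0, 0.0, None, False)

    def test_pure_strain_not_admixed(self):
        assert classify_admixture(self._profile({"A": 1.0})) is False

    def test_exactly_ninety_percent_not_admixed(self):
        assert classify_admixture(self._profile({"A": 0.90, "B": 0.10})) is False

    def test_below_ninety_percent_admixed(self):
        assert classify_admixture(self._profile({"A": 0.85, "B": 0.15})) is True

    def test_no_assigned_windows_is_an_error(self):
        with pytest.raises(ValueError, match="assigned"):
            classify_admixture(self._profile({}))


class TestCalibration:
    def test_identical_strains_suggest_minimum_resolution(self):
        seq = np.zeros(90_000, dtype=np.uint8)
        panel = BackbonePanel(
            {"A": [StrainGenome(f"A_s{i}", {"chr01": seq.copy()}) for i in range(3)]}
        )
        result = calibrate_threshold(panel)
        assert (result.within == 0).all()
        assert result.suggested_threshold == pytest.approx(1 / 30_000)

    def test_single_strain_clades_warn(self):
        seq = np.zeros(60_000, dtype=np.uint8)
        panel = BackbonePanel(
            {
                "A": [StrainGenome("a", {"chr01": seq.copy()})],
                "B": [StrainGenome("b", {"chr01": seq.copy()})],
            }
        )
        result = calibrate_threshold(panel)
        assert result.within.size == 0
        assert result.warning is not None

    def test_paperlike_panel_reproduces_threshold_justification(
        self, paperlike_panel
    ):
        result = calibrate_threshold(paperlike_panel)
        assert result.fraction_within_below >= 0.90
        assert result.fraction_between_above > 0.5
        assert result.suggested_threshold <= 0.003


class TestValidateBackbone:
    def test_clean_panel_keeps_everything(self, paperlike_panel):
        kept, removals = validate_backbone(paperlike_panel)
        assert removals == []
        assert kept.strain_ids() == paperlike_panel.strain_ids()

    def test_two_clade_mosaic_removed_for_secondary_assignment(
        self, paperlike_cohort, paperlike_panel
    ):
        # rebuild the panel with one backbone strain replaced by a 60/40
        # NorthAmericanA/EuropeanOak chimera (chromosome-level swap)
        chimera = paperlike_cohort.genome("NorthAmericanA_s01").copy()
        donor = paperlike_cohort.genome("EuropeanOak_s02")
        lengths = {c: len(s) for c, s in chimera.sequences.items()}
        total = sum(lengths.values())
        swapped = 0
        for chrom in sorted(lengths, reverse=True):
            if swapped / total >= 0.4:
                break
            chimera.sequences[chrom] = donor.sequences[chrom].copy()
            swapped += lengths[chrom]
        clades = {c: list(gs) for c, gs in paperlike_panel.clades.items()}
        clades["NorthAmericanA"] = [
            chimera if g.strain == "NorthAmericanA_s01" else g
            for g in clades["NorthAmericanA"]
        ]
        _, removals = validate_backbone(BackbonePanel(clades))
        assert ("NorthAmericanA_s01", "secondary_assignment_above_10pct") in removals

    def test_diverged_outsider_removed_for_low_primary(self, paperlike_panel):
        rng = np.random.default_rng(5)
        first_clade = paperlike_panel.clade_names[0]
        outsider = paperlike_panel.clades[first_clade][0].copy()
        for chrom, seq in outsider.sequences.items():
            outsider.sequences[chrom] = rng.integers(
                0, 4, len(seq), dtype=np.uint8
            )
        clades = {c: list(gs) for c, gs in paperlike_panel.clades.items()}
        clades[first_clade] = [outsider] + clades[first_clade][1:]
        _, removals = validate_backbone(BackbonePanel(clades))
        assert (outsider.strain, "primary_assignment_below_50pct") in removals
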