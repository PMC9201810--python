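"""CNV-profile reduction, mode classification and breakpoint refinement."""

import numpy as np
import pytest

from quadseg import (
    CNVCall,
    EmbryoCNVProfile,
    classify,
    enumerate_gamete_classes,
    estimate_breakpoints,
    profile_to_dosage,
    signature_table,
)
from quadseg.classifier import (
    BreakpointEstimationUnavailable,
    CNVInputError,
)
from quadseg.segregation import embryo_signature

TOL = 5_000_000


def profile_from_entry(entry, embryo_id="e1", carrier_id="T1", shift=0):
    calls = tuple(
        CNVCall(chromosome=c, start_bp=max(0, s + shift), end_bp=e + shift, copy_number=cn)
        for c, s, e, cn in entry.intervals
    )
    return EmbryoCNVProfile(embryo_id=embryo_id, carrier_id=carrier_id, calls=calls)


class TestProfileToDosage:
    def test_empty_profile_is_disomic(self, toy_table, toy_translocation):
        p = EmbryoCNVProfile("e0", "T1", ())
        dosage, residuals, dev = profile_to_dosage(p, toy_translocation, toy_table)
        assert dosage.as_tuple() == (2, 2, 2, 2)
        assert residuals == [] and dev == 0

    def test_signature_intervals_invert(self, toy_table, toy_translocation):
        # gain of ts_a (breakpoint -> qter of chr4), loss of ts_b
        p = EmbryoCNVProfile(
            "e1", "T1",
            (
                CNVCall("4", 80_000_000, 100_000_000, 3),
                CNVCall("13", 30_000_000, 60_000_000, 1),
            ),
        )
        dosage, residuals, _ = profile_to_dosage(p, toy_translocation, toy_table)
        assert dosage.as_tuple() == (2, 3, 2, 1)
        assert residuals == []

    def test_uninvolved_whole_chromosome_is_residual(self, chrom_table, real_translocation):
        p = EmbryoCNVProfile(
            "e2", "R1",
            (CNVCall("16", 0, chrom_table["16"].length_bp, 3),),
        )
        dosage, residuals, _ = profile_to_dosage(p, real_translocation, chrom_table)
        assert dosage.as_tuple() == (2, 2, 2, 2)
        assert len(residuals) == 1

    def test_overlapping_calls_rejected(self, toy_table, toy_translocation):
        p = EmbryoCNVProfile(
            "e3", "T1",
            (
                CNVCall("4", 10_000_000, 30_000_000, 3),
                CNVCall("4", 20_000_000, 40_000_000, 1),
            ),
        )
        with pytest.raises(CNVInputError, match="overlapping"):
            profile_to_dosage(p, toy_translocation, toy_table)


class TestClassify:
    def test_round_trip_all_sixteen_classes(self, toy_table, toy_translocation):
        """Emitting each class's exact signature intervals as CNV calls
        recovers that class's mode (balanced classes -> alternate)."""
        table = signature_table(toy_translocation, toy_table)
        for g in enumerate_gamete_classes(include_recombinants=False):
            sig = embryo_signature(g)
            entry = table[sig.dosage.as_tuple()]
            call = classify(
                profile_from_entry(entry), toy_translocation, toy_table
            )
            assert call.mode == g.mode
            assert call.balanced == (g.mode == "alternate")
            assert not call.incidental_aneuploidy

    def test_tolerance_bounded_perturbation_invariance(self, toy_table, toy_translocation):
        table = signature_table(toy_translocation, toy_table)
        entry = table[(2, 3, 2, 1)]
        for shift in (-4_000_000, -1_000_000, 2_500_000, 4_000_000):
            call = classify(
                profile_from_entry(entry, shift=shift), toy_translocation, toy_table,
                tol_bp=TOL,
            )
            assert call.mode == "adjacent-1"
            assert call.max_breakpoint_deviation_bp <= TOL

    def test_balanced_with_incidental_trisomy(self, chrom_table, real_translocation):
        """Trisomy 16 on a balanced quadrivalent: counted as alternate but
        flagged, mirroring the alternate vs transferable-normal distinction."""
        p = EmbryoCNVProfile(
            "e4", "R1", (CNVCall("16", 0, chrom_table["16"].length_bp, 3),)
        )
        call = classify(p, real_translocation, chrom_table)
        assert call.mode == "alternate" and call.balanced
        assert call.incidental_aneuploidy

    def test_partial_residual_on_involved_chromosome_is_nd(self, toy_table, toy_translocation):
        # mid-arm fragment matching no segment boundary
        p = EmbryoCNVProfile(
            "e5", "T1", (CNVCall("4", 55_000_000, 70_000_000, 3),)
        )
        call = classify(p, toy_translocation, toy_table)
        assert call.mode == "ND"
        assert not call.balanced and call.matched_dosage is None

    def test_unmatched_dosage_is_nd(self, toy_table, toy_translocation):
        # both translocated segments gained: no segregation product
        p = EmbryoCNVProfile(
            "e6", "T1",
            (
                CNVCall("4", 80_000_000, 100_000_000, 4),
                CNVCall("13", 30_000_000, 60_000_000, 4),
            ),
        )
        call = classify(p, toy_translocation, toy_table)
        assert call.mode == "ND"

    def test_sub_floor_and_high_cn_calls_dropped(self, toy_table, toy_translocation):
        p = EmbryoCNVProfile(
            "e7", "T1",
            (
                CNVCall("4", 50_000_000, 50_500_000, 3),  # < 1 Mb floor
                CNVCall("13", 30_000_000, 60_000_000, 5),  # cn > 4
            ),
        )
        call = classify(p, toy_translocation, toy_table)
        assert call.mode == "alternate" and call.balanced


class TestEstimateBreakpoints:
    def _profiles(self, boundaries, carrier="T1"):
        return [
            EmbryoCNVProfile(
                f"e{i}", carrier, (CNVCall("4", int(b), 100_000_000, 3),)
            )
            for i, b in enumerate(boundaries)
        ]

    def test_exact_boundaries(self, toy_table, toy_translocation):
        profs = self._profiles([80_000_000] * 5)
        profs += [
            EmbryoCNVProfile("x", "T1", (CNVCall("13", 30_000_000, 60_000_000, 1),))
        ]
        e1, e2 = estimate_breakpoints(profs, toy_translocation, toy_table)
        assert e1.position_bp == 80_000_000 and e1.dispersion_bp == 0
        assert e1.n_supporting_embryos == 5
        assert e2.position_bp == 30_000_000

    def test_median_and_mad(self, toy_table, toy_translocation):
        profs = self._profiles([79_000_000, 80_000_000, 81_000_000])
        profs += [
            EmbryoCNVProfile("x", "T1", (CNVCall("13", 30_000_000, 60_000_000, 1),))
        ]
        e1, _ = estimate_breakpoints(profs, toy_translocation, toy_table)
        assert e1.position_bp == 80_000_000
        assert e1.dispersion_bp == pytest.approx(1_000_000)

    def test_no_support_raises(self, toy_table, toy_translocation):
        with pytest.raises(BreakpointEstimationUnavailable):
            estimate_breakpoints(
                [EmbryoCNVProfile("e", "T1", ())], toy_translocation, toy_table
            )

    def test_monte_carlo_accuracy(self, toy_table, toy_translocation):
        """Median of jittered boundaries (SD 1 Mb, 20 embryos) lands within
        0.5 Mb of the true breakpoint in >= 95% of 200 replicates."""
        rng = np.random.default_rng(2024)
        hits = 0
        for _ in range(200):
            bounds = 80_000_000 + rng.normal(0, 1_000_000, size=20)
            profs = self._profiles(bounds) + [
                EmbryoCNVProfile("x", "T1", (CNVCall("13", 30_000_000, 60_000_000, 1),))
            ]
            est, _ = estimate_breakpoints(profs, toy_translocation, toy_table)
            hits += abs(est.position_bp - 80_000_000) <= 500_000
        assert hits >= 190


class TestNDMonotonicity:
    def test_nd_rate_nondecreasing_in_noise(self, chrom_table):
        """Boundary jitter beyond the matching tolerance can only push
        embryos into ND, never out of it."""
        from quadseg import default_config_from_paper, simulate_cohort
        from quadseg.pipeline import classified_table_from_simulation

        fractions = []
        for sd in (0.0, 6e6, 12e6):
            cfg = default_config_from_paper(seed=5, n_carriers=150)
            cfg.cnv_noise_sd_bp = sd
            cfg.nd_rate = 0.0
            sim = simulate_cohort(cfg)
            tab = classified_table_from_simulation(sim, chrom_table)
            fractions.append((tab["mode"] == "ND").mean())
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[0] == 0.0
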