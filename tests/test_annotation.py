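"""Peak annotation, LOD filtering, redox/group summaries, CL decomposition."""

import numpy as np
import pytest

from picocell.annotation import (
    AnnotationHit,
    MetaboliteRecord,
    Peak,
    annotate_peaks,
    calibration_fit,
    cl_pg_pairs,
    group_cumulative_intensity,
    load_metabolite_db,
    lod_filter,
    redox_ratios,
)
from picocell.chem import AcylComposition, ElementalFormula, IonMode, ion_mz


def make_hit(name, group, mz, intensity):
    record = MetaboliteRecord(
        name, (ElementalFormula.parse("C6H12O6"),), group, (IonMode.DEPROTONATED,)
    )
    return AnnotationHit(Peak(mz, intensity), record, record.ions()[0], 0.0)


class TestBundledDatabase:
    def test_nominal_mz_reproduces_reported_assignments(self, db_by_name):
        expected = {
            "malate": ("deprotonated", 133),
            "glutamate": ("deprotonated", 146),
            "hexose": ("deprotonated", 179),
            "citrate": ("deprotonated", 191),
            "hexose_phosphate": ("deprotonated", 259),
            "hexose_disaccharide": ("deprotonated", 341),
            "hexose_phosphate+hexose": ("cluster_deprotonated", 439),
            "hexose_disaccharide_dimer": ("cluster_deprotonated", 683),
            "CL(70:5)": ("double_deprotonated", 712),
            "PC(31:2)": ("deprotonated", 714),
            "PE(34:2)": ("deprotonated", 714),
            "PG(32:1)": ("deprotonated", 719),
            "PC(33:4)": ("deprotonated", 738),
            "PG(34:2)": ("deprotonated", 745),
            "PS(33:0)": ("deprotonated", 748),
            "MGDG(36:5)": ("deprotonated", 775),
            "PI(34:2)": ("deprotonated", 833),
            "PI(36:2)": ("deprotonated", 861),
        }
        # printed nominal m/z truncate the decimal part (lipids sit at x.5)
        for name, (mode, nominal) in expected.items():
            record = db_by_name[name]
            ion = next(i for i in record.ions() if i.mode.value == mode)
            assert int(ion_mz(ion)) == nominal, name

    def test_chloride_adduct_of_disaccharide_at_377(self, db_by_name):
        record = db_by_name["hexose_disaccharide"]
        ion = next(i for i in record.ions() if i.mode is IonMode.CHLORIDE)
        assert round(ion_mz(ion)) == 377


class TestAnnotatePeaks:
    def test_exact_match_single_hit(self, db):
        hits = annotate_peaks([Peak(191.0197, 100.0)], db)
        assert len(hits) == 1
        assert hits[0].record.name == "citrate"
        assert abs(hits[0].ppm_error) < 0.5

    def test_outside_tolerance_no_hit(self, db):
        hits = annotate_peaks([Peak(191.0197 * (1 + 10e-6), 100.0)], db)
        assert hits == []

    def test_exact_isobars_reported_side_by_side(self, db):
        pc_pe_mz = 714.5074
        names = {h.record.name for h in annotate_peaks([Peak(pc_pe_mz, 50.0)], db)}
        assert {"PC(31:2)", "PE(34:2)"} <= names

    def test_empty_db_gives_empty_result(self):
        assert annotate_peaks([Peak(191.0, 1.0)], []) == []

    def test_hits_sorted_by_absolute_ppm_error(self, db):
        peaks = [Peak(191.0197 * (1 + 3e-6), 10.0), Peak(133.0142, 10.0)]
        hits = annotate_peaks(peaks, db)
        errors = [abs(h.ppm_error) for h in hits]
        assert errors == sorted(errors)

    def test_jittered_synthetic_spectrum_fully_recovered(self):
        # 20 well-separated synthetic formulas; jitter within +/-4 ppm
        records = [
            MetaboliteRecord(
                f"m{k}",
                (ElementalFormula.from_dict({"C": 6 + k, "H": 10 + 2 * k, "O": 5}),),
                "other",
                (IonMode.DEPROTONATED,),
            )
            for k in range(20)
        ]
        theoreticals = [ion_mz(r.ions()[0]) for r in records]
        # brute-force pairwise separation check of the generated db
        for i in range(20):
            for j in range(i + 1, 20):
                sep = abs(theoreticals[i] - theoreticals[j]) / theoreticals[j] * 1e6
                assert sep > 25.0
        rng = np.random.default_rng(7)
        peaks = [
            Peak(t * (1 + rng.uniform(-4, 4) * 1e-6), 100.0) for t in theoreticals
        ]
        hits = annotate_peaks(peaks, records)
        assert len(hits) == 20
        assert {h.record.name for h in hits} == {r.name for r in records}


class TestLodFilter:
    def test_boundary_inclusive(self):
        peaks = [Peak(100.0, 29.0), Peak(101.0, 30.0), Peak(102.0, 31.0)]
        kept = lod_filter(peaks, 10.0)
        assert [p.intensity for p in kept] == [30.0, 31.0]

    def test_all_below_threshold(self):
        assert lod_filter([Peak(100.0, 10.0), Peak(101.0, 29.9)], 10.0) == []

    def test_matches_brute_force_count_and_preserves_order(self):
        rng = np.random.default_rng(3)
        peaks = [
            Peak(float(mz), float(i))
            for mz, i in zip(rng.uniform(80, 900, 1000), rng.uniform(0, 100, 1000))
        ]
        kept = lod_filter(peaks, 10.0)
        assert len(kept) == sum(1 for p in peaks if p.intensity >= 30.0)
        assert kept == [p for p in peaks if p.intensity >= 30.0]

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            lod_filter([], 0.0)


class TestRedoxRatios:
    def test_reduced_over_oxidized(self):
        hits = [
            make_hit("ascorbate", "redox", 175.02, 100.0),
            make_hit("dehydroascorbate", "redox", 173.01, 50.0),
            make_hit("glutathione", "redox", 306.08, 40.0),
            make_hit("glutathione_oxidized", "redox", 611.14, 40.0),
        ]
        ratios = redox_ratios(hits)
        assert ratios.asc_dha == pytest.approx(2.0)
        assert ratios.gsh_gssg == pytest.approx(1.0)

    def test_missing_oxidized_form_flagged_undefined(self):
        hits = [make_hit("ascorbate", "redox", 175.02, 100.0)]
        assert redox_ratios(hits).asc_dha is None

    def test_zero_denominator_flagged_not_infinite(self):
        hits = [
            make_hit("ascorbate", "redox", 175.02, 100.0),
            make_hit("dehydroascorbate", "redox", 173.01, 0.0),
        ]
        assert redox_ratios(hits).asc_dha is None


class TestGroupIntensity:
    def test_simple_sum(self):
        hits = [make_hit("a", "TCA", 133.0, 10.0), make_hit("b", "TCA", 191.0, 20.0)]
        assert group_cumulative_intensity(hits, "TCA") == pytest.approx(30.0)

    def test_empty_group_is_zero(self):
        assert group_cumulative_intensity([], "CL") == 0.0

    def test_peak_with_multiple_hits_in_group_counted_once(self):
        peak_mz, peak_i = 714.5074, 33.0
        hits = [
            make_hit("PC(31:2)", "phospholipid", peak_mz, peak_i),
            make_hit("PE(34:2)", "phospholipid", peak_mz, peak_i),
        ]
        assert group_cumulative_intensity(hits, "phospholipid") == pytest.approx(33.0)

    def test_random_hits_match_brute_force_tally(self):
        rng = np.random.default_rng(11)
        groups = ["TCA", "glycolysis", "CL"]
        hits = []
        for k in range(50):
            group = groups[int(rng.integers(3))]
            hits.append(make_hit(f"s{k}", group, 100.0 + k, float(rng.uniform(1, 10))))
        for group in groups:
            expected = sum(h.peak.intensity for h in hits if h.record.pathway_group == group)
            assert group_cumulative_intensity(hits, group) == pytest.approx(expected)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            group_cumulative_intensity([], "lipidomicz")


class TestClPgPairs:
    def test_reported_cl70_4_decomposition(self):
        candidates = [AcylComposition.parse(t) for t in ("32:1", "34:1", "34:2", "36:2", "36:3")]
        pairs = cl_pg_pairs(AcylComposition(70, 4), candidates)
        as_text = {(str(a), str(b)) for a, b in pairs}
        assert as_text == {("34:1", "36:3"), ("34:2", "36:2")}

    def test_no_complement_gives_empty(self):
        assert cl_pg_pairs(AcylComposition(70, 4), [AcylComposition(34, 1)]) == []

    def test_self_pair_requires_duplicate_listing(self):
        one = cl_pg_pairs(AcylComposition(72, 4), [AcylComposition(36, 2)])
        assert one == []
        two = cl_pg_pairs(
            AcylComposition(72, 4), [AcylComposition(36, 2), AcylComposition(36, 2)]
        )
        assert [(str(a), str(b)) for a, b in two] == [("36:2", "36:2")]

    def test_pairs_sum_to_cl_composition_brute_force(self):
        rng = np.random.default_rng(5)
        candidates = [
            AcylComposition(int(2 * rng.integers(14, 22)), int(rng.integers(0, 4)))
            for _ in range(12)
        ]
        cl = AcylComposition(70, 4)
        for a, b in cl_pg_pairs(cl, candidates):
            assert a.carbons + b.carbons == cl.carbons
            assert a.double_bonds + b.double_bonds == cl.double_bonds


class TestCalibrationFit:
    def test_perfectly_linear(self):
        moles = [1.0, 2.0, 3.0, 4.0]
        fit = calibration_fit(moles, [10.0, 20.0, 30.0, 40.0])
        assert fit.slope == pytest.approx(10.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_intensities_zero_slope(self):
        with pytest.warns(UserWarning):
            fit = calibration_fit([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            calibration_fit([1.0, 2.0], [1.0, 2.0, 3.0])
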