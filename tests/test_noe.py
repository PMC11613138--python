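"""NOE volume -> distance calibration and restraint export."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from meltfold import synth
from meltfold.noe import (
    BDNA_REFERENCE_DISTANCES,
    CrossPeak,
    calibrate_reference,
    compare_to_bdna,
    export_restraints,
    peak_to_distance,
    peaks_to_distances,
    read_restraints,
    restraints_md_block,
)


def _ref_peak(volume, res="C-4"):
    return CrossPeak((res, "H5"), (res, "H6"), volume)


class TestCalibration:
    def test_mean_of_reference_volumes(self):
        peaks = [_ref_peak(1.0), _ref_peak(2.0, "C-5"), _ref_peak(3.0, "C7")]
        assert calibrate_reference(peaks) == pytest.approx(2.0)

    def test_single_reference(self):
        assert calibrate_reference([_ref_peak(7.5)]) == 7.5

    def test_missing_reference_errors(self):
        peaks = [CrossPeak(("A6", "H8"), ("A6", "H1'"), 10.0)]
        with pytest.raises(ValueError, match="CH5-H6"):
            calibrate_reference(peaks)

    def test_internucleotide_h5_h6_not_a_reference(self):
        # H5 and H6 on different cytosines do not calibrate
        peaks = [CrossPeak(("C-4", "H5"), ("C-5", "H6"), 5.0)]
        with pytest.raises(ValueError):
            calibrate_reference(peaks)


class TestDistanceConversion:
    def test_reference_volume_gives_reference_distance(self):
        d = peak_to_distance(_ref_peak(4.0), I_ref=4.0)
        assert d.d == pytest.approx(2.9)

    @pytest.mark.parametrize("ratio,expected", [(1 / 64, 5.8), (64.0, 1.45)])
    def test_sixth_root_scaling(self, ratio, expected):
        d = peak_to_distance(_ref_peak(4.0 * ratio), I_ref=4.0)
        assert d.d == pytest.approx(expected)

    def test_nonpositive_volume_errors(self):
        with pytest.raises(ValueError):
            peak_to_distance(_ref_peak(-1.0), I_ref=1.0)

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, k):
        peaks = [_ref_peak(2.0), CrossPeak(("A6", "H8"), ("A6", "H1'"), 0.31)]
        d1 = peaks_to_distances(peaks)
        d2 = peaks_to_distances(
            [CrossPeak(p.atom_a, p.atom_b, p.volume * k) for p in peaks]
        )
        for a, b in zip(d1, d2):
            assert a.d == pytest.approx(b.d, rel=1e-12)

    def test_monotone_volume_to_distance(self):
        I_ref = 1.0
        vols = [0.1, 0.5, 1.0, 4.0, 20.0]
        ds = [peak_to_distance(_ref_peak(v), I_ref).d for v in vols]
        assert all(a > b for a, b in zip(ds, ds[1:]))

    def test_symmetric_peaks_averaged(self):
        peaks = [
            _ref_peak(1.0),
            CrossPeak(("A6", "H8"), ("T5", "H6"), 2.0),
            CrossPeak(("T5", "H6"), ("A6", "H8"), 4.0),
        ]
        dists = peaks_to_distances(peaks)
        cross = [d for d in dists if {"H8"} & {d.pair[0][1], d.pair[1][1]}]
        assert len(cross) == 1
        assert cross[0].I == pytest.approx(3.0)

    def test_methyl_pseudoatom_convention(self):
        # a methyl peak integrates 3 protons; its volume is divided by 3
        methyl = CrossPeak(("T-2", "M7"), ("A-1", "H8"), 3.0)
        plain = CrossPeak(("T-2", "H6"), ("A-1", "H8"), 1.0)
        dm = peak_to_distance(methyl, I_ref=1.0)
        dp = peak_to_distance(plain, I_ref=1.0)
        assert dm.d == pytest.approx(dp.d)


class TestSyntheticClosure:
    def test_noiseless_geometry_round_trip(self):
        geometry = [
            (("C-4", "H5"), ("C-4", "H6"), 2.9),
            (("A6", "H8"), ("A6", "H1'"), 3.71),
            (("T-2", "M7"), ("A-1", "H8"), 3.42),
            (("G5", "H8"), ("A6", "H1'"), 2.17),
        ]
        cfg = synth.SynthConfig(seed=0, noe_noise_rel=0.0)
        peaks = synth.synth_noesy_peaks(geometry, scale=5e5, cfg=cfg)
        dists = {tuple(sorted((d.pair[0], d.pair[1]))): d.d
                 for d in peaks_to_distances(peaks)}
        for a, b, true_d in geometry:
            key = tuple(sorted((a, b)))
            assert dists[key] == pytest.approx(true_d, abs=1e-10)

    def test_small_volume_noise_compressed_by_sixth_root(self):
        geometry = [(("C-4", "H5"), ("C-4", "H6"), 2.9)] + [
            (("A6", "H8"), (f"T{k}", "H6"), 3.5) for k in range(1, 30)
        ]
        cfg = synth.SynthConfig(seed=8, noe_noise_rel=0.05)
        peaks = synth.synth_noesy_peaks(geometry, scale=1e6, cfg=cfg)
        dists = [d.d for d in peaks_to_distances(peaks) if d.d != pytest.approx(2.9, abs=0.2)]
        rel = np.abs(np.array(dists) - 3.5) / 3.5
        assert np.median(rel) < 0.01  # ~ 5%/6 before calibration jitter


class TestBdnaComparison:
    def _estimates(self, offset_central_intra=0.0):
        from meltfold.noe import DistanceEstimate

        out = []
        for pos, kind in [(-7, "intra"), (6, "inter"), (-2, "intra"), (1, "intra")]:
            ref = BDNA_REFERENCE_DISTANCES[kind]
            d = ref + (offset_central_intra if abs(pos) < 4 and kind == "intra" else 0.0)
            out.append(
                DistanceEstimate(
                    pair=((f"A{pos}", "H8"), (f"A{pos}", "H1'")),
                    d=d, I=1.0, I_ref=1.0, kind=kind,
                )
            )
        return out

    def test_matching_distances_give_zero_deviation(self):
        rep = compare_to_bdna(self._estimates())
        assert np.allclose(rep["mean_deviation"], 0.0)
        assert set(rep["sign"]) == {"matching"}

    def test_central_shortening_reported_with_sign(self):
        rep = compare_to_bdna(self._estimates(offset_central_intra=-0.3))
        row = rep[(rep.region == "central") & (rep.kind == "intra")].iloc[0]
        assert row["mean_deviation"] == pytest.approx(-0.3)
        assert row["sign"] == "shortened"

    def test_unlabeled_pairs_excluded(self):
        from meltfold.noe import DistanceEstimate

        unl = DistanceEstimate(
            pair=(("A1", "H8"), ("A1", "H1'")), d=3.0, I=1.0, I_ref=1.0, kind=""
        )
        rep = compare_to_bdna([unl])
        assert rep.empty


class TestRestraints:
    def test_bounds_arithmetic(self):
        from meltfold.noe import DistanceEstimate

        de = DistanceEstimate(pair=(("C-4", "H5"), ("C-4", "H6")), d=2.9, I=1, I_ref=1)
        table = read_restraints(export_restraints([de], fractional=0.2))
        assert table.loc[0, "lower"] == pytest.approx(2.32)
        assert table.loc[0, "upper"] == pytest.approx(3.48)

    def test_empty_list_gives_header_only(self):
        text = export_restraints([])
        assert text.strip() == "atom_a\tatom_b\tdistance\tlower\tupper"

    def test_round_trip(self, tmp_path):
        geometry = [
            (("C-4", "H5"), ("C-4", "H6"), 2.9),
            (("A6", "H8"), ("A6", "H1'"), 3.7),
        ]
        peaks = synth.synth_noesy_peaks(
            geometry, 1e5, synth.SynthConfig(seed=0, noe_noise_rel=0.0)
        )
        dists = peaks_to_distances(peaks)
        path = tmp_path / "restraints.tsv"
        path.write_text(export_restraints(dists))
        back = read_restraints(path)
        np.testing.assert_allclose(
            sorted(back["distance"]), sorted(d.d for d in dists), atol=1e-6
        )

    def test_md_block_format(self):
        from meltfold.noe import DistanceEstimate

        de = DistanceEstimate(pair=(("C-4", "H5"), ("C-4", "H6")), d=2.9, I=1, I_ref=1)
        block = restraints_md_block([de])
        assert "low 2.320 high 3.480" in block
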