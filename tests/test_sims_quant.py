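"""Isotope-ratio math and ROI quantification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sipcoculture import (
    IonImageStack,
    IsotopeStandards,
    ROISet,
    ape,
    atom_fraction_to_ratio,
    quantify_experiment,
    ratio_to_atom_fraction,
    source_carbon_fraction,
    summarize_rois,
    x_net,
)
from sipcoculture.simulate import FieldSpec, render_sip_field
from tests.conftest import make_truth


class TestRatioConversion:
    @pytest.mark.parametrize(
        "R, species, expected",
        [
            (0.02247, "C_dimer", 0.0111102),  # natural 13C abundance
            (0.00367, "N_cyanide", 0.0036566),
            (0.0, "C_dimer", 0.0),
            (0.0, "N_cyanide", 0.0),
        ],
    )
    def test_standard_ratios_map_to_natural_abundance(self, R, species, expected):
        assert ratio_to_atom_fraction(R, species) == pytest.approx(expected, abs=5e-7)

    def test_linear_dimer_convention_available(self):
        assert ratio_to_atom_fraction(0.1, "C_dimer", dimer_model="linear") == (
            pytest.approx(0.1 / 1.1)
        )

    @given(st.floats(min_value=0.0, max_value=10.0),
           st.sampled_from(["C_dimer", "N_cyanide"]))
    def test_round_trip_identity(self, R, species):
        p = ratio_to_atom_fraction(R, species)
        assert atom_fraction_to_ratio(p, species) == pytest.approx(R, abs=1e-12)

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            ratio_to_atom_fraction(-0.1, "C_dimer")


class TestApeAndXnet:
    def test_ape_zero_at_natural_abundance(self, standards):
        # APE computed at the standard ratio itself is exactly 0, both species
        pC = ratio_to_atom_fraction(standards.R_std_C, "C_dimer")
        pN = ratio_to_atom_fraction(standards.R_std_N, "N_cyanide")
        assert ape(pC, standards.F_unlabeled_C) == 0.0
        assert ape(pN, standards.F_unlabeled_N) == 0.0

    def test_ape_arithmetic(self):
        assert ape(0.0611, 0.0111) == pytest.approx(5.0)

    def test_xnet_endpoints(self, standards):
        Fu, Fs = standards.F_unlabeled_N, standards.F_substrate_N
        assert x_net(Fu, Fu, Fs) == pytest.approx(0.0, abs=1e-12)
        assert x_net(Fs, Fu, Fs) == pytest.approx(1.0, abs=1e-12)

    def test_xnet_half_labeled_substrate_example(self):
        # F_substrate for 50% ammonium replacement at 99 atom% label
        Fs = 0.5 * 0.99 + 0.5 * 0.003657
        assert x_net(0.25, 0.003657, Fs) == pytest.approx(0.4996, abs=5e-4)

    def test_xnet_out_of_range_not_clipped(self):
        assert x_net(0.9, 0.0, 0.5) == pytest.approx(1.8)

    def test_xnet_degenerate_denominator(self):
        with pytest.raises(ValueError):
            x_net(0.5, 0.2, 0.2)

    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_xnet_monotone_in_cell_fraction(self, f):
        lo = x_net(f * 0.99, 0.0037, 0.4968)
        hi = x_net(min(f * 0.99 + 0.01, 1.0), 0.0037, 0.4968)
        assert hi > lo


class TestSummarizeRois:
    def test_two_pixel_roi_sums(self):
        img = np.full((4, 4), 50, dtype=np.uint32)
        mask = np.zeros((4, 4), dtype=np.uint16)
        mask[0, :2] = 1
        stack = IonImageStack({"C2": img}, pixel_size_um=0.1)
        rois = ROISet(mask, pd.DataFrame({"cell_id": [1], "partner": ["alga"]}))
        out = summarize_rois(stack, rois, min_pixels=1)
        assert out.loc[0, "C2"] == 100
        assert out.loc[0, "n_pixels"] == 2

    def test_sums_match_pixel_loop_oracle(self, small_field):
        _, stack, rois = small_field
        out = summarize_rois(stack, rois).set_index("cell_id")
        for cid in rois.annotations["cell_id"]:
            for ch, img in stack.channels.items():
                acc = 0
                for r in range(img.shape[0]):        # naive per-pixel oracle
                    for c in range(img.shape[1]):
                        if rois.mask[r, c] == cid:
                            acc += int(img[r, c])
                assert out.loc[cid, ch] == acc

    def test_small_rois_reported_not_dropped(self):
        img = np.ones((4, 4), dtype=np.uint32)
        mask = np.zeros((4, 4), dtype=np.uint16)
        mask[0, 0] = 1
        mask[1:3, 1:3] = 2
        stack = IonImageStack({"C2": img}, pixel_size_um=0.1)
        rois = ROISet(mask, pd.DataFrame(
            {"cell_id": [1, 2], "partner": ["bacterium", "bacterium"]}))
        out = summarize_rois(stack, rois, min_pixels=3)
        assert out["excluded"].tolist() == [True, False]

    def test_empty_annotations_warn(self):
        stack = IonImageStack({"C2": np.zeros((2, 2), dtype=int)}, pixel_size_um=0.1)
        rois = ROISet(np.zeros((2, 2), dtype=int),
                      pd.DataFrame(columns=["cell_id", "partner"]))
        with pytest.warns(UserWarning):
            out = summarize_rois(stack, rois)
        assert out.empty

    def test_shape_mismatch_raises(self):
        stack = IonImageStack({"C2": np.zeros((2, 2), dtype=int)}, pixel_size_um=0.1)
        mask = np.zeros((3, 3), dtype=int)
        mask[0, 0] = 1
        rois = ROISet(mask, pd.DataFrame({"cell_id": [1], "partner": ["alga"]}))
        with pytest.raises(ValueError, match="shape"):
            summarize_rois(stack, rois)

    def test_annotation_absent_from_mask_raises(self):
        with pytest.raises(ValueError, match="absent"):
            ROISet(np.zeros((2, 2), dtype=int),
                   pd.DataFrame({"cell_id": [7], "partner": ["alga"]}))


class TestSourceEstimate:
    def test_single_and_mean(self):
        rec = pd.DataFrame({"partner": ["alga"], "F13C": [0.2]})
        assert source_carbon_fraction(rec) == pytest.approx(0.2)
        rec2 = pd.DataFrame({"partner": ["alga", "alga", "bacterium"],
                             "F13C": [0.1, 0.3, 0.9]})
        assert source_carbon_fraction(rec2) == pytest.approx(0.2)

    def test_no_algae_raises(self):
        rec = pd.DataFrame({"partner": ["bacterium"], "F13C": [0.1]})
        with pytest.raises(ValueError):
            source_carbon_fraction(rec)


class TestQuantifyExperiment:
    def test_natural_abundance_field_has_near_zero_net_assimilation(self):
        natC, natN = 0.0111, 0.00366
        truth = make_truth(
            p13=[natC] * 4, p15=[natN] * 4, lengths=[6.0, 2.0, 2.0, 2.0],
            partners=["alga", "bacterium", "bacterium", "bacterium"],
        )
        stack, rois = render_sip_field(truth, FieldSpec(), seed=7)
        # unlabeled run: score against the known N substrate, but C against a
        # labeled-experiment-like source to keep the denominator defined
        records, _ = quantify_experiment([(stack, rois)])
        # with an unlabeled source the C denominator is ~0; check N directly
        assert records["N_net"].abs().max() < 0.02
        assert records["APE_C"].abs().max() < 0.5

    def test_recovers_rendered_truth(self, small_field):
        truth, stack, rois = small_field
        records, summary = quantify_experiment([(stack, rois)])
        rec = records.set_index("cell_id")
        for _, row in truth.iterrows():
            assert rec.loc[row["cell_id"], "F13C"] == pytest.approx(
                row["true_p13C"], abs=0.01
            )
            assert rec.loc[row["cell_id"], "F15N"] == pytest.approx(
                row["true_p15N"], abs=0.01
            )
        assert summary["F_substrate_C"] == pytest.approx(0.25, abs=0.01)

    def test_duplicate_cultures_reported_separately_and_pooled(self, continuous_sim):
        from sipcoculture.simulate import render_experiment

        truth = continuous_sim.truth
        sub = truth[truth["timepoint_h"] == 48.0]
        fields = render_experiment(sub, FieldSpec(), seed=3)
        records, summary = quantify_experiment(fields)
        per_culture = summary["median_xnet_per_culture"]
        assert set(per_culture["replicate"]) == {1, 2}
        pooled = summary["median_xnet"]
        n_bact = (records["partner"] == "bacterium").sum()
        assert n_bact >= 10  # pooling convention: n >= 10 cells per group
        assert not pooled.empty
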