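import numpy as np
import pytest

import leukotype as lt
from leukotype.afa import (
    ALL_CONTROLS,
    Amplicon,
    LENGTH_MAX,
    LENGTH_MIN,
    MIN_SPACING,
    PanelDefinition,
)


def _mini_panel(marker_lengths=(140, 150, 160), panel=1, controls=True):
    amps = [
        Amplicon(gene=f"G{i}", length=ln, panel=panel)
        for i, ln in enumerate(marker_lengths)
    ]
    if controls:
        for c, ln in zip(ALL_CONTROLS, (280, 286, 292, 298, 304)):
            amps.append(Amplicon(gene=c, length=ln, panel=panel, is_control=True))
    return PanelDefinition(amps)


class TestValidatePanel:
    def test_default_panel_is_clean(self, panel_def, panel):
        assert lt.validate_panel(panel_def, panel) == []

    def test_close_spacing_flagged(self):
        p = _mini_panel((200, 203, 260))
        violations = lt.validate_panel(p)
        assert any(v.startswith("spacing:") and "3 bp" in v for v in violations)

    def test_length_out_of_range_flagged(self):
        violations = lt.validate_panel(_mini_panel((140, 150, 320)))
        assert any(v.startswith("range:") and "320" in v for v in violations)

    def test_missing_control_flagged(self):
        p = _mini_panel(controls=False)
        violations = lt.validate_panel(p)
        assert sum(v.startswith("controls:") for v in violations) == len(ALL_CONTROLS)

    def test_coverage_mismatch_flagged(self, panel_def, panel):
        wrong = list(panel.genes)[:-1] + ["NOT_A_MARKER"]
        violations = lt.validate_panel(panel_def, wrong)
        assert any(v.startswith("coverage:") for v in violations)

    def test_planted_violations_all_caught(self, panel_def, panel):
        """Sound and complete over 200 random single-rule mutations."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            amps = list(panel_def.amplicons)
            kind = rng.choice(["spacing", "range", "controls"])
            if kind == "spacing":
                # move one marker to within <4 bp of another marker in its panel
                markers = [i for i, a in enumerate(amps) if not a.is_control]
                i, j = rng.choice(markers, size=2, replace=False)
                a, b = amps[int(i)], amps[int(j)]
                new_len = b.length + int(rng.integers(0, MIN_SPACING))
                amps[int(i)] = Amplicon(a.gene, new_len, b.panel)
            elif kind == "range":
                markers = [i for i, a in enumerate(amps) if not a.is_control]
                i = int(rng.choice(markers))
                a = amps[i]
                bad = LENGTH_MIN - 30 if rng.random() < 0.5 else LENGTH_MAX + 30
                amps[i] = Amplicon(a.gene, int(bad), a.panel)
            else:
                controls = [i for i, a in enumerate(amps) if a.is_control]
                del amps[int(rng.choice(controls))]
            violations = lt.validate_panel(PanelDefinition(amps), panel)
            assert violations, f"planted {kind} violation not caught"
            expected_tag = {"spacing": ("spacing:",), "range": ("range:", "spacing:"),
                            "controls": ("controls:",)}[kind]
            assert any(v.startswith(expected_tag) for v in violations)


class TestAssignPeaks:
    def test_peak_within_tolerance_matched(self):
        p = _mini_panel((200, 250, 300))
        pt = lt.PeakTable("S1", 1, [(200.4, 7.0)])
        areas, artifacts = lt.assign_peaks(pt, p, tolerance_bp=1.5)
        assert areas["G0"] == 7.0
        assert artifacts == []

    def test_peak_between_amplicons_is_artifact(self):
        # 202.1 bp sits between 200 and 204: nearest is 204 at 1.9 bp,
        # which exceeds the 1.5 bp tolerance -> artifact, not a call
        p = _mini_panel((200, 204, 300))
        pt = lt.PeakTable("S1", 1, [(202.1, 5.0)])
        areas, artifacts = lt.assign_peaks(pt, p, tolerance_bp=1.5)
        assert areas["G0"] == 0.0 and areas["G1"] == 0.0
        assert artifacts == [(202.1, 5.0)]

    def test_empty_peak_list_gives_all_zero(self):
        p = _mini_panel()
        areas, artifacts = lt.assign_peaks(lt.PeakTable("S1", 1, []), p)
        assert all(a == 0.0 for a in areas.values())

    def test_two_peaks_on_one_amplicon_is_ambiguous(self):
        p = _mini_panel((200, 250, 300))
        pt = lt.PeakTable("S1", 1, [(199.5, 1.0), (200.5, 2.0)])
        with pytest.raises(lt.AmbiguousPeakError, match="G0"):
            lt.assign_peaks(pt, p)

    def test_nearest_neighbor_oracle_over_enumerated_positions(self):
        p = _mini_panel((150, 160, 170))
        lengths = {150: "G0", 160: "G1", 170: "G2"}
        for size in np.arange(145.0, 175.0, 0.7):
            areas, artifacts = lt.assign_peaks(
                lt.PeakTable("S", 1, [(float(size), 1.0)]), p, tolerance_bp=1.5
            )
            # oracle: explicit nearest-expected-length scan
            best = min(lengths, key=lambda ln: abs(ln - size))
            if abs(best - size) <= 1.5:
                assert areas[lengths[best]] == 1.0
                assert not artifacts
            else:
                assert all(v == 0.0 for v in areas.values())
                assert artifacts

    def test_simulated_peaks_round_trip_exactly(self, panel_def, panel):
        cfg = lt.SimulationConfig(
            n_per_subtype={"T-ALL": 3, "Others": 2}, peak_jitter_bp=0.5, seed=77
        )
        m, _ = lt.simulate_cohort(cfg, platform="AFA", panel=panel)
        tables = lt.simulate_peaks(m, panel_def, cfg)
        back = lt.peaks_to_matrix(tables, panel_def, panel)
        np.testing.assert_allclose(
            back.values.loc[m.gene_ids, m.sample_ids].to_numpy(),
            m.values.to_numpy(),
            rtol=1e-12,
        )

    def test_excessive_jitter_rejected(self, panel_def, panel):
        cfg = lt.SimulationConfig(
            n_per_subtype={"T-ALL": 1}, peak_jitter_bp=3.0, seed=1
        )
        m, _ = lt.simulate_cohort(cfg, platform="AFA", panel=panel)
        with pytest.raises(lt.ConfigError, match="jitter"):
            lt.simulate_peaks(m, panel_def, cfg)


class TestQCControls:
    def _areas(self, **overrides):
        areas = {c: 50.0 for c in ALL_CONTROLS}
        areas.update(overrides)
        return areas

    def test_all_controls_present_pass(self, panel_def):
        verdict = lt.qc_controls(self._areas(), panel_def)
        assert verdict.passed

    def test_missing_kanr_is_rt_pcr_failure(self, panel_def):
        verdict = lt.qc_controls(self._areas(KanR=0.0), panel_def)
        assert any("RT/PCR failure" in f for f in verdict.flags)

    def test_missing_pcdna_with_kanr_is_pcr_anomaly(self, panel_def):
        verdict = lt.qc_controls(self._areas(**{"pcDNA3.1(+)": 0.0}), panel_def)
        assert any("PCR anomaly" in f for f in verdict.flags)

    def test_low_endogenous_reference_is_low_input(self, panel_def):
        verdict = lt.qc_controls(self._areas(B2M=0.2), panel_def, min_endogenous=1.0)
        assert any("low input" in f and "B2M" in f for f in verdict.flags)


class TestQuantify:
    def test_identity_curve_with_unit_references_passes_areas_through(self):
        curve = lt.identity_curve()
        areas = {"GX": 8.0, "GY": 0.0, "B2M": 1.0, "PSMC4": 1.0, "GUSB": 1.0}
        out = lt.quantify(areas, curve)
        assert out["GX"] == pytest.approx(8.0)
        assert out["GY"] == 0.0

    def test_global_scaling_cancels(self):
        curve = lt.identity_curve()
        areas = {"GX": 8.0, "GY": 2.0, "B2M": 4.0, "PSMC4": 4.0, "GUSB": 4.0}
        with pytest.warns(UserWarning):  # areas above the toy calibration range
            base = lt.quantify(areas, curve)
            doubled = lt.quantify({g: 2 * a for g, a in areas.items()}, curve)
        assert doubled["GX"] == pytest.approx(base["GX"])
        assert doubled["GY"] == pytest.approx(base["GY"])

    def test_two_point_curve_closed_form(self):
        # log-log line through (1,10) and (100,1000): slope 1, intercept 1,
        # so area 100 inverts to quantity 10
        curve = lt.StandardCurve([(1.0, 10.0), (100.0, 1000.0)])
        assert curve.quantity(100.0) == pytest.approx(10.0, rel=1e-12)

    def test_zero_reference_is_sample_level_error(self):
        curve = lt.identity_curve()
        areas = {"GX": 8.0, "B2M": 0.0, "PSMC4": 1.0, "GUSB": 1.0}
        with pytest.raises(lt.QuantificationError, match="B2M"):
            lt.quantify(areas, curve)

    def test_decreasing_curve_rejected(self):
        with pytest.raises(lt.ValidationError, match="increasing"):
            lt.StandardCurve([(1.0, 100.0), (100.0, 1.0)])
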