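"""Derived summaries: symmetry, timing, gating, architecture, ensembles."""

from dataclasses import replace

import numpy as np
import pytest

from klinfo.assays import (
    Recording,
    StimulusEnsemble,
    concentration_step_assay,
    information_clamp_assay,
    phase_sweep,
)
from klinfo.info import InfoProfile
from klinfo.reporting import (
    CHEMICAL_EDGES,
    GAP_EDGES,
    InfoArchitecture,
    build_architecture,
    ensemble_report,
    gating_curves,
    symmetry_index,
    timing_metrics,
)


def _profile(values, H_S=1.0):
    values = np.asarray(values, float)
    return InfoProfile(
        t=np.arange(values.size) * 0.01,
        bits=values * H_S,
        H_S=H_S,
        measure="MI",
        variables=("x",),
    )


def _disconnected(params):
    """All chemical weights zero: nothing downstream of the sensors."""
    zeros = {f: 0.0 for f in (
        "w_ON_AIYL", "w_ON_AIYR", "w_OFF_AIYL", "w_OFF_AIYR",
        "w_AIYL_AIZL", "w_AIYR_AIZR",
        "w_AIZL_SMBDL", "w_AIZL_SMBVL", "w_AIZR_SMBDR", "w_AIZR_SMBVR",
        "w_SMBDL_self", "w_SMBDR_self", "w_SMBVL_self", "w_SMBVR_self",
    )}
    return replace(params, **zeros)


class TestSymmetryIndex:
    def test_identical_profiles_are_fully_symmetric(self):
        p = _profile([0.2, 0.4, 0.3])
        assert symmetry_index(p, p) == 1.0

    def test_one_silent_cell_is_fully_asymmetric(self):
        assert symmetry_index(_profile([0.0, 0.0]), _profile([0.5, 0.7])) == 0.0

    def test_two_silent_cells_count_as_symmetric(self):
        assert symmetry_index(_profile([0.0, 0.0]), _profile([0.0, 0.0])) == 1.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            symmetry_index(_profile([0.1]), _profile([0.1, 0.2]))

    def test_ratio_of_time_averages(self):
        assert symmetry_index(
            _profile([0.2, 0.2]), _profile([0.4, 0.4])
        ) == pytest.approx(0.5)


class TestTimingMetrics:
    def _recording(self, sensor_window, neck_window, n_steps=60, n=300):
        """Synthetic recording: variables copy the stimulus inside their
        active windows and are silent outside."""
        rng = np.random.default_rng(0)
        stim = rng.uniform(-0.01, 0.01, n)
        traces = np.zeros((n, n_steps, 3))
        on = np.clip(stim, 0, None)
        off = np.clip(-stim, 0, None)
        for t0, t1 in [sensor_window]:
            traces[:, t0:t1, 0] = on[:, None]
            traces[:, t0:t1, 1] = off[:, None]
        for t0, t1 in [neck_window]:
            traces[:, t0:t1, 2] = stim[:, None]
        return Recording(
            stimulus=stim,
            traces=traces,
            dt=0.01,
            variables=("V_ON", "V_OFF", "phi"),
            meta={"stim_lo": -0.01, "stim_hi": 0.01},
        )

    def test_durations_read_off_known_windows(self):
        rec = self._recording(sensor_window=(0, 30), neck_window=(5, 45))
        tm = timing_metrics(rec, threshold=0.05, bins=10, shifts=2)
        assert tm.propagation_delay == pytest.approx(0.05, abs=0.011)
        assert tm.sensor_duration == pytest.approx(0.30, abs=0.011)
        assert tm.persistence == pytest.approx(0.15, abs=0.021)
        assert tm.neck_duration == pytest.approx(0.40, abs=0.021)
        assert tm.propagation_delay >= 0.0  # neck cannot precede the stimulus

    def test_no_neck_response_reports_undefined_not_zero(self):
        rec = self._recording(sensor_window=(0, 30), neck_window=(0, 0))
        tm = timing_metrics(rec, threshold=0.05, bins=10, shifts=2)
        assert tm.propagation_delay is None
        assert tm.neck_duration is None
        assert tm.sensor_duration is not None


class TestGatingCurves:
    def test_disconnected_circuit_has_flat_zero_curves(self, rand_params):
        p = _disconnected(rand_params)
        ens = StimulusEnsemble.uniform("dc", 60, seed=0)
        sweep = phase_sweep(p, ens, n_phases=3, record_cycles=0.5)
        phases, fixed, averaged = gating_curves(sweep, delay=0.05, bins=10, shifts=2)
        for c in fixed:
            np.testing.assert_allclose(fixed[c], 0.0, atol=1e-9)
            assert (averaged[c] >= -1e-12).all() and (averaged[c] <= 1 + 1e-9).all()

    def test_rejects_empty_sweep_and_bad_delay(self, rand_params):
        with pytest.raises(ValueError):
            gating_curves([], delay=0.05)
        ens = StimulusEnsemble.uniform("dc", 10, seed=0)
        sweep = phase_sweep(rand_params, ens, n_phases=1, record_cycles=0.25)
        with pytest.raises(ValueError):
            gating_curves(sweep, delay=1e6)


@pytest.fixture(scope="module")
def recs(rand_params):
    ens_dc = StimulusEnsemble.uniform("dc", 80, seed=1)
    ens_cd = StimulusEnsemble.uniform("cdot", 80, seed=2)
    step = concentration_step_assay(rand_params, ens_dc, record_cycles=0.5)
    clamp = information_clamp_assay(rand_params, ens_cd, record_cycles=0.5)
    return step, clamp


class TestArchitecture:

    def test_node_values_match_profile_time_averages(self, rand_params, recs):
        step, clamp = recs
        arch = build_architecture(rand_params, step, clamp, bins=10, shifts=2)
        for name, prof in arch._profiles.items():
            assert arch.nodes[name]["mi"] == pytest.approx(
                prof.time_average(), abs=1e-12
            )
        assert set(arch.edges) == {
            f"{s}->{d}" for s, d in CHEMICAL_EDGES + GAP_EDGES
        }
        for attrs in arch.nodes.values():
            assert -1e-12 <= attrs["mi"] <= 1.0 + 1e-9  # up to float cancellation
            assert attrs["pos"] + attrs["neg"] == pytest.approx(1.0)

    def test_disconnected_circuit_has_silent_interneurons(self, rand_params):
        p = _disconnected(rand_params)
        ens_dc = StimulusEnsemble.uniform("dc", 80, seed=1)
        ens_cd = StimulusEnsemble.uniform("cdot", 80, seed=2)
        step = concentration_step_assay(p, ens_dc, record_cycles=0.5)
        clamp = information_clamp_assay(p, ens_cd, record_cycles=0.5)
        arch = build_architecture(p, step, clamp, bins=10, shifts=2)
        for name in ("AIYL", "AIYR", "AIZL", "AIZR", "neck"):
            assert arch.nodes[name]["mi"] < 0.02
        assert arch.nodes["ASEL"]["mi"] > 0.2

    def test_mirrored_circuit_swaps_labels(self, rand_params, recs):
        step, clamp = recs
        mirrored = rand_params.mirror_lr()
        ens_dc = StimulusEnsemble(step.meta["feature"], step.stimulus)
        step_m = concentration_step_assay(mirrored, ens_dc, record_cycles=0.5)
        ens_cd = StimulusEnsemble("cdot", clamp.stimulus)
        clamp_m = information_clamp_assay(mirrored, ens_cd, record_cycles=0.5)
        arch = build_architecture(rand_params, step, clamp, bins=10, shifts=2)
        arch_m = build_architecture(mirrored, step_m, clamp_m, bins=10, shifts=2)

        def flip(name):
            # ASE is functionally lateralized (ON vs OFF), not mirror-symmetric
            if name.startswith("ASE") or name == "neck":
                return name
            return name[:-1] + ("R" if name.endswith("L") else "L")

        for name, attrs in arch.nodes.items():
            assert arch_m.nodes[flip(name)]["mi"] == pytest.approx(
                attrs["mi"], abs=1e-9
            )

    def test_json_round_trip(self, rand_params, recs, tmp_path):
        step, clamp = recs
        arch = build_architecture(rand_params, step, clamp, bins=10, shifts=2)
        path = tmp_path / "arch.json"
        arch.to_json(path)
        loaded = InfoArchitecture.from_json(path)
        assert loaded.nodes == arch.nodes and loaded.edges == arch.edges
        arch.to_graphml(tmp_path / "arch.graphml")
        assert (tmp_path / "arch.graphml").read_text().startswith("<?xml")

    def test_missing_variable_named_in_error(self, rand_params, recs):
        step, clamp = recs
        broken = Recording(
            stimulus=step.stimulus,
            traces=step.traces[:, :, :2],
            dt=step.dt,
            variables=step.variables[:2],
            meta=step.meta,
        )
        with pytest.raises(KeyError, match="sigma_AIYL"):
            build_architecture(rand_params, broken, clamp, bins=10, shifts=2)


class TestEnsembleReport:
    def test_duplicated_circuit_has_zero_dispersion(self):
        profs = {
            "AIYL": _profile([0.5, 0.6]),
            "AIYR": _profile([0.1, 0.2]),
            "AIZL": _profile([0.3, 0.3]),
            "AIZR": _profile([0.25, 0.35]),
            "neck": _profile([0.4, 0.4]),
        }
        out = ensemble_report([profs, profs])
        for mean, sd in out.values():
            np.testing.assert_allclose(sd, 0.0, atol=1e-15)
        np.testing.assert_allclose(out["AIY_hi"][0], [0.5, 0.6])

    def test_alignment_invariant_to_left_right_relabelling(self):
        a = {
            "AIYL": _profile([0.5, 0.6]),
            "AIYR": _profile([0.1, 0.2]),
            "AIZL": _profile([0.3, 0.3]),
            "AIZR": _profile([0.2, 0.2]),
        }
        flipped = {
            "AIYL": a["AIYR"],
            "AIYR": a["AIYL"],
            "AIZL": a["AIZR"],
            "AIZR": a["AIZL"],
        }
        out = ensemble_report([a, flipped])
        np.testing.assert_allclose(out["AIY_hi"][1], 0.0, atol=1e-15)
        np.testing.assert_allclose(out["AIZ_down"][0], [0.3, 0.3])

    def test_single_circuit_rejected(self):
        with pytest.raises(ValueError):
            ensemble_report([{"AIYL": _profile([0.1])}])
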