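"""Tests for same-cell (SASCA) and cross-cell (DISCA) comparisons."""

import numpy as np
import pandas as pd
import pytest

import sascakit as sk
from sascakit import published
from sascakit.sasca import disca_summarize, sasca_compare, split_phases
from sascakit.synthetic import PhaseSchedule


def _sasca_trace(phase1, phase2, *, t_switch=1020.0, noise_sd=0.0, seed=7):
    schedule = PhaseSchedule.continuous(t_switch, phase1, phase2)
    acq = sk.AcquisitionConfig(noise_sd=noise_sd, seed=seed)
    raw = sk.simulate_sasca_trace(schedule, acq)
    return sk.process_trace(raw)


@pytest.fixture(scope="module")
def cell58_sasca_trace(vlb58_truth, vlb58_inhibitor_truth):
    return _sasca_trace(vlb58_truth, vlb58_inhibitor_truth)


# session-scoped truth fixtures are redefined at module scope for reuse here
@pytest.fixture(scope="module")
def vlb58_truth():
    return sk.GroundTruth("two_exp", published.vlb_two_exp_params("58"))


@pytest.fixture(scope="module")
def vlb58_inhibitor_truth():
    return sk.GroundTruth("two_exp", published.sasca_two_exp_params("58", "inhibitor"))


class TestSplitPhases:
    def test_exact_boundaries(self, cell58_sasca_trace):
        p1, p2 = split_phases(cell58_sasca_trace, 1020.0)
        assert p1.times.max() < 1020.0
        assert p2.times.min() >= 0.0
        assert p2.metadata["sasca_phase"] == "inhibitor"
        assert len(p1) + len(p2) == len(cell58_sasca_trace)

    def test_phase2_starts_near_zero(self, cell58_sasca_trace):
        """After offset subtraction by the phase-1 fitted plateau, the
        early phase-2 signal is a small increment above zero."""
        _, p2 = split_phases(cell58_sasca_trace, 1020.0)
        assert abs(p2.f[0]) < 0.05

    def test_t_switch_outside_span_rejected(self, cell58_sasca_trace):
        with pytest.raises(ValueError):
            split_phases(cell58_sasca_trace, cell58_sasca_trace.times[-1])
        with pytest.raises(ValueError):
            split_phases(cell58_sasca_trace, 5000.0)

    def test_short_phase_rejected(self, cell58_sasca_trace):
        with pytest.raises(ValueError, match="12"):
            split_phases(cell58_sasca_trace, 4.0)


class TestSASCACompare:
    def test_published_cell58_fold_B(self, cell58_sasca_trace):
        """Within-cell fast-rate fold for cell 58: 0.0973 / 0.0556 = 1.750."""
        res = sasca_compare(cell58_sasca_trace)   # t_switch from metadata
        assert res.fold_B == pytest.approx(0.0973 / 0.0556, rel=1e-3)
        assert res.fit_control.params[1] == pytest.approx(0.0556, abs=5e-5)
        assert res.fit_inhibitor.params[1] == pytest.approx(0.0973, abs=5e-5)

    def test_published_cell58_plateau_folds_both_definitions(self, cell58_sasca_trace):
        """Incremental fold (A+C)2/(A+C)1 = 0.5586/0.9283; the cumulative
        definition adds the phase-1 plateau back in."""
        res = sasca_compare(cell58_sasca_trace)
        assert res.fold_plateau == pytest.approx(0.5586 / 0.9283, rel=1e-3)
        assert res.fold_plateau_cumulative == pytest.approx((0.9283 + 0.5586) / 0.9283, rel=1e-3)

    def test_identical_phases_fold_one(self, vlb58_truth):
        trace = _sasca_trace(vlb58_truth, vlb58_truth)
        res = sasca_compare(trace, 1020.0)
        assert res.fold_B == pytest.approx(1.0, rel=1e-4)
        assert res.fold_plateau == pytest.approx(1.0, rel=1e-3)

    def test_doubled_rates_fold_two(self, vlb58_truth):
        A, B, C, D = vlb58_truth.params
        doubled = sk.GroundTruth("two_exp", (A, 2 * B, C, 2 * D))
        res = sasca_compare(_sasca_trace(vlb58_truth, doubled), 1020.0)
        assert res.fold_B == pytest.approx(2.0, rel=1e-4)

    def test_null_folds_center_on_one_under_noise(self, vlb58_truth):
        """Same kinetics in both phases with 2% noise: the median fold over
        seeded replicates stays within 5% of unity."""
        folds_B, folds_P = [], []
        for seed in range(100):
            trace = _sasca_trace(vlb58_truth, vlb58_truth,
                                 noise_sd=0.02 * 0.9283 * 100.0, seed=seed)
            res = sasca_compare(trace, 1020.0)
            folds_B.append(res.fold_B)
            folds_P.append(res.fold_plateau)
        assert 0.95 < np.median(folds_P) < 1.05

    def test_split_fit_composition(self, vlb58_truth, vlb58_inhibitor_truth):
        """Fits through sasca_compare equal independent fits of separately
        generated phases (noiseless)."""
        res = sasca_compare(_sasca_trace(vlb58_truth, vlb58_inhibitor_truth), 1020.0)
        acq = sk.AcquisitionConfig(noise_sd=0.0, seed=1)
        for truth, fit in ((vlb58_truth, res.fit_control),
                           (vlb58_inhibitor_truth, res.fit_inhibitor)):
            solo = sk.fit_two_exp(sk.process_trace(sk.simulate_raw_trace(truth, acq)))
            np.testing.assert_allclose(fit.params, solo.params, rtol=1e-6, atol=1e-9)


class TestDISCASummarize:
    @staticmethod
    def _published_cohort():
        a = published.VLB_FITS.assign(condition="no CsA")
        b = published.VLB_CSA_FITS.assign(condition="CsA")
        return pd.concat([a, b], ignore_index=True)

    def test_published_ranges_overlap(self):
        """Cross-cell plateau ranges with and without inhibitor intersect:
        the heterogeneity-masking observation."""
        summary = disca_summarize(self._published_cohort(), "condition")
        assert summary.overlap["A_plus_C"] is True
        assert summary.group_sizes == {"CsA": 4, "no CsA": 20}
        assert summary.ranges["A_plus_C"]["no CsA"] == (pytest.approx(0.2642), pytest.approx(1.4980))
        assert summary.ranges["A_plus_C"]["CsA"][1] == pytest.approx(1.2744)

    def test_disjoint_ranges_not_overlapping(self):
        df = pd.DataFrame({
            "condition": ["x"] * 3 + ["y"] * 3,
            "A": [1, 2, 3, 10, 11, 12.0],
        })
        summary = disca_summarize(df, "condition", params=("A",))
        assert summary.overlap["A"] is False

    def test_identical_groups_rank_p_near_one(self):
        vals = np.linspace(0.2, 1.4, 12)
        df = pd.DataFrame({
            "condition": ["x"] * 12 + ["y"] * 12,
            "A": np.concatenate([vals, vals]),
        })
        summary = disca_summarize(df, "condition", params=("A",))
        assert summary.p_values["A"] > 0.8

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"condition": ["x"] * 3, "A": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            disca_summarize(df, "condition", params=("A",))


class TestHeterogeneityMasking:
    def test_uniform_effect_masked_across_cells_visible_within(self):
        """A uniform 1.4x plateau effect disappears in cross-cell range
        comparison (ranges overlap) yet every cell's within-cell fold
        exceeds one: the core motivation for the same-cell design."""
        rng = np.random.default_rng(12)
        med = {k: float(published.VLB_FITS[k].median()) for k in "ABCD"}
        spec = sk.PopulationSpec(
            20, "two_exp", {k: (med[k], 0.5) for k in "ABCD"},
            condition_label="no-inhibitor", seed=12,
        )
        acq = sk.AcquisitionConfig(noise_sd=0.0, seed=0)
        control = [t for _, t in sk.simulate_cohort(spec, acq)]
        spec_inh = sk.PopulationSpec(
            4, "two_exp", {k: (med[k], 0.5) for k in "ABCD"},
            condition_label="inhibitor", seed=99,
        )
        inhibited_base = [t for _, t in sk.simulate_cohort(spec_inh, acq)]

        rows = []
        for t in control:
            A, B, C, D = t.params
            rows.append(("no-inhibitor", A, B, C, D))
        for t in inhibited_base:
            A, B, C, D = t.params
            rows.append(("inhibitor", 1.4 * A, B, 1.4 * C, D))
        df = pd.DataFrame(rows, columns=["condition", "A", "B", "C", "D"])
        summary = disca_summarize(df, "condition")
        assert summary.overlap["A_plus_C"] is True

        # Within-cell: same cells, before vs after the 1.4x effect.
        n_above = 0
        for t in control[:20]:
            A, B, C, D = t.params
            boosted = sk.GroundTruth("two_exp", (1.4 * A, B, 1.4 * C, D))
            trace = _sasca_trace(t, boosted, noise_sd=0.02 * t.plateau * 100.0,
                                 seed=int(1000 * A) % 2**16)
            res = sasca_compare(trace, 1020.0)
            n_above += res.fold_plateau > 1.0
        assert n_above >= 19  # >= 95% of cells
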