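"""PB frequencies, N_eq, classification, delta-PB and region summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pbflex as pf
from pbflex.flexibility import classify_values, pool_frequencies

from _oracles import delta_pb_reference, frequency_tally_reference


def pbs_from_rows(rows):
    """Build a PBEnsemble from a list of equal-length letter strings."""
    labels = np.array([list(r) for r in rows], dtype="U1")
    L = labels.shape[1]
    return pf.PBEnsemble(labels, ["A"] * L, np.arange(L))


def profile_from_freq(freq_rows):
    freq = np.asarray(freq_rows, dtype=float)
    n_obs = np.where(np.isfinite(freq).all(axis=1), 100, 0)
    freq = np.where(np.isfinite(freq), freq, np.nan)
    return pf.PBFrequencyProfile(freq, n_obs, ["A"] * len(freq), np.arange(len(freq)))


def delta_row(letter, weight=1.0, other=None, other_weight=0.0):
    row = np.zeros(16)
    row[pf.PB_LABELS.index(letter)] = weight
    if other is not None:
        row[pf.PB_LABELS.index(other)] = other_weight
    return row


class TestFrequencies:
    def test_pure_and_mixed_counts(self):
        pbs = pbs_from_rows(["m"] * 8 + ["k"] * 2)
        freq = pf.pb_frequencies(pbs)
        assert freq.freq[0, pf.PB_LABELS.index("m")] == pytest.approx(0.8)
        assert freq.freq[0, pf.PB_LABELS.index("k")] == pytest.approx(0.2)
        assert freq.n_obs[0] == 10

    def test_all_z_position_is_undefined(self):
        pbs = pbs_from_rows(["Zm", "Zm", "Zk"])
        freq = pf.pb_frequencies(pbs)
        assert freq.n_obs[0] == 0 and np.all(np.isnan(freq.freq[0]))
        assert freq.n_obs[1] == 3

    def test_matches_naive_double_loop_tally(self, rng):
        letters = np.array(list(pf.PB_LABELS + ("Z",)))
        labels = letters[rng.integers(0, 17, size=(40, 12))]
        L = labels.shape[1]
        pbs = pf.PBEnsemble(labels, ["A"] * L, np.arange(L))
        freq = pf.pb_frequencies(pbs)
        ref_freq, ref_n = frequency_tally_reference(labels)
        assert np.array_equal(freq.n_obs, ref_n)
        assert np.allclose(freq.freq, ref_freq, equal_nan=True)

    @given(st.integers(1, 30), st.integers(1, 30))
    @settings(max_examples=30, derandomize=True)
    def test_pooling_equals_weighted_average(self, n1, n2):
        """Pooling two ensembles reproduces the frame-count-weighted
        average of their frequencies (concatenated-trajectory identity)."""
        rng = np.random.default_rng(n1 * 100 + n2)
        letters = np.array(list(pf.PB_LABELS))
        rows_a = letters[rng.integers(0, 16, size=(n1, 6))]
        rows_b = letters[rng.integers(0, 16, size=(n2, 6))]
        fa = pf.pb_frequencies(pf.PBEnsemble(rows_a, ["A"] * 6, np.arange(6)))
        fb = pf.pb_frequencies(pf.PBEnsemble(rows_b, ["A"] * 6, np.arange(6)))
        pooled = pool_frequencies([fa, fb])
        merged = pf.pb_frequencies(
            pf.PBEnsemble(np.vstack([rows_a, rows_b]), ["A"] * 6, np.arange(6))
        )
        assert np.allclose(pooled.freq, merged.freq)
        expected = (fa.freq * n1 + fb.freq * n2) / (n1 + n2)
        assert np.allclose(pooled.freq, expected)


class TestNeq:
    def test_boundary_anchors(self):
        """Single PB gives N_eq = 1; uniform over all 16 gives N_eq = 16."""
        single = profile_from_freq([delta_row("m")])
        assert pf.neq(single).values[0] == pytest.approx(1.0, abs=1e-12)
        uniform = profile_from_freq([np.full(16, 1 / 16)])
        assert pf.neq(uniform).values[0] == pytest.approx(16.0, abs=1e-9)

    def test_two_equal_pbs_give_two(self):
        half = profile_from_freq([delta_row("m", 0.5, "d", 0.5)])
        assert pf.neq(half).values[0] == pytest.approx(2.0, abs=1e-12)

    def test_invariant_under_label_permutation(self, rng):
        f = rng.dirichlet(np.ones(16), size=5)
        base = profile_from_freq(f)
        perm = profile_from_freq(f[:, rng.permutation(16)])
        assert np.allclose(pf.neq(base).values, pf.neq(perm).values)

    def test_undefined_positions_propagate(self):
        prof = profile_from_freq([delta_row("m"), [np.nan] * 16])
        values = pf.neq(prof).values
        assert np.isnan(values[1]) and np.isfinite(values[0])


class TestClassification:
    def test_paper_anchor_values(self):
        assert classify_values(np.array([1.0]))[0] == "rigid"
        assert classify_values(np.array([9.2]))[0] == "disordered"
        assert classify_values(np.array([8.0]))[0] == "disordered"
        assert classify_values(np.array([7.999]))[0] == "flexible"
        assert classify_values(np.array([4.0]))[0] == "flexible"
        assert classify_values(np.array([2.0]))[0] == "intermediate"

    def test_monotone_in_neq(self):
        order = {"rigid": 0, "intermediate": 1, "flexible": 2, "disordered": 3}
        v = np.linspace(1.0, 16.0, 200)
        ranks = [order[c] for c in classify_values(v)]
        assert ranks == sorted(ranks)

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            pf.FlexibilityThresholds(flexible_lo=9.0, flexible_hi=8.0)

    def test_custom_thresholds_respected(self):
        t = pf.FlexibilityThresholds(rigid_max=1.5, flexible_lo=2.0,
                                     flexible_hi=6.0, disordered_min=6.0)
        assert classify_values(np.array([1.4]), t)[0] == "rigid"
        assert classify_values(np.array([6.5]), t)[0] == "disordered"


class TestDeltaPB:
    def test_identity_and_disjoint_bounds(self):
        a = profile_from_freq([delta_row("m"), delta_row("d")])
        assert np.allclose(pf.delta_pb(a, a).values, 0.0)
        b = profile_from_freq([delta_row("d"), delta_row("d")])
        d = pf.delta_pb(a, b)
        assert d.values[0] == pytest.approx(2.0)  # disjoint sampling
        assert d.values[1] == pytest.approx(0.0)

    def test_matches_hand_summation(self, rng):
        fa = rng.dirichlet(np.ones(16), size=8)
        fb = rng.dirichlet(np.ones(16), size=8)
        d = pf.delta_pb(profile_from_freq(fa), profile_from_freq(fb))
        for i in range(8):
            assert d.values[i] == pytest.approx(delta_pb_reference(fa[i], fb[i]), abs=1e-12)
            assert 0.0 <= d.values[i] <= 2.0

    def test_symmetry(self, rng):
        fa = profile_from_freq(rng.dirichlet(np.ones(16), size=6))
        fb = profile_from_freq(rng.dirichlet(np.ones(16), size=6))
        assert np.allclose(pf.delta_pb(fa, fb).values, pf.delta_pb(fb, fa).values)

    def test_roster_mismatch_names_first_position(self):
        a = profile_from_freq([delta_row("m")] * 3)
        b = pf.PBFrequencyProfile(
            a.freq.copy(), a.n_obs.copy(), ["A", "B", "B"], np.array([0, 0, 1])
        )
        with pytest.raises(ValueError, match="position 1"):
            pf.delta_pb(a, b)


class TestRegionSummary:
    def _annotation(self, segments):
        rows = []
        for seg, residues in segments.items():
            for r in residues:
                rows.append({"chain": "A", "residue": r, "topology": "TM",
                             "ss": "alpha", "segment": seg, "exon": 1})
        return pf.AnnotationTrack(pd.DataFrame(rows))

    def test_max_rule_classifies_segment(self):
        neqp = pf.NeqProfile(np.array([1.0, 2.0, 5.0, 9.0]), ["A"] * 4, np.arange(4))
        ann = self._annotation({"helix1": [0], "loop1": [1, 2, 3]})
        summary = pf.region_summary(neqp, ann)
        by = summary.set_index("segment")
        assert by.loc["helix1", "class"] == "rigid"
        assert by.loc["loop1", "max_neq"] == pytest.approx(9.0)
        assert by.loc["loop1", "class"] == "disordered"

    def test_empty_segment_omitted_with_warning(self):
        neqp = pf.NeqProfile(np.array([1.0, np.nan]), ["A"] * 2, np.arange(2))
        ann = self._annotation({"helix1": [0], "loop9": [1]})
        with pytest.warns(UserWarning, match="loop9"):
            summary = pf.region_summary(neqp, ann)
        assert list(summary["segment"]) == ["helix1"]

    def test_uniformly_sampled_loop_is_disordered(self):
        """A loop sampling all 16 PBs uniformly classifies as disordered in
        >= 99/100 seeded replicates."""
        target = np.full((5, 16), 1 / 16)
        ann = self._annotation({"loop": [0, 1, 2, 3, 4]})
        hits = 0
        for rep in range(100):
            spec = pf.GeneratorSpec(n_residues=5, n_frames=200,
                                    position_target=target, rho=0.0)
            states, _ = pf.sample_pb_trajectory(spec, np.random.default_rng(1000 + rep))
            letters = np.array(list(pf.PB_LABELS), dtype="U1")[states]
            pbs = pf.PBEnsemble(letters, ["A"] * 5, np.arange(5))
            summary = pf.region_summary(pf.neq(pf.pb_frequencies(pbs)), ann)
            hits += summary["class"].iloc[0] == "disordered"
        assert hits >= 99
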