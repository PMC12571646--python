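"""Windowed, per-repeat and per-residue PPII content estimators."""

import math

import numpy as np
import pandas as pd
import pytest

from ppiihelix import (
    GROEL_CTC,
    GROEL_CTS,
    SegmentMap,
    SimulationSpec,
    TrajectoryPPII,
    per_repeat_content,
    per_residue_population,
    run_summary,
    simulate_ensemble,
    windowed_content,
)
from tests.conftest import constant_ensemble

PPII = (-75.0, 150.0)
COIL = (60.0, -60.0)


def _segmap(ens):
    return SegmentMap.from_sequences(ens.sequence)


class TestSegmentMap:
    def test_canonical_cts_assignment(self):
        seg = SegmentMap.from_sequences({"c": GROEL_CTS})
        assert seg.positions("c", "CtS") == tuple(range(1, 15))
        assert seg.positions("c", "GGM1") == (2, 3, 4)
        assert seg.positions("c", "GGM4") == (11, 12, 13)

    def test_canonical_ctc_assignment(self):
        seg = SegmentMap.from_sequences({"c": GROEL_CTC})
        assert seg.positions("c", "CtC") == tuple(range(1, 25))
        assert seg.positions("c", "CtS") == tuple(range(11, 25))
        assert seg.positions("c", "GGM1") == (12, 13, 14)
        # the leading Ala of CtS and the final Met belong to no repeat
        claimed = set().union(*(seg.positions("c", f"GGM{k}") for k in range(1, 5)))
        assert claimed == set(range(12, 24))
        assert 11 not in claimed and 24 not in claimed

    def test_overlapping_repeats_rejected(self):
        with pytest.raises(ValueError):
            SegmentMap(segments={"c": {"GGM1": (1, 2, 3), "GGM2": (3, 4, 5)}})

    def test_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            SegmentMap(segments={"c": {"CtS": ()}})


class TestWindowedContent:
    def test_saturated_ensemble_gives_unity(self):
        ens = constant_ensemble(*PPII, n_frames=100)
        df = windowed_content(ens, _segmap(ens), "CtS")
        assert np.allclose(df["fraction"], 1.0)

    def test_never_ppii_gives_zero(self):
        ens = constant_ensemble(*COIL, n_frames=100)
        df = windowed_content(ens, _segmap(ens), "CtS")
        assert np.allclose(df["fraction"], 0.0)

    def test_trailing_window_semantics(self):
        """Window at t covers (t-50, t]; report times are stride multiples;
        a trailing partial window is dropped."""
        ens = constant_ensemble(*PPII, n_frames=130)
        # frames 51..130 moved out of the window
        for c in ens.chains:
            ens.phi[c][50:, 1:] = 60.0
        df = windowed_content(ens, _segmap(ens), "CtS")
        assert list(df["time_ns"]) == [50.0, 100.0]  # (100,130] dropped
        assert df.loc[df["time_ns"] == 50.0, "fraction"].iloc[0] == 1.0
        assert df.loc[df["time_ns"] == 100.0, "fraction"].iloc[0] == 0.0

    def test_binomial_recovery_with_one_covering_window(self):
        spec = SimulationSpec(n_chains=1, n_frames=1000, occupancy=0.30, seed=11)
        ens = simulate_ensemble(spec)
        df = windowed_content(ens, _segmap(ens), "CtS", window_ns=1000.0, stride_ns=1000.0)
        assert len(df) == 1
        n = df["n_obs"].iloc[0]
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(df["fraction"].iloc[0] - 0.30) < 3 * se

    def test_unknown_segment_and_short_run_errors(self):
        ens = constant_ensemble(*PPII, n_frames=10)
        with pytest.raises(KeyError):
            windowed_content(ens, _segmap(ens), "nope")
        with pytest.raises(ValueError):
            windowed_content(ens, _segmap(ens), "CtS", window_ns=100.0, stride_ns=100.0)

    def test_denominator_excludes_undefined_termini(self):
        ens = constant_ensemble(*PPII, n_frames=10)
        df = windowed_content(ens, _segmap(ens), "CtS", window_ns=10.0, stride_ns=10.0)
        # 14 residues, minus first (no phi) and last (no psi): 12 per frame
        assert df["n_obs"].iloc[0] == 12 * 10


class TestPerResidue:
    def test_pinned_residue_is_unity_and_termini_are_na(self):
        ens = constant_ensemble(*PPII, n_frames=8)
        df = per_residue_population(ens)
        interior = df[(df["residue_index"] > 1) & (df["residue_index"] < 14)]
        assert np.allclose(interior["mean_fraction"], 1.0)
        ends = df[df["residue_index"].isin([1, 14])]
        assert ends["mean_fraction"].isna().all()
        assert (ends["n_obs"] == 0).all()

    def test_exact_alternation_gives_half(self):
        ens = constant_ensemble(*PPII, n_frames=10)
        for c in ens.chains:
            ens.phi[c][::2, 1:] = 60.0  # every other frame out of the window
        df = per_residue_population(ens)
        interior = df[(df["residue_index"] > 1) & (df["residue_index"] < 14)]
        assert np.allclose(interior["mean_fraction"], 0.5)

    def test_profile_recovery_across_occupancy_gradient(self):
        occ = np.array([0.1, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        spec = SimulationSpec(n_chains=4, n_frames=1500, occupancy=occ, seed=5)
        ens = simulate_ensemble(spec)
        df = per_residue_population(ens)
        pooled = df.groupby("residue_index").apply(
            lambda d: pd.Series(
                {
                    "frac": (d["mean_fraction"] * d["n_obs"]).sum() / d["n_obs"].sum()
                    if d["n_obs"].sum()
                    else np.nan,
                    "n": d["n_obs"].sum(),
                }
            ),
            include_groups=False,
        )
        for ri in range(2, 14):  # interior residues
            p = occ[ri - 1]
            row = pooled.loc[ri]
            se = math.sqrt(p * (1 - p) / row["n"])
            assert abs(row["frac"] - p) < 3 * se, f"residue {ri}"


class TestPerRepeat:
    def test_segregation_only_first_repeat_ppii(self):
        ens = constant_ensemble(*COIL, n_frames=20, chains=("c1", "c2"))
        seg = _segmap(ens)
        for c in ens.chains:
            for pos in seg.positions(c, "GGM1"):
                ens.phi[c][:, pos - 1] = PPII[0]
                ens.psi[c][:, pos - 1] = PPII[1]
        df = per_repeat_content(ens, seg, window_ns=20.0, stride_ns=20.0)
        by = df.set_index("segment")["fraction"]
        assert by["GGM1"] == 1.0
        assert by["GGM2"] == by["GGM3"] == by["GGM4"] == 0.0

    def test_repeats_exchangeable_under_uniform_occupancy(self):
        spec = SimulationSpec(n_chains=7, n_frames=800, occupancy=0.3, seed=23)
        ens = simulate_ensemble(spec)
        df = per_repeat_content(ens, _segmap(ens), window_ns=800.0, stride_ns=800.0)
        for _, row in df.iterrows():
            se = math.sqrt(0.3 * 0.7 / row["n_obs"])
            assert abs(row["fraction"] - 0.3) < 3 * se, row["segment"]

    def test_missing_repeats_error(self):
        ens = constant_ensemble(*PPII, n_frames=10)
        bare = SegmentMap(segments={c: {"CtS": tuple(range(1, 15))} for c in ens.chains})
        with pytest.raises(ValueError):
            per_repeat_content(ens, bare)


class TestAggregation:
    def test_denominator_conservation(self):
        spec = SimulationSpec(n_chains=2, n_frames=100, occupancy=0.3, seed=3)
        ens = simulate_ensemble(spec)
        df = windowed_content(ens, _segmap(ens), "CtS", window_ns=100.0, stride_ns=100.0)
        # PPII + non-PPII observations = defined observations
        n_def = sum(
            np.sum(np.isfinite(ens.phi[c]) & np.isfinite(ens.psi[c])) for c in ens.chains
        )
        assert df["n_obs"].sum() == n_def

    def test_whole_run_mean_equals_weighted_window_mean_when_tiling(self):
        spec = SimulationSpec(n_chains=3, n_frames=100, occupancy=0.25, seed=9)
        ens = simulate_ensemble(spec)
        seg = _segmap(ens)
        tiled = windowed_content(ens, seg, "CtS", window_ns=25.0, stride_ns=25.0)
        whole = windowed_content(ens, seg, "CtS", window_ns=100.0, stride_ns=100.0)
        assert run_summary(tiled, "CtS") == pytest.approx(
            run_summary(whole, "CtS"), abs=1e-12
        )

    def test_segment_nesting_weighted_average(self):
        """CtC content is the observation-weighted mix of CtS and the rest."""
        spec = SimulationSpec(
            n_chains=2, sequence=GROEL_CTC, n_frames=200, occupancy=0.3, seed=17
        )
        ens = simulate_ensemble(spec)
        seg = _segmap(ens)
        for c in ens.chains:
            seg.segments[c]["head"] = tuple(range(1, 11))  # CtC minus CtS
        f_ctc = windowed_content(ens, seg, "CtC", 200.0, 200.0)
        f_cts = windowed_content(ens, seg, "CtS", 200.0, 200.0)
        f_head = windowed_content(ens, seg, "head", 200.0, 200.0)
        for chain in ens.chains:
            ctc = f_ctc[f_ctc["chain"] == chain].iloc[0]
            cts = f_cts[f_cts["chain"] == chain].iloc[0]
            head = f_head[f_head["chain"] == chain].iloc[0]
            mix = (
                cts["fraction"] * cts["n_obs"] + head["fraction"] * head["n_obs"]
            ) / (cts["n_obs"] + head["n_obs"])
            assert ctc["fraction"] == pytest.approx(mix, abs=1e-12)
            assert ctc["n_obs"] == cts["n_obs"] + head["n_obs"]

    def test_estimator_bias_small_across_occupancies(self):
        for i, p in enumerate((0.05, 0.15, 0.25, 0.35)):
            spec = SimulationSpec(n_chains=7, n_frames=1000, occupancy=p, seed=100 + i)
            ens = simulate_ensemble(spec)
            df = windowed_content(ens, _segmap(ens), "CtS", 1000.0, 1000.0)
            est = run_summary(df, "CtS")
            assert abs(est - p) < 0.01, p

    def test_chain_and_obs_weights_agree_for_balanced_design(self):
        ens = constant_ensemble(*PPII, n_frames=50, chains=("a", "b"))
        ens.phi["b"][:, 1:] = 60.0  # chain b never PPII
        df = windowed_content(ens, _segmap(ens), "CtS", 50.0, 50.0)
        assert run_summary(df, "CtS", weights="obs") == pytest.approx(0.5)
        assert run_summary(df, "CtS", weights="chain") == pytest.approx(0.5)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self):
        spec = SimulationSpec(n_chains=2, n_frames=120, occupancy=0.22, seed=1)
        res = TrajectoryPPII(simulate_ensemble(spec)).fit()
        text = res.summary()
        assert "CtS" in text and "GGM1" in text
        assert 0.0 <= res.run_summary("CtS") <= 1.0
        assert set(res.per_residue.columns) >= {
            "chain", "residue_index", "residue_name", "mean_fraction", "n_obs",
        }
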