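"""Synthetic-data generator: determinism, intensity bookkeeping, noise
calibration and cyanoethylation redistribution."""

import numpy as np
import pandas as pd
import pytest

from silnas.digestion import AnnotatedSequence
from silnas.quantification import CEParams
from silnas.simulator import (
    SimConfig,
    build_species,
    design_ground_truth,
    simulate,
    simulate_calibration,
    simulate_ce,
)


def quiet_config(**overrides):
    defaults = dict(
        parents=[AnnotatedSequence("p", "AAUUGCCAGCAUGAAAG", three_prime="OH")],
        intensity_cv=0.0,
        mass_error_ppm_sd=0.0,
        rt_jitter_sd=0.0,
        replicates=1,
        seed=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


class TestDeterminism:
    def test_same_seed_is_bit_identical(self):
        config = quiet_config(intensity_cv=0.05, mass_error_ppm_sd=3.0, rt_jitter_sd=2.0)
        a = simulate(config).features
        b = simulate(config).features
        pd.testing.assert_frame_equal(a, b)

    def test_ce_run_is_deterministic_under_seed(self):
        config = quiet_config(intensity_cv=0.05)
        res = simulate(config)
        a = simulate_ce(res, CEParams(), seed=5)
        b = simulate_ce(res, CEParams(), seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate(quiet_config(intensity_cv=0.05, seed=1)).features
        b = simulate(quiet_config(intensity_cv=0.05, seed=2)).features
        assert not a["intensity"].equals(b["intensity"])


class TestIntensityModel:
    def test_unmodified_rna_has_unit_light_heavy_ratio(self):
        res = simulate(quiet_config())
        df = res.features
        for (start, end), grp in df.groupby(["start", "end"]):
            light = grp[~grp["is_heavy"]]["intensity"].iloc[0]
            heavy = grp[grp["is_heavy"]]["intensity"].iloc[0]
            assert light == pytest.approx(heavy)

    def test_partial_site_splits_intensity(self):
        parent = AnnotatedSequence(
            "p", "AAUUGCCAGCAUGAAAG", mods={3: "Y"}, three_prime="OH"
        )
        config = quiet_config(parents=[parent], fractions={("p", 3): 0.76})
        df = simulate(config).features
        first = df[(df["start"] == 1) & (df["end"] == 5) & (df["missed_cleavages"] == 0)]
        heavy = first[first["is_heavy"]]["intensity"].iloc[0]
        unmod = first[(~first["is_heavy"]) & (first["mods"] == "[]")]["intensity"].iloc[0]
        modded = first[(~first["is_heavy"]) & (first["mods"] != "[]")]["intensity"].iloc[0]
        assert unmod == pytest.approx(0.24 * heavy)
        assert modded == pytest.approx(0.76 * heavy)

    def test_modification_splitting_conserves_intensity(self):
        parent = AnnotatedSequence(
            "p", "AAUUGCCAGCAUGAAAG", mods={3: "Y", 12: "Um"}, three_prime="OH"
        )
        config = quiet_config(
            parents=[parent],
            fractions={("p", 3): 0.3, ("p", 12): 0.6},
            missed_cleavage_fraction=0.0,
            min_rel_intensity=0.0,
        )
        species = build_species(config)
        light = [
            s
            for s in species
            if not s.is_heavy and s.fragment.missed_cleavages == 0
        ]
        totals = {}
        for sp in light:
            totals.setdefault(sp.fragment.identity, 0.0)
            totals[sp.fragment.identity] += sp.rel_intensity
        assert len(totals) == 4  # the four T1 products of the parent
        for total in totals.values():
            assert total == pytest.approx(1.0)

    def test_missed_cleavage_species_at_configured_abundance(self):
        df = simulate(quiet_config()).features
        missed = df[(df["missed_cleavages"] == 1) & df["is_heavy"]]
        full = df[(df["missed_cleavages"] == 0) & df["is_heavy"]]
        assert missed["intensity"].max() == pytest.approx(
            0.1 * full["intensity"].max()
        )


class TestNoiseModel:
    def test_ppm_errors_centered_with_configured_sd(self):
        config = quiet_config(mass_error_ppm_sd=3.0, replicates=150)
        res = simulate(config)
        clean = simulate(quiet_config(replicates=1)).features
        ref = clean.set_index(["species_id", "charge"])["mz"]
        obs = res.features
        ppm = (
            (obs["mz"].values
             - ref.loc[list(zip(obs["species_id"], obs["charge"]))].values)
            / ref.loc[list(zip(obs["species_id"], obs["charge"]))].values
            * 1e6
        )
        assert len(ppm) >= 1000
        assert abs(np.mean(ppm)) < 0.5
        assert abs(np.std(ppm) - 3.0) / 3.0 < 0.2

    def test_modification_rt_shifts_follow_class_offsets(self):
        parent = AnnotatedSequence(
            "p", "AAUUGCCAGCAUGAAAG", mods={3: "Y", 12: "Um"}, three_prime="OH"
        )
        config = quiet_config(parents=[parent], fractions={("p", 3): 0.5, ("p", 12): 0.5})
        df = simulate(config).features
        f1 = df[(df["start"] == 1) & (df["end"] == 5)]
        psi_rt = f1[f1["mods"] != "[]"]["rt_sec"].iloc[0]
        ref_rt = f1[f1["is_heavy"]]["rt_sec"].iloc[0]
        assert psi_rt - ref_rt == pytest.approx(-48.0)
        f2 = df[(df["start"] == 10) & (df["end"] == 13)]
        nm_rt = f2[f2["mods"] != "[]"]["rt_sec"].iloc[0]
        ref2 = f2[f2["is_heavy"]]["rt_sec"].iloc[0]
        assert nm_rt - ref2 == pytest.approx(90.0)


class TestCyanoethylation:
    def test_zero_efficiency_is_identity(self):
        res = simulate(quiet_config())
        ce = simulate_ce(res, CEParams(efficiency_psi=0.0, efficiency_u=0.0))
        base = res.features
        assert len(ce) == len(base)
        assert np.allclose(sorted(ce["mz"]), sorted(base["mz"]))

    def test_single_psi_fragment_ce_fraction_matches_efficiency(self):
        # fragment 1-5 AAUUG with psi at 3 (fully modified), U at 4 plain
        parent = AnnotatedSequence(
            "p", "AAUUGCCAGCAUGAAAG", mods={3: "Y"}, three_prime="OH"
        )
        config = quiet_config(parents=[parent], min_rel_intensity=0.0, ce_max_adducts=4)
        res = simulate(config)
        ce = simulate_ce(res, CEParams(efficiency_psi=0.30, efficiency_u=0.0))
        light = ce[(ce["start"] == 1) & (ce["end"] == 5) & (~ce["is_heavy"])
                   & (ce["charge"] == 1) & (ce["missed_cleavages"] == 0)]
        ced = light[light["mods"].str.contains("ce")]["intensity"].sum()
        assert ced / light["intensity"].sum() == pytest.approx(0.30)

    def test_total_intensity_conserved_across_ce_states(self):
        config = quiet_config(min_rel_intensity=0.0, ce_max_adducts=6)
        res = simulate(config)
        ce = simulate_ce(res, CEParams())
        pre = res.features.groupby(["species_id", "charge"])["intensity"].sum()
        # compare per original species at charge 1 (CE can add charge states)
        post = ce[ce["charge"] == 1].groupby("species_id")["intensity"].sum()
        for sid, total in pre[pre.index.get_level_values("charge") == 1].items():
            assert post.loc[sid[0]] == pytest.approx(total)


class TestCalibration:
    def test_noise_free_series_is_exact(self):
        df = simulate_calibration(cv=0.0, seed=0)
        assert np.allclose(df["measured_ratio"], df["molar_ratio"])

    def test_shape(self):
        df = simulate_calibration(ratios=(0.5, 1, 2), replicates=3, seed=0)
        assert len(df) == 9
        assert set(df.columns) == {"molar_ratio", "measured_ratio", "replicate"}


class TestDesign:
    def test_design_is_reproducible(self):
        a_parent, a_fracs = design_ground_truth(10, seed=5)
        b_parent, b_fracs = design_ground_truth(10, seed=5)
        assert a_parent.residues == b_parent.residues
        assert a_fracs == b_fracs

    def test_design_respects_site_plan_and_palette(self):
        plan = ["Y"] * 4
        parent, fracs = design_ground_truth(
            4, seed=3, site_plan=plan, palette=[0.0, 0.25, 0.5, 1.0], spacing=1
        )
        assert len(parent.mods) == 4
        assert all(codes == ("Y",) for codes in parent.mods.values())
        assert sorted(fracs.values()) == [0.0, 0.25, 0.5, 1.0]

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                parents=[AnnotatedSequence("p", "AAG")],
                fractions={("p", 1): 1.5},
            )
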