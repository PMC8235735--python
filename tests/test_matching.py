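"""S/N filtering, ppm matching, matrix assembly, replicate correlation."""

import numpy as np
import pandas as pd
import pytest

import glycomud as g

from .conftest import brute_force_match


def _features(masses, sample="s1", abundance=100.0, snr=10.0):
    masses = np.atleast_1d(masses)
    return pd.DataFrame(
        {
            "sample_id": sample,
            "neutral_mass": masses,
            "rt_min": 10.0,
            "abundance": abundance,
            "snr": snr,
        }
    )


class TestSnrFilter:
    def test_boundary_inclusive(self):
        df = _features([100.0, 200.0, 300.0])
        df["snr"] = [5.0, 4.9, 50.0]
        kept = g.filter_snr(df, 5.0)
        assert list(kept["neutral_mass"]) == [100.0, 300.0]

    def test_zero_threshold_is_identity(self):
        df = _features([100.0, 200.0])
        df["snr"] = [0.0, 1.0]
        assert len(g.filter_snr(df, 0.0)) == 2


class TestMatchFeatures:
    def test_worked_ppm_examples(self, hp_library):
        # GP3 Hex4HexNAc3 sits at 3051.453 (3 dp): a +0.002 Da offset is
        # well inside 10 ppm, a +0.047 Da offset (~15 ppm) is outside
        theo = hp_library.by_key()["GP3:Hex4HexNAc3"].theoretical_mass
        out = g.match_features(_features([3051.455, 3051.500]), hp_library, 10.0)
        assert out.loc[0, "entry_key"] == "GP3:Hex4HexNAc3"
        assert out.loc[0, "ppm_error"] == pytest.approx(
            g.ppm_error(3051.455, theo), abs=1e-9
        )
        assert 0 < out.loc[0, "ppm_error"] < 1.0
        assert pd.isna(out.loc[1, "entry_key"])
        assert g.ppm_error(3051.500, theo) > 10.0

    def test_exact_mass_matches_at_zero_ppm(self, hp_library):
        m = hp_library.entries[0].theoretical_mass
        out = g.match_features(_features([m]), hp_library, 10.0)
        assert out.loc[0, "ppm_error"] == 0.0
        assert not out.loc[0, "ambiguous"]

    def test_tie_flagged_ambiguous(self):
        lib = g.make_fixture_library(2, 1, 1, seed=5)
        e0, e1 = lib.entries[:2]
        mid = (e0.theoretical_mass + e1.theoretical_mass) / 2
        # force a near-tie library: use two entries symmetric around mid
        spread_ppm = abs(e1.theoretical_mass - e0.theoretical_mass) / mid * 1e6
        out = g.match_features(_features([mid]), lib, max(spread_ppm, 10.0) + 1)
        # |ppm| to both entries differs only through the denominators; the
        # match must agree with brute force and flag a tie when exact
        ref_key, ref_ppm, ref_amb = brute_force_match(_features([mid]), lib,
                                                      max(spread_ppm, 10.0) + 1)[0]
        assert out.loc[0, "entry_key"] == ref_key
        assert bool(out.loc[0, "ambiguous"]) == ref_amb

    def test_identical_masses_are_ambiguous(self):
        lib = g.make_fixture_library(3, 2, [1, 1], seed=21)
        # graft one backbone's entry mass onto another library entry by
        # matching an observed mass equal to two entries' duplicated mass
        e = lib.entries[0]
        dup = g.GlycopeptideEntry(
            backbone=lib.entries[-1].backbone,
            occupied_sites=1,
            total_composition=e.total_composition,
            site_assignments=e.site_assignments,
            theoretical_mass=e.theoretical_mass,
            group_label=lib.entries[-1].group_label,
        )
        lib.entries.append(dup)
        out = g.match_features(_features([e.theoretical_mass]), lib, 10.0)
        assert bool(out.loc[0, "ambiguous"])

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lib = g.make_fixture_library(
            n_glycans=int(rng.integers(2, 8)),
            n_backbones=int(rng.integers(1, 3)),
            sites_per_backbone=int(rng.integers(1, 3)),
            seed=seed,
        )
        masses = np.array(lib.masses())
        obs = np.concatenate(
            [
                rng.choice(masses, 30) * (1 + rng.normal(0, 3e-6, 30)),
                rng.uniform(masses.min() * 0.9, masses.max() * 1.1, 30),
            ]
        )
        out = g.match_features(_features(obs), lib, 10.0)
        ref = brute_force_match(_features(obs), lib, 10.0)
        for i, (key, ppm, amb) in enumerate(ref):
            if key is None:
                assert pd.isna(out.loc[i, "entry_key"])
            else:
                assert out.loc[i, "entry_key"] == key
                assert out.loc[i, "ppm_error"] == pytest.approx(ppm, abs=1e-9)
            assert bool(out.loc[i, "ambiguous"]) == amb

    def test_tightening_tolerance_never_gains_matches(self, small_library):
        rng = np.random.default_rng(0)
        masses = np.array(small_library.masses())
        obs = rng.choice(masses, 50) * (1 + rng.normal(0, 5e-6, 50))
        wide = g.match_features(_features(obs), small_library, 10.0)
        narrow = g.match_features(_features(obs), small_library, 3.0)
        assert set(narrow.dropna(subset=["entry_key"]).index) <= set(
            wide.dropna(subset=["entry_key"]).index
        )


class TestAssembleMatrix:
    def _manifest(self, ids, groups=None):
        return pd.DataFrame(
            {"sample_id": ids, "group": groups or ["control"] * len(ids)}
        )

    def test_multiple_features_sum(self, hp_library):
        m = hp_library.entries[0].theoretical_mass
        feats = pd.concat(
            [_features([m], abundance=100.0), _features([m], abundance=50.0)],
            ignore_index=True,
        )
        matched = g.match_features(feats, hp_library, 10.0)
        mx = g.assemble_matrix(matched, self._manifest(["s1"]), hp_library)
        assert mx.values.iloc[0, 0] == pytest.approx(150.0)

    def test_unmatched_entries_absent_and_abundance_conserved(self, hp_library):
        rng = np.random.default_rng(1)
        masses = np.array(hp_library.masses())
        obs = rng.choice(masses, 40)
        feats = _features(obs, abundance=1.0)
        feats["abundance"] = rng.uniform(10, 100, len(feats))
        matched = g.match_features(feats, hp_library, 10.0)
        mx = g.assemble_matrix(matched, self._manifest(["s1"]), hp_library)
        usable = matched[matched["entry_key"].notna() & ~matched["ambiguous"]]
        assert mx.values.to_numpy().sum() == pytest.approx(usable["abundance"].sum())
        assert set(mx.entry_keys) == set(usable["entry_key"])

    def test_sample_missing_from_manifest_is_an_error(self, hp_library):
        m = hp_library.entries[0].theoretical_mass
        matched = g.match_features(_features([m], sample="ghost"), hp_library, 10.0)
        with pytest.raises(ValueError, match="ghost"):
            g.assemble_matrix(matched, self._manifest(["s1"]), hp_library)

    def test_manifest_defines_rows_and_labels(self, hp_library):
        m = hp_library.entries[0].theoretical_mass
        matched = g.match_features(_features([m], sample="a"), hp_library, 10.0)
        manifest = self._manifest(["a", "b", "c"], ["cancer", "control", "control"])
        mx = g.assemble_matrix(matched, manifest, hp_library)
        assert mx.sample_ids == ["a", "b", "c"]
        assert list(mx.groups.loc[mx.sample_ids]) == ["cancer", "control", "control"]
        assert mx.values.loc["b"].sum() == 0.0
        assert not mx.detected.loc["b"].any()


class TestReplicateCorrelation:
    def test_identical_and_scaled_replicates(self):
        p = pd.Series({"GP1:a": 10.0, "GP1:b": 5.0, "GP1:c": 1.0})
        out = g.replicate_correlation(p, p)
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)
        out2 = g.replicate_correlation(p, 2 * p)
        assert out2.loc[0, "pearson_r"] == pytest.approx(1.0)
        assert out2.loc[0, "n_pairs"] == 3

    def test_anti_ordered_vectors(self):
        a = pd.Series({"GP1:x": 1.0, "GP1:y": 2.0, "GP1:z": 3.0})
        b = pd.Series({"GP1:x": 3.0, "GP1:y": 2.0, "GP1:z": 1.0})
        assert g.replicate_correlation(a, b).loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_insufficient_overlap_not_computable(self):
        a = pd.Series({"GP1:x": 1.0})
        b = pd.Series({"GP1:x": 2.0})
        out = g.replicate_correlation(a, b)
        assert np.isnan(out.loc[0, "pearson_r"])
        assert out.loc[0, "n_pairs"] == 1
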