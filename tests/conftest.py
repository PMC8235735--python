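"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import glycomud as g

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Published reference masses for the three haptoglobin beta-subunit tryptic
# glycopeptide groups (neutral monoisotopic Da, 3 dp), with glycan
# compositions as (hex, hexnac, fuc, neuac).
GP_PEPTIDES = {
    "GP1": "MVSHHNLTTGATLINEQWLLTTAK",
    "GP2": "NLFLNHSENATAK",
    "GP3": "VVLHPNYSQVDIGLIK",
}

REFERENCE_GLYCOPEPTIDE_MASSES = [
    ("GP1", (4, 3, 0, 1), 4226.930),
    ("GP1", (5, 4, 1, 1), 4738.120),
    ("GP1", (6, 4, 0, 1), 4754.115),
    ("GP1", (5, 4, 0, 2), 4883.157),
    ("GP1", (6, 5, 1, 2), 5394.348),
    ("GP1", (6, 5, 1, 3), 5685.443),
    ("GP2", (10, 8, 1, 3), 5722.234),
    ("GP2", (10, 8, 0, 4), 5867.271),
    ("GP2", (10, 8, 1, 4), 6013.329),
    ("GP2", (11, 9, 1, 4), 6378.461),
    ("GP2", (11, 9, 1, 5), 6669.557),
    ("GP2", (12, 10, 1, 4), 6743.593),
    ("GP2", (12, 10, 1, 5), 7034.689),
    ("GP2", (12, 10, 1, 6), 7325.784),
    ("GP3", (4, 3, 0, 0), 3051.453),
    ("GP3", (4, 3, 0, 1), 3342.549),
    ("GP3", (4, 4, 0, 1), 3545.628),
    ("GP3", (5, 4, 0, 1), 3707.681),
    ("GP3", (6, 4, 0, 1), 3869.734),
    ("GP3", (5, 4, 0, 2), 3998.776),
    ("GP3", (5, 4, 1, 2), 4144.834),
    ("GP3", (6, 4, 0, 2), 4160.829),
    ("GP3", (6, 5, 1, 3), 4801.062),
]

# Independent residue-mass oracle: 5-dp monoisotopic residue masses
# transcribed by hand, NOT taken from the implementation's mass source.
ORACLE_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.010565


def oracle_peptide_mass(sequence: str) -> float:
    return sum(ORACLE_RESIDUE_MASS[a] for a in sequence) + ORACLE_WATER


def brute_force_match(features: pd.DataFrame, library, ppm_tolerance: float):
    """Full-scan nearest-entry matcher: the reference for match_features.

    Scans every library entry for every feature; ties at the minimal
    |ppm| are resolved toward the lowest theoretical mass (library
    order for exactly equal masses) and flagged ambiguous.
    """
    rows = []
    for m in features["neutral_mass"]:
        best_key, best_ppm, n_best = None, None, 0
        for e in library.entries:
            ppm = 1e6 * (m - e.theoretical_mass) / e.theoretical_mass
            if abs(ppm) > ppm_tolerance:
                continue
            if best_ppm is None or abs(ppm) < abs(best_ppm):
                best_key, best_ppm, n_best = e.key, ppm, 1
            elif abs(ppm) == abs(best_ppm):
                n_best += 1
                # equal |ppm| at a larger mass cannot beat the incumbent;
                # equal masses keep the earlier (library-order) entry
        rows.append((best_key, best_ppm, n_best > 1))
    return rows


def brute_force_glycoform_totals(glycans, n_sites):
    """Exhaustive enumeration of all occupied-site multisets and their
    distinct totals, independent of the library module's combinatorics."""
    from itertools import combinations_with_replacement

    forms = []
    for size in range(1, n_sites + 1):
        forms.extend(combinations_with_replacement(sorted(glycans), size))
    totals = set()
    for form in forms:
        t = (
            sum(c.hex for c in form),
            sum(c.hexnac for c in form),
            sum(c.fuc for c in form),
            sum(c.neuac for c in form),
        )
        totals.add(t)
    return forms, totals


@pytest.fixture(scope="session")
def hp_library():
    return g.haptoglobin_library()


@pytest.fixture(scope="session")
def small_library():
    return g.make_fixture_library(n_glycans=6, n_backbones=2,
                                  sites_per_backbone=[1, 2], seed=11)


@pytest.fixture()
def toy_matrix():
    """A small two-cohort abundance matrix with known structure."""
    rng = np.random.default_rng(5)
    lib = g.make_fixture_library(n_glycans=5, n_backbones=1,
                                 sites_per_backbone=1, seed=3)
    keys = [e.key for e in lib.entries]
    n_ctrl, n_case = 12, 12
    vals = rng.lognormal(8, 0.3, size=(n_ctrl + n_case, len(keys)))
    vals[n_ctrl:, 0] *= 3.0  # strong planted effect on the first entry
    idx = [f"c{i}" for i in range(n_ctrl)] + [f"d{i}" for i in range(n_case)]
    values = pd.DataFrame(vals, index=idx, columns=keys)
    groups = pd.Series(["control"] * n_ctrl + ["cancer"] * n_case, index=idx)
    return g.AbundanceMatrix(
        values=values, groups=groups, detected=values > 0,
        entries={e.key: e for e in lib.entries},
    )
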