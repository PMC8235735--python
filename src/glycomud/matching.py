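"""Accurate-mass matching of deconvoluted LC–MS features to the library.

The input is a per-sample table of deconvoluted neutral monoisotopic
masses with retention time, abundance and signal-to-noise — the shape
of a vendor molecular-feature-extraction export.  Features are filtered
on S/N, then each is assigned to the library entry minimising the
absolute ppm error within a tolerance (10 ppm by default).  Ties at the
minimal |ppm| are flagged ambiguous and excluded from quantitation.
Retention time is carried through for reporting but not used as a match
constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scistats

from .library import GlycopeptideEntry, GlycopeptideLibrary

FEATURE_CSV_COLUMNS = ["sample_id", "neutral_mass", "rt_min", "abundance", "snr"]

#: Maps alternative vendor-ish column spellings onto the canonical names.
FEATURE_COLUMN_ALIASES: dict[str, str] = {
    "sample": "sample_id",
    "mass": "neutral_mass",
    "neutral mass": "neutral_mass",
    "rt": "rt_min",
    "retention time": "rt_min",
    "intensity": "abundance",
    "volume": "abundance",
    "height": "abundance",
    "s/n": "snr",
    "signal_to_noise": "snr",
}


def read_features_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature CSV; canonical header ``sample_id,neutral_mass,rt_min,abundance,snr``."""
    df = pd.read_csv(path)
    df = df.rename(
        columns={c: FEATURE_COLUMN_ALIASES.get(c.strip().lower(), c) for c in df.columns}
    )
    missing = [c for c in FEATURE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature CSV missing columns {missing}")
    if (df["neutral_mass"] <= 0).any():
        raise ValueError(f"{path}: neutral_mass must be positive")
    if (df["abundance"] < 0).any():
        raise ValueError(f"{path}: abundance must be non-negative")
    return df[FEATURE_CSV_COLUMNS + [c for c in df.columns if c not in FEATURE_CSV_COLUMNS]]


def filter_snr(features: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Keep features with snr >= threshold (boundary inclusive), order preserved."""
    if threshold < 0:
        raise ValueError("snr threshold must be >= 0")
    return features[features["snr"] >= threshold].copy()


def match_features(
    features: pd.DataFrame,
    library: GlycopeptideLibrary,
    ppm_tolerance: float = 10.0,
) -> pd.DataFrame:
    """Assign each feature to the nearest library entry within tolerance.

    Returns a copy of ``features`` with three columns appended:
    ``entry_key`` (library entry identifier, or NA if unmatched),
    ``ppm_error`` (signed, NA if unmatched) and ``ambiguous`` (True when
    two or more entries tie at the minimal |ppm| within tolerance; such
    features keep the lowest-mass tying entry for reporting but are
    excluded from quantitation).
    """
    if not library.entries:
        raise ValueError("library is empty")
    if ppm_tolerance <= 0:
        raise ValueError("ppm tolerance must be > 0")
    masses = np.asarray(library.masses())
    order = np.argsort(masses, kind="stable")
    sorted_masses = masses[order]
    keys = [library.entries[i].key for i in order]

    obs = features["neutral_mass"].to_numpy(dtype=float)
    tol = ppm_tolerance * 1e-6
    lo = np.searchsorted(sorted_masses, obs / (1.0 + tol), side="left")
    hi = np.searchsorted(sorted_masses, obs / (1.0 - tol), side="right")

    entry_key: list[object] = []
    ppm_err: list[float] = []
    ambig: list[bool] = []
    for m, a, b in zip(obs, lo, hi):
        if b <= a:
            entry_key.append(pd.NA)
            ppm_err.append(np.nan)
            ambig.append(False)
            continue
        cand = sorted_masses[a:b]
        ppm = 1e6 * (m - cand) / cand
        absppm = np.abs(ppm)
        best = absppm.min()
        idx = np.flatnonzero(absppm == best)
        entry_key.append(keys[a + idx[0]])
        ppm_err.append(float(ppm[idx[0]]))
        ambig.append(len(idx) > 1)

    out = features.copy()
    out["entry_key"] = entry_key
    out["ppm_error"] = ppm_err
    out["ambiguous"] = ambig
    return out


@dataclass
class AbundanceMatrix:
    """Samples × glycopeptide-entries abundance matrix with group labels.

    ``values`` is a DataFrame indexed by sample_id with entry keys as
    columns; non-detected cells are zero.  ``groups`` maps sample_id to
    its cohort label; ``detected`` is the boolean detection mask;
    ``entries`` maps entry key to the library record.
    """

    values: pd.DataFrame
    groups: pd.Series
    detected: pd.DataFrame
    entries: dict[str, GlycopeptideEntry] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def entry_keys(self) -> list[str]:
        return list(self.values.columns)

    def subset_entries(self, keys: Sequence[str]) -> "AbundanceMatrix":
        keys = [k for k in self.entry_keys if k in set(keys)]
        return AbundanceMatrix(
            values=self.values[keys].copy(),
            groups=self.groups.copy(),
            detected=self.detected[keys].copy(),
            entries={k: self.entries[k] for k in keys if k in self.entries},
            metadata=dict(self.metadata),
        )

    def entry_group(self, key: str) -> str:
        if key in self.entries:
            return self.entries[key].group_label
        return key.split(":", 1)[0]

    def write_csv(self, matrix_path: str | Path, manifest_path: str | Path) -> None:
        self.values.to_csv(matrix_path, index_label="sample_id")
        pd.DataFrame(
            {"sample_id": self.values.index, "group": self.groups.loc[self.values.index]}
        ).to_csv(manifest_path, index=False)

    @classmethod
    def read_csv(
        cls,
        matrix_path: str | Path,
        manifest_path: str | Path,
        library: GlycopeptideLibrary | None = None,
    ) -> "AbundanceMatrix":
        values = pd.read_csv(matrix_path, index_col="sample_id")
        manifest = read_manifest(manifest_path)
        groups = manifest.set_index("sample_id")["group"].loc[values.index]
        entries = {}
        if library is not None:
            by_key = library.by_key()
            entries = {k: by_key[k] for k in values.columns if k in by_key}
        return cls(
            values=values,
            groups=groups,
            detected=values > 0,
            entries=entries,
        )


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest CSV with columns ``sample_id,group``."""
    df = pd.read_csv(path)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError(f"{path}: manifest must have columns sample_id,group")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id in manifest")
    return df


def assemble_matrix(
    matched: pd.DataFrame,
    manifest: pd.DataFrame,
    library: GlycopeptideLibrary | None = None,
) -> AbundanceMatrix:
    """Build the samples × entries abundance matrix from match results.

    Abundances of multiple unambiguous features matching one entry in
    one sample are summed; ambiguous and unmatched features are
    discarded; entries never matched in any sample are absent; samples
    follow manifest order and non-detected cells are zero.
    """
    known = set(manifest["sample_id"])
    present = set(matched["sample_id"].unique())
    unknown = sorted(present - known)
    if unknown:
        raise ValueError(f"samples missing from manifest: {', '.join(map(str, unknown))}")

    usable = matched[matched["entry_key"].notna() & ~matched["ambiguous"]]
    wide = (
        usable.groupby(["sample_id", "entry_key"], sort=False)["abundance"]
        .sum()
        .unstack(fill_value=0.0)
        .reindex(index=manifest["sample_id"], fill_value=0.0)
    )
    wide.columns.name = None
    if library is not None:
        by_key = library.by_key()
        order = [e.key for e in library.entries if e.key in set(wide.columns)]
        wide = wide[order]
        entries = {k: by_key[k] for k in order}
    else:
        entries = {}
    groups = manifest.set_index("sample_id")["group"]
    return AbundanceMatrix(
        values=wide,
        groups=groups,
        detected=wide > 0,
        entries=entries,
        metadata={
            "aggregation": "sum of unambiguous matched feature abundances",
            "missing_value_policy": "zero-imputed non-detections",
        },
    )


def replicate_correlation(
    profile1: pd.Series,
    profile2: pd.Series,
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson R between two replicate glycoform profiles, per GP group.

    ``profile1``/``profile2`` are abundance Series indexed by entry key;
    only entries present in both (the shared set) are paired, and the
    pair count is reported.  Groups default to the prefix before ``:``
    in the entry key.  Groups with fewer than two shared entries are
    reported with R = NaN (not computable).
    """
    shared = profile1.index.intersection(profile2.index)
    if groups is None:
        groups = {k: str(k).split(":", 1)[0] for k in shared}
    rows = []
    for g in sorted(set(groups[k] for k in shared)):
        keys = [k for k in shared if groups[k] == g]
        x = profile1.loc[keys].to_numpy(dtype=float)
        y = profile2.loc[keys].to_numpy(dtype=float)
        if len(keys) < 2 or np.std(x) == 0 or np.std(y) == 0:
            r = np.nan
        else:
            r = float(_scistats.pearsonr(x, y).statistic)
        rows.append({"group": g, "n_pairs": len(keys), "pearson_r": r})
    return pd.DataFrame(rows, columns=["group", "n_pairs", "pearson_r"])
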