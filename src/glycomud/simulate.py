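"""Synthetic cohort and feature-table generator.

Emulates the statistical structure the downstream analysis assumes for
a two-cohort serum glycoproteomics study: per-glycoform lognormal
abundances around a fixed baseline profile, multiplicative disease
effects planted on chosen glycoforms, abundance-dependent dropout
(logistic in log10 intensity), ppm-scale mass jitter on the theoretical
masses, a signal-to-noise value per feature, and decoy masses placed at
least 50 ppm away from every library mass so they can never match.

The baseline profile mimics a mature serum glycoprotein: one dominant
bi-antennary di-sialylated glycan holding over half of each site's
signal, the remaining glycans spread over several orders of magnitude.
All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` children, so identical seed + config
gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .digest import PeptideBackbone
from .glycans import GlycanClass, GlycanComposition, classify_glycan
from .library import (
    GlycopeptideLibrary,
    build_library,
    deduplicate_by_total_composition,
    enumerate_glycoforms,
)
from .masses import peptide_mass

DECOY_MIN_PPM = 50.0

#: Typical elution windows (minutes) of the haptoglobin glycopeptide
#: groups on a diphenyl column; unknown groups get a generic window.
GROUP_RT_MIN: dict[str, float] = {"GP1": 17.5, "GP2": 10.5, "GP3": 16.0}


@dataclass
class SimulationConfig:
    """Generative model parameters; defaults are the study conditions.

    Cohort sizes default to 47 controls / 43 cancer.  ``log_sd`` is the
    natural-log standard deviation of per-sample multiplicative noise
    (0.4 corresponds to a ~40% CV, typical of label-free LC–MS
    intensities).  ``planted_effects`` maps entry keys to multiplicative
    fold changes applied in the cancer cohort.  Dropout is a logistic
    function of log10 abundance with the given midpoint and slope
    (``dropout_midpoint=None`` disables dropout).  ``ppm_jitter_sd`` is
    the mass-accuracy jitter in ppm; decoy masses are guaranteed to be
    at least 50 ppm from every library mass.
    """

    n_control: int = 47
    n_cancer: int = 43
    log_sd: float = 0.4
    planted_effects: dict[str, float] = field(default_factory=dict)
    dropout_midpoint: Optional[float] = 2.0
    dropout_slope: float = 0.4
    ppm_jitter_sd: float = 1.0
    snr_log_mean: float = 3.0
    snr_log_sd: float = 0.6
    n_decoys: int = 25
    seed: int = 0
    profile_seed: int = 0
    base_total: float = 1e7
    group_scale: dict[str, float] = field(default_factory=dict)
    dominant_glycan: tuple[int, int, int, int] = (5, 4, 0, 2)
    dominant_fraction: float = 0.55
    baseline_log_sd: float = 1.2

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_cancer < 0 or self.n_control + self.n_cancer == 0:
            raise ValueError("cohort sizes must be non-negative with at least one sample")
        if any(f <= 0 for f in self.planted_effects.values()):
            raise ValueError("planted fold changes must be > 0")
        if self.ppm_jitter_sd < 0:
            raise ValueError("ppm_jitter_sd must be >= 0")


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_baseline_profile(
    library: GlycopeptideLibrary, config: SimulationConfig
) -> pd.Series:
    """Deterministic per-entry baseline abundances for a library.

    Each glycan gets a weight: the dominant glycan (bi-antennary
    di-sialylated by default) takes ``dominant_fraction`` of the pool,
    the rest is spread lognormally.  A one-site entry's weight is its
    glycan's weight; a multi-site entry's weight sums the products of
    glycan weights over its consistent assignments (independent site
    occupancy).  Weights are normalised within each GP group and scaled
    to the group's total intensity.

    The profile is drawn from ``profile_seed``, separate from the cohort
    sampling seed: the baseline glycosylation pattern is a property of
    the biology being emulated, so replicate cohorts (different ``seed``)
    share one profile unless ``profile_seed`` is changed too.
    """
    (rng,) = _rng_children(config.profile_seed, 1)
    glycans = sorted(library.glycan_list)
    w = np.exp(rng.normal(0.0, config.baseline_log_sd, size=len(glycans)))
    weights = {g.as_tuple(): x for g, x in zip(glycans, w)}
    dom = config.dominant_glycan
    if dom in weights:
        rest = sum(v for k, v in weights.items() if k != dom)
        scale = (1.0 - config.dominant_fraction) / rest
        weights = {
            k: (config.dominant_fraction if k == dom else v * scale)
            for k, v in weights.items()
        }
    else:
        total = sum(weights.values())
        weights = {k: v / total for k, v in weights.items()}

    baseline = {}
    for group in library.group_labels():
        entries = library.entries_for_group(group)
        raw = []
        for e in entries:
            raw.append(
                sum(
                    float(np.prod([weights[g.as_tuple()] for g in a]))
                    for a in e.site_assignments
                )
            )
        raw = np.asarray(raw)
        group_total = config.base_total * config.group_scale.get(group, 1.0)
        for e, v in zip(entries, raw / raw.sum() * group_total):
            baseline[e.key] = v
    return pd.Series(baseline, name="baseline")


def _draw_decoys(
    rng: np.random.Generator,
    n: int,
    sorted_masses: np.ndarray,
    lo: float,
    hi: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform decoy masses in [lo, hi], each >= 50 ppm from every library mass."""
    out: list[float] = []
    for _ in range(max_tries):
        if len(out) >= n:
            break
        cand = rng.uniform(lo, hi, size=4 * n)
        i = np.searchsorted(sorted_masses, cand)
        ok = np.ones(len(cand), dtype=bool)
        left = np.clip(i - 1, 0, len(sorted_masses) - 1)
        right = np.clip(i, 0, len(sorted_masses) - 1)
        for nb in (left, right):
            ppm = np.abs(cand - sorted_masses[nb]) / sorted_masses[nb] * 1e6
            ok &= ppm >= DECOY_MIN_PPM
        out.extend(cand[ok][: n - len(out)])
    if len(out) < n:
        raise ValueError(
            "decoy placement impossible: library masses too dense for "
            f"{DECOY_MIN_PPM} ppm exclusion zones"
        )
    return np.asarray(out[:n])


def simulate_cohort(
    library: GlycopeptideLibrary,
    config: SimulationConfig,
    baseline: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate per-sample deconvoluted feature tables for a cohort.

    Returns ``(features, manifest, truth)``: a long-format feature
    table in the canonical CSV dialect (sample_id, neutral_mass,
    rt_min, abundance, snr), the manifest (sample_id, group), and a
    ground-truth record holding the planted effects, the baseline
    profile and the pre-dropout true abundance matrix.
    """
    if not library.entries:
        raise ValueError("library is empty")
    if baseline is None:
        baseline = build_baseline_profile(library, config)
    keys = [e.key for e in library.entries]
    baseline = baseline.loc[keys]
    theo = np.array([e.theoretical_mass for e in library.entries])
    groups_of_entries = [e.group_label for e in library.entries]
    rts = np.array(
        [
            GROUP_RT_MIN.get(g, 8.0 + sum(map(ord, g)) % 7)
            for g in groups_of_entries
        ]
    )
    unknown = set(config.planted_effects) - set(keys)
    if unknown:
        raise ValueError(f"planted effects reference unknown entries: {sorted(unknown)}")
    fold = np.array([config.planted_effects.get(k, 1.0) for k in keys])

    sample_ids = [f"ctrl_{i + 1:03d}" for i in range(config.n_control)] + [
        f"case_{i + 1:03d}" for i in range(config.n_cancer)
    ]
    labels = ["control"] * config.n_control + ["cancer"] * config.n_cancer
    n_samples, n_entries = len(sample_ids), len(keys)

    rng_ab, rng_drop, rng_mass, rng_feat, rng_decoy = _rng_children(config.seed + 1, 5)

    noise = rng_ab.normal(0.0, config.log_sd, size=(n_samples, n_entries))
    abundance = baseline.to_numpy() * np.exp(noise)
    is_cancer = np.array([lab == "cancer" for lab in labels])
    abundance[is_cancer] *= fold

    if config.dropout_midpoint is None:
        p_detect = np.ones_like(abundance)
    else:
        p_detect = expit(
            (np.log10(abundance) - config.dropout_midpoint) / config.dropout_slope
        )
    detected = rng_drop.random(abundance.shape) < p_detect

    jitter = rng_mass.normal(0.0, config.ppm_jitter_sd, size=abundance.shape) * 1e-6
    obs_mass = theo[None, :] * (1.0 + jitter)

    sorted_masses = np.sort(theo)
    dlo, dhi = 0.9 * sorted_masses[0], 1.1 * sorted_masses[-1]

    frames = []
    for si, sid in enumerate(sample_ids):
        idx = np.flatnonzero(detected[si])
        n_true = len(idx)
        decoys = _draw_decoys(rng_decoy, config.n_decoys, sorted_masses, dlo, dhi)
        n_rows = n_true + len(decoys)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "neutral_mass": np.concatenate([obs_mass[si, idx], decoys]),
                    "rt_min": np.concatenate(
                        [
                            rts[idx] + rng_feat.normal(0.0, 0.3, n_true),
                            rng_feat.uniform(5.0, 20.0, len(decoys)),
                        ]
                    ),
                    "abundance": np.concatenate(
                        [
                            abundance[si, idx],
                            rng_feat.lognormal(np.log(1e3), 1.0, len(decoys)),
                        ]
                    ),
                    "snr": rng_feat.lognormal(
                        config.snr_log_mean, config.snr_log_sd, n_rows
                    ),
                }
            )
        )
    features = pd.concat(frames, ignore_index=True)
    manifest = pd.DataFrame({"sample_id": sample_ids, "group": labels})
    truth = {
        "planted_effects": dict(config.planted_effects),
        "baseline": {k: float(v) for k, v in baseline.items()},
        "true_abundance": pd.DataFrame(
            abundance, index=sample_ids, columns=keys
        ),
        "config": asdict(config),
    }
    return features, manifest, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    payload = dict(truth)
    payload["true_abundance"] = truth["true_abundance"].to_dict(orient="index")
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=1)


def make_fixture_library(
    n_glycans: int,
    n_backbones: int = 1,
    sites_per_backbone: int | Sequence[int] = 1,
    seed: int = 0,
) -> GlycopeptideLibrary:
    """A random but valid glycopeptide library for property tests.

    Glycan compositions are unique random draws; each synthetic
    backbone is a tryptic-looking peptide with exactly the requested
    number of sequons planted at known positions.
    """
    if n_glycans <= 0 or n_backbones <= 0:
        raise ValueError("parameters must be positive")
    if isinstance(sites_per_backbone, int):
        sites = [sites_per_backbone] * n_backbones
    else:
        sites = list(sites_per_backbone)
        if len(sites) != n_backbones:
            raise ValueError("sites_per_backbone length must equal n_backbones")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    comps: set[tuple[int, int, int, int]] = set()
    while len(comps) < n_glycans:
        comps.add(
            (
                int(rng.integers(3, 10)),
                int(rng.integers(2, 7)),
                int(rng.integers(0, 3)),
                int(rng.integers(0, 5)),
            )
        )
    glycans = [GlycanComposition(*t) for t in sorted(comps)]

    filler = np.array(list("ADEFGILQVW"))
    entries = []
    pos = 1
    for bi, n_sites in enumerate(sites, start=1):
        body = "".join(rng.choice(filler, size=8 + 4 * n_sites))
        seq = ""
        offs = []
        for s in range(n_sites):
            chunk = body[4 * s : 4 * s + 4]
            offs.append(len(seq))
            seq += "NAS" + chunk
        seq += body[4 * n_sites :] + "K"
        backbone = PeptideBackbone(
            sequence=seq,
            protein_start=pos,
            protein_end=pos + len(seq) - 1,
            missed_cleavages=0,
            sequon_positions=[pos + o for o in offs],
            neutral_mass=peptide_mass(seq),
            group_label=f"GP{bi}",
        )
        pos += len(seq)
        entries.extend(
            deduplicate_by_total_composition(enumerate_glycoforms(backbone, glycans))
        )
    entries.sort(key=lambda e: (e.group_label, e.theoretical_mass))
    return GlycopeptideLibrary(
        entries=entries,
        glycan_list=glycans,
        provenance={"synthetic_fixture": True, "seed": seed},
    )


def default_cancer_scenario(
    library: GlycopeptideLibrary,
    seed: int = 0,
    fold: float = 2.0,
    markers_per_group: Optional[dict[str, int]] = None,
) -> tuple[SimulationConfig, pd.Series]:
    """The default disease scenario: fold increases on top C/H-FS glycoforms.

    Plants a multiplicative ``fold`` (2x by default) on the
    highest-baseline fucosylated-sialylated glycoforms of each GP group
    — 6/8/9 for GP1/GP2/GP3, echoing the relative marker richness of
    the three haptoglobin glycosites (planting on glycoforms below the
    detection floor would make no selection rule recoverable).  Returns
    the ready config and the baseline profile it was derived from.
    """
    if markers_per_group is None:
        markers_per_group = {"GP1": 6, "GP2": 8, "GP3": 9}
    config = SimulationConfig(seed=seed)
    baseline = build_baseline_profile(library, config)
    planted: dict[str, float] = {}
    for group in library.group_labels():
        fs = [
            e
            for e in library.entries_for_group(group)
            if classify_glycan(e.total_composition) is GlycanClass.CH_FS
        ]
        fs.sort(key=lambda e: baseline[e.key], reverse=True)
        k = markers_per_group.get(group, 6)
        for e in fs[:k]:
            planted[e.key] = fold
    config.planted_effects = planted
    return config, baseline


def haptoglobin_library() -> GlycopeptideLibrary:
    """The packaged haptoglobin library (synthetic-stand-in FASTA + default panel)."""
    from .digest import packaged_haptoglobin_fasta
    from .glycans import default_glycans

    return build_library(packaged_haptoglobin_fasta(), default_glycans())
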