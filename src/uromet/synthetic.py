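"""Synthetic urine-metabolomics cohorts with planted marker structure.

The generator emulates the data structure the analysis assumes: a
training cohort enriched for cancer strata and an independent validation
cohort whose composition is close to the enrollment pool; right-skewed
serum PSA that rises with NCCN severity; per-stratum prevalences of the
three binary clinical factors; a large raw peak table (default 1,941
features) in which only a minority of features are reliably detected and
therefore survive the presence filter; and a small set of planted
informative metabolites whose log intensities shift monotonically with
severity — some down in cancer, some up in significant cancer, matching
the directional structure of the reported marker panels.

Peak areas are log-normal per feature; planted effects are additive on
the log scale in units of the feature's log-SD.  Missingness is a point
mass at "not detected" whose probability falls with the sample's latent
intensity, so low-abundance signals drop out first, exercising the
presence filter and the half-minimum imputation downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .strata import ANALYSIS_STRATA, analysis_stratum

__all__ = [
    "CohortConfig",
    "PeakTable",
    "generate_cohort",
    "plant_marker_effects",
    "default_marker_effects",
    "write_fixture",
    "read_fixture",
]

# Table-row stratum counts for the two cohorts (benign, VLR/LR, FIR,
# UIR, HR/VHR, mPC).
_TRAINING_COUNTS = {"benign": 110, "VLR/LR": 74, "FIR": 74, "UIR": 105, "HR/VHR": 202, "mPC": 38}
_VALIDATION_COUNTS = {"benign": 158, "VLR/LR": 26, "FIR": 25, "UIR": 34, "HR/VHR": 66, "mPC": 16}

# Log-normal PSA (ng/mL): location = ln(median), scale; severity-increasing
# so clinical models carry real signal.
_PSA_PARAMS = {
    "benign": (np.log(7.0), 0.45),
    "VLR/LR": (np.log(7.0), 0.30),
    "FIR": (np.log(9.0), 0.40),
    "UIR": (np.log(11.0), 0.45),
    "HR/VHR": (np.log(18.0), 0.70),
    "mPC": (np.log(45.0), 0.90),
}

# (family history, previous negative biopsy, abnormal DRE) prevalence.
_CLINICAL_RATES = {
    "benign": (0.07, 0.30, 0.20),
    "VLR/LR": (0.08, 0.22, 0.24),
    "FIR": (0.09, 0.18, 0.28),
    "UIR": (0.09, 0.15, 0.38),
    "HR/VHR": (0.10, 0.12, 0.50),
    "mPC": (0.10, 0.10, 0.60),
}

# Severity ramp for markers elevated in significant cancer.
_UP_PROFILE = {"benign": 0.0, "VLR/LR": 0.35, "FIR": 0.6, "UIR": 0.8, "HR/VHR": 1.0, "mPC": 1.0}
# Flat suppression in all cancer strata for benign-vs-cancer markers.
_DOWN_PROFILE = {"benign": 0.0, "VLR/LR": -1.0, "FIR": -1.0, "UIR": -1.0, "HR/VHR": -1.0, "mPC": -1.0}

_GLEASON_FIXED = {"VLR": 6, "LR": 6, "FIR": 7, "UIR": 7, "HR": 8}


@dataclass
class CohortConfig:
    """Parameters of the synthetic study.

    ``effect_sizes`` maps feature id -> stratum -> shift in units of
    that feature's log-intensity SD; when None, a default set of
    ``n_informative`` markers is planted on the first feature ids,
    alternating flat "down in cancer" and severity-ramped "up in
    significant cancer" profiles at magnitude ``informative_effect``.
    """

    n_per_group_training: dict = field(default_factory=lambda: dict(_TRAINING_COUNTS))
    n_per_group_validation: dict = field(default_factory=lambda: dict(_VALIDATION_COUNTS))
    n_features: int = 1941
    n_informative: int = 20
    informative_effect: float = 1.25
    effect_sizes: dict | None = None
    missing_rate_base: float = 0.75
    detected_fraction: float = 0.088
    psa_params: dict = field(default_factory=lambda: dict(_PSA_PARAMS))
    clinical_rates: dict = field(default_factory=lambda: dict(_CLINICAL_RATES))
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_per_group_training", "n_per_group_validation"):
            counts = getattr(self, name)
            for g, n in counts.items():
                if g not in ANALYSIS_STRATA:
                    raise ValueError(f"{name}: unknown stratum {g!r}")
                if not (isinstance(n, (int, np.integer)) and n >= 0):
                    raise ValueError(f"{name}[{g!r}] must be a non-negative integer, got {n!r}")
        if self.n_features < 1:
            raise ValueError(f"n_features must be >= 1, got {self.n_features}")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError(
                f"n_informative must be in [0, n_features], got {self.n_informative}"
            )
        if not 0.0 <= self.missing_rate_base < 1.0:
            raise ValueError(f"missing_rate_base must be in [0, 1), got {self.missing_rate_base}")
        if not 0.0 < self.detected_fraction <= 1.0:
            raise ValueError(f"detected_fraction must be in (0, 1], got {self.detected_fraction}")
        for g in ANALYSIS_STRATA:
            if g not in self.psa_params:
                raise ValueError(f"psa_params missing stratum {g!r}")
            if g not in self.clinical_rates:
                raise ValueError(f"clinical_rates missing stratum {g!r}")

    @classmethod
    def tiny(cls, seed: int = 42) -> "CohortConfig":
        """A 10-subject, 12-feature configuration for fixtures and docs."""
        return cls(
            n_per_group_training={"benign": 2, "VLR/LR": 1, "FIR": 1, "UIR": 1, "HR/VHR": 1, "mPC": 1},
            n_per_group_validation={"benign": 1, "VLR/LR": 0, "FIR": 0, "UIR": 1, "HR/VHR": 1, "mPC": 0},
            n_features=12,
            n_informative=2,
            detected_fraction=0.6,
            seed=seed,
        )


@dataclass
class PeakTable:
    """Samples x features raw peak areas with an explicit missing mask.

    ``values`` holds positive peak areas with NaN marking "not
    detected"; rows are indexed by sample id.  ``creatinine`` is the
    per-sample urinary creatinine used for dilution correction.  The
    total peak area is always recomputed from the observed values.
    """

    values: pd.DataFrame
    creatinine: pd.Series

    @property
    def sample_ids(self):
        return self.values.index

    @property
    def feature_ids(self):
        return self.values.columns

    def total_peak_area(self) -> pd.Series:
        return self.values.sum(axis=1, skipna=True)

    def validate(self) -> None:
        obs = self.values.to_numpy()
        if np.any(obs[~np.isnan(obs)] <= 0):
            raise ValueError("observed peak areas must be positive")
        if not self.creatinine.index.equals(self.values.index):
            raise ValueError("creatinine index does not match sample ids")
        if np.any(self.creatinine.to_numpy() <= 0):
            bad = self.creatinine.index[self.creatinine <= 0].tolist()
            raise ValueError(f"non-positive creatinine for samples {bad}")


def default_marker_effects(config: CohortConfig) -> dict:
    """The planted-marker effect map implied by a config.

    Markers sit on the first ``n_informative`` feature ids; odd-indexed
    markers are suppressed in all cancer strata, even-indexed markers
    ramp up with severity.  Shifts are in log-SD units.
    """
    if config.effect_sizes is not None:
        return config.effect_sizes
    effects = {}
    for j in range(config.n_informative):
        fid = f"M{j + 1:04d}"
        profile = _DOWN_PROFILE if j % 2 == 0 else _UP_PROFILE
        effects[fid] = {g: config.informative_effect * s for g, s in profile.items()}
    return effects


def _make_subjects(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for cohort, counts in (
        ("training", config.n_per_group_training),
        ("validation", config.n_per_group_validation),
    ):
        for stratum in ANALYSIS_STRATA:
            n = counts.get(stratum, 0)
            mu, sd = config.psa_params[stratum]
            fh_r, pnb_r, dre_r = config.clinical_rates[stratum]
            for _ in range(n):
                i += 1
                if stratum == "benign":
                    rg, gs = "benign", np.nan
                elif stratum == "VLR/LR":
                    rg = rng.choice(["VLR", "LR"])
                    gs = _GLEASON_FIXED[rg]
                elif stratum == "HR/VHR":
                    rg = rng.choice(["HR", "VHR"])
                    gs = _GLEASON_FIXED.get(rg) or rng.choice([8, 9, 10])
                elif stratum == "mPC":
                    rg = "mPC"
                    gs = rng.choice([7, 8, 9, 10], p=[0.15, 0.35, 0.30, 0.20])
                else:
                    rg = stratum
                    gs = _GLEASON_FIXED[rg]
                rows.append(
                    {
                        "id": f"S{i:04d}",
                        "age": int(np.clip(np.round(rng.normal(69.0, 8.0)), 45, 90)),
                        "psa_ng_ml": float(np.round(np.exp(rng.normal(mu, sd)), 2)),
                        "family_history": int(rng.random() < fh_r),
                        "prior_negative_biopsy": int(rng.random() < pnb_r),
                        "abnormal_dre": int(rng.random() < dre_r),
                        "risk_group": rg,
                        "gleason_sum": float(gs) if np.isfinite(gs) else np.nan,
                        "cohort": cohort,
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, PeakTable]:
    """Generate a (SubjectTable, PeakTable) pair.

    Deterministic for a fixed ``config.seed``: one global seed drives a
    per-purpose seed sequence (subjects, peaks, missingness) so each
    layer regenerates stably.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_subj, rng_peak, rng_miss = (np.random.default_rng(s) for s in ss.spawn(3))

    subjects = _make_subjects(config, rng_subj)
    n = len(subjects)
    F = config.n_features
    feature_ids = [f"M{j + 1:04d}" for j in range(F)]
    strata = np.array([analysis_stratum(g) for g in subjects["risk_group"]])

    # feature-level log-normal parameters and sample loading (dilution)
    mu_f = rng_peak.normal(10.0, 1.5, size=F)
    sigma_f = rng_peak.uniform(0.4, 1.0, size=F)
    ln_load = rng_peak.normal(0.0, 0.35, size=n)
    eps = rng_peak.standard_normal((n, F))

    logv = mu_f[None, :] + ln_load[:, None] + sigma_f[None, :] * eps

    effects = default_marker_effects(config)
    fid_index = {fid: j for j, fid in enumerate(feature_ids)}
    for fid, shifts in effects.items():
        if fid not in fid_index:
            raise ValueError(f"effect_sizes names unknown feature {fid!r}")
        j = fid_index[fid]
        shift = np.array([shifts.get(g, 0.0) for g in strata])
        logv[:, j] += shift * sigma_f[j]

    values = np.exp(logv)

    # detectability: a fixed-size reliable subset (always containing the
    # planted markers) plus a poorly detected remainder
    n_detected = max(int(round(config.detected_fraction * F)), min(config.n_informative, F))
    informative_idx = np.array([fid_index[fid] for fid in effects], dtype=int)
    pool = np.setdiff1d(np.arange(F), informative_idx)
    extra = n_detected - informative_idx.size
    detected = set(informative_idx.tolist())
    if extra > 0 and pool.size:
        detected |= set(rng_miss.choice(pool, size=min(extra, pool.size), replace=False).tolist())
    m_f = np.empty(F)
    for j in range(F):
        if j in detected:
            m_f[j] = rng_miss.uniform(0.02, 0.25)
        else:
            lo = max(config.missing_rate_base - 0.20, 0.01)
            hi = min(config.missing_rate_base + 0.20, 0.98)
            m_f[j] = rng_miss.uniform(lo, hi)
    # lower latent intensity -> more likely missing (detection limit acts
    # on the actual abundance, planted shifts included, not just noise)
    latent = (logv - mu_f[None, :] - ln_load[:, None]) / sigma_f[None, :]
    logit_m = np.log(m_f / (1.0 - m_f))
    p_miss = 1.0 / (1.0 + np.exp(-(logit_m[None, :] - 0.8 * latent)))
    mask = rng_miss.random((n, F)) < p_miss
    values[mask] = np.nan

    creatinine = np.exp(ln_load + rng_miss.normal(0.0, 0.25, size=n))

    peaks = PeakTable(
        values=pd.DataFrame(values, index=subjects["id"].to_numpy(), columns=feature_ids),
        creatinine=pd.Series(creatinine, index=subjects["id"].to_numpy(), name="urine_creatinine"),
    )
    return subjects, peaks


def plant_marker_effects(peaks: PeakTable, subjects: pd.DataFrame, effects: dict) -> PeakTable:
    """Shift named features additively on the log scale, per stratum.

    ``effects`` maps feature id -> {analysis stratum: log shift}; the
    observed values of each named feature are multiplied by exp(shift)
    for samples in that stratum.  Missing cells and all other features
    are untouched.  Unlike the generator config, shifts here are raw log
    units (not SD-standardised).
    """
    missing = [fid for fid in effects if fid not in peaks.values.columns]
    if missing:
        raise ValueError(f"unknown features: {missing}")
    values = peaks.values.copy()
    strata = pd.Series(
        [analysis_stratum(g) for g in subjects["risk_group"]],
        index=subjects["id"].to_numpy(),
    ).reindex(values.index)
    for fid, shifts in effects.items():
        factor = strata.map(lambda g: np.exp(shifts.get(g, 0.0))).to_numpy(dtype=float)
        values[fid] = values[fid].to_numpy() * factor
    return PeakTable(values=values, creatinine=peaks.creatinine.copy())


# ---------------------------------------------------------------------------
# Fixture I/O (CSV contracts)
# ---------------------------------------------------------------------------

_SUBJECT_COLUMNS = [
    "id",
    "age",
    "psa_ng_ml",
    "family_history",
    "prior_negative_biopsy",
    "abnormal_dre",
    "risk_group",
    "gleason_sum",
    "cohort",
]


def write_fixture(subjects: pd.DataFrame, peaks: PeakTable, path) -> dict:
    """Write subjects.csv, peaks.csv and creatinine.csv under ``path``.

    Missing peak cells serialise as empty fields (never zeros); the
    round trip through :func:`read_fixture` reproduces every cell and
    the missing mask exactly.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if not set(peaks.sample_ids) == set(subjects["id"]):
        raise ValueError("subject ids and peak sample ids disagree")
    files = {
        "subjects": path / "subjects.csv",
        "peaks": path / "peaks.csv",
        "creatinine": path / "creatinine.csv",
    }
    subjects[_SUBJECT_COLUMNS].to_csv(files["subjects"], index=False)
    peaks.values.to_csv(files["peaks"], index_label="id")
    peaks.creatinine.rename("urine_creatinine").to_csv(files["creatinine"], index_label="id")
    return {k: str(v) for k, v in files.items()}


def read_fixture(path) -> tuple[pd.DataFrame, PeakTable]:
    """Read tables written by :func:`write_fixture`."""
    path = Path(path)
    subjects = pd.read_csv(path / "subjects.csv", dtype={"risk_group": str, "cohort": str})
    values = pd.read_csv(path / "peaks.csv", index_col="id")
    creat = pd.read_csv(path / "creatinine.csv", index_col="id")["urine_creatinine"]
    return subjects, PeakTable(values=values, creatinine=creat)
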