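"""Peak-table preprocessing: presence filter, normalization, imputation.

Order is fixed: presence filter -> normalization -> imputation -> log
transform.  A feature is retained when it is observed in strictly more
than ``presence_threshold`` (default 60%) of the samples of at least
one risk stratum.  Normalization corrects urine dilution and batch
scale: division by total peak area, by urinary creatinine, or (default)
sequentially by both.  Remaining missing cells are imputed at half the
feature's minimum observed normalized value — the conventional
detection-limit surrogate in metabolomics — before a natural-log
transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import ANALYSIS_STRATA, analysis_stratum
from .synthetic import PeakTable

__all__ = [
    "PreprocessConfig",
    "NormalizedMatrix",
    "presence_filter",
    "normalize_peaks",
    "impute_and_transform",
    "preprocess_pipeline",
]


@dataclass
class PreprocessConfig:
    presence_threshold: float = 0.60
    normalization_mode: str = "sequential"  # creatinine | total_area | sequential
    impute_mode: str = "half_min"  # half_min | none
    log_transform: bool = True

    def validate(self) -> None:
        if not 0.0 < self.presence_threshold <= 1.0:
            raise ValueError(
                f"presence_threshold must be in (0, 1], got {self.presence_threshold}"
            )
        if self.normalization_mode not in ("creatinine", "total_area", "sequential"):
            raise ValueError(f"unknown normalization_mode {self.normalization_mode!r}")
        if self.impute_mode not in ("half_min", "none"):
            raise ValueError(f"unknown impute_mode {self.impute_mode!r}")


@dataclass
class NormalizedMatrix:
    """Samples x retained features with a provenance trail of the steps
    applied (name + parameters + feature counts)."""

    data: pd.DataFrame
    provenance: list = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


def presence_filter(peaks: PeakTable, subjects: pd.DataFrame, threshold: float = 0.60) -> list:
    """Feature ids observed in > ``threshold`` of samples of >= 1 stratum.

    The boundary is strict: a feature observed in exactly the threshold
    fraction of every stratum is dropped.
    """
    if len(subjects) == 0:
        raise ValueError("empty subject table")
    if subjects["risk_group"].isna().any():
        bad = subjects.loc[subjects["risk_group"].isna(), "id"].tolist()
        raise ValueError(f"samples without a risk group: {bad}")
    strata = pd.Series(
        [analysis_stratum(g) for g in subjects["risk_group"]],
        index=subjects["id"].to_numpy(),
    ).reindex(peaks.values.index)
    if strata.isna().any():
        bad = list(peaks.values.index[strata.isna()])
        raise ValueError(f"peak samples missing from subject table: {bad}")
    observed = peaks.values.notna()
    keep = np.zeros(peaks.values.shape[1], dtype=bool)
    for g in ANALYSIS_STRATA:
        members = strata == g
        if members.sum() == 0:
            continue
        frac = observed.loc[members.to_numpy()].mean(axis=0).to_numpy()
        keep |= frac > threshold
    return [fid for fid, k in zip(peaks.values.columns, keep) if k]


def normalize_peaks(peaks: PeakTable, mode: str = "sequential") -> NormalizedMatrix:
    """Dilution/batch normalization; missing cells stay missing.

    ``creatinine``: value / urinary creatinine.  ``total_area``: value /
    the sample's total observed peak area.  ``sequential``: both, total
    area first.
    """
    total = peaks.total_peak_area()
    creat = peaks.creatinine
    if (total <= 0).any():
        bad = list(total.index[total <= 0])
        raise ValueError(f"non-positive total peak area for samples {bad}")
    if (creat <= 0).any():
        bad = list(creat.index[creat <= 0])
        raise ValueError(f"non-positive creatinine for samples {bad}")
    data = peaks.values.copy()
    if mode == "creatinine":
        data = data.div(creat, axis=0)
    elif mode == "total_area":
        data = data.div(total, axis=0)
    elif mode == "sequential":
        data = data.div(total, axis=0).div(creat, axis=0)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    nm = NormalizedMatrix(data=data)
    nm.record("normalize", mode=mode, n_samples=data.shape[0], n_features=data.shape[1])
    return nm


def impute_and_transform(matrix: NormalizedMatrix, config: PreprocessConfig) -> NormalizedMatrix:
    """Half-minimum imputation followed by natural log (both optional)."""
    data = matrix.data.copy()
    if config.impute_mode == "half_min":
        n_obs = data.notna().sum(axis=0)
        if (n_obs == 0).any():
            bad = list(data.columns[n_obs == 0])
            raise RuntimeError(
                f"features with no observed values reached imputation: {bad}"
            )
        fill = data.min(axis=0, skipna=True) / 2.0
        data = data.fillna(fill)
    elif data.isna().any().any():
        bad = list(data.columns[data.isna().any()])
        raise ValueError(f"impute_mode='none' but missing values remain in {bad}")
    if config.log_transform:
        data = np.log(data)
    if not np.isfinite(data.to_numpy()).all():
        raise RuntimeError("non-finite values after imputation/log transform")
    out = NormalizedMatrix(data=data, provenance=list(matrix.provenance))
    out.record("impute", mode=config.impute_mode)
    out.record("log_transform", applied=bool(config.log_transform))
    return out


def preprocess_pipeline(
    peaks: PeakTable, subjects: pd.DataFrame, config: PreprocessConfig | None = None
) -> NormalizedMatrix:
    """presence filter -> normalize -> impute -> log, with provenance."""
    config = config or PreprocessConfig()
    config.validate()
    retained = presence_filter(peaks, subjects, config.presence_threshold)
    if not retained:
        raise ValueError("presence filter removed every feature")
    filtered = PeakTable(values=peaks.values[retained], creatinine=peaks.creatinine)
    nm = normalize_peaks(filtered, config.normalization_mode)
    nm.provenance.insert(
        0,
        {
            "step": "presence_filter",
            "threshold": config.presence_threshold,
            "features_in": int(peaks.values.shape[1]),
            "features_out": len(retained),
        },
    )
    return impute_and_transform(nm, config)
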