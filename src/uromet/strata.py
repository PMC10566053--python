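"""Shared vocabulary for NCCN risk strata and cohort labels.

Subjects carry one of eight clinical risk-group labels (benign plus the
seven NCCN prostate-cancer strata).  All stratum-level computation —
presence filtering, synthetic generation, enrollment reweighting — works
on six *analysis strata* that merge VLR with LR and HR with VHR, the row
structure used throughout the study's demographic tables.
"""

from __future__ import annotations

RISK_GROUPS = ("benign", "VLR", "LR", "FIR", "UIR", "HR", "VHR", "mPC")

#: Analysis strata, ordered by clinical severity.
ANALYSIS_STRATA = ("benign", "VLR/LR", "FIR", "UIR", "HR/VHR", "mPC")

_TO_ANALYSIS = {
    "benign": "benign",
    "VLR": "VLR/LR",
    "LR": "VLR/LR",
    "FIR": "FIR",
    "UIR": "UIR",
    "HR": "HR/VHR",
    "VHR": "HR/VHR",
    "mPC": "mPC",
}

#: Risk-group composition of the full enrollment pool, used to reweight
#: biopsy-avoidance figures back to the at-risk population.
ENROLLMENT_WEIGHTS = {
    "benign": 0.520,
    "VLR/LR": 0.087,
    "FIR": 0.074,
    "UIR": 0.110,
    "HR/VHR": 0.183,
    "mPC": 0.026,
}

COHORTS = ("training", "validation")

CLINICAL_FACTORS = (
    "age",
    "psa_ng_ml",
    "family_history",
    "prior_negative_biopsy",
    "abnormal_dre",
)


def analysis_stratum(risk_group: str) -> str:
    """Map a risk-group label onto its merged analysis stratum."""
    try:
        return _TO_ANALYSIS[risk_group]
    except KeyError:
        raise ValueError(f"unknown risk group: {risk_group!r}") from None


def analysis_strata_of(risk_groups) -> "list[str]":
    """Vectorised :func:`analysis_stratum` over an iterable of labels."""
    return [analysis_stratum(g) for g in risk_groups]
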