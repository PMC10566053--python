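"""Decision curve analysis: net benefit and interventions avoided.

At threshold probability ``p_t`` a subject is biopsied when the model
probability is >= ``p_t``.  Net benefit trades true against false
positives at the odds implied by the threshold:

    NB = TP/n - (FP/n) * p_t / (1 - p_t)

"Biopsy for all" has NB = pi - (1 - pi) p_t/(1 - p_t) at prevalence pi
(crossing zero at p_t = pi); "biopsy for none" is identically zero.
The number of biopsies potentially avoided per 1,000 at-risk subjects
by using the model instead of biopsying everyone is
``1000 * (NB_model - NB_all) * (1 - p_t) / p_t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DcaCurve",
    "net_benefit",
    "net_benefit_treat_all",
    "dca_curves",
    "interventions_avoided_per_1000",
    "default_grid",
]


@dataclass
class DcaCurve:
    grid: np.ndarray
    nb_model: np.ndarray
    nb_all: np.ndarray
    nb_none: np.ndarray
    prevalence: float
    n: int

    def avoided_per_1000(self) -> np.ndarray:
        return interventions_avoided_per_1000(self.nb_model, self.nb_all, self.grid)


def default_grid() -> np.ndarray:
    """Threshold probabilities 0.01 .. 0.50, step 0.01."""
    return np.round(np.arange(1, 51) * 0.01, 2)


def _check_pt(p_t) -> np.ndarray:
    p_t = np.asarray(p_t, dtype=float)
    if np.any(p_t <= 0.0) or np.any(p_t >= 1.0):
        raise ValueError("threshold probability p_t must lie in (0, 1)")
    return p_t


def net_benefit(probabilities, labels, p_t) -> float | np.ndarray:
    """Net benefit of biopsying at probability >= p_t (scalar or grid)."""
    p_t = _check_pt(p_t)
    prob = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.any(prob < 0.0) or np.any(prob > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    n = prob.size
    scalar = p_t.ndim == 0
    pts = np.atleast_1d(p_t)
    treat = prob[None, :] >= pts[:, None]
    tp = (treat & (labels == 1)[None, :]).sum(axis=1)
    fp = (treat & (labels == 0)[None, :]).sum(axis=1)
    nb = tp / n - (fp / n) * pts / (1.0 - pts)
    return float(nb[0]) if scalar else nb


def net_benefit_treat_all(prevalence: float, p_t):
    """Closed form for the biopsy-for-all reference strategy."""
    p_t = _check_pt(p_t)
    return prevalence - (1.0 - prevalence) * p_t / (1.0 - p_t)


def dca_curves(probabilities, labels, grid=None) -> DcaCurve:
    """Model / biopsy-for-all / biopsy-for-none curves over a grid."""
    grid = default_grid() if grid is None else _check_pt(np.asarray(grid, dtype=float))
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within (0, 1)")
    labels = np.asarray(labels, dtype=int)
    prevalence = float(labels.mean())
    return DcaCurve(
        grid=grid,
        nb_model=np.asarray(net_benefit(probabilities, labels, grid)),
        nb_all=np.asarray(net_benefit_treat_all(prevalence, grid)),
        nb_none=np.zeros_like(grid),
        prevalence=prevalence,
        n=int(labels.size),
    )


def interventions_avoided_per_1000(nb_model, nb_all, p_t):
    """Biopsies avoided per 1,000 at-risk subjects vs biopsy-for-all."""
    p_t = _check_pt(p_t)
    return 1000.0 * (np.asarray(nb_model) - np.asarray(nb_all)) * (1.0 - p_t) / p_t
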