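"""Ensemble marker selection over resampled logistic models.

The selection engine repeats stratified K-fold resampling (default
K = 5, 20 rounds -> 100 fold-models).  Within each fold-training set a
three-stage screen runs: (1) univariate logistic regression drops
features with Wald p > 0.1; (2) greedy backward elimination minimises
the AIC; (3) the joint multivariable model iteratively drops the worst
feature with p > 0.1.  Each fold-model's surviving set is scored by AUC
on the held-out fold.  Features are then ranked by how often they recur
among the best 75% of fold-models, and the final panel size is the
nadir of the AIC over nested models built from the top of that ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc
from .logistic import fit_logistic

__all__ = [
    "SelectionConfig",
    "CandidateModel",
    "RankedPanel",
    "univariate_screen",
    "aic_backward_eliminate",
    "multivariable_prune",
    "run_selection_ensemble",
    "rank_by_recurrence",
    "select_panel_size_aic_nadir",
    "select_markers",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    k_folds: int = 5
    rounds: int = 20
    univariate_alpha: float = 0.1
    multivariable_alpha: float = 0.1
    top_model_fraction: float = 0.75
    top_n_recurring: int = 30
    max_panel: int | None = None  # defaults to top_n_recurring
    seed: int = 0

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.rounds < 1:
            raise ValueError(f"rounds must be >= 1, got {self.rounds}")
        for name in ("univariate_alpha", "multivariable_alpha"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {a}")
        if not 0.0 < self.top_model_fraction <= 1.0:
            raise ValueError(
                f"top_model_fraction must be in (0, 1], got {self.top_model_fraction}"
            )
        if self.top_n_recurring < 1:
            raise ValueError(f"top_n_recurring must be >= 1, got {self.top_n_recurring}")

    @property
    def effective_max_panel(self) -> int:
        return self.max_panel if self.max_panel is not None else self.top_n_recurring


@dataclass
class CandidateModel:
    """Outcome of the three-stage screen on one fold-training set."""

    round_index: int
    fold_index: int
    features: tuple
    test_auc: float
    train_aic: float
    test_ids: tuple = ()
    univariate_p: dict = field(default_factory=dict)


@dataclass
class RankedPanel:
    """Recurrence-ranked features with the AIC-nadir panel size."""

    ranked_features: tuple
    recurrence_counts: dict
    panel_size: int
    aic_sequence: tuple

    @property
    def panel(self) -> tuple:
        return self.ranked_features[: self.panel_size]


def univariate_screen(X: pd.DataFrame, y, alpha: float = 0.1, return_pvalues: bool = False):
    """Features whose single-predictor logistic slope has Wald p <= alpha.

    Constant features are excluded (slope undefined) with a log note.
    """
    y = np.asarray(y)
    kept, pvals = [], {}
    for fid in X.columns:
        x = X[fid].to_numpy(dtype=float)
        if np.ptp(x) == 0.0:
            logger.info("univariate screen: %s is constant, excluded", fid)
            continue
        fit = fit_logistic(x[:, None], y, predictor_ids=(fid,))
        p = float(fit.pvalues[1])
        pvals[fid] = 0.0 if fit.penalty > 0 else p
        if fit.penalty > 0 or np.isnan(p) or p <= alpha:
            # a ridge-rescued fit signals (quasi-)separation — maximal
            # signal whose Wald p is meaningless, so the feature is kept
            kept.append(fid)
    if return_pvalues:
        return kept, pvals
    return kept


def _aic_of(X: np.ndarray, y: np.ndarray, cols: list, start=None) -> tuple[float, np.ndarray]:
    if not cols:
        # intercept-only closed form
        p = y.mean()
        if p in (0.0, 1.0):
            return 2.0, None
        llf = y.size * (p * math.log(p) + (1 - p) * math.log(1 - p))
        return 2.0 - 2.0 * llf, None
    fit = fit_logistic(X[:, cols], y, start=start, compute_se=False)
    return fit.aic, fit.params


def aic_backward_eliminate(X: pd.DataFrame, y, features=None) -> list:
    """Greedy backward elimination minimising AIC.

    At each step the single feature whose removal lowers the AIC the
    most is dropped; the search stops when no removal lowers it.  The
    empty (intercept-only) model is a legal endpoint.
    """
    features = list(features if features is not None else X.columns)
    y = np.asarray(y, dtype=float)
    Xmat = X[features].to_numpy(dtype=float)
    current = list(range(len(features)))
    cur_aic, cur_params = _aic_of(Xmat, y, current)
    while current:
        best_aic, best_j = cur_aic, None
        for pos, j in enumerate(current):
            cand = current[:pos] + current[pos + 1 :]
            start = None
            if cur_params is not None:
                start = np.delete(cur_params, pos + 1)  # +1 skips intercept
            aic, _ = _aic_of(Xmat, y, cand, start=start)
            if aic < best_aic - 1e-10:
                best_aic, best_j = aic, pos
        if best_j is None:
            break
        del current[best_j]
        cur_aic, cur_params = _aic_of(Xmat, y, current)
    return [features[j] for j in current]


def multivariable_prune(X: pd.DataFrame, y, features, alpha: float = 0.1) -> list:
    """Iteratively drop the worst Wald p > alpha from the joint model."""
    features = list(features)
    y = np.asarray(y, dtype=float)
    while features:
        fit = fit_logistic(X[features], y)
        p = fit.pvalues[1:]
        p = np.where(np.isnan(p), 0.0, p)  # rescued separation = strong signal
        worst = int(np.argmax(p))
        if p[worst] <= alpha:
            break
        del features[worst]
    return features


def _screen_stages(X: pd.DataFrame, y, config: SelectionConfig):
    kept, pvals = univariate_screen(X, y, config.univariate_alpha, return_pvalues=True)
    cap = max(len(y) // 10, 2)
    if len(kept) > cap:
        logger.info("pre-truncating %d screened features to %d by univariate p", len(kept), cap)
        kept = sorted(kept, key=lambda f: (pvals.get(f, 0.0), f))[:cap]
    kept = aic_backward_eliminate(X, y, kept)
    kept = multivariable_prune(X, y, kept, config.multivariable_alpha)
    return kept, pvals


def run_selection_ensemble(X: pd.DataFrame, y, config: SelectionConfig) -> list:
    """The rounds x K-fold ensemble of screened fold-models.

    Folds are stratified by outcome and reshuffled each round; every
    subject appears in exactly one testing fold per round.  Returns
    exactly ``rounds * k_folds`` :class:`CandidateModel`s, reproducible
    from ``config.seed``.
    """
    config.validate()
    y = np.asarray(y, dtype=int)
    if min((y == 0).sum(), (y == 1).sum()) < config.k_folds:
        raise ValueError("each outcome class needs at least k_folds members")
    round_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   np.random.SeedSequence(config.seed).spawn(config.rounds)]
    models = []
    for r in range(config.rounds):
        skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True, random_state=round_seeds[r])
        for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            X_tr, y_tr = X.iloc[train_idx], y[train_idx]
            X_te, y_te = X.iloc[test_idx], y[test_idx]
            feats, pvals = _screen_stages(X_tr, y_tr, config)
            if feats:
                fit = fit_logistic(X_tr[feats], y_tr)
                scores = fit.params[0] + X_te[feats].to_numpy(dtype=float) @ fit.params[1:]
                auc = roc_auc(scores, y_te).auc
                aic = fit.aic
            else:
                auc, aic = 0.5, _aic_of(np.empty((len(y_tr), 0)), y_tr.astype(float), [])[0]
            models.append(
                CandidateModel(
                    round_index=r,
                    fold_index=f,
                    features=tuple(feats),
                    test_auc=float(auc),
                    train_aic=float(aic),
                    test_ids=tuple(X.index[test_idx]),
                    univariate_p={fid: pvals[fid] for fid in feats if fid in pvals},
                )
            )
    assert len(models) == config.rounds * config.k_folds
    return models


def rank_by_recurrence(models: list, config: SelectionConfig, rank_by: str = "test_auc"):
    """Order features by recurrence among the best fold-models.

    The best ``ceil(top_model_fraction * M)`` models (by held-out AUC,
    or training AIC when ``rank_by='train_aic'``) vote with their
    retained sets.  Ties in recurrence break by mean univariate p
    (ascending) across the voting models, then lexicographic id.
    Returns (ordered feature ids, recurrence counts).
    """
    if not models:
        raise ValueError("no candidate models")
    m_used = math.ceil(config.top_model_fraction * len(models))
    if rank_by == "test_auc":
        order = sorted(models, key=lambda m: -m.test_auc)
    elif rank_by == "train_aic":
        order = sorted(models, key=lambda m: m.train_aic)
    else:
        raise ValueError(f"unknown rank_by {rank_by!r}")
    used = order[:m_used]
    counts: dict = {}
    psums: dict = {}
    for m in used:
        for fid in m.features:
            counts[fid] = counts.get(fid, 0) + 1
            if fid in m.univariate_p:
                psums.setdefault(fid, []).append(m.univariate_p[fid])
    mean_p = {fid: float(np.mean(v)) for fid, v in psums.items()}
    ranked = sorted(counts, key=lambda f: (-counts[f], mean_p.get(f, 1.0), f))
    if len(ranked) < config.top_n_recurring:
        logger.info(
            "only %d distinct features recurred (requested top %d)",
            len(ranked), config.top_n_recurring,
        )
    return ranked[: config.top_n_recurring], counts


def select_panel_size_aic_nadir(
    X: pd.DataFrame, y, ranked, max_panel: int | None = None,
    recurrence_counts: dict | None = None,
) -> RankedPanel:
    """Size the final panel at the nadir of the cumulative AIC.

    Nested joint logistic models on the top-1, top-2, ... ranked
    features are fit on the full training cohort; the panel size is the
    argmin of their AIC (ties -> smaller size).
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("ranked feature list is empty")
    max_panel = min(max_panel or len(ranked), len(ranked))
    y = np.asarray(y, dtype=float)
    aics = []
    for k in range(1, max_panel + 1):
        fit = fit_logistic(X[ranked[:k]], y)
        aics.append(float(fit.aic))
    size = int(np.argmin(aics)) + 1  # first minimum = smallest size on ties
    return RankedPanel(
        ranked_features=tuple(ranked),
        recurrence_counts=dict(recurrence_counts or {}),
        panel_size=size,
        aic_sequence=tuple(aics),
    )


def select_markers(X: pd.DataFrame, y, config: SelectionConfig):
    """Ensemble -> recurrence ranking -> AIC-nadir sizing.

    Returns (RankedPanel, list of CandidateModels).
    """
    models = run_selection_ensemble(X, y, config)
    ranked, counts = rank_by_recurrence(models, config)
    panel = select_panel_size_aic_nadir(
        X, y, ranked, config.effective_max_panel, recurrence_counts=counts
    )
    return panel, models
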