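"""Replicate-based evaluation and TSS-filtered consensus ensembles.

Each niche method is fit on ``n_replicates`` stratified train/test splits
(default 10 replicates at 75/25). Every (method, replicate) member is scored
on its held-out rows with the True Skill Statistic — sensitivity +
specificity - 1 at the TSS-maximizing cutoff — and the ROC AUC. Members with
test TSS at or above the filter (default 0.7) are retained, refit on the
full table, projected over the climate grid, and averaged pixel-wise into
the arithmetic-mean consensus suitability map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateGrid
from .niche import FittedNicheModel, NicheMethodSpec, fit_method, project

logger = logging.getLogger(__name__)

__all__ = [
    "EvaluationRecord",
    "EnsembleResult",
    "EmptyEnsembleError",
    "split_replicates",
    "tss",
    "best_tss",
    "roc_auc",
    "build_ensemble",
]

EVALUATION_COLUMNS = ("method", "replicate", "tss", "roc_auc", "best_threshold", "n_train", "n_test")


class EmptyEnsembleError(RuntimeError):
    """No member passed the TSS filter; carries the full evaluation table."""

    def __init__(self, tss_threshold: float, evaluation_table: pd.DataFrame):
        super().__init__(
            f"no (method, replicate) member reached TSS >= {tss_threshold}; "
            f"best was {evaluation_table['tss'].max():.3f}"
        )
        self.evaluation_table = evaluation_table


@dataclass(frozen=True)
class EvaluationRecord:
    method: str
    replicate: int
    tss: float
    roc_auc: float
    best_threshold: float
    n_train: int
    n_test: int


@dataclass
class EnsembleResult:
    """TSS-filtered arithmetic-mean consensus for one ecosystem."""

    ecosystem: str
    members: list[tuple[str, int]]
    consensus: np.ndarray
    tss_threshold: float
    evaluation_table: pd.DataFrame
    member_projections: dict[tuple[str, int], np.ndarray] = field(default_factory=dict)
    member_models: dict[tuple[str, int], FittedNicheModel] = field(default_factory=dict)


def split_replicates(
    table: pd.DataFrame,
    ecosystem: str,
    n_replicates: int = 10,
    train_frac: float = 0.75,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent stratified train/test splits.

    Stratification is by the ecosystem's presence flag so both classes
    appear in every partition; the train set size is exactly
    ``round(train_frac * n)`` with per-class counts within one row of
    proportionality. Deterministic per seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    y = table[f"present_{ecosystem}"].to_numpy(dtype=int)
    n = len(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_train = int(round(train_frac * n))
    n_pos_train = int(round(train_frac * pos.size))
    n_neg_train = n_train - n_pos_train
    if min(n_pos_train, n_neg_train) < 1 or n_pos_train >= pos.size or n_neg_train >= neg.size:
        raise ValueError(
            f"cannot stratify: {pos.size} presences / {neg.size} absences at train_frac {train_frac}"
        )
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_replicates):
        p = rng.permutation(pos)
        a = rng.permutation(neg)
        train = np.sort(np.concatenate([p[:n_pos_train], a[:n_neg_train]]))
        test = np.sort(np.concatenate([p[n_pos_train:], a[n_neg_train:]]))
        splits.append((train, test))
    return splits


def _confusion(labels: np.ndarray, scores: np.ndarray, threshold: float) -> tuple[int, int, int, int]:
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    return tp, fn, tn, fp


def tss(labels, scores, threshold: float) -> float:
    """True Skill Statistic at a cutoff: sensitivity + specificity - 1.

    Scores at or above ``threshold`` predict presence. Requires both classes.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("TSS is undefined with a single class in labels")
    tp, fn, tn, fp = _confusion(labels, scores, threshold)
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def best_tss(labels, scores) -> tuple[float, float]:
    """TSS-maximizing cutoff and its TSS.

    Scans the midpoints of adjacent sorted unique scores plus {0, 1};
    returns the smallest maximizing threshold. Equivalent to (and tested
    against) a dense brute-force threshold grid.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("TSS is undefined with a single class in labels")
    uniq = np.unique(scores)
    candidates = np.concatenate([[0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]]) if uniq.size > 1 else np.array([0.0, 1.0])
    candidates = np.unique(candidates)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    # vectorized confusion over candidates
    pred = scores[None, :] >= candidates[:, None]
    tp = (pred & (labels == 1)).sum(axis=1)
    tn = (~pred & (labels == 0)).sum(axis=1)
    values = tp / n_pos + tn / n_neg - 1.0
    k = int(np.argmax(values))  # first max = smallest candidate on ties
    return float(candidates[k]), float(values[k])


def roc_auc(labels, scores) -> float:
    """Rank-based ROC AUC (Mann-Whitney statistic), ties counting half."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC is undefined with a single class in labels")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def build_ensemble(
    table: pd.DataFrame,
    climate: ClimateGrid,
    ecosystem: str,
    methods: list[NicheMethodSpec],
    n_replicates: int = 10,
    train_frac: float = 0.75,
    tss_threshold: float = 0.7,
    seed: int = 0,
    refit_full: bool = True,
) -> EnsembleResult:
    """Fit, evaluate, filter, and average into a consensus suitability map.

    Every (method, replicate) pair is fit on its train split and evaluated
    on its held-out rows; members with test TSS >= ``tss_threshold`` are
    retained. By default retained members are refit on the full table before
    projection (``refit_full=False`` projects the split fits instead). The
    consensus is the pixel-wise arithmetic mean of the member projections.
    The full evaluation table is always produced; if no member passes the
    filter an :class:`EmptyEnsembleError` carrying it is raised.
    """
    if not methods:
        raise ValueError("at least one niche method is required")
    splits = split_replicates(table, ecosystem, n_replicates, train_frac, seed)
    records: list[EvaluationRecord] = []
    split_models: dict[tuple[str, int], FittedNicheModel] = {}
    for spec in methods:
        for r, (train, test) in enumerate(splits):
            model = fit_method(spec, table.iloc[train], ecosystem)
            scores = model.predict(table.iloc[test])
            labels = table.iloc[test][f"present_{ecosystem}"].to_numpy(dtype=int)
            thr, t = best_tss(labels, scores)
            records.append(
                EvaluationRecord(
                    method=spec.name,
                    replicate=r,
                    tss=t,
                    roc_auc=roc_auc(labels, scores),
                    best_threshold=thr,
                    n_train=len(train),
                    n_test=len(test),
                )
            )
            split_models[(spec.name, r)] = model
    evaluation_table = pd.DataFrame([r.__dict__ for r in records], columns=list(EVALUATION_COLUMNS))
    passing = [(rec.method, rec.replicate) for rec in records if rec.tss >= tss_threshold]
    if not passing:
        raise EmptyEnsembleError(tss_threshold, evaluation_table)

    spec_by_name = {s.name: s for s in methods}
    full_fits: dict[str, FittedNicheModel] = {}
    projections: dict[tuple[str, int], np.ndarray] = {}
    models: dict[tuple[str, int], FittedNicheModel] = {}
    full_proj: dict[str, np.ndarray] = {}
    for method, r in passing:
        if refit_full:
            if method not in full_fits:
                full_fits[method] = fit_method(spec_by_name[method], table, ecosystem)
                full_proj[method] = project(full_fits[method], climate)
            models[(method, r)] = full_fits[method]
            projections[(method, r)] = full_proj[method]
        else:
            models[(method, r)] = split_models[(method, r)]
            projections[(method, r)] = project(split_models[(method, r)], climate)
    consensus = np.mean(np.stack([projections[m] for m in passing]), axis=0)
    logger.info(
        "%s ensemble: %d/%d members passed TSS >= %.2f",
        ecosystem,
        len(passing),
        len(records),
        tss_threshold,
    )
    return EnsembleResult(
        ecosystem=ecosystem,
        members=passing,
        consensus=consensus,
        tss_threshold=tss_threshold,
        evaluation_table=evaluation_table,
        member_projections=projections,
        member_models=models,
    )
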