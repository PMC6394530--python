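"""Virtual-screening benchmark metrics and the cross-validation protocol.

A druglikeness scorer ranks a labeled pool of actives and inactives; its
screening power is summarized by the ROC-AUC and by early enrichment
factors EF(x%) = n_actives_in_top_x% / (N_actives * x%). Model fitting uses
actives only; inactives appear solely in evaluation rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .errors import MetricError, ModelError
from .properties import PROPERTY_NAMES, CompoundRecord, PropertyVector, property_matrix
from .scoring import QEXModel

__all__ = [
    "DEFAULT_EF_CUTOFFS", "ScreeningRanking", "EnrichmentReport", "CVResult",
    "ro5_pass_count", "roc_auc", "enrichment_factor", "evaluate_ranking",
    "cross_validate", "evaluate_fixed_model", "qex_scorer_factory",
]

#: EF cutoffs (in percent) reported by default.
DEFAULT_EF_CUTOFFS = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)


def ro5_pass_count(props: PropertyVector) -> int:
    """Number of Lipinski rule-of-five criteria satisfied (0-4).

    HBA <= 5, HBD <= 5, MW < 500, logP < 5 (the Ghose-Crippen ALogP is used
    for the logP criterion). The count serves as a five-level ranking score.
    """
    return (
        int(props.hba <= 5) + int(props.hbd <= 5)
        + int(props.mw < 500) + int(props.alogp < 5)
    )


@dataclass
class ScreeningRanking:
    """Scored, labeled compound list from which AUC and EF are computed."""

    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray  # boolean, True = active
    provenance: str = ""

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=bool)
        if not (len(self.ids) == self.scores.size == self.labels.size):
            raise MetricError("ids, scores and labels must have equal length")
        if not np.all(np.isfinite(self.scores)):
            raise MetricError("scores must be finite")

    @property
    def n_actives(self) -> int:
        return int(self.labels.sum())

    @property
    def n_inactives(self) -> int:
        return int((~self.labels).sum())

    def _require_both_classes(self):
        if self.n_actives == 0 or self.n_inactives == 0:
            raise MetricError(
                f"need both classes: {self.n_actives} actives, "
                f"{self.n_inactives} inactives"
            )

    def order(self, tie_seed: Optional[int] = None) -> np.ndarray:
        """Indices sorted by score descending; ties keep input order unless
        ``tie_seed`` is given, in which case they are shuffled reproducibly."""
        if tie_seed is None:
            return np.argsort(-self.scores, kind="stable")
        rng = np.random.default_rng(tie_seed)
        jitter = rng.permutation(self.scores.size)
        return np.lexsort((jitter, -self.scores))


def roc_auc(ranking: ScreeningRanking) -> float:
    """Area under the ROC curve, Mann-Whitney tie convention (ties count 1/2)."""
    ranking._require_both_classes()
    return float(roc_auc_score(ranking.labels, ranking.scores))


def enrichment_factor(ranking: ScreeningRanking, x_pct: float,
                      ties: str = "fractional",
                      tie_seed: Optional[int] = None) -> float:
    """EF(x%): actives found in the top ceil(x% * total), over N_actives * x%.

    The cutoff set always contains at least one compound for x% > 0.
    Compounds tied at the cutoff-boundary score are handled per ``ties``:

    - ``"fractional"`` (default): boundary slots count actives fractionally,
      equal to the expectation over random tie orderings. Deterministic and
      invariant to input order; an uninformative constant scorer gets EF ~ 1.
    - ``"stable"``: score-descending sort keeping input order among ties
      (metrics then depend on the ordering of tied inputs).
    - a ``tie_seed`` overrides both with one seeded random tie shuffle, for
      sensitivity checks.
    """
    ranking._require_both_classes()
    if not 0 < x_pct <= 100:
        raise MetricError(f"cutoff must be in (0, 100] percent, got {x_pct}")
    total = len(ranking.ids)
    top_n = int(np.ceil(x_pct / 100.0 * total))
    if top_n == 0:
        raise MetricError(f"EF({x_pct}%) cutoff selects no compounds (n={total})")

    if tie_seed is not None or ties == "stable":
        order = ranking.order(tie_seed=tie_seed)
        n_found: float = float(ranking.labels[order[:top_n]].sum())
    elif ties == "fractional":
        scores, labels = ranking.scores, ranking.labels
        cutoff_score = np.sort(scores)[::-1][top_n - 1]
        above = scores > cutoff_score
        at = scores == cutoff_score
        slots = top_n - int(above.sum())
        tied_total = int(at.sum())
        tied_actives = int(labels[at].sum())
        n_found = float(labels[above].sum())
        if slots > 0 and tied_total > 0:
            n_found += slots * tied_actives / tied_total
    else:
        raise MetricError(f"unknown tie policy {ties!r}")
    return n_found / (ranking.n_actives * x_pct / 100.0)


@dataclass
class EnrichmentReport:
    """AUC plus enrichment factors at the standard cutoffs."""

    auc: float
    ef: dict[float, float]
    provenance: str = ""

    def to_dict(self) -> dict:
        out = {"auc": self.auc}
        out.update({f"ef_{g:g}pct": v for g, v in self.ef.items()})
        return out


def evaluate_ranking(ranking: ScreeningRanking,
                     cutoffs: Sequence[float] = DEFAULT_EF_CUTOFFS,
                     tie_seed: Optional[int] = None) -> EnrichmentReport:
    """Full benchmark report (AUC + EF at every cutoff) for one ranking."""
    return EnrichmentReport(
        auc=roc_auc(ranking),
        ef={float(c): enrichment_factor(ranking, c, tie_seed=tie_seed)
            for c in cutoffs},
        provenance=ranking.provenance,
    )


@dataclass
class CVResult:
    """Per-fold and mean enrichment reports from k-fold cross-validation."""

    folds: list[EnrichmentReport]
    mean: EnrichmentReport
    k: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() | {"fold": i} for i, r in enumerate(self.folds)]
        rows.append(self.mean.to_dict() | {"fold": "mean"})
        return pd.DataFrame(rows).set_index("fold")


def _mean_report(reports: Sequence[EnrichmentReport], provenance: str) -> EnrichmentReport:
    cutoffs = reports[0].ef.keys()
    return EnrichmentReport(
        auc=float(np.mean([r.auc for r in reports])),
        ef={c: float(np.mean([r.ef[c] for r in reports])) for c in cutoffs},
        provenance=provenance,
    )


def _fold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Random permutation under ``seed`` chunked into k near-equal folds."""
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, k)


ScorerFactory = Callable[[np.ndarray], Callable[[np.ndarray], np.ndarray]]


def qex_scorer_factory(**fit_kwargs) -> ScorerFactory:
    """Scorer factory for cross_validate that fits a QEX model per fold."""
    from .scoring import fit_qex_model

    def factory(train_props: np.ndarray):
        model = fit_qex_model(train_props, **fit_kwargs)
        return model.score_matrix

    return factory


def _as_matrix(compounds) -> tuple[list[str], np.ndarray]:
    if isinstance(compounds, pd.DataFrame):
        ids = [str(i) for i in compounds["id"]] if "id" in compounds else \
            [str(i) for i in range(len(compounds))]
        return ids, compounds[list(PROPERTY_NAMES)].to_numpy(dtype=float)
    records = list(compounds)
    return [r.id for r in records], property_matrix(records)


def cross_validate(
    actives: Union[Sequence[CompoundRecord], pd.DataFrame],
    inactives: Union[Sequence[CompoundRecord], pd.DataFrame],
    scorer_factory: ScorerFactory,
    k: int = 5,
    seed: int = 0,
    cutoffs: Sequence[float] = DEFAULT_EF_CUTOFFS,
    min_train: int = 20,
) -> CVResult:
    """The k-fold protocol: fit on k-1 folds of actives, rank held-out
    actives against the full inactive pool.

    Inactives never inform fitting (the method needs actives only) and are
    not split: every fold's test ranking contains all of them. Fold
    assignment is a seeded permutation chunked into k near-equal parts.
    """
    act_ids, A = _as_matrix(actives)
    inact_ids, I = _as_matrix(inactives)
    folds = _fold_indices(A.shape[0], k, seed)
    reports = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(A.shape[0]), test_idx)
        if train_idx.size < min_train:
            raise ModelError(
                f"fold {fold_no}: training split has {train_idx.size} actives "
                f"(need >= {min_train}); cross-validation aborted"
            )
        scorer = scorer_factory(A[train_idx])
        test_props = np.vstack([A[test_idx], I])
        scores = np.asarray(scorer(test_props), dtype=float)
        ranking = ScreeningRanking(
            ids=[act_ids[i] for i in test_idx] + inact_ids,
            scores=scores,
            labels=np.concatenate([np.ones(test_idx.size, bool),
                                   np.zeros(I.shape[0], bool)]),
            provenance=f"cv fold {fold_no}/{k} seed {seed}",
        )
        reports.append(evaluate_ranking(ranking, cutoffs))
    return CVResult(folds=reports, mean=_mean_report(reports, f"cv mean k={k} seed {seed}"),
                    k=k, seed=seed)


def evaluate_fixed_model(
    model: QEXModel,
    actives: Union[Sequence[CompoundRecord], pd.DataFrame],
    inactives: Union[Sequence[CompoundRecord], pd.DataFrame],
    cutoffs: Sequence[float] = DEFAULT_EF_CUTOFFS,
    folds: Optional[tuple[int, int]] = None,
    flag_training_overlap: bool = False,
) -> Union[EnrichmentReport, CVResult]:
    """Benchmark a pre-built model without refitting.

    With ``folds=(k, seed)`` the evaluation mirrors the cross-validation
    protocol — each fold's held-out actives plus all inactives — so the
    fixed model's numbers are comparable to a cross-validated one. Otherwise
    a single report over all actives + inactives is returned.
    ``flag_training_overlap`` marks the provenance when the test actives are
    known to be the model's own training set.
    """
    act_ids, A = _as_matrix(actives)
    inact_ids, I = _as_matrix(inactives)
    note = " [evaluated-on-training-actives]" if flag_training_overlap else ""

    def report_for(test_idx: np.ndarray, tag: str) -> EnrichmentReport:
        props = np.vstack([A[test_idx], I])
        ranking = ScreeningRanking(
            ids=[act_ids[i] for i in test_idx] + inact_ids,
            scores=model.score_matrix(props),
            labels=np.concatenate([np.ones(test_idx.size, bool),
                                   np.zeros(I.shape[0], bool)]),
            provenance=f"fixed model {model.model_hash[:12]} {tag}{note}",
        )
        return evaluate_ranking(ranking, cutoffs)

    if folds is None:
        return report_for(np.arange(A.shape[0]), "full")
    k, seed = folds
    reports = [report_for(idx, f"fold {i}/{k} seed {seed}")
               for i, idx in enumerate(_fold_indices(A.shape[0], k, seed))]
    return CVResult(folds=reports,
                    mean=_mean_report(reports, f"fixed-model cv mean k={k} seed {seed}"),
                    k=k, seed=seed)
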