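"""QEX score aggregation and entropy-based weight selection.

The score of a compound is the weighted geometric mean of its eight
normalized desirabilities,

    score = exp( sum_i w_i ln Q~_i / sum_i w_i ),

so it lives in (0, 1] and is monotone in every desirability. The weight
vector is chosen by exhaustive search: every combination of the eight
weights over {0, 0.25, 0.5, 0.75, 1} (except all-zero) is scored on the
training actives, the Shannon entropy

    H = - sum_k score_k * log2(score_k)

of the resulting score set is computed, and the component-wise mean of the
1000 highest-entropy candidates is adopted. High entropy spreads scores away
from the degenerate all-ones solution, favouring informative weightings.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .desirability import DesirabilityFunction, HistogramSpec, fit_ads, normalize_desirability
from .errors import ModelError, QexError
from .properties import (
    HBA_DEFINITION,
    HBD_DEFINITION,
    INTEGER_PROPERTIES,
    PROPERTY_NAMES,
    CompoundRecord,
    PropertyVector,
    property_matrix,
)

__all__ = [
    "DESIRABILITY_FLOOR", "WEIGHT_GRID_LEVELS", "QEXModel",
    "qex_score", "shannon_entropy", "enumerate_weight_grid",
    "select_weights", "fit_qex_model",
]

#: Desirabilities are clamped to [floor, 1] before the log transform so the
#: geometric mean stays finite and order-preserving.
DESIRABILITY_FLOOR = 1e-6

#: The exhaustive weight grid: each of the eight weights takes these levels.
WEIGHT_GRID_LEVELS = (0.0, 0.25, 0.5, 0.75, 1.0)

_LN2 = math.log(2.0)
_SCHEMA_VERSION = 1


def _floored_log_desirability(values: np.ndarray) -> np.ndarray:
    return np.log(np.clip(values, DESIRABILITY_FLOOR, 1.0))


def shannon_entropy(scores: Sequence[float]) -> float:
    """Shannon entropy of a score set: ``-sum s*log2(s)`` with 0*log2(0) = 0.

    Computed on the raw scores (not renormalized to probabilities); scores
    must lie in [0, 1].
    """
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < 0 or s.max() > 1):
        raise QexError(f"scores outside [0, 1]: min={s.min()}, max={s.max()}")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(s > 0, s * np.log2(np.where(s > 0, s, 1.0)), 0.0)
    return float(-terms.sum())


def enumerate_weight_grid(levels: Sequence[float] = WEIGHT_GRID_LEVELS,
                          n_properties: int = 8) -> np.ndarray:
    """All weight combinations over ``levels`` except all-zero, in a fixed order.

    The order is odometer-style (last property varies fastest), matching
    ``itertools.product``. For the default 5 levels and 8 properties this is
    5**8 - 1 = 390,624 candidates.
    """
    levels = np.asarray(levels, dtype=float)
    L, P = levels.size, n_properties
    idx = np.indices([L] * P).reshape(P, -1).T  # product order
    grid = levels[idx]
    nonzero = np.any(grid != 0.0, axis=1)
    return grid[nonzero]


def _candidate_entropies(grid: np.ndarray, logq: np.ndarray,
                         chunk: int = 32768) -> np.ndarray:
    """Entropy of the training score set under every candidate weight vector.

    Works on the precomputed (n, 8) floored log-desirability table so each
    chunk is a dense matrix product; s*log2(s) is evaluated as
    exp(m)*m/ln2 with m the weighted mean log, avoiding a second log.
    """
    wsum = grid.sum(axis=1)
    ent = np.empty(grid.shape[0])
    for start in range(0, grid.shape[0], chunk):
        W = grid[start:start + chunk]
        M = (W @ logq.T) / wsum[start:start + chunk, None]
        ent[start:start + chunk] = -(np.exp(M) * M).sum(axis=1) / _LN2
    return ent


def select_weights(logq: np.ndarray, top: int = 1000,
                   levels: Sequence[float] = WEIGHT_GRID_LEVELS) -> np.ndarray:
    """Adopt the mean of the ``top`` highest-entropy weight candidates.

    ``logq`` is the (n_compounds, n_properties) table of floored
    log-desirabilities of the training actives. Ties at the selection
    boundary are broken by enumeration order (stable sort), so the result is
    deterministic and independent of compound order.
    """
    logq = np.asarray(logq, dtype=float)
    if logq.ndim != 2:
        raise ModelError("logq must be 2-D (compounds x properties)")
    if logq.shape[0] < 2:
        raise ModelError(f"need >= 2 training compounds, got {logq.shape[0]}")
    grid = enumerate_weight_grid(levels, n_properties=logq.shape[1])
    ent = _candidate_entropies(grid, logq)
    top = min(top, grid.shape[0])
    order = np.argsort(-ent, kind="stable")[:top]
    return grid[order].mean(axis=0)


@dataclass
class QEXModel:
    """Eight normalized desirability functions plus their weight vector.

    Fitted on the active compounds of one target (or, for the original-QED
    analogue, on a set of approved drugs). Scores any compound's property
    vector into [0, 1].
    """

    desirabilities: tuple[DesirabilityFunction, ...]
    weights: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.desirabilities) != len(PROPERTY_NAMES):
            raise ModelError(
                f"expected {len(PROPERTY_NAMES)} desirability functions, "
                f"got {len(self.desirabilities)}"
            )
        for fn, name in zip(self.desirabilities, PROPERTY_NAMES):
            if fn.property_name != name:
                raise ModelError(
                    f"desirability order mismatch: {fn.property_name} != {name}"
                )
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(PROPERTY_NAMES),):
            raise ModelError(f"weights must have shape (8,), got {self.weights.shape}")
        if self.weights.min() < 0 or not self.weights.any():
            raise ModelError("weights must be non-negative with at least one positive")

    # -- scoring -----------------------------------------------------------

    def log_desirability_table(self, props: np.ndarray) -> np.ndarray:
        """Floored log-desirabilities for an (n, 8) property matrix."""
        props = np.atleast_2d(np.asarray(props, dtype=float))
        cols = [
            _floored_log_desirability(fn(props[:, i]))
            for i, fn in enumerate(self.desirabilities)
        ]
        return np.column_stack(cols)

    def score_matrix(self, props: np.ndarray) -> np.ndarray:
        """Scores for an (n, 8) property matrix, vectorized."""
        logq = self.log_desirability_table(props)
        return np.exp(logq @ self.weights / self.weights.sum())

    def score(self, props: Union[PropertyVector, np.ndarray]) -> float:
        """QEX score of a single compound."""
        arr = props.as_array() if isinstance(props, PropertyVector) else np.asarray(props)
        return float(self.score_matrix(arr.reshape(1, -1))[0])

    def peaks(self) -> pd.Series:
        """Per-property peak locations of the fitted desirability curves."""
        return pd.Series({fn.property_name: fn.peak for fn in self.desirabilities})

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": _SCHEMA_VERSION,
            "desirabilities": [fn.to_dict() for fn in self.desirabilities],
            "weights": [float(w) for w in self.weights],
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QEXModel":
        version = d.get("schema_version")
        if version != _SCHEMA_VERSION:
            raise ModelError(
                f"model schema version {version!r} not supported "
                f"(expected {_SCHEMA_VERSION}); no migration available"
            )
        fns = tuple(DesirabilityFunction.from_dict(x) for x in d["desirabilities"])
        return cls(desirabilities=fns, weights=np.array(d["weights"]),
                   metadata=d.get("metadata", {}))

    @property
    def model_hash(self) -> str:
        """SHA-256 over the canonical serialization, excluding volatile metadata."""
        doc = self.to_dict()
        doc["metadata"] = {k: v for k, v in doc["metadata"].items()
                           if k not in ("created",)}
        blob = json.dumps(doc, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()


def qex_score(props: Union[PropertyVector, np.ndarray], model: QEXModel) -> float:
    """Weighted geometric mean of the compound's floored desirabilities."""
    return model.score(props)


def fit_qex_model(
    actives: Union[Sequence[CompoundRecord], pd.DataFrame, np.ndarray],
    spec: HistogramSpec = HistogramSpec(),
    top: int = 1000,
    levels: Sequence[float] = WEIGHT_GRID_LEVELS,
    metadata: Optional[dict] = None,
) -> QEXModel:
    """Fit the full model: eight desirability curves + entropy-selected weights.

    ``actives`` may be CompoundRecords, a property-table DataFrame, or a raw
    (n, 8) matrix in canonical property order. Requires at least 20 actives.
    The procedure is deterministic: identical inputs reproduce the model
    bit-exactly.
    """
    if isinstance(actives, pd.DataFrame):
        X = actives[list(PROPERTY_NAMES)].to_numpy(dtype=float)
    elif isinstance(actives, np.ndarray):
        X = np.asarray(actives, dtype=float)
    else:
        X = property_matrix(actives)
    if X.ndim != 2 or X.shape[1] != len(PROPERTY_NAMES):
        raise ModelError(f"property matrix must be (n, 8), got {X.shape}")
    if X.shape[0] < 20:
        raise ModelError(f"need >= 20 active compounds, got {X.shape[0]}")

    fns = []
    for i, name in enumerate(PROPERTY_NAMES):
        col = X[:, i]
        params = fit_ads(col, spec, integer_valued=name in INTEGER_PROPERTIES,
                         property_name=name)
        domain = (float(col.min()), float(col.max()))
        fns.append(normalize_desirability(params, domain, property_name=name))

    model = QEXModel(desirabilities=tuple(fns), weights=np.ones(len(PROPERTY_NAMES)))
    logq = model.log_desirability_table(X)
    model.weights = select_weights(logq, top=top, levels=levels)

    import rdkit
    meta = {
        "n_train": int(X.shape[0]),
        "toolkit": f"rdkit {rdkit.__version__}",
        "hbd_definition": HBD_DEFINITION,
        "hba_definition": HBA_DEFINITION,
        "bin_rule": spec.bin_rule,
        "weight_grid_levels": list(levels),
        "weight_top": int(top),
        "desirability_floor": DESIRABILITY_FLOOR,
    }
    if metadata:
        meta.update(metadata)
    model.metadata = meta
    return model
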