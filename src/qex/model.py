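"""Model/Results front-end for fitting and applying QEX filters.

``QEX`` holds the training data (an active-compound property table) and fit
configuration; ``QEX.fit()`` returns a :class:`QEXResults` carrying the
fitted desirability curves, the entropy-selected weights, per-property peak
locations and a ``summary()`` table, in the style of statsmodels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .desirability import HistogramSpec
from .properties import (
    PROPERTY_NAMES,
    AlertSet,
    CompoundRecord,
    properties_table,
    property_matrix,
    records_to_frame,
)
from .scoring import WEIGHT_GRID_LEVELS, QEXModel, fit_qex_model
from .screening import DEFAULT_EF_CUTOFFS, EnrichmentReport, evaluate_fixed_model

__all__ = ["QEX", "QEXResults"]


class QEX:
    """A target-specific druglikeness model, specified by its training actives.

    Parameters
    ----------
    properties : DataFrame
        Property table with columns ``id, MW, ALOGP, HBD, HBA, PSA, ROTB,
        AROM, ALERTS`` — the known actives of one target (or a drug set for
        an original-QED-style model).
    histogram_spec : HistogramSpec, optional
        Binning policy for the per-property histograms.
    """

    def __init__(self, properties: pd.DataFrame,
                 histogram_spec: HistogramSpec = HistogramSpec()):
        missing = [c for c in PROPERTY_NAMES if c not in properties.columns]
        if missing:
            raise ValueError(f"property table missing columns: {missing}")
        self.data = properties.reset_index(drop=True)
        self.histogram_spec = histogram_spec

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_records(cls, records: Sequence[CompoundRecord],
                     **kwargs) -> "QEX":
        return cls(records_to_frame(records), **kwargs)

    @classmethod
    def from_sdf(cls, path: Union[str, Path], alerts: Optional[AlertSet] = None,
                 dedupe: bool = True, on_error: str = "skip", **kwargs) -> "QEX":
        """Compute the property table from an SDF of active compounds."""
        records = properties_table(path, alerts=alerts, on_error=on_error,
                                   dedupe=dedupe)
        return cls.from_records(records, **kwargs)

    @classmethod
    def from_csv(cls, path: Union[str, Path], **kwargs) -> "QEX":
        """Load a precomputed property table (no chemistry toolkit needed)."""
        return cls.from_records(properties_table(path), **kwargs)

    # -- estimation --------------------------------------------------------

    def fit(self, top: int = 1000,
            levels: Sequence[float] = WEIGHT_GRID_LEVELS,
            metadata: Optional[dict] = None) -> "QEXResults":
        """Fit desirability curves and select weights; returns results."""
        model = fit_qex_model(self.data, spec=self.histogram_spec,
                              top=top, levels=levels, metadata=metadata)
        return QEXResults(self, model)


class QEXResults:
    """Fitted QEX filter: desirability curves, weights, and scoring."""

    def __init__(self, model_spec: QEX, qexmodel: QEXModel):
        self.model = model_spec
        self.qexmodel = qexmodel

    @property
    def weights(self) -> pd.Series:
        return pd.Series(self.qexmodel.weights, index=list(PROPERTY_NAMES))

    @property
    def peaks(self) -> pd.Series:
        """Per-property peak locations of the fitted desirability curves."""
        return self.qexmodel.peaks()

    def params_frame(self) -> pd.DataFrame:
        """ADS coefficients, normalization constants and peaks per property."""
        rows = []
        for fn in self.qexmodel.desirabilities:
            p = fn.params
            rows.append({
                "property": fn.property_name, "a": p.a, "b": p.b, "c": p.c,
                "d": p.d, "e": p.e, "f": p.f, "norm_max": fn.norm_max,
                "peak": fn.peak,
                "weight": self.weights[fn.property_name],
            })
        return pd.DataFrame(rows).set_index("property")

    def score(self, compounds) -> np.ndarray:
        """Score compounds: an (n, 8) matrix, property DataFrame, or records."""
        if isinstance(compounds, pd.DataFrame):
            X = compounds[list(PROPERTY_NAMES)].to_numpy(dtype=float)
        elif isinstance(compounds, np.ndarray):
            X = compounds
        else:
            X = property_matrix(list(compounds))
        return self.qexmodel.score_matrix(X)

    def training_scores(self) -> np.ndarray:
        return self.score(self.model.data)

    def evaluate(self, actives, inactives,
                 cutoffs: Sequence[float] = DEFAULT_EF_CUTOFFS,
                 **kwargs) -> EnrichmentReport:
        """Benchmark this fitted filter on a labeled active/inactive pool."""
        return evaluate_fixed_model(self.qexmodel, actives, inactives,
                                    cutoffs=cutoffs, **kwargs)

    def save(self, path: Union[str, Path]) -> None:
        from .io import save_model
        save_model(self.qexmodel, path)

    def summary(self) -> str:
        """Human-readable fit summary (coefficients, peaks, weights)."""
        meta = self.qexmodel.metadata
        lines = [
            "QEX desirability model",
            "=" * 70,
            f"Training compounds: {meta.get('n_train', len(self.model.data))}",
            f"Toolkit:            {meta.get('toolkit', 'n/a')}",
            f"Weight grid:        {meta.get('weight_grid_levels', 'n/a')} "
            f"(mean of top {meta.get('weight_top', 'n/a')} by entropy)",
            f"Model hash:         {self.qexmodel.model_hash[:16]}",
            "-" * 70,
        ]
        frame = self.params_frame()[["c", "d", "e", "f", "peak", "weight"]]
        lines.append(frame.to_string(float_format=lambda v: f"{v:10.3f}"))
        lines.append("-" * 70)
        s = self.training_scores()
        lines.append(
            f"Training scores: mean {s.mean():.3f}  min {s.min():.3f}  "
            f"max {s.max():.3f}"
        )
        return "\n".join(lines)
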