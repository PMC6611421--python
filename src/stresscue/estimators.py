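"""scikit-learn-style estimators wrapping the scoring and calibration core.

``ConsistencyScorer`` is a transformer: fit on a trial list, transform
collections of response sets into a tidy score table.  ``RandomResponse
Classifier`` is an estimator whose ``fit`` runs the Monte-Carlo null
calibration on the trial list and whose ``predict`` labels score rows as
random-compatible (True) or not; both expose ``get_params``/
``set_params`` and fitted attributes with trailing underscores, so they
compose with sklearn tooling (clone, pipelines over pre-scored tables).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import nullcal
from .design import validate_trials
from .scoring import score_table


class ConsistencyScorer(BaseEstimator, TransformerMixin):
    """Transform response sets into consistency-score rows.

    Parameters
    ----------
    include_cells : bool
        Whether the output table carries the 27 per-cell columns.
    """

    def __init__(self, include_cells: bool = False):
        self.include_cells = include_cells

    def fit(self, X, y=None):
        """Validate and store the trial list (a TrialSequence or frame)."""
        self.trials_ = validate_trials(X)
        self.n_trials_ = len(self.trials_)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Score an iterable of ResponseSet objects against the fitted trials."""
        if not hasattr(self, "trials_"):
            raise RuntimeError("ConsistencyScorer is not fitted; call fit(trials)")
        return score_table(self.trials_, X, include_cells=self.include_cells)


class RandomResponseClassifier(BaseEstimator):
    """Classify participants as inside/outside the random-response box.

    ``fit(trials)`` simulates ``n_sims`` uniform-guessing participants
    on the design and stores the empirical box bounds; ``predict``
    takes a score table (columns ``OC`` and ``sd_cells``) and returns a
    boolean array, True where the participant is random-compatible.
    """

    def __init__(self, n_sims: int = 10_000, level: float = 0.95, random_state: int = 0):
        self.n_sims = n_sims
        self.level = level
        self.random_state = random_state

    def fit(self, X, y=None):
        calib = nullcal.simulate_null(
            X, n_sims=self.n_sims, seed=self.random_state, level=self.level
        )
        self.calibration_ = calib
        self.oc_low_ = calib.oc_low
        self.oc_high_ = calib.oc_high
        self.sd_high_ = calib.sd_high
        self.oc_samples_ = calib.oc_samples
        self.sd_samples_ = calib.sd_samples
        return self

    def _check_fitted(self):
        if not hasattr(self, "calibration_"):
            raise RuntimeError("RandomResponseClassifier is not fitted; call fit(trials)")

    def predict(self, X) -> np.ndarray:
        """Boolean random-compatibility per score row (boundary inclusive)."""
        self._check_fitted()
        table = nullcal.classify_table(self.calibration_, self._as_table(X))
        return table["in_random_region"].to_numpy()

    def exceedance_p(self, oc) -> np.ndarray:
        """One-sided upper Monte-Carlo p-value for each OC value."""
        self._check_fitted()
        return np.asarray(
            [nullcal.oc_exceedance_p(self.calibration_, v) for v in np.atleast_1d(oc)]
        )

    @staticmethod
    def _as_table(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            table = X.copy()
        else:
            arr = np.atleast_2d(np.asarray(X, dtype=float))
            table = pd.DataFrame(arr[:, :2], columns=["OC", "sd_cells"])
        if "participant_id" not in table.columns:
            table["participant_id"] = [f"p{i}" for i in range(len(table))]
        return table
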