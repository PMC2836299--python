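"""Threshold calling of copy-number states from log2 ratios.

A clone is called a gain when its log2 ratio exceeds +0.25, a loss below
-0.25, and additionally an amplification above +1.0 — strict inequalities,
applied per clone with no smoothing across neighbors.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .model import GAIN, LOSS, MISSING, NEUTRAL, CallMatrix, Thresholds

#: Float codes used on the sklearn surface (NaN = missing measurement).
CODE_LOSS, CODE_NEUTRAL, CODE_GAIN, CODE_AMP = -1.0, 0.0, 1.0, 2.0


def call_cell(value: float | None, thresholds: Thresholds = Thresholds()) -> tuple[int, bool]:
    """Call one measurement; returns (state code, amplified flag)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return MISSING, False
    value = float(value)
    if math.isinf(value):
        raise ValueError("non-finite log2 ratio")
    if value > thresholds.amp_cut:
        return GAIN, True
    if value > thresholds.gain_cut:
        return GAIN, False
    if value < thresholds.loss_cut:
        return LOSS, False
    return NEUTRAL, False


def _call_array(values: np.ndarray, t: Thresholds) -> tuple[np.ndarray, np.ndarray]:
    missing = np.isnan(values)
    if np.isinf(values).any():
        raise ValueError("non-finite log2 ratio in matrix")
    state = np.zeros(values.shape, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        state[values > t.gain_cut] = GAIN
        state[values < t.loss_cut] = LOSS
        amplified = (values > t.amp_cut) & ~missing
    state[missing] = MISSING
    amplified &= ~missing
    return state, amplified


def call_matrix(ratios: pd.DataFrame, thresholds: Thresholds = Thresholds()) -> CallMatrix:
    """Element-wise calling of a clones x samples log2-ratio frame."""
    values = ratios.to_numpy(dtype=float)
    state, amplified = _call_array(values, thresholds)
    return CallMatrix(
        state=pd.DataFrame(state, index=ratios.index, columns=ratios.columns),
        amplified=pd.DataFrame(amplified, index=ratios.index, columns=ratios.columns),
    )


class DCNACaller(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer from log2 ratios to copy-number call codes.

    Expects ``X`` with samples as rows and clones as columns (the sklearn
    orientation; note this is the transpose of the on-disk matrices).  The
    transform returns a float array with codes -1 (loss), 0 (neutral),
    1 (gain), 2 (amplified gain) and NaN (missing), so amplified cells stay
    distinguishable while "call >= 1" still means gain.

    Parameters
    ----------
    gain_cut, loss_cut, amp_cut : float
        Strict thresholds on the log2 ratio; defaults +0.25 / -0.25 / +1.0.
    """

    def __init__(self, gain_cut: float = 0.25, loss_cut: float = -0.25,
                 amp_cut: float = 1.0):
        self.gain_cut = gain_cut
        self.loss_cut = loss_cut
        self.amp_cut = amp_cut

    def _thresholds(self) -> Thresholds:
        return Thresholds(self.gain_cut, self.loss_cut, self.amp_cut)

    def fit(self, X, y=None):
        X = self._validate(X)
        self._thresholds()  # raises on an invalid parameter combination
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = self._validate(X)
        state, amplified = _call_array(X.T, self._thresholds())
        codes = state.T.astype(float)
        codes[amplified.T] = CODE_AMP
        codes[state.T == MISSING] = np.nan
        return codes

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X.to_numpy() if hasattr(X, "to_numpy") else X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional (samples x clones)")
        return X


def codes_to_call_matrix(codes: np.ndarray, clone_ids, sample_ids) -> CallMatrix:
    """Rebuild a CallMatrix from DCNACaller codes (samples x clones)."""
    codes = np.asarray(codes, dtype=float).T  # -> clones x samples
    state = np.zeros(codes.shape, dtype=np.int8)
    state[codes == CODE_LOSS] = LOSS
    state[codes >= CODE_GAIN] = GAIN
    state[np.isnan(codes)] = MISSING
    amplified = codes == CODE_AMP
    return CallMatrix(
        state=pd.DataFrame(state, index=pd.Index(clone_ids, name="clone_id"),
                           columns=sample_ids),
        amplified=pd.DataFrame(amplified, index=pd.Index(clone_ids, name="clone_id"),
                               columns=sample_ids),
    )
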