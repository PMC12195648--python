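"""Standardization-based applicability domain.

Each descriptor i of query compound k is standardized against the training
set, S_ik = |x_ik - mean_i| / sd_i.  A compound with every S_ik <= 3 lies
inside the domain (within ~3 sd of the training mean on every axis); one
with even its smallest deviate above 3 lies outside.  In between, the
90th-percentile proxy

    S_new(k) = mean(S_k) + 1.28 sd(S_k)

decides: inside iff S_new <= 3.  Because raw grid descriptors are thousands
of near-duplicate collinear columns, the domain is assessed on the PLS
latent-score space by default (see :func:`ad_report`); raw-descriptor
assessment remains available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

THRESHOLD = 3.0


@dataclass
class Standardizer:
    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray  # descriptors with non-zero training sd

    def transform(self, X) -> np.ndarray:
        """Standardized absolute deviations S, shape (n_query, n_kept)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.abs(X[:, self.kept] - self.means[self.kept]) / self.sds[self.kept]


def fit_standardizer(X_train, ddof: int = 1) -> Standardizer:
    """Per-descriptor training mean and standard deviation (sample sd by
    default); zero-variance descriptors are excluded from AD scoring."""
    X = np.asarray(X_train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 training compounds")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    kept = sds > 0
    if not kept.all():
        warnings.warn(f"{int((~kept).sum())} constant descriptor(s) excluded "
                      "from AD scoring")
    if not kept.any():
        raise ValueError("all descriptors are constant in the training set")
    return Standardizer(means=means, sds=sds, kept=kept)


@dataclass
class ADVerdict:
    s_max: float
    s_min: float
    s_new: float | None  # computed only in the intermediate case
    inside: bool


def ad_assess(s_k) -> ADVerdict:
    """Domain verdict from one compound's standardized-deviation vector."""
    s = np.asarray(s_k, dtype=float).ravel()
    if s.size == 0:
        raise ValueError("empty standardized vector")
    s_max, s_min = float(s.max()), float(s.min())
    if s_max <= THRESHOLD:
        return ADVerdict(s_max, s_min, None, True)
    if s_min > THRESHOLD:
        return ADVerdict(s_max, s_min, None, False)
    sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
    s_new = float(s.mean()) + 1.28 * sd
    return ADVerdict(s_max, s_min, s_new, s_new <= THRESHOLD)


def ad_report(X_train, X_query, query_ids=None, ddof: int = 1) -> pd.DataFrame:
    """AD verdicts for query compounds against a training descriptor matrix.

    Pass latent scores (``fit.x_scores()`` for training, ``fit.x_scores(Xq)``
    for queries) to assess the domain in PLS score space.
    """
    std = fit_standardizer(X_train, ddof=ddof)
    S = std.transform(X_query)
    if query_ids is None:
        query_ids = [str(i) for i in range(S.shape[0])]
    rows = []
    for cid, s_k in zip(query_ids, S):
        v = ad_assess(s_k)
        rows.append({"compound_id": cid, "s_max": v.s_max, "s_min": v.s_min,
                     "s_new": v.s_new,
                     "verdict": "inside" if v.inside else "outside"})
    return pd.DataFrame(rows)
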