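"""External validation, Y-randomization and residual outlier flagging.

External predictivity is judged by the Golbraikh–Tropsha battery on the
held-out test set: beyond q2 > 0.5 and r2_test > 0.6, predicted-versus-
observed points must hug the identity line, which is checked through the
origin-constrained regressions in both directions (slopes k, k') and their
determination coefficients r2_0, r'2_0.  The r2_m metric,

    r2_m = r2_test (1 - sqrt(r2_test - r2_0)),

penalises divergence between the free and through-origin fits; above 0.5 is
acceptable.  Y-randomization refits the model on shuffled activities to
rule out chance correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pls as _pls


@dataclass
class ExternalValidation:
    r2_test: float
    r2_0: float        # through-origin regression of y on yhat
    r2_0_prime: float  # through-origin regression of yhat on y
    k: float           # through-origin slope, y vs yhat
    k_prime: float     # through-origin slope, yhat vs y
    rm2: float
    condition_flags: dict = field(default_factory=dict)


def _through_origin_r2(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and r2 of the no-intercept regression of y on x."""
    k = float(np.sum(y * x) / np.sum(x * x))
    resid = y - k * x
    return k, 1.0 - float(np.sum(resid ** 2) / np.sum((y - y.mean()) ** 2))


def rm2(r2_test: float, r2_0: float) -> float:
    """Roy's metric penalising the gap between r2_test and the
    through-origin r2_0; the gap enters as |r2_test - r2_0| under the root."""
    for v in (r2_test, r2_0):
        if not (0.0 <= v <= 1.0):
            raise ValueError("rm2 inputs must lie in [0, 1]")
    return r2_test * (1.0 - np.sqrt(abs(r2_test - r2_0)))


def external_metrics(y_obs, y_pred) -> ExternalValidation:
    """All test-set regression statistics of the validation battery."""
    y = np.asarray(y_obs, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if len(y) != len(p):
        raise ValueError("observed and predicted lengths differ")
    if len(y) < 3:
        raise ValueError("need at least 3 test compounds")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("constant observed or predicted vector")
    r2_test = float(np.corrcoef(y, p)[0, 1] ** 2)
    k, r2_0 = _through_origin_r2(y, p)
    k_prime, r2_0_prime = _through_origin_r2(p, y)
    return ExternalValidation(
        r2_test=r2_test, r2_0=r2_0, r2_0_prime=r2_0_prime,
        k=k, k_prime=k_prime,
        rm2=rm2(r2_test, r2_0) if 0.0 <= r2_0 <= 1.0 else float("nan"))


def gt_conditions(ev: ExternalValidation, q2: float) -> dict:
    """Pass/fail flags of the predictivity conditions.

    1: q2 > 0.5;  2: r2_test > 0.6;
    3: (r2_test - r2_0)/r2_test < 0.1 or the primed analogue;
    4: 0.85 <= k <= 1.15 or 0.85 <= k' <= 1.15;
    5: |r2_0 - r'2_0| < 0.3;  rm2 > 0.5 reported separately.
    The verdict requires conditions 1-5; the rm2 check is its own flag.
    """
    rt = ev.r2_test
    flags = {
        "q2_gt_0.5": q2 > 0.5,
        "r2_test_gt_0.6": rt > 0.6,
        "origin_r2_close": ((rt - ev.r2_0) / rt < 0.1) or ((rt - ev.r2_0_prime) / rt < 0.1),
        "slope_near_unity": (0.85 <= ev.k <= 1.15) or (0.85 <= ev.k_prime <= 1.15),
        "origin_r2_gap_lt_0.3": abs(ev.r2_0 - ev.r2_0_prime) < 0.3,
        "rm2_gt_0.5": ev.rm2 > 0.5,
    }
    battery = ["q2_gt_0.5", "r2_test_gt_0.6", "origin_r2_close",
               "slope_near_unity", "origin_r2_gap_lt_0.3"]
    flags["verdict"] = all(flags[name] for name in battery)
    ev.condition_flags = flags
    return flags


@dataclass
class RandomizationReport:
    n_iterations: int
    q2_values: np.ndarray
    r2_ncv_values: np.ndarray
    passed: bool  # every scrambled model is poor (q2 < 0.5 and r2_ncv < 0.6)

    @property
    def fraction_q2_below_05(self) -> float:
        return float(np.mean(self.q2_values < 0.5))


def y_randomization(X, y, n_iterations: int = 50, n_components: int = 2,
                    seed: int = 0, permutations=None) -> RandomizationReport:
    """Refit after shuffling the activities, keeping the descriptor matrix
    and the original component count; robust models leave every scrambled
    refit with q2 < 0.5 and r2_ncv < 0.6.

    ``permutations`` overrides the seeded shuffles with explicit index
    arrays (one per iteration) for controlled scrambles.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    Xarr, _ = _pls._as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    q2s, r2s = np.empty(n_iterations), np.empty(n_iterations)
    for it in range(n_iterations):
        perm = (rng.permutation(len(y)) if permutations is None
                else np.asarray(permutations[it]))
        ys = y[perm]
        q2s[it] = _pls.loo_q2(Xarr, ys, n_components).q2
        r2s[it] = _pls.fit_pls(Xarr, ys, n_components).r2_ncv
    return RandomizationReport(
        n_iterations=n_iterations, q2_values=q2s, r2_ncv_values=r2s,
        passed=bool(np.all(q2s < 0.5) and np.all(r2s < 0.6)))


def flag_outliers(y_obs, y_pred, ids=None, threshold: float = 1.0) -> set[str]:
    """Compounds whose |residual| exceeds one log unit of activity
    (strictly greater than the threshold)."""
    y = np.asarray(y_obs, dtype=float).ravel()
    p = np.asarray(y_pred, dtype=float).ravel()
    if ids is None:
        ids = [str(i) for i in range(len(y))]
    return {str(i) for i, yo, yp in zip(ids, y, p) if abs(yo - yp) > threshold}


def prediction_table(ids, y_obs, y_pred, subset=None) -> pd.DataFrame:
    """Per-compound observed/predicted/residual report with outlier flags."""
    df = pd.DataFrame({"compound_id": list(ids),
                       "observed": np.asarray(y_obs, float).ravel(),
                       "predicted": np.asarray(y_pred, float).ravel()})
    if subset is not None:
        df["subset"] = list(subset)
    df["residual"] = df["observed"] - df["predicted"]
    df["outlier"] = df["residual"].abs() > 1.0
    return df


def stratified_split(y, test_fraction: float = 0.2, seed: int = 0,
                     n_bins: int = 4) -> np.ndarray:
    """Seeded activity-stratified train/test assignment (returns a boolean
    test mask).  Fallback for sets that arrive without a subset column."""
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    rng = np.random.default_rng(seed)
    order = np.argsort(y)
    mask = np.zeros(n, dtype=bool)
    bins = np.array_split(order, n_bins)
    want = max(1, int(round(test_fraction * n)))
    picked: list[int] = []
    while len(picked) < want:
        for b in bins:
            remaining = [i for i in b if i not in picked]
            if remaining and len(picked) < want:
                picked.append(int(rng.choice(remaining)))
    mask[picked] = True
    return mask
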