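"""PLS regression on field matrices with leave-one-out model selection.

Many collinear grid columns and few compounds is the canonical PLS setting:
latent components are extracted from the centered, block-scaled descriptor
matrix and regressed against pIC50.  Internal predictivity is the
leave-one-out cross-validated coefficient

    q2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

with yhat_i predicted by a model refit without compound i and ybar the mean
over the full training set.  Leave-one-out is run explicitly (the sets are
small); the number of components is the q2 maximiser with ties broken
toward the smaller model.  SEE follows the sqrt(RSS/(n - N - 1)) convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .fields import FieldMatrix


def _as_matrix(X) -> tuple[np.ndarray, FieldMatrix | None]:
    if isinstance(X, FieldMatrix):
        return X.modeling_matrix(), X
    return np.asarray(X, dtype=float), None


def _pls_model(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    model = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns when y is deflated flat
        model.fit(X, y.reshape(-1, 1))
    return model


@dataclass
class PLSFit:
    """A fitted field-PLS model plus the statistics reported for it."""

    n_components: int
    coefficients: np.ndarray          # raw field units, retained columns
    coefficients_scaled: np.ndarray   # block-scaled modeling units
    intercept: float
    r2_ncv: float
    see: float
    training_ids: list[str] | None
    q2: float | None = None
    press: float | None = None
    loo_predictions: np.ndarray | None = None
    field_fractions: dict = field(default_factory=dict)
    fitted: np.ndarray | None = None
    fm: FieldMatrix | None = None     # training descriptor metadata
    _model: PLSRegression | None = None

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """Predict from a modeling-space matrix (retained, scaled columns)."""
        return self._model.predict(X).ravel()

    def modeling_matrix_for(self, fm: FieldMatrix) -> np.ndarray:
        """Map a query FieldMatrix (assembled on the training lattice) into
        this model's input space: restrict to the fitted field blocks, apply
        the training column mask and block scaling."""
        if self.fm is None:
            raise ValueError("fit was not made from a FieldMatrix")
        if fm.lattice != self.fm.lattice:
            raise ValueError("lattice mismatch between model and query fields")
        letters = [lbl.split(":")[-1] for lbl in self.fm.blocks]
        sub = fm.subset_fields(letters)
        if (not np.array_equal(sub.field_labels, self.fm.field_labels)
                or not np.array_equal(sub.point_indices, self.fm.point_indices)):
            raise ValueError("query field layout does not match the model")
        return sub.values[:, self.fm.column_mask] \
            / self.fm.scale_vector()[self.fm.column_mask]

    def predict_fieldmatrix(self, fm: FieldMatrix) -> np.ndarray:
        """Predict new compounds whose fields were assembled on the training
        lattice; the training column mask and block scaling are applied."""
        return self.predict_matrix(self.modeling_matrix_for(fm))

    def x_scores(self, X: np.ndarray | None = None) -> np.ndarray:
        """Latent-score coordinates; training scores when X is None."""
        if X is None:
            return self._model.x_scores_
        return self._model.transform(X)


def fit_pls(X, y, n_components: int) -> PLSFit:
    """Fit a PLS model with a fixed number of latent components.

    ``X`` is a (filtered) :class:`FieldMatrix` or a plain 2D array; ``y`` the
    activity vector in pIC50 units.
    """
    Xarr, fm = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = Xarr.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components={n_components} outside [1, {min(n - 1, p)}]")

    model = _pls_model(Xarr, y, n_components)
    yhat = model.predict(Xarr).ravel()
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    dof = n - n_components - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")

    coef_scaled = np.asarray(model.coef_).reshape(-1)
    if fm is not None:
        scale = fm.scale_vector()[fm.column_mask]
        coef_raw = coef_scaled / scale
        ids = list(fm.compound_ids)
    else:
        coef_raw = coef_scaled.copy()
        ids = None

    fit = PLSFit(n_components=n_components, coefficients=coef_raw,
                 coefficients_scaled=coef_scaled,
                 intercept=float(np.asarray(model.intercept_).ravel()[0]),
                 r2_ncv=r2, see=see, training_ids=ids,
                 fitted=yhat, fm=fm, _model=model)
    fit.field_fractions = field_fraction(fit) if fm is not None else {}
    return fit


@dataclass
class LOOResult:
    q2: float
    press: float
    predictions: np.ndarray


def loo_q2(X, y, n_components: int) -> LOOResult:
    """Explicit leave-one-out cross-validation of the PLS model."""
    Xarr, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 compounds for LOO")
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("y has zero variance")
    if not (1 <= n_components <= min(n - 2, Xarr.shape[1])):
        raise ValueError("n_components out of range for LOO refits")
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        model = _pls_model(Xarr[keep], y[keep], n_components)
        preds[i] = model.predict(Xarr[i:i + 1]).ravel()[0]
    press = float(np.sum((y - preds) ** 2))
    return LOOResult(q2=1.0 - press / tss, press=press, predictions=preds)


def select_components(X, y, max_n: int = 6) -> tuple[int, pd.DataFrame]:
    """Pick the component count maximising LOO q2 (smaller N wins ties);
    the full q2-versus-N profile is returned alongside."""
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    Xarr, _ = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n_max = min(max_n, len(y) - 2, Xarr.shape[1])
    rows = []
    for ncomp in range(1, n_max + 1):
        res = loo_q2(Xarr, y, ncomp)
        rows.append({"n_components": ncomp, "q2": res.q2, "press": res.press})
    profile = pd.DataFrame(rows)
    best = int(profile.loc[profile["q2"].idxmax(), "n_components"])
    return best, profile


def fit_with_selection(X, y, max_n: int = 6) -> PLSFit:
    """Select N by LOO q2, then fit the final model and attach q2/PRESS."""
    n_star, _ = select_components(X, y, max_n)
    res = loo_q2(X, y, n_star)
    fit = fit_pls(X, y, n_star)
    fit.q2, fit.press, fit.loo_predictions = res.q2, res.press, res.predictions
    return fit


@dataclass
class ModelSearchResult:
    label: str
    fit: PLSFit
    rank: int = 0


def model_search(fm: FieldMatrix, y, fields: tuple[str, ...] | None = None,
                 max_n: int = 6) -> list[ModelSearchResult]:
    """Fit every non-empty combination of field blocks and rank by q2.

    Labels concatenate the field letters in canonical S,E,H,D,A order
    (e.g. "SE", "SEH").
    """
    letters = [lbl.split(":")[-1] for lbl in fm.blocks]
    if fields is not None:
        letters = [f for f in letters if f in set(fields)]
    if not letters:
        raise ValueError("no field blocks to search")
    results = []
    for k in range(1, len(letters) + 1):
        for combo in itertools.combinations(letters, k):
            sub = fm.subset_fields(combo)
            label = "".join(combo)
            if not sub.column_mask.any():
                warnings.warn(f"combination {label}: all columns filtered out")
                continue
            results.append(ModelSearchResult(label=label,
                                             fit=fit_with_selection(sub, y, max_n)))
    results.sort(key=lambda r: r.fit.q2, reverse=True)
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def search_table(results: list[ModelSearchResult]) -> pd.DataFrame:
    """Model-search report: one row per field combination."""
    rows = []
    for r in results:
        row = {"fields": r.label, "q2": r.fit.q2, "N": r.fit.n_components,
               "SEE": r.fit.see, "r2_ncv": r.fit.r2_ncv, "rank": r.rank}
        for lbl, frac in r.fit.field_fractions.items():
            row[f"frac_{lbl.split(':')[-1]}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def field_fraction(fit: PLSFit) -> dict[str, float]:
    """Percent contribution of each field block: the share of
    sum |coef_j * sd_j| over the block's retained columns, normalised to 100."""
    if fit.fm is None:
        raise ValueError("field fractions need FieldMatrix metadata")
    X = fit.fm.modeling_matrix()
    sds = X.std(axis=0, ddof=1)
    labels = fit.fm.field_labels[fit.fm.column_mask]
    weight = np.abs(fit.coefficients_scaled) * sds
    total = weight.sum()
    out = {}
    for lbl in fit.fm.blocks:
        sel = labels == lbl
        out[lbl] = 100.0 * float(weight[sel].sum()) / total if total > 0 else 0.0
    return out


@dataclass
class ContourSet:
    """Favored/disfavored lattice points of one field's coef*sd product.

    Favored means activity increases with increasing field value at the
    point (positive coefficient-variance product); disfavored the reverse.
    """

    field: str
    favored_points: np.ndarray      # flat lattice indices
    disfavored_points: np.ndarray
    point_indices: np.ndarray       # retained columns of this field
    product: np.ndarray             # coef*sd per retained column


def contour_grid(fit: PLSFit, upper_pct: float = 80.0,
                 lower_pct: float = 20.0) -> dict[str, ContourSet]:
    """Threshold each field's coefficient-times-sd product at the stated
    percentiles; returns favored/disfavored lattice point sets per field."""
    if fit.fm is None:
        raise ValueError("contours need FieldMatrix metadata")
    X = fit.fm.modeling_matrix()
    sds = X.std(axis=0, ddof=1)
    labels = fit.fm.field_labels[fit.fm.column_mask]
    points = fit.fm.point_indices[fit.fm.column_mask]
    product = fit.coefficients_scaled * sds
    out = {}
    for lbl in fit.fm.blocks:
        sel = labels == lbl
        v, pts = product[sel], points[sel]
        letter = lbl.split(":")[-1]
        if v.size == 0 or np.ptp(v) == 0:
            warnings.warn(f"field {lbl}: degenerate product field, empty contours")
            out[letter] = ContourSet(letter, np.array([], int), np.array([], int),
                                     pts, v)
            continue
        fav, dis = threshold_points(v, upper_pct, lower_pct)
        out[letter] = ContourSet(
            field=letter,
            favored_points=pts[fav],
            disfavored_points=pts[dis],
            point_indices=pts, product=v)
    return out


def threshold_points(values: np.ndarray, upper_pct: float,
                     lower_pct: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks of values at or beyond the upper/lower percentiles."""
    hi = np.percentile(values, upper_pct)
    lo = np.percentile(values, lower_pct)
    return values >= hi, values <= lo


def contours_to_pdb(contours: dict[str, ContourSet], lattice, path) -> None:
    """Dump contour lattice points as HETATM pseudo-atoms for viewer overlay
    (element C for favored, N for disfavored; one residue per field)."""
    pts = lattice.points()
    serial = 1
    with open(path, "w") as fh:
        for resno, (letter, cs) in enumerate(sorted(contours.items()), start=1):
            for kind, element, idxs in (("FAV", "C", cs.favored_points),
                                        ("DIS", "N", cs.disfavored_points)):
                for i in idxs:
                    x, y, z = pts[int(i)]
                    fh.write(
                        f"HETATM{serial:5d} {element:>2}   {kind} {letter[0]}"
                        f"{resno:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                        f"  1.00  0.00          {element:>2}\n")
                    serial += 1
        fh.write("END\n")
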