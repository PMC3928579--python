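"""Exploratory factor analysis of ONH feature tables.

Reproduces the feature-selection methodology used to motivate the BGA
score: Pearson correlation of the features, eigen-decomposition of the
correlation matrix, choice of the number of classes by the Kaiser
(eigenvalue > 1) and Cattell (scree elbow) criteria, principal-component
loadings rotated by varimax, and correlation of the rotated class scores
with perimetric mean defect. A linear BGA-to-MD regression refit is also
provided so the conversion model can be re-estimated on a new cohort.

Extraction is principal-component based (loadings sqrt(lambda_j) * v_j);
rotation is varimax via statsmodels; factor scores use the regression
method. The LV (loss-variance) column, w30, is excluded throughout.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.multivariate.factor_rotation import rotate_factors

from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

_EXCLUDED_COLUMNS = ("w30", "LV", "lv")


@dataclasses.dataclass
class FactorModel:
    feature_names: list[str]
    correlation_matrix: np.ndarray   # p x p
    eigenvalues: np.ndarray          # descending, length p
    n_classes: int
    loadings: pd.DataFrame           # p x k, varimax-rotated
    communalities: np.ndarray        # per feature
    column_means: np.ndarray
    column_stds: np.ndarray

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Regression-method factor scores: Z R^-1 Lambda.

        Missing values are mean-imputed (logged) before scoring.
        """
        data = table[self.feature_names].to_numpy(dtype=float)
        n_missing = int(np.isnan(data).sum())
        if n_missing:
            log.info("factor scores: mean-imputing %d missing values", n_missing)
        z = (data - self.column_means) / self.column_stds
        z = np.nan_to_num(z, nan=0.0)
        weights = np.linalg.solve(self.correlation_matrix, self.loadings.to_numpy())
        return z @ weights


@dataclasses.dataclass
class ScreeChoice:
    kaiser: int
    cattell: int


def _varimax(loadings: np.ndarray) -> np.ndarray:
    if loadings.shape[1] < 2:
        return loadings
    rotated, _ = rotate_factors(loadings, "varimax")
    return rotated


def fit_factor_model(table: pd.DataFrame, n_classes: int | None = None) -> FactorModel:
    """Fit the exploratory factor model to a patients-by-features table.

    Correlations are Pearson, pairwise-complete. Constant columns are
    dropped with a warning, as are the excluded LV columns. ``n_classes``
    defaults to the Kaiser count (eigenvalue > 1); a warning is emitted
    when the spectrum is so flat that Kaiser is ambiguous.
    """
    numeric = table.select_dtypes(include=[np.number])
    numeric = numeric.drop(columns=[c for c in _EXCLUDED_COLUMNS if c in numeric],
                           errors="ignore")
    if len(numeric) < 3:
        raise ValidationError(f"need at least 3 rows, got {len(numeric)}")
    constant = [c for c in numeric.columns if numeric[c].nunique(dropna=True) <= 1]
    if constant:
        log.warning("dropping constant columns: %s", constant)
        numeric = numeric.drop(columns=constant)
    if numeric.shape[1] < 3:
        raise ValidationError(f"need at least 3 usable features, got {numeric.shape[1]}")
    if len(numeric) < numeric.shape[1]:
        log.warning("fewer rows (%d) than features (%d); loadings will be unstable",
                    len(numeric), numeric.shape[1])

    corr = numeric.corr(method="pearson").to_numpy()  # pairwise-complete
    n_pairs_missing = int(np.isnan(corr).sum())
    if n_pairs_missing:
        raise ValidationError("correlation matrix has undefined entries "
                              "(feature pairs with no joint observations)")
    corr = (corr + corr.T) / 2.0

    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)

    kaiser = int(np.sum(eigvals > 1.0))
    if n_classes is None:
        if kaiser == 0 or np.all(np.abs(eigvals - 1.0) < 0.2):
            log.warning("flat eigenvalue spectrum; Kaiser criterion is ambiguous")
        n_classes = max(kaiser, 1)
    if not 1 <= n_classes <= len(eigvals):
        raise ValidationError(f"n_classes must lie in [1, {len(eigvals)}]")

    raw = eigvecs[:, :n_classes] * np.sqrt(eigvals[:n_classes])
    rotated = _varimax(raw)
    # orient every class so its largest-magnitude loading is positive
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(n_classes)])
    signs[signs == 0] = 1.0
    rotated = rotated * signs

    loadings = pd.DataFrame(rotated, index=numeric.columns,
                            columns=[f"class{k + 1}" for k in range(n_classes)])
    return FactorModel(
        feature_names=list(numeric.columns),
        correlation_matrix=corr,
        eigenvalues=eigvals,
        n_classes=n_classes,
        loadings=loadings,
        communalities=(rotated ** 2).sum(axis=1),
        column_means=numeric.mean(skipna=True).to_numpy(),
        column_stds=numeric.std(skipna=True, ddof=1).to_numpy(),
    )


def select_n_classes_scree(eigenvalues: np.ndarray) -> ScreeChoice:
    """Kaiser count and Cattell elbow for a descending eigenvalue sequence.

    The elbow is the position maximizing the second difference of the
    sequence; an all-equal spectrum has no elbow and raises
    :class:`DegenerateInputError`.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size < 3:
        raise ValidationError(f"need at least 3 eigenvalues, got {ev.size}")
    if np.any(np.diff(ev) > 1e-12):
        raise ValidationError("eigenvalues must be sorted in descending order")
    second_diff = ev[:-2] - 2.0 * ev[1:-1] + ev[2:]
    if np.allclose(second_diff, 0.0):
        raise DegenerateInputError("flat eigenvalue spectrum: no scree elbow")
    # second_diff[j] is centred on eigenvalue j+1 (0-based), i.e. position j+2 1-based
    cattell = int(np.argmax(second_diff)) + 2
    return ScreeChoice(kaiser=int(np.sum(ev > 1.0)), cattell=cattell)


def class_perimetry_correlation(model: FactorModel, table: pd.DataFrame,
                                md_column: str) -> dict:
    """Correlate rotated class scores with perimetric MD.

    Returns per-class Pearson correlations and the multiple correlation of
    all class scores with MD jointly.
    """
    if md_column not in table.columns:
        raise ValidationError(f"MD column {md_column!r} not in table")
    md = table[md_column].to_numpy(dtype=float)
    ok = np.isfinite(md)
    if ok.sum() < 3:
        raise ValidationError("need at least 3 finite MD values")
    if np.nanstd(md) == 0:
        raise DegenerateInputError("MD is constant; correlation undefined")
    scores = model.scores(table)[ok]
    md = md[ok]
    per_class = {
        col: float(stats.pearsonr(scores[:, k], md)[0])
        for k, col in enumerate(model.loadings.columns)
    }
    design = np.column_stack([np.ones(len(md)), scores])
    beta, *_ = np.linalg.lstsq(design, md, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((md - fitted) ** 2))
    ss_tot = float(np.sum((md - md.mean()) ** 2))
    multiple_r = float(np.sqrt(max(1.0 - ss_res / ss_tot, 0.0)))
    return {"per_class": per_class, "multiple_r": multiple_r}


def fit_bga_md_regression(bga_values, md_values) -> tuple[float, float, float]:
    """Ordinary least squares of MD on BGA; returns (slope, intercept, r)."""
    bga = np.asarray(bga_values, dtype=float)
    md = np.asarray(md_values, dtype=float)
    if bga.shape != md.shape:
        raise ValidationError("bga and md must have equal length")
    ok = np.isfinite(bga) & np.isfinite(md)
    if ok.sum() < 3:
        raise ValidationError("need at least 3 complete (BGA, MD) pairs")
    if np.std(bga[ok]) == 0:
        raise DegenerateInputError("BGA is constant; regression undefined")
    fit = stats.linregress(bga[ok], md[ok])
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)
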