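"""Linear age-prediction models producing the periorbital skin age.

Nine models, each an ordinary-least-squares fit of chronological age on a
fixed subset of the seven periorbital indices (``y = b0 + sum b_i x_i``):

====== ==============================
model  features
====== ==============================
1      Wb, Wu, Wa           (wrinkles)
2      Md, Mw               (morphology)
3      Pb, Pu               (pigmented spots)
4      Wb, Wu, Wa, Md, Mw
5      Wb, Wu, Wa, Pb, Pu
6      Md, Mw, Pb, Pu
7      all seven
8      Wb, Wu               (model 1 without Wa)
9      Wb, Wu, Pb, Pu       (model 5 without Wa)
====== ==============================

Models 8 and 9 keep only indices a dedicated measurement device reports
directly. Performance is the Pearson correlation between predicted and
actual age, evaluated by 10-fold cross-validation on the build cohort and
by an independent validation cohort for the final full-data fits. Models
whose full-data fit carries negative coefficients (a collinearity artifact)
can be *refined* by iteratively dropping the most negative coefficient and
refitting until all remaining coefficients are nonnegative; refined models
are the "double-prime" variants. The predicted age from a final model is
the subject's periorbital skin age.

The API follows the model/results idiom: :class:`PeriorbitalAgeModel`
wraps a cohort and feature subset, ``fit()`` returns a
:class:`PeriorbitalAgeResults` with coefficients, standard errors,
diagnostics, ``predict``, ``refine`` and ``summary``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

FEATURES = ("Wb", "Wu", "Wa", "Pb", "Pu", "Md", "Mw")

_CATALOG: dict[int, tuple[str, ...]] = {
    1: ("Wb", "Wu", "Wa"),
    2: ("Md", "Mw"),
    3: ("Pb", "Pu"),
    4: ("Wb", "Wu", "Wa", "Md", "Mw"),
    5: ("Wb", "Wu", "Wa", "Pb", "Pu"),
    6: ("Md", "Mw", "Pb", "Pu"),
    7: ("Wb", "Wu", "Wa", "Pb", "Pu", "Md", "Mw"),
    8: ("Wb", "Wu"),
    9: ("Wb", "Wu", "Pb", "Pu"),
}


def model_catalog() -> dict[int, tuple[str, ...]]:
    """The nine feature subsets, keyed by model number."""
    return dict(_CATALOG)


@dataclass
class CVResult:
    """k-fold cross-validation outcome for one feature subset."""

    fold_r: list[float]
    k: int
    seed: int
    subset: tuple[str, ...]

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.fold_r))


def _design(cohort: pd.DataFrame, subset: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    missing = [f for f in subset if f not in cohort.columns]
    if missing:
        raise KeyError(f"cohort is missing feature column(s): {', '.join(missing)}")
    x = cohort.loc[:, list(subset)].to_numpy(dtype=float)
    y = cohort["age"].to_numpy(dtype=float)
    return x, y


def _check_rank(x: np.ndarray, subset: tuple[str, ...]) -> None:
    design = np.column_stack([np.ones(len(x)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the features involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [subset[i - 1] for i in range(1, design.shape[1]) if diag[i] < 1e-10 * diag.max()]
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear feature(s): {', '.join(bad) or 'intercept-level'}"
        )


class PeriorbitalAgeModel:
    """OLS age model for one feature subset of a cohort table.

    Parameters
    ----------
    cohort : DataFrame
        Must contain an ``age`` column and every feature in ``subset``.
    subset : sequence of str
        Feature names (a catalog subset or any custom combination).
    number : int, optional
        Catalog model number, recorded on the results.
    training_id : str
        Identifier of the training set, for provenance.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        subset,
        number: int | None = None,
        training_id: str = "unspecified",
    ) -> None:
        self.cohort = cohort
        self.subset = tuple(subset)
        self.number = number
        self.training_id = training_id
        if len(cohort) <= len(self.subset) + 1:
            raise ValueError(
                f"need more than {len(self.subset) + 1} subjects to fit {len(self.subset)} features"
            )

    @classmethod
    def from_catalog(cls, cohort: pd.DataFrame, number: int, training_id: str = "unspecified"):
        if number not in _CATALOG:
            raise KeyError(f"model number must be 1..9, got {number}")
        return cls(cohort, _CATALOG[number], number=number, training_id=training_id)

    def fit(self) -> "PeriorbitalAgeResults":
        x, y = _design(self.cohort, self.subset)
        _check_rank(x, self.subset)
        res = sm.OLS(y, sm.add_constant(x)).fit()
        params = pd.Series(res.params, index=["const", *self.subset])
        bse = pd.Series(res.bse, index=params.index)
        pvalues = pd.Series(res.pvalues, index=params.index)
        return PeriorbitalAgeResults(
            model=self,
            params=params,
            bse=bse,
            pvalues=pvalues,
            rsquared=float(res.rsquared),
            nobs=int(res.nobs),
            refined=False,
            removed=(),
        )


@dataclass
class PeriorbitalAgeResults:
    """Fitted age model: coefficients, uncertainties and predictions."""

    model: PeriorbitalAgeModel
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    rsquared: float
    nobs: int
    refined: bool = False
    removed: tuple[str, ...] = ()

    @property
    def subset(self) -> tuple[str, ...]:
        return tuple(self.params.index[1:])

    @property
    def intercept(self) -> float:
        return float(self.params["const"])

    @property
    def coefficients(self) -> pd.Series:
        return self.params.drop("const")

    def predict(self, features) -> np.ndarray | float:
        """Periorbital skin age for one subject (mapping) or a cohort table.

        Out-of-range predicted ages are reported as-is with a warning --
        the score is a biomarker, not a clipped age.
        """
        subset = self.subset
        if isinstance(features, pd.DataFrame):
            missing = [f for f in subset if f not in features.columns]
            if missing:
                raise KeyError(f"missing feature(s): {', '.join(missing)}")
            x = features.loc[:, list(subset)].to_numpy(dtype=float)
        else:
            try:
                x = np.array([[float(features[f]) for f in subset]])
            except (KeyError, TypeError) as exc:
                raise KeyError(f"missing feature {exc} for prediction") from None
        yhat = self.intercept + x @ self.coefficients.to_numpy()
        if np.any((yhat < 0) | (yhat > 120)):
            warnings.warn("predicted age outside [0, 120]; reported unclipped", stacklevel=2)
        return yhat if isinstance(features, pd.DataFrame) else float(yhat[0])

    def refine(self) -> "PeriorbitalAgeResults":
        """Drop negative-coefficient features until all coefficients are >= 0.

        Iterative: after each removal the model is refit on the training
        cohort, since dropping one collinear feature can flip the sign of
        another. Returns the double-prime results with the removal sequence
        recorded; a model already free of negative coefficients is returned
        unchanged.
        """
        return refine_model(self)

    def summary(self) -> str:
        label = f"model {self.model.number}" if self.model.number else "custom model"
        if self.refined:
            label += "''"
        lines = [
            f"Periorbital skin age ({label})",
            f"  training set : {self.model.training_id} (n = {self.nobs})",
            f"  features     : {', '.join(self.subset)}",
            f"  R-squared    : {self.rsquared:.4f}",
            "",
            f"  {'term':<8}{'coef':>10}{'std err':>10}{'P>|t|':>10}",
        ]
        for term in self.params.index:
            lines.append(
                f"  {term:<8}{self.params[term]:>10.4f}{self.bse[term]:>10.4f}{self.pvalues[term]:>10.3g}"
            )
        if self.removed:
            lines.append(f"  removed (refinement): {', '.join(self.removed)}")
        return "\n".join(lines)

    # -- persistence ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "number": self.model.number,
            "training_id": self.model.training_id,
            "refined": self.refined,
            "removed": list(self.removed),
            "nobs": self.nobs,
            "rsquared": self.rsquared,
            "intercept": self.intercept,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def plot_predictions(self, cohort: pd.DataFrame | None = None, ax=None):
        """Scatter of predicted vs actual age (build cohort by default)."""
        import matplotlib.pyplot as plt

        cohort = self.model.cohort if cohort is None else cohort
        yhat = self.predict(cohort)
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(cohort["age"], yhat, s=8, alpha=0.5)
        lims = [cohort["age"].min(), cohort["age"].max()]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel("chronological age (years)")
        ax.set_ylabel("periorbital skin age (years)")
        return ax


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_model(cohort: pd.DataFrame, subset, training_id: str = "unspecified", number: int | None = None) -> PeriorbitalAgeResults:
    """OLS fit of age on a feature subset (see :class:`PeriorbitalAgeModel`)."""
    return PeriorbitalAgeModel(cohort, subset, number=number, training_id=training_id).fit()


def predict_age(results: PeriorbitalAgeResults, features) -> float | np.ndarray:
    """Periorbital skin age for one feature vector or a cohort table."""
    return results.predict(features)


def refine_model(results: PeriorbitalAgeResults) -> PeriorbitalAgeResults:
    """Iteratively remove negative-coefficient features and refit (see results.refine)."""
    current = results
    removed: list[str] = list(results.removed)
    while True:
        coefs = current.coefficients
        if (coefs >= 0).all():
            if not removed:
                return results
            current.refined = True
            current.removed = tuple(removed)
            return current
        if len(coefs) == 1:
            raise ValueError(
                "refinement removed every feature: the remaining single coefficient "
                f"({coefs.index[0]}) is negative; model is degenerate on this cohort"
            )
        worst = str(coefs.idxmin())
        removed.append(worst)
        new_subset = tuple(f for f in current.subset if f != worst)
        current = PeriorbitalAgeModel(
            results.model.cohort,
            new_subset,
            number=results.model.number,
            training_id=results.model.training_id,
        ).fit()


def cross_validate(
    cohort: pd.DataFrame,
    subset,
    k: int = 10,
    seed: int = 0,
    stratify_by_decade: bool = False,
) -> CVResult:
    """k-fold cross-validated performance of one feature subset.

    Subjects are partitioned into k folds by a seeded random permutation
    (optionally stratified by 10-year age band); each fold in turn is held
    out, the model fit on the rest, and the Pearson correlation between
    predicted and actual age computed on the held-out fold. The mean of the
    k fold correlations is the evaluation performance. When the cohort has
    an ``id`` column, subjects are ordered by id before partitioning, so
    the result is invariant to row order given the seed.
    """
    subset = tuple(subset)
    if "id" in cohort.columns:
        cohort = cohort.sort_values("id", kind="stable").reset_index(drop=True)
    n = len(cohort)
    if n < 10 * k:
        raise ValueError(f"need at least {10 * k} subjects for {k}-fold CV, got {n}")
    rng = np.random.default_rng(seed)

    if stratify_by_decade:
        fold_of = np.empty(n, dtype=int)
        decade = (cohort["age"].to_numpy() // 10).astype(int)
        for d in np.unique(decade):
            idx = np.flatnonzero(decade == d)
            idx = rng.permutation(idx)
            fold_of[idx] = np.arange(idx.size) % k
    else:
        fold_of = rng.permutation(np.arange(n) % k)

    x, y = _design(cohort, subset)
    fold_r: list[float] = []
    for fold in range(k):
        test = fold_of == fold
        if test.sum() < 3:
            raise ValueError(f"fold {fold} has fewer than 3 subjects")
        train = ~test
        design = np.column_stack([np.ones(train.sum()), x[train]])
        beta, *_ = np.linalg.lstsq(design, y[train], rcond=None)
        yhat = beta[0] + x[test] @ beta[1:]
        fold_r.append(float(np.corrcoef(yhat, y[test])[0, 1]))
    return CVResult(fold_r=fold_r, k=k, seed=seed, subset=subset)


def validate_model(results: PeriorbitalAgeResults, validation: pd.DataFrame) -> float:
    """Pearson r between predicted and actual age on an independent cohort."""
    if len(validation) < 10:
        raise ValueError("validation cohort must have at least 10 subjects")
    yhat = results.predict(validation)
    return float(np.corrcoef(yhat, validation["age"].to_numpy(dtype=float))[0, 1])


def expected_multiple_correlation(correlations) -> float:
    """Population multiple correlation of age on features that are
    conditionally independent given age.

    If feature i satisfies ``x_i = r_i z + sqrt(1 - r_i**2) e_i`` with
    independent noise, the squared multiple correlation of z on the x's is
    ``S / (1 + S)`` with ``S = sum r_i**2 / (1 - r_i**2)`` (Sherman-Morrison
    applied to the rank-one-plus-diagonal feature covariance). This is the
    large-n ceiling any linear age model can reach on such a cohort.
    """
    r = np.asarray(list(correlations), dtype=float)
    s = np.sum(r**2 / (1.0 - r**2))
    return float(np.sqrt(s / (1.0 + s)))
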