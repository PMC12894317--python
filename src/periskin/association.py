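"""Disease-history associations of the periorbital skin age.

For each self-reported disease flag (D1 heart disease, D2 high blood
pressure, D3 hyperlipidemia, D4 fatty liver, D5 kidney disease, D6
diabetes, D7 cancer, and the derived D0 = any of the seven) the package
fits maximum-likelihood logistic regressions of the flag on a predictor --
chronological age or periorbital skin age -- optionally adjusted for
covariates (chronological age, sun-exposure hours). Wald p-values across
the skin-age family are corrected with the Benjamini-Hochberg step-up FDR.
The seven binary indicators are additionally summarized by PCA on their
correlation matrix; the first principal component (PC1), sign-fixed so the
loading sum is positive, acts as a one-dimensional disease burden whose
Pearson correlation with skin age is the collective association measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

DISEASES = ("D0", "D1", "D2", "D3", "D4", "D5", "D6", "D7")

DISEASE_LABELS = {
    "D0": "History of any following diseases",
    "D1": "Heart diseases",
    "D2": "High blood pressure",
    "D3": "Hyperlipidemia",
    "D4": "Fatty liver",
    "D5": "Kidney diseases",
    "D6": "Diabetes",
    "D7": "Cancer",
}


@dataclass
class AssociationResult:
    """One logistic association: disease ~ predictor (+ covariates)."""

    disease: str
    predictor: str
    covariates: tuple[str, ...]
    beta: float
    se: float
    pvalue: float
    qvalue: float | None = None
    nobs: int = 0

    def __str__(self) -> str:
        cov = f" + {' + '.join(self.covariates)}" if self.covariates else ""
        q = f", q = {self.qvalue:.3g}" if self.qvalue is not None else ""
        return (
            f"{self.disease} ~ {self.predictor}{cov}: "
            f"beta = {self.beta:.3f} (SE {self.se:.3f}), p = {self.pvalue:.3g}{q}"
        )


@dataclass
class PCAResult:
    """PCA of the binary disease-history matrix (correlation convention)."""

    loadings: pd.DataFrame          # diseases x components
    scores: np.ndarray              # subjects x components
    explained_variance_ratio: np.ndarray
    dropped: tuple[str, ...] = ()   # zero-variance columns removed

    @property
    def pc1(self) -> np.ndarray:
        return self.scores[:, 0]

    @property
    def pc1_loadings(self) -> pd.Series:
        return self.loadings.iloc[:, 0]


def logistic_association(
    cohort: pd.DataFrame,
    disease: str,
    predictor: str,
    covariates: tuple[str, ...] = (),
    use_lrt: bool = False,
) -> AssociationResult:
    """Logistic regression of one disease flag on a predictor.

    Returns the predictor's log-odds coefficient with its Wald p-value (or
    a likelihood-ratio p-value when ``use_lrt``). The disease column must
    be binary with both classes present; quasi-complete separation raises
    with guidance rather than returning an unstable estimate.
    """
    for col in (disease, predictor, *covariates):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    y = cohort[disease].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"disease column {disease!r} must be binary 0/1")
    if y.min() == y.max():
        raise ValueError(
            f"disease {disease!r} has a single observed class; association undefined"
        )
    terms = [predictor, *covariates]
    x = sm.add_constant(cohort.loc[:, terms].to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, x).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            f"logistic fit for {disease} ~ {' + '.join(terms)} is separable "
            "(a predictor perfectly splits cases from controls); use a larger "
            "cohort, coarser predictor, or penalized estimation"
        ) from exc
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if use_lrt:
        if covariates:
            x0 = sm.add_constant(cohort.loc[:, list(covariates)].to_numpy(dtype=float))
        else:
            x0 = np.ones((len(y), 1))
        ll0 = sm.Logit(y, x0).fit(disp=False, maxiter=200).llf
        lr = 2.0 * (fit.llf - ll0)
        pvalue = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        pvalue = float(fit.pvalues[1])
    return AssociationResult(
        disease=disease,
        predictor=predictor,
        covariates=tuple(covariates),
        beta=beta,
        se=se,
        pvalue=pvalue,
        nobs=len(y),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family of tests.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values; ties get
    equal q-values and the map is order-preserving.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def disease_pca(disease_matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the binary disease indicators on the correlation convention.

    Columns are standardized to zero mean / unit variance (so the
    decomposition is of the correlation matrix of the indicators);
    zero-variance columns are dropped with a warning. PC1's sign is fixed
    so its loading sum is positive, making downstream correlations
    reproducible across seeds and platforms.
    """
    if len(disease_matrix) < 30:
        raise ValueError("need at least 30 subjects for disease PCA")
    x = disease_matrix.to_numpy(dtype=float)
    if np.all(x == 0):
        raise ValueError("all-zero disease matrix; PCA undefined")
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = tuple(disease_matrix.columns[~keep])
    if dropped:
        warnings.warn(f"dropping zero-variance disease column(s): {', '.join(dropped)}", stacklevel=2)
    if keep.sum() < 2:
        raise ValueError("need at least 2 diseases with nonzero variance")
    cols = list(disease_matrix.columns[keep])
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    n_comp = min(len(cols), len(z)) if n_components is None else n_components
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(z)
    loadings = pca.components_.T.copy()  # columns = components, unit norm

    # sign convention: PC1 loading sum positive (applied per component)
    for j in range(loadings.shape[1]):
        if loadings[:, j].sum() < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    return PCAResult(
        loadings=pd.DataFrame(
            loadings, index=cols, columns=[f"PC{j + 1}" for j in range(loadings.shape[1])]
        ),
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )


def pc1_correlation(pca_result: PCAResult, skin_ages) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between PC1 and skin age."""
    skin_ages = np.asarray(skin_ages, dtype=float)
    if skin_ages.shape[0] != pca_result.scores.shape[0]:
        raise ValueError(
            f"length mismatch: {pca_result.scores.shape[0]} PC1 scores vs "
            f"{skin_ages.shape[0]} skin ages"
        )
    r, p = stats.pearsonr(pca_result.pc1, skin_ages)
    return float(r), float(p)


def association_table(
    cohort: pd.DataFrame,
    skin_ages,
    covariates: tuple[str, ...] = (),
    fdr_family: str = "all",
) -> pd.DataFrame:
    """Disease-by-disease association report (one row per D0..D7).

    For every disease the table carries the logistic coefficient of
    chronological age and of periorbital skin age (each optionally adjusted
    by ``covariates``), the skin-age Wald p-value, and its BH-FDR q-value.
    ``fdr_family`` is ``"all"`` (the eight rows D0-D7, the printed-table
    convention) or ``"individual"`` (D1-D7 only; D0's q is then computed as
    a family of one).
    """
    if fdr_family not in ("all", "individual"):
        raise ValueError("fdr_family must be 'all' or 'individual'")
    work = cohort.copy()
    work["_skin_age"] = np.asarray(skin_ages, dtype=float)

    rows = []
    for code in DISEASES:
        res_age = logistic_association(work, code, "age", covariates=covariates)
        res_skin = logistic_association(work, code, "_skin_age", covariates=covariates)
        rows.append(
            {
                "code": code,
                "disease": DISEASE_LABELS[code],
                "beta_age": res_age.beta,
                "p_age": res_age.pvalue,
                "beta_skin_age": res_skin.beta,
                "p_skin_age": res_skin.pvalue,
            }
        )
    table = pd.DataFrame(rows)

    if fdr_family == "all":
        table["q_skin_age"] = bh_fdr(table["p_skin_age"])
    else:
        q = np.empty(len(table))
        individual = table["code"] != "D0"
        q[individual.to_numpy()] = bh_fdr(table.loc[individual, "p_skin_age"])
        q[~individual.to_numpy()] = table.loc[~individual, "p_skin_age"]
        table["q_skin_age"] = q
    return table


@dataclass
class DiseaseAssociationResults:
    """Fitted association study: per-disease table, PCA summary, diagnostics."""

    table: pd.DataFrame
    pca: PCAResult
    pc1_r: float
    pc1_p: float
    adjusted: dict[str, AssociationResult] = field(default_factory=dict)
    fdr_alpha: float = 0.05

    @property
    def significant(self) -> list[str]:
        """Disease codes whose skin-age q-value clears the FDR threshold."""
        hit = self.table["q_skin_age"] < self.fdr_alpha
        return list(self.table.loc[hit, "code"])

    def summary(self) -> str:
        lines = [
            "Periorbital skin age vs disease history",
            f"  n = {self.pca.scores.shape[0]} subjects, FDR alpha = {self.fdr_alpha}",
            "",
            f"  {'code':<5}{'beta(age)':>10}{'p(age)':>10}{'beta(skin)':>11}{'p(skin)':>10}{'q(skin)':>10}",
        ]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['code']:<5}{row['beta_age']:>10.3f}{row['p_age']:>10.2g}"
                f"{row['beta_skin_age']:>11.3f}{row['p_skin_age']:>10.2g}{row['q_skin_age']:>10.2g}"
            )
        lines.append("")
        lines.append(
            f"  significant at FDR < {self.fdr_alpha}: {', '.join(self.significant) or 'none'}"
        )
        lines.append(f"  PC1 (disease burden) vs skin age: r = {self.pc1_r:.3f}, p = {self.pc1_p:.3g}")
        for name, res in self.adjusted.items():
            lines.append(f"  D0 adjusted for {name}: beta = {res.beta:.3f}, p = {res.pvalue:.3g}")
        return "\n".join(lines)


class DiseaseAssociationStudy:
    """Model-object wrapper for the full association analysis.

    ``fit()`` runs the per-disease logistic screen with BH-FDR, the disease
    PCA with PC1 correlation, and the adjusted D0 analyses (chronological
    age; chronological age + sun-exposure hours when available).
    """

    def __init__(self, cohort: pd.DataFrame, skin_ages, fdr_family: str = "all") -> None:
        self.cohort = cohort
        self.skin_ages = np.asarray(skin_ages, dtype=float)
        self.fdr_family = fdr_family

    def fit(self, fdr_alpha: float = 0.05) -> DiseaseAssociationResults:
        table = association_table(self.cohort, self.skin_ages, fdr_family=self.fdr_family)
        individual = [c for c in DISEASES if c != "D0"]
        pca = disease_pca(self.cohort.loc[:, individual])
        r, p = pc1_correlation(pca, self.skin_ages)

        work = self.cohort.copy()
        work["_skin_age"] = self.skin_ages
        adjusted = {
            "age": logistic_association(work, "D0", "_skin_age", covariates=("age",))
        }
        if "sun_hours" in work.columns:
            adjusted["age + sun_hours"] = logistic_association(
                work, "D0", "_skin_age", covariates=("age", "sun_hours")
            )
        return DiseaseAssociationResults(
            table=table, pca=pca, pc1_r=r, pc1_p=p, adjusted=adjusted, fdr_alpha=fdr_alpha
        )
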