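"""Meta-regression of per-study effect sizes on study-level covariates.

For one gene, the per-study log2 fold-changes are regressed by ordinary
least squares on

* total sample size (cases + controls; a case-only variant is available),
* study age in years since deposition, and
* country of origin, one-hot encoded against the most frequent country.

Each numeric factor reports its coefficient's two-sided t-test p-value;
the multi-level country factor reports a single partial-F p-value.  An
inverse-variance weighted variant (WLS) is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .effect_size import EffectEstimate
from .formats_io import ExpressionStudy

logger = logging.getLogger(__name__)

SAMPLE_SIZE = "sample_size"
STUDY_AGE = "study_age"
COUNTRY = "country"
FACTORS = (SAMPLE_SIZE, STUDY_AGE, COUNTRY)


@dataclass
class MlrReport:
    """Per-gene meta-regression summary."""

    gene: str
    k: int
    coefficients: dict[str, float]
    factor_p: dict[str, float]
    r2: float
    dropped: list[str] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        rows = []
        for factor, p in self.factor_p.items():
            rows.append(
                {
                    "gene": self.gene,
                    "factor": factor,
                    "coefficient": self.coefficients.get(factor, np.nan),
                    "p_value": p,
                    "k": self.k,
                    "r2": self.r2,
                }
            )
        return rows


def study_metadata(studies: Sequence[ExpressionStudy]) -> pd.DataFrame:
    """Tabulate the covariates the regression uses, one row per study."""
    return pd.DataFrame(
        {
            "study_id": [s.study_id for s in studies],
            "n_control": [s.n_control for s in studies],
            "n_case": [s.n_case for s in studies],
            "country": [s.country for s in studies],
            "study_age": [s.study_age for s in studies],
        }
    ).set_index("study_id")


class EffectMetaRegression:
    """OLS model of one gene's study effects on study covariates.

    Parameters
    ----------
    effects : sequence of EffectEstimate
        The response: one LFC per study.
    metadata : pandas.DataFrame
        Indexed by study_id with columns n_control, n_case, country,
        study_age (see ``study_metadata``).
    sample_size : {"total", "case"}
        Whether the size covariate counts all samples or cases only.
    weighted : bool
        Inverse-variance WLS instead of OLS.
    """

    def __init__(
        self,
        effects: Sequence[EffectEstimate],
        metadata: pd.DataFrame,
        *,
        sample_size: str = "total",
        weighted: bool = False,
    ) -> None:
        if sample_size not in ("total", "case"):
            raise ValueError(f"unknown sample_size mode {sample_size!r}")
        self.gene = effects[0].gene if effects else "<none>"
        # sort for order invariance
        self.effects = sorted(effects, key=lambda e: e.study_id)
        self.metadata = metadata
        self.sample_size_mode = sample_size
        self.weighted = weighted
        self.dropped: list[str] = []

    def _design(self) -> tuple[pd.DataFrame, pd.Series, np.ndarray, list[str]]:
        ids = [e.study_id for e in self.effects]
        missing = [i for i in ids if i not in self.metadata.index]
        if missing:
            raise KeyError(f"metadata missing for studies {missing}")
        meta = self.metadata.loc[ids]
        y = pd.Series([e.lfc for e in self.effects], index=ids, name="lfc")
        if self.sample_size_mode == "total":
            size = meta["n_control"] + meta["n_case"]
        else:
            size = meta["n_case"]
        X = pd.DataFrame(
            {SAMPLE_SIZE: size.astype(float), STUDY_AGE: meta["study_age"].astype(float)},
            index=ids,
        )
        country_cols: list[str] = []
        countries = meta["country"].astype(str)
        if countries.nunique() >= 2:
            reference = countries.value_counts().index[0]
            for level in sorted(countries.unique()):
                if level == reference:
                    continue
                col = f"country[{level}]"
                X[col] = (countries == level).astype(float)
                country_cols.append(col)
        else:
            self.dropped.append(COUNTRY)
            logger.warning(
                "%s: single country %r; country factor dropped",
                self.gene, countries.iloc[0] if len(countries) else "",
            )
        X = sm.add_constant(X, prepend=True)
        # drop aliased columns (rank-deficient design)
        while np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            for col in reversed(X.columns.drop("const")):
                reduced = X.drop(columns=[col])
                if np.linalg.matrix_rank(reduced.to_numpy()) == np.linalg.matrix_rank(
                    X.to_numpy()
                ):
                    logger.warning("%s: aliased term %s dropped", self.gene, col)
                    self.dropped.append(col)
                    if col in country_cols:
                        country_cols.remove(col)
                    X = reduced
                    break
        weights = (
            np.array([1.0 / max(e.se, 1e-12) ** 2 for e in self.effects])
            if self.weighted
            else np.ones(len(self.effects))
        )
        return X, y, weights, country_cols

    def fit(self) -> MlrReport:
        X, y, weights, country_cols = self._design()
        k = len(y)
        if k < X.shape[1] + 1:
            raise ValueError(
                f"{self.gene}: k={k} studies cannot support {X.shape[1]} "
                f"terms; need at least {X.shape[1] + 1}"
            )
        model = sm.WLS(y, X, weights=weights) if self.weighted else sm.OLS(y, X)
        res = model.fit()
        coefficients = {term: float(res.params[term]) for term in X.columns}
        factor_p: dict[str, float] = {}
        for factor in (SAMPLE_SIZE, STUDY_AGE):
            if factor in res.pvalues:
                factor_p[factor] = float(res.pvalues[factor])
        if country_cols:
            # single partial-F p for the multi-level country factor
            restriction = np.zeros((len(country_cols), X.shape[1]))
            for i, col in enumerate(country_cols):
                restriction[i, X.columns.get_loc(col)] = 1.0
            ftest = res.f_test(restriction)
            factor_p[COUNTRY] = float(np.squeeze(ftest.pvalue))
        return MlrReport(
            gene=self.gene,
            k=k,
            coefficients=coefficients,
            factor_p=factor_p,
            r2=float(res.rsquared),
            dropped=list(self.dropped),
        )


def fit_mlr(
    effects: Sequence[EffectEstimate],
    metadata: pd.DataFrame | Sequence[ExpressionStudy],
    *,
    sample_size: str = "total",
    weighted: bool = False,
) -> MlrReport:
    """Fit the covariate meta-regression for one gene (see module docs)."""
    if not isinstance(metadata, pd.DataFrame):
        metadata = study_metadata(metadata)
    return EffectMetaRegression(
        effects, metadata, sample_size=sample_size, weighted=weighted
    ).fit()
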