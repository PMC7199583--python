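"""Pooling per-study log2 fold-changes across cohorts ("mega-analysis").

The term mega-analysis marks that effect sizes are computed from each
cohort's original expression matrix rather than lifted from publications;
the pooling itself is classical inverse-variance meta-analysis.

Fixed-effects model
    w_i = 1 / se_i^2,  pooled = sum(w_i * lfc_i) / sum(w_i),
    se_pooled = 1 / sqrt(sum(w_i)),  p from a two-sided z test.

Heterogeneity
    Q  = sum w_i (lfc_i - pooled_fixed)^2   (Cochran's Q, "total variance")
    df = k - 1                              ("expected between-study variance")
    ISq = 0 if Q <= df else 100 * (Q - df) / Q
    Qp = upper tail of chi-square(df) at Q.

Model selection follows the ISq clamp: ISq == 0 selects the fixed-effects
model, anything else the DerSimonian-Laird random-effects model with

    tau2 = max(0, (Q - df) / C),  C = sum(w_i) - sum(w_i^2) / sum(w_i)

and re-weighting w*_i = 1 / (se_i^2 + tau2).  Qp is reported but never
gates the choice.  Note the output field name ISq is kept for continuity
with the upstream worksheet convention although the formula is the
conventional between-study I^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .effect_size import EffectEstimate, substitute_degenerate_se

FIXED = "fixed"
RANDOM = "random"

_TINY_P = float(np.nextafter(0, 1))  # keep p in (0, 1]


@dataclass(frozen=True)
class Heterogeneity:
    """Cochran's Q, its degrees of freedom, the clamped ISq percentage and
    the chi-square upper-tail probability Qp."""

    Q: float
    df: int
    ISq: float
    Qp: float

    def __post_init__(self) -> None:
        assert self.Q >= 0 and self.df >= 0
        assert 0.0 <= self.ISq <= 100.0
        assert 0.0 <= self.Qp <= 1.0


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect for one gene with heterogeneity diagnostics."""

    gene: str
    k: int
    pooled_lfc: float
    pooled_se: float
    p_value: float
    model: str  # fixed | random
    tau2: float
    het: Heterogeneity | None

    def __post_init__(self) -> None:
        if self.model == FIXED and self.tau2 != 0.0:
            raise ValueError("fixed-effects result must have tau2 == 0")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")


class MegaAnalysis:
    """Inverse-variance pooling model over one gene's per-study effects.

    Parameters
    ----------
    effects : sequence of EffectEstimate
        Per-study log2 fold-changes with standard errors; zero standard
        errors are floored (see ``substitute_degenerate_se``) so weights
        stay finite.
    weighting : {"inverse-variance", "equal"}
        ``"equal"`` replaces the weights with ones (the pooled estimate
        becomes the plain mean); heterogeneity and tau2 still use the
        chosen weights.

    Examples
    --------
    >>> from megapath.effect_size import EffectEstimate
    >>> eff = [EffectEstimate("G", s, l, 1.0, 5, 5)
    ...        for s, l in [("a", 0.0), ("b", 2.0)]]
    >>> res = MegaAnalysis(eff).fit()
    >>> res.model, round(res.tau2, 6)
    ('random', 1.0)
    """

    def __init__(
        self,
        effects: Sequence[EffectEstimate],
        weighting: str = "inverse-variance",
    ) -> None:
        if not effects:
            raise ValueError("at least one effect estimate is required")
        genes = {e.gene for e in effects}
        if len(genes) > 1:
            raise ValueError(f"effects mix genes: {sorted(genes)}")
        if weighting not in ("inverse-variance", "equal"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.gene = effects[0].gene
        self.effects = substitute_degenerate_se(effects)
        self.weighting = weighting
        self._lfc = np.array([e.lfc for e in self.effects])
        if weighting == "equal":
            self._w = np.ones(len(self.effects))
        else:
            self._w = np.array([1.0 / e.se**2 for e in self.effects])

    @property
    def k(self) -> int:
        return len(self.effects)

    # -- building blocks ----------------------------------------------------

    def _pool(self, weights: np.ndarray) -> tuple[float, float, float]:
        pooled = float(np.sum(weights * self._lfc) / np.sum(weights))
        se = float(1.0 / np.sqrt(np.sum(weights)))
        z = pooled / se
        p = max(2.0 * stats.norm.sf(abs(z)), _TINY_P)
        return pooled, se, p

    def heterogeneity(self) -> Heterogeneity:
        """Q, df, the clamped ISq and Qp; requires k >= 2."""
        if self.k < 2:
            raise ValueError("heterogeneity needs at least two studies")
        pooled, _, _ = self._pool(self._w)
        Q = float(np.sum(self._w * (self._lfc - pooled) ** 2))
        df = self.k - 1
        ISq = 0.0 if Q <= df else 100.0 * (Q - df) / Q
        Qp = float(stats.chi2.sf(Q, df))
        return Heterogeneity(Q=Q, df=df, ISq=ISq, Qp=Qp)

    def tau2_dl(self, het: Heterogeneity | None = None) -> float:
        """DerSimonian-Laird moment estimate of the between-study variance."""
        het = het or self.heterogeneity()
        s1 = float(np.sum(self._w))
        s2 = float(np.sum(self._w**2))
        C = s1 - s2 / s1
        if C <= 0:
            return 0.0
        return max(0.0, (het.Q - het.df) / C)

    # -- fitting ------------------------------------------------------------

    def fit(self, method: str = "auto") -> "MegaAnalysisResults":
        """Pool the effects.

        ``method="fixed"`` and ``method="random"`` force a model;
        ``"auto"`` applies the selection rule: compute heterogeneity, and
        take the fixed-effects model exactly when ISq clamps to zero
        (Q <= df), the random-effects model otherwise.  With a single
        study the fixed model is used and heterogeneity left undefined.
        """
        if method not in ("auto", FIXED, RANDOM):
            raise ValueError(f"unknown method {method!r}")
        het = self.heterogeneity() if self.k >= 2 else None
        if method == "auto":
            if het is None:
                method = FIXED
            else:
                method = FIXED if het.ISq == 0.0 else RANDOM
        if method == RANDOM and self.k < 2:
            raise ValueError("random-effects model needs at least two studies")

        if method == FIXED:
            tau2 = 0.0
            pooled, se, p = self._pool(self._w)
        else:
            tau2 = self.tau2_dl(het)
            se_i = np.array([e.se for e in self.effects])
            w_star = 1.0 / (se_i**2 + tau2)
            pooled, se, p = self._pool(w_star)

        result = MetaResult(
            gene=self.gene,
            k=self.k,
            pooled_lfc=pooled,
            pooled_se=se,
            p_value=p,
            model=method,
            tau2=tau2,
            het=het,
        )
        return MegaAnalysisResults(self, result)


class MegaAnalysisResults:
    """Fitted pooling results; attribute access mirrors ``MetaResult``."""

    def __init__(self, model: MegaAnalysis, result: MetaResult) -> None:
        self.model_obj = model
        self.result = result

    def __getattr__(self, name):
        return getattr(self.result, name)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        r = self.result
        return (r.pooled_lfc - z * r.pooled_se, r.pooled_lfc + z * r.pooled_se)

    def summary(self) -> str:
        r = self.result
        lo, hi = self.conf_int()
        lines = [
            f"Mega-analysis: {r.gene}",
            "=" * 40,
            f"studies pooled (k)     {r.k:>12d}",
            f"model                  {r.model:>12s}",
            f"pooled LFC             {r.pooled_lfc:>12.4f}",
            f"pooled SE              {r.pooled_se:>12.4f}",
            f"95% CI           [{lo:>9.4f}, {hi:>9.4f}]",
            f"p-value (z)            {r.p_value:>12.3e}",
            f"tau2                   {r.tau2:>12.4f}",
        ]
        if r.het is not None:
            lines += [
                f"Q                      {r.het.Q:>12.4f}",
                f"df                     {r.het.df:>12d}",
                f"ISq (%)                {r.het.ISq:>12.2f}",
                f"Q-p                    {r.het.Qp:>12.4f}",
            ]
        else:
            lines.append("heterogeneity     undefined (k = 1)")
        return "\n".join(lines)

    def to_row(self) -> dict:
        """Flat mapping for the mega-analysis worksheet analogue."""
        r = self.result
        row = {
            "gene": r.gene,
            "k": r.k,
            "pooled_LFC": r.pooled_lfc,
            "SE": r.pooled_se,
            "p_value": r.p_value,
            "model": r.model,
            "tau2": r.tau2,
        }
        if r.het is not None:
            row.update(Q=r.het.Q, df=r.het.df, ISq=r.het.ISq, Qp=r.het.Qp)
        else:
            row.update(Q=np.nan, df=np.nan, ISq=np.nan, Qp=np.nan)
        return row


# ---------------------------------------------------------------------------
# functional surface


def fixed_effects(effects: Sequence[EffectEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling."""
    return MegaAnalysis(effects).fit(method=FIXED).result


def random_effects(effects: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling."""
    return MegaAnalysis(effects).fit(method=RANDOM).result


def heterogeneity(effects: Sequence[EffectEstimate]) -> Heterogeneity:
    """Cochran's Q, df, clamped ISq and Qp for k >= 2 effects."""
    return MegaAnalysis(effects).heterogeneity()


def meta_analyze(effects: Sequence[EffectEstimate]) -> MetaResult:
    """Pool with the ISq-based fixed/random selection rule."""
    return MegaAnalysis(effects).fit(method="auto").result


def meta_analyze_genes(
    effects_by_gene: dict[str, Sequence[EffectEstimate]]
) -> dict[str, MetaResult]:
    """Convenience: pool every gene in a mapping gene -> effect list."""
    return {g: meta_analyze(e) for g, e in effects_by_gene.items() if e}
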