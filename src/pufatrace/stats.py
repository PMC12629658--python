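"""Statistical layer: two-factor OLS on total conversion efficiency,
small-sample AIC model selection, and the paired corrected-vs-uncorrected
comparison.

The design is a balanced two-factor layout (species × pathway) with total
CE as the response.  Both factors are treatment-coded against the
alphabetically first level, so with levels {barn_swallow, purple_martin} and
{omega3, omega6} the reported coefficients are the purple-martin offset and
the omega-6 offset.

Model selection uses AICc with the Gaussian log-likelihood written out in
full,

    AICc = n·ln(2π) + n·ln(RSS/n) + n + 2k + 2k(k+1)/(n − k − 1),

where k counts the mean parameters **plus** the residual variance
(k = p + 1).  Conventions differ between software packages on both the
constant terms and whether σ² counts as a parameter; this one matches R's
``AICc`` as used by MuMIn.

Because a balanced OLS fit depends on the data only through cell means and
within-cell sums of squares, the same model can be fit *exactly* from
printed group summaries (mean ± SD, n): :func:`lm_from_cell_summaries`
constructs any raw realization of the summaries and fits it, and provably
agrees with :func:`fit_lm` on real data having those summaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .pathways import CellSummary, ConversionProfile


@dataclass(frozen=True)
class LMResult:
    """Ordinary least-squares fit summary."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    r_squared: float
    rss: float
    aicc: float
    n_obs: int
    n_params: int  # mean parameters p (residual variance excluded)
    formula: str

    def report(self) -> str:
        """Human-readable coefficient table plus fit statistics."""
        tab = pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )
        lines = [
            f"model: {self.formula}",
            tab.to_string(float_format=lambda x: f"{x:.4f}"),
            f"residual df = {self.df_resid}   R^2 = {self.r_squared:.4f}   "
            f"RSS = {self.rss:.4f}   AICc = {self.aicc:.2f}",
        ]
        return "\n".join(lines)


def aicc(rss: float, n_obs: int, n_mean_params: int) -> float:
    """Small-sample AIC; k = mean parameters + 1 for the residual variance."""
    k = n_mean_params + 1
    if n_obs - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n_obs} too small for k={k} parameters")
    aic = n_obs * math.log(2 * math.pi) + n_obs * math.log(rss / n_obs) + n_obs + 2 * k
    return aic + 2 * k * (k + 1) / (n_obs - k - 1)


def fit_lm(records, with_interaction: bool = False) -> LMResult:
    """OLS of total CE on species and pathway (treatment coding).

    Parameters
    ----------
    records:
        DataFrame with columns ``total_ce``, ``species``, ``pathway``, or an
        iterable of ``(total_ce, species, pathway)`` tuples, or a list of
        :class:`~pufatrace.pathways.ConversionProfile`.
    with_interaction:
        Include the species:pathway interaction.
    """
    df = _as_frame(records)
    for col in ("species", "pathway"):
        empty = df.groupby(col, observed=True)["total_ce"].count()
        if (empty < 1).any() or empty.size < 2:
            raise ValueError(f"factor {col!r} needs at least one record in each of >=2 levels")
    formula = "total_ce ~ species * pathway" if with_interaction else "total_ce ~ species + pathway"
    res = smf.ols(formula, df).fit()
    if np.linalg.matrix_rank(res.model.exog) < res.model.exog.shape[1]:
        counts = df.groupby(["species", "pathway"], observed=True).size()
        raise ValueError(f"design matrix is rank deficient; cell counts:\n{counts}")
    p = res.model.exog.shape[1]
    rsq = float(res.rsquared)
    if not math.isfinite(rsq):  # constant response: zero total SS
        rsq = 0.0
    return LMResult(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        df_resid=int(res.df_resid),
        r_squared=rsq,
        rss=float(res.ssr),
        aicc=aicc(float(res.ssr), int(res.nobs), p),
        n_obs=int(res.nobs),
        n_params=p,
        formula=formula,
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records[["total_ce", "species", "pathway"]].copy()
    if records and isinstance(records[0], ConversionProfile):
        return pd.DataFrame(
            {
                "total_ce": [p.total_ce for p in records],
                "species": [p.species for p in records],
                "pathway": [p.pathway.name for p in records],
            }
        )
    return pd.DataFrame(records, columns=["total_ce", "species", "pathway"])


def realize_cell(mean: float, sd: float, n: int) -> np.ndarray:
    """A raw sample with exactly the given mean and sample SD (n−1).

    Any such realization yields the identical balanced OLS fit, since the
    fit depends on the data only through cell means and within-cell SS.
    """
    if n < 2:
        raise ValueError("need n >= 2 to realize a standard deviation")
    z = np.arange(n, dtype=float)
    z -= z.mean()
    z /= z.std(ddof=1)
    return mean + sd * z


def lm_from_cell_summaries(cells: list[CellSummary], with_interaction: bool = False) -> LMResult:
    """Exact OLS reconstruction from four balanced 2×2 group summaries."""
    if len(cells) != 4:
        raise ValueError(f"expected the 4 cells of a 2x2 species x pathway design, got {len(cells)}")
    if len({(c.species, c.pathway) for c in cells}) != 4:
        raise ValueError("duplicate (species, pathway) cells")
    if len({c.species for c in cells}) != 2 or len({c.pathway for c in cells}) != 2:
        raise ValueError("cells must form a full 2x2 species x pathway cross")
    ns = {c.n for c in cells}
    if len(ns) != 1:
        raise ValueError(f"unbalanced design not supported: cell sizes {sorted(ns)}")
    rows = []
    for c in cells:
        for v in realize_cell(c.mean, c.sd, c.n):
            rows.append((v, c.species, c.pathway))
    return fit_lm(rows, with_interaction=with_interaction)


@dataclass(frozen=True)
class ModelSelection:
    full: LMResult
    reduced: LMResult
    selected: LMResult
    delta_aicc: float  # full - reduced


def aicc_compare(full: LMResult, reduced: LMResult) -> ModelSelection:
    """Pick the lower-AICc model; ties go to the model with fewer parameters."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("models were fit to different numbers of observations")
    d = full.aicc - reduced.aicc
    if d < 0:
        selected = full
    elif d > 0:
        selected = reduced
    else:
        selected = reduced if reduced.n_params <= full.n_params else full
    return ModelSelection(full, reduced, selected, d)


def paired_t(corrected, uncorrected) -> tuple[float, int, float]:
    """Paired t-test on per-bird totals; returns (t, df, p).

    Zero-variance differences with a nonzero mean yield an infinite t with
    a warning; identical vectors yield t = 0.
    """
    a = np.asarray(corrected, dtype=float)
    b = np.asarray(uncorrected, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("corrected and uncorrected must be equal-length 1-d vectors")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    df = a.size - 1
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, df, 1.0
        warnings.warn("differences have zero variance but nonzero mean; t is infinite")
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = sps.ttest_rel(a, b)
    return float(t), df, float(p)
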