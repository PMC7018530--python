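"""Per-taxon diversity by the unique-sequence ratio and log-log regression.

For each taxon (usually a phylum) the number of unique sequences is
regressed on the number of total observations on log10 axes; the fitted
line is the average level of diversity, and a taxon's residual relative to
the 95% confidence band of the mean response classifies it as more diverse
(above the line), average (on the line), or less diverse (below).
The unique/total ratio itself is the headline per-taxon statistic
(e.g. 1109/2222 -> 0.50 for the Archaea vs 0.31 for the Bacteria).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

ABOVE = "above_line"
ON = "on_line"
BELOW = "below_line"


@dataclass
class TaxonDiversity:
    taxon: str
    n_total: int
    n_unique: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError(f"{self.taxon}: n_total must be positive")
        if not 0 < self.n_unique <= self.n_total:
            raise ValueError(
                f"{self.taxon}: need 0 < n_unique <= n_total "
                f"(got {self.n_unique}/{self.n_total})"
            )

    @property
    def ratio(self) -> float:
        return self.n_unique / self.n_total

    @property
    def log_total(self) -> float:
        return math.log10(self.n_total)

    @property
    def log_unique(self) -> float:
        return math.log10(self.n_unique)


@dataclass
class RegressionFit:
    """OLS of log10 unique on log10 total with a mean-response band."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float           # two-sided t-test on the slope
    _model: object = None    # fitted statsmodels results, for the band

    def predict(self, log_total: float) -> float:
        return self.intercept + self.slope * log_total

    def band_half_width(self, log_total: float, alpha: float = 0.05) -> float:
        """Half-width of the pointwise (1-alpha) CI of the mean response."""
        if self._model is None:
            raise ValueError("fit carries no model; band unavailable")
        exog = np.array([[1.0, float(log_total)]])
        pred = self._model.get_prediction(exog)
        frame = pred.summary_frame(alpha=alpha)
        return float(frame["mean_ci_upper"].iloc[0] - frame["mean"].iloc[0])


def unique_ratio(n_unique: int, n_total: int) -> float:
    """Unique-sequence ratio n_unique / n_total (display-round to 2 decimals)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 < n_unique <= n_total:
        raise ValueError("need 0 < n_unique <= n_total")
    return n_unique / n_total


def fit_loglog(points: list[TaxonDiversity]) -> RegressionFit:
    """OLS regression of log10(unique) on log10(total) across taxa.

    Needs at least 3 taxa with a non-degenerate abscissa.  r_squared equals
    the squared Pearson correlation of the two log vectors; the p-value is
    the two-sided t-test on the slope.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 taxa for the regression")
    x = np.array([p.log_total for p in points])
    y = np.array([p.log_unique for p in points])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate abscissa: all n_total equal")
    exog = sm.add_constant(x)
    res = sm.OLS(y, exog).fit()
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        _model=res,
    )


def classify_diversity(point: TaxonDiversity, fit: RegressionFit,
                       alpha: float = 0.05) -> str:
    """Place one taxon relative to the regression confidence band.

    Above the band means more diverse than the average trend, below means
    less, inside means average-level diversity.
    """
    pred = fit.predict(point.log_total)
    half = fit.band_half_width(point.log_total, alpha=alpha)
    if point.log_unique > pred + half:
        return ABOVE
    if point.log_unique < pred - half:
        return BELOW
    return ON


def read_counts_table(path) -> list[TaxonDiversity]:
    """Read a per-taxon counts TSV with columns taxon, n_total, n_unique."""
    df = pd.read_csv(path, sep="\t")
    required = {"taxon", "n_total", "n_unique"}
    if not required.issubset(df.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    return [TaxonDiversity(taxon=str(r.taxon), n_total=int(r.n_total),
                           n_unique=int(r.n_unique))
            for r in df.itertuples(index=False)]


def diversity_table(points: list[TaxonDiversity],
                    fit: RegressionFit) -> pd.DataFrame:
    """Annotated per-taxon table: counts, ratio, residual, classification."""
    rows = []
    for p in points:
        pred = fit.predict(p.log_total)
        rows.append({
            "taxon": p.taxon,
            "n_total": p.n_total,
            "n_unique": p.n_unique,
            "ratio": round(p.ratio, 2),
            "log_total": p.log_total,
            "log_unique": p.log_unique,
            "residual": p.log_unique - pred,
            "classification": classify_diversity(p, fit),
        })
    return pd.DataFrame(rows)
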