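"""Two-part price-elasticity estimation from smoker microdata.

The demand response is split into an extensive margin — whether a person
smokes at all — and an intensive margin — how much continuing smokers
smoke:

* **prevalence elasticity** (per region): a probit of smoking status on the
  log state-average price with region-specific price slopes plus individual
  controls; the elasticity is the average marginal effect of log price
  divided by the region's sample prevalence;
* **conditional elasticity** (per region x price category): a single OLS
  regression of log cigarettes/day on the log state-average cell price
  fully interacted with region and price category, with cell intercepts,
  the same controls and heteroskedasticity-robust (HC1) standard errors.

To blunt the endogeneity of self-reported prices (smokers who cut back
switch to cheaper brands), the individually reported price is replaced by
the state-average price throughout: the state mean of the (state, PC) cell
means for the prevalence part, the (state, PC) cell mean for the
conditional part. The total elasticity is the sum of the two margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .market import LEGAL_PCS, PCS
from .states import REGIONS

CONTROLS = ["age", "female", "log_income", "education"]


class SeparationError(ValueError):
    """Perfect separation: the probit likelihood is unbounded."""


@dataclass
class ElasticityTable:
    """Point estimates (and standard errors) of the two-part elasticities.

    ``total(r, k) = prevalence(r) + conditional(r, k)`` by construction.
    """

    prevalence: dict[str, float]
    conditional: dict[tuple[str, int], float]
    prevalence_se: dict[str, float] | None = None
    conditional_se: dict[tuple[str, int], float] | None = None

    @property
    def total(self) -> dict[tuple[str, int], float]:
        return {
            (r, k): self.prevalence[r] + c for (r, k), c in self.conditional.items()
        }

    def regions(self) -> list[str]:
        return [r for r in REGIONS if r in self.prevalence]

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: one row per region, prevalence plus total per PC."""
        rows = {}
        for r in self.regions():
            row = {"prevalence": self.prevalence[r]}
            for k in sorted({k for (_, k) in self.conditional}):
                if (r, k) in self.conditional:
                    row[f"total_pc{k}"] = self.prevalence[r] + self.conditional[(r, k)]
            rows[r] = row
        return pd.DataFrame.from_dict(rows, orient="index").rename_axis("region")

    def to_csv(self, path) -> None:
        recs = []
        for r in self.regions():
            se = (self.prevalence_se or {}).get(r, np.nan)
            recs.append(("prevalence", r, "", self.prevalence[r], se))
        for (r, k), v in sorted(self.conditional.items(), key=lambda x: (x[0][1], x[0][0])):
            se = (self.conditional_se or {}).get((r, k), np.nan)
            recs.append(("conditional", r, k, v, se))
        pd.DataFrame(
            recs, columns=["component", "region", "pc", "estimate", "se"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ElasticityTable":
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        prev, prev_se, cond, cond_se = {}, {}, {}, {}
        for _, row in df.iterrows():
            if row["component"] == "prevalence":
                prev[row["region"]] = float(row["estimate"])
                prev_se[row["region"]] = float(row["se"])
            else:
                key = (row["region"], int(row["pc"]))
                cond[key] = float(row["estimate"])
                cond_se[key] = float(row["se"])
        return cls(prev, cond, prev_se, cond_se)


def combine(
    prevalence: dict[str, float], conditional: dict[tuple[str, int], float]
) -> ElasticityTable:
    """Assemble the table from separately estimated margins; the total is
    their elementwise sum."""
    missing = {r for (r, _) in conditional} - set(prevalence)
    if missing:
        raise ValueError(f"no prevalence elasticity for region(s): {sorted(missing)}")
    return ElasticityTable(dict(prevalence), dict(conditional))


# -- price substitution -------------------------------------------------------

def attach_state_prices(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``log_state_price`` (state-level price index,
    the unweighted mean of the state's PC cell-mean prices) on every record
    and ``log_cell_price`` (log of the (state, PC) mean price) on smokers."""
    out = records.copy()
    smk = out[out["smokes"].astype(bool)]
    cell_mean = smk.groupby(["state", "price_category"])["price_paid"].mean()
    state_index = cell_mean.groupby(level="state").mean()
    out["log_state_price"] = np.log(out["state"].map(state_index))
    key = pd.MultiIndex.from_frame(out[["state", "price_category"]])
    out["log_cell_price"] = np.log(pd.Series(cell_mean.reindex(key).values, index=out.index))
    out["log_income"] = np.log(out["income"])
    return out


def _prepared(records: pd.DataFrame) -> pd.DataFrame:
    if "log_state_price" not in records.columns:
        return attach_state_prices(records)
    return records


# -- extensive margin ---------------------------------------------------------

def estimate_prevalence(
    records: pd.DataFrame,
) -> tuple[dict[str, float], dict[str, float], sm.discrete.discrete_model.BinaryResultsWrapper]:
    """Probit prevalence elasticities per region.

    Returns ``(elasticity, se, probit_results)``. The elasticity of region
    ``r`` is the sample-average marginal effect of log price for its
    respondents divided by the region's smoking prevalence.
    """
    df = _prepared(records)
    regions = [r for r in REGIONS if r in set(df["region"])]
    for r in regions:
        status = df.loc[df["region"] == r, "smokes"].astype(bool)
        if status.all():
            raise ValueError(f"region {r} has no non-smokers; prevalence margin undefined")
        if not status.any():
            raise ValueError(f"region {r} has no smokers; prevalence margin undefined")

    y = df["smokes"].astype(float).to_numpy()
    X = pd.DataFrame(index=df.index)
    for r in regions:
        X[f"region[{r}]"] = (df["region"] == r).astype(float)
        X[f"logprice[{r}]"] = X[f"region[{r}]"] * df["log_state_price"]
    for c in CONTROLS:
        X[c] = df[c].astype(float)

    model = sm.Probit(y, X.to_numpy())
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"probit failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.bse)):
        raise SeparationError(
            "probit standard errors are not finite — likely perfect separation; "
            "check that every region mixes smokers and non-smokers"
        )
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)

    xb = X.to_numpy() @ res.params
    phi = stats.norm.pdf(xb)
    elast, se = {}, {}
    for r in regions:
        mask = (df["region"] == r).to_numpy()
        prev = float(y[mask].mean())
        ame = float(params[f"logprice[{r}]"] * phi[mask].mean())
        elast[r] = ame / prev
        se[r] = float(bse[f"logprice[{r}]"] * phi[mask].mean() / prev)
    return elast, se, res


# -- intensive margin ---------------------------------------------------------

def estimate_conditional(
    records: pd.DataFrame,
) -> tuple[dict[tuple[str, int], float], dict[tuple[str, int], float], sm.regression.linear_model.RegressionResultsWrapper]:
    """Conditional (intensity) elasticities per (region, PC) from one OLS
    regression with cell intercepts and cell-specific log-price slopes,
    HC1-robust standard errors.
    """
    df = _prepared(records)
    smk = df[df["smokes"].astype(bool)].copy()
    smk = smk[np.isfinite(smk["log_cell_price"])]
    smk["pc"] = smk["price_category"].astype(int)

    cells = sorted(
        {(r, k) for r, k in zip(smk["region"], smk["pc"])},
        key=lambda x: (x[1], x[0]),
    )
    for r, k in cells:
        sub = smk[(smk["region"] == r) & (smk["pc"] == k)]
        if sub["log_cell_price"].nunique() < 2:
            raise ValueError(
                f"cell ({r}, PC{k}) has fewer than 2 distinct state-average "
                "prices; its conditional elasticity is unidentified"
            )

    y = np.log(smk["cigarettes_per_day"].astype(float).to_numpy())
    X = pd.DataFrame(index=smk.index)
    for r, k in cells:
        d = ((smk["region"] == r) & (smk["pc"] == k)).astype(float)
        X[f"cell[{r},{k}]"] = d
        X[f"slope[{r},{k}]"] = d * smk["log_cell_price"]
    for c in CONTROLS + ["years_smoking"]:
        X[c] = smk[c].astype(float)

    arr = X.to_numpy()
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # small R diagonal entries of the QR factor flag the collinear columns
        rdiag = np.abs(np.diag(np.linalg.qr(arr, mode="r")))
        bad = [X.columns[i] for i in np.where(rdiag < 1e-8 * rdiag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear terms: {bad or 'unknown'}")

    res = sm.OLS(y, arr).fit(cov_type="HC1")
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    est = {(r, k): float(params[f"slope[{r},{k}]"]) for r, k in cells}
    se = {(r, k): float(bse[f"slope[{r},{k}]"]) for r, k in cells}
    return est, se, res


# -- model / results facade ---------------------------------------------------

class TwoPartDemandModel:
    """Two-part cigarette demand model on survey microdata.

    Parameters
    ----------
    records : DataFrame
        Survey rows with the documented columns (see
        :data:`cigtax.survey.RECORD_COLUMNS`); weights are currently only
        supported when constant.
    legal_only : bool
        If True, drop PC1 smokers from the conditional margin.
    """

    def __init__(self, records: pd.DataFrame, legal_only: bool = False):
        self.records = _prepared(records)
        self.legal_only = legal_only

    @classmethod
    def from_csv(cls, path, **kw) -> "TwoPartDemandModel":
        return cls(pd.read_csv(path), **kw)

    def fit(self) -> "ElasticityResults":
        prev, prev_se, probit_res = estimate_prevalence(self.records)
        rec = self.records
        if self.legal_only:
            rec = rec[~(rec["smokes"].astype(bool) & (rec["price_category"] == 1))]
        cond, cond_se, ols_res = estimate_conditional(rec)
        table = ElasticityTable(prev, cond, prev_se, cond_se)
        return ElasticityResults(self, table, probit_res, ols_res)


class ElasticityResults:
    """Fitted two-part demand elasticities with the underlying regressions."""

    def __init__(self, model, table: ElasticityTable, probit_results, ols_results):
        self.model = model
        self.table = table
        self.probit_results = probit_results
        self.ols_results = ols_results

    @property
    def prevalence(self):
        return self.table.prevalence

    @property
    def conditional(self):
        return self.table.conditional

    @property
    def total(self):
        return self.table.total

    def summary(self) -> str:
        lines = ["Two-part demand model: price elasticities", ""]
        frame = self.table.to_frame()
        lines.append(frame.round(3).to_string())
        lines.append("")
        lines.append("prevalence SE: " + ", ".join(
            f"{r}={s:.3f}" for r, s in (self.table.prevalence_se or {}).items()
        ))
        return "\n".join(lines)
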