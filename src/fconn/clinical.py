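"""Group comparison of clinical summaries and covariate-adjusted
edge-clinical associations.

``ttest_from_summary`` reproduces independent-sample t-tests from printed
(mean, sd, n) summaries using the pooled-variance (Student) form, which
matches reported demographic tables; ``chisq_2x2`` is the Pearson
chi-square without continuity correction for the sex contingency table.

``adjusted_association`` fits, within the patient group only,

    edge_z ~ intercept + clinical_variable + age + sex + education

by OLS and reports the slope, t and p of the clinical variable — the
general linear model used to ask whether edge strength tracks glycaemia
(FPG, 2hPG, HbA1c), insulin resistance (HOMA-IR) or cognition (MoCA)
after removing age / sex / education effects.  P-values are uncorrected
by default; pass ``fdr=True`` to ``associate_edges`` for BH adjustment.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class AssociationResult:
    edge: str
    variable: str
    coefficient: float
    se: float
    t: float
    p: float
    n: int
    df_resid: int

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        half = stats.t.ppf(0.5 + level / 2, self.df_resid) * self.se
        return self.coefficient - half, self.coefficient + half


def load_clinical_table() -> pd.DataFrame:
    """Bundled demographic/clinical summary table (two groups of
    mean / sd / n per variable, with the originally printed p-values)."""
    ref = importlib.resources.files("fconn.data") / "table1_clinical.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def ttest_from_summary(mean_a: float, sd_a: float, n_a: int,
                       mean_b: float, sd_b: float, n_b: int,
                       ) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summaries.

    Returns (t, df, two-sided p) with df = n_a + n_b - 2.  Degenerate
    zero-variance summaries give p = 1 for equal means and p = 0
    otherwise.
    """
    if min(n_a, n_b) < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("sd must be nonnegative")
    df = n_a + n_b - 2
    if sd_a == 0 and sd_b == 0:
        return (0.0, df, 1.0) if mean_a == mean_b else (np.inf, df, 0.0)
    t, p = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                      equal_var=True)
    return float(t), df, float(p)


def summary_table_tests(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Run :func:`ttest_from_summary` over every row of a clinical summary
    table (defaults to the bundled one)."""
    if table is None:
        table = load_clinical_table()
    rows = []
    for _, r in table.iterrows():
        t, df, p = ttest_from_summary(r["mean_t2d"], r["sd_t2d"], int(r["n_t2d"]),
                                      r["mean_control"], r["sd_control"],
                                      int(r["n_control"]))
        rows.append({"variable": r["variable"], "t": t, "df": df, "p": p})
    out = pd.DataFrame(rows)
    if "p_printed" in table.columns:
        out["p_printed"] = table["p_printed"].to_numpy()
    return out


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) for a 2x2
    count table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def adjusted_association(edge_values, variable, age, sex, education,
                         edge: str = "", variable_name: str = "",
                         ) -> AssociationResult:
    """OLS edge ~ 1 + variable + age + sex + education; slope test for
    the clinical variable.  Sex is coded 0/1 (any consistent binary
    coding gives identical tests for the other terms).  Rows with any
    missing value are dropped listwise."""
    df = pd.DataFrame({
        "edge": np.asarray(edge_values, dtype=float),
        "variable": np.asarray(variable, dtype=float),
        "age": np.asarray(age, dtype=float),
        "sex": np.asarray(sex, dtype=float),
        "education": np.asarray(education, dtype=float),
    }).dropna()
    # drop covariates with no variation so the fit stays full rank; the
    # clinical variable itself is always kept
    keep = ["variable"] + [c for c in ("age", "sex", "education")
                           if df[c].nunique() > 1]
    design = sm.add_constant(df[keep], has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(f"collinear design columns among {list(design.columns)}")
    fit = sm.OLS(df["edge"], design).fit()
    return AssociationResult(
        edge=edge, variable=variable_name,
        coefficient=float(fit.params["variable"]),
        se=float(fit.bse["variable"]),
        t=float(fit.tvalues["variable"]), p=float(fit.pvalues["variable"]),
        n=len(df), df_resid=int(fit.df_resid))


def associate_edges(edge_table: pd.DataFrame, covariates: pd.DataFrame,
                    variables: list[str], fdr: bool = False) -> pd.DataFrame:
    """Adjusted association of every edge column against every clinical
    variable.  ``edge_table`` columns are edge names ('A--B'); the
    covariate table must carry age / sex / education plus the variables.
    """
    rows = []
    for var in variables:
        for edge in edge_table.columns:
            res = adjusted_association(
                edge_table[edge], covariates[var], covariates["age"],
                covariates["sex"], covariates["education"],
                edge=edge, variable_name=var)
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
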