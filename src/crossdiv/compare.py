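"""Distribution comparisons, correlations, and per-taxon linear models.

Implements the statistical toolkit used downstream of standardization:
two-tailed Mann-Whitney U tests between divergence distributions, Pearson
and Spearman correlations between levels, and the three multiple linear
regressions per taxon in which each level's divergence is predicted from
the other two.

Group-ordering summaries report medians — the statistic a boxplot
displays.  Pooled z-score group means are constrained to sum to zero
within each pooling, so means cannot express patterns like "one taxon
highest at every level"; medians of the residually skewed groups can.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, DegenerateInputError, SingularFitError
from .metrics import LEVELS


@dataclass(frozen=True)
class UTestResult:
    """Two-tailed Mann-Whitney U test outcome."""

    u: float            # min(U1, U2), the conventionally reported statistic
    p: float
    n1: int
    n2: int
    method: str         # "exact" or "normal-approximation"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    rho: float
    p_r: float
    p_rho: float
    n: int


@dataclass(frozen=True)
class LinearModelFit:
    """One OLS rotation: a response level regressed on the other two."""

    taxon: str
    response: str
    features: tuple[str, str]
    coefficients: tuple[float, float]
    std_errors: tuple[float, float]
    t_values: tuple[float, float]
    p_values: tuple[float, float]
    intercept: float
    r_squared: float


def mann_whitney_u(x, y, exact_max: int = 8) -> UTestResult:
    """Two-tailed Mann-Whitney U test.

    The exact null distribution (full enumeration over rank assignments)
    is used when ``max(n1, n2) <= exact_max`` and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  The two-tailed p doubles the one-tailed p, capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ComputationError("Mann-Whitney test requires nonempty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (max(x.size, y.size) <= exact_max) and not has_ties
    method = "exact" if use_exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    return UTestResult(
        u=min(u1, u2),
        p=min(1.0, float(res.pvalue)),
        n1=int(x.size),
        n2=int(y.size),
        method="exact" if use_exact else "normal-approximation",
    )


def correlations(x, y) -> CorrelationResult:
    """Pearson r and Spearman rho with two-sided p-values (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ComputationError("samples differ in length")
    if x.size < 3:
        raise ComputationError("correlation requires n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in correlation input")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        r=float(pr.statistic),
        rho=float(sr.statistic),
        p_r=float(pr.pvalue),
        p_rho=float(sr.pvalue),
        n=int(x.size),
    )


def fit_divergence_models(
    z_table: pd.DataFrame,
    taxon: str | None = None,
    responses: tuple[str, ...] = LEVELS,
) -> list[LinearModelFit]:
    """The per-taxon OLS rotations over taxon-specific z-scores.

    ``z_table`` holds one taxon's rows with columns ``gene, level, z``
    (or a standardized table filtered to one taxon, using ``z_taxon``).
    Each level in ``responses`` (default: all three) in turn is the
    response, the other two the features.
    """
    frame = z_table.copy()
    if "z" not in frame.columns:
        if "z_taxon" not in frame.columns:
            raise ComputationError("need a 'z' or 'z_taxon' column")
        frame = frame.rename(columns={"z_taxon": "z"})
    if taxon is None:
        taxa = frame["taxon"].unique() if "taxon" in frame.columns else ["?"]
        if len(taxa) != 1:
            raise ComputationError("z table must contain exactly one taxon")
        taxon = str(taxa[0])

    wide = frame.pivot_table(index="gene", columns="level", values="z", aggfunc="first")
    missing = [lv for lv in LEVELS if lv not in wide.columns]
    if missing:
        raise ComputationError(f"levels missing from z table: {missing}")
    wide = wide[list(LEVELS)].dropna()
    if len(wide) < 10:
        raise ComputationError(f"need >= 10 complete genes, got {len(wide)}")

    import statsmodels.api as sm

    fits: list[LinearModelFit] = []
    for response in responses:
        feats = tuple(lv for lv in LEVELS if lv != response)
        design = sm.add_constant(wide[list(feats)].to_numpy())
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise SingularFitError(
                f"collinear features {feats} for response {response} in taxon {taxon}"
            )
        model = sm.OLS(wide[response].to_numpy(), design).fit()
        fits.append(
            LinearModelFit(
                taxon=taxon,
                response=response,
                features=feats,
                coefficients=(float(model.params[1]), float(model.params[2])),
                std_errors=(float(model.bse[1]), float(model.bse[2])),
                t_values=(float(model.tvalues[1]), float(model.tvalues[2])),
                p_values=(float(model.pvalues[1]), float(model.pvalues[2])),
                intercept=float(model.params[0]),
                r_squared=float(model.rsquared),
            )
        )
    return fits


# ---------------------------------------------------------------------------
# report assembly over a standardized table
# ---------------------------------------------------------------------------

def group_medians(std_table: pd.DataFrame) -> pd.DataFrame:
    """Median z of each (taxon, level) group under both poolings."""
    rows = []
    for (taxon, level), sub in std_table.groupby(["taxon", "level"], sort=True):
        rows.append(
            (
                taxon,
                level,
                float(sub["z_taxon"].median()),
                float(sub["z_level"].median()),
                len(sub),
            )
        )
    return pd.DataFrame(
        rows, columns=["taxon", "level", "median_z_taxon", "median_z_level", "n"]
    )


def taxon_ordering(std_table: pd.DataFrame) -> dict[str, list[str]]:
    """Per level, taxa ordered by ascending median taxon-specific z."""
    med = group_medians(std_table)
    out: dict[str, list[str]] = {}
    for level, sub in med.groupby("level"):
        out[level] = list(sub.sort_values("median_z_taxon")["taxon"])
    return out


def level_ordering(std_table: pd.DataFrame) -> dict[str, list[str]]:
    """Per taxon, levels ordered by ascending median level-specific z."""
    med = group_medians(std_table)
    out: dict[str, list[str]] = {}
    for taxon, sub in med.groupby("taxon"):
        out[taxon] = list(sub.sort_values("median_z_level")["level"])
    return out


def comparison_report(std_table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Full comparison battery over a standardized divergence table.

    Returns frames: ``medians`` (group medians), ``utests_taxa``
    (taxon pairs within each level, taxon-specific z), ``utests_levels``
    (level pairs within each taxon, level-specific z), ``correlations``
    (level pairs within each taxon, taxon-specific z), and ``models``
    (three OLS rotations per taxon).
    """
    taxa = sorted(std_table["taxon"].unique())

    utests_taxa = []
    for level in LEVELS:
        sub = std_table[std_table["level"] == level]
        for t1, t2 in combinations(taxa, 2):
            res = mann_whitney_u(
                sub.loc[sub["taxon"] == t1, "z_taxon"],
                sub.loc[sub["taxon"] == t2, "z_taxon"],
            )
            utests_taxa.append((level, t1, t2, res.u, res.p, res.n1, res.n2, res.method))
    utests_taxa = pd.DataFrame(
        utests_taxa, columns=["level", "group1", "group2", "u", "p", "n1", "n2", "method"]
    )

    utests_levels = []
    for taxon in taxa:
        sub = std_table[std_table["taxon"] == taxon]
        for l1, l2 in combinations(LEVELS, 2):
            res = mann_whitney_u(
                sub.loc[sub["level"] == l1, "z_level"],
                sub.loc[sub["level"] == l2, "z_level"],
            )
            utests_levels.append((taxon, l1, l2, res.u, res.p, res.n1, res.n2, res.method))
    utests_levels = pd.DataFrame(
        utests_levels, columns=["taxon", "group1", "group2", "u", "p", "n1", "n2", "method"]
    )

    corr_rows = []
    for taxon in taxa:
        sub = std_table[std_table["taxon"] == taxon]
        wide = sub.pivot_table(index="gene", columns="level", values="z_taxon", aggfunc="first")
        wide = wide[list(LEVELS)].dropna()
        for l1, l2 in combinations(LEVELS, 2):
            res = correlations(wide[l1], wide[l2])
            corr_rows.append((taxon, l1, l2, res.r, res.p_r, res.rho, res.p_rho, res.n))
    corr_frame = pd.DataFrame(
        corr_rows, columns=["taxon", "level1", "level2", "r", "p_r", "rho", "p_rho", "n"]
    )

    model_rows = []
    for taxon in taxa:
        sub = std_table[std_table["taxon"] == taxon]
        for fit in fit_divergence_models(sub, taxon=taxon):
            for feat, coef, se, tval, pval in zip(
                fit.features, fit.coefficients, fit.std_errors, fit.t_values, fit.p_values
            ):
                model_rows.append(
                    (taxon, fit.response, feat, coef, se, tval, pval, fit.intercept, fit.r_squared)
                )
    models = pd.DataFrame(
        model_rows,
        columns=[
            "taxon", "response", "feature", "coefficient", "std_error",
            "t_value", "p_value", "intercept", "r_squared",
        ],
    )

    return {
        "medians": group_medians(std_table),
        "utests_taxa": utests_taxa,
        "utests_levels": utests_levels,
        "correlations": corr_frame,
        "models": models,
    }
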