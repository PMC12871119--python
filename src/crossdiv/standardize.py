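"""Two-step standardization of raw divergence values.

Raw divergence distributions at different molecular levels live on
incommensurate scales (substitution rates near 0.1, profile distances near
0.3, structural percentage differences near 20), so they are first
normalized with a Box-Cox power transform (lambda chosen by maximum
profile likelihood) and then converted to z-scores under two poolings:

* taxon-specific z: values of all three levels pooled within one taxon —
  how far a gene's divergence lies from that taxon's mean across levels;
* level-specific z: values of all taxa pooled within one level — how far
  it lies from that level's mean across taxa.

Box-Cox requires strictly positive input, but raw divergence contains
exact zeros (identical proteins have Ka = 0, identical structures give
s = 100), so a data-driven positive shift — half the smallest positive
value — is added when zeros are present.

Fitting granularity.  By default one lambda is fitted per pooled dataset
(per taxon for the taxon-specific variant, per level for the
level-specific variant) so that every pool is standardized on a single
common scale.  The alternative granularity fits one lambda per
(taxon, level) dataset and pools the per-dataset transforms; it is exposed
via ``granularity="per-dataset"``.  Pooling values transformed with
different lambdas mixes units and is statistically delicate, which is why
it is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ComputationError, DegenerateInputError

LAMBDA_BOUNDS = (-5.0, 5.0)

GRANULARITIES = ("pooled", "per-dataset")


@dataclass(frozen=True)
class BoxCoxFit:
    """A fitted Box-Cox transform for one dataset."""

    group_id: str
    lam: float
    shift: float
    log_likelihood: float


def fit_boxcox(values, group_id: str = "") -> BoxCoxFit:
    """Maximum-likelihood Box-Cox fit with automatic zero shift.

    The shift is 0 when all values are positive, otherwise half the
    smallest positive value minus the minimum (all shifted values strictly
    positive).  lambda maximizes the profile log-likelihood over [-5, 5]
    to absolute tolerance 1e-6.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise DegenerateInputError(f"Box-Cox fit for {group_id!r} needs >= 3 values, got {x.size}")
    if not np.isfinite(x).all():
        raise DegenerateInputError(f"non-finite values in Box-Cox input for {group_id!r}")
    if np.all(x == x[0]):
        raise DegenerateInputError(f"all values equal in Box-Cox input for {group_id!r}")
    if x.min() < 0:
        raise DegenerateInputError(f"negative values in Box-Cox input for {group_id!r}")

    if x.min() > 0:
        shift = 0.0
    else:
        positive = x[x > 0]
        if positive.size == 0:
            raise DegenerateInputError(f"all values zero in Box-Cox input for {group_id!r}")
        shift = float(positive.min() / 2.0 - x.min())
    shifted = x + shift

    result = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, shifted),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(result.x)
    return BoxCoxFit(
        group_id=group_id,
        lam=lam,
        shift=shift,
        log_likelihood=float(stats.boxcox_llf(lam, shifted)),
    )


def apply_boxcox(values, fit: BoxCoxFit) -> np.ndarray:
    """Elementwise Box-Cox transform; strictly increasing in the input."""
    x = np.asarray(values, dtype=float) + fit.shift
    if (x <= 0).any():
        raise ComputationError(
            f"nonpositive shifted value under Box-Cox fit {fit.group_id!r}"
        )
    if fit.lam == 0.0:
        return np.log(x)
    # expm1 form avoids catastrophic cancellation for |lambda| near zero
    return np.expm1(fit.lam * np.log(x)) / fit.lam


def _zscore_pooled(values: np.ndarray, label: str) -> np.ndarray:
    if values.size < 2:
        raise DegenerateInputError(f"group {label!r} has fewer than 2 rows")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(f"zero pooled variance in group {label!r}")
    return (values - values.mean()) / sd


def compute_taxon_zscores(table: pd.DataFrame, column: str = "transformed") -> pd.Series:
    """z-scores pooling all levels within each taxon (sample sd, n-1)."""
    return _grouped_z(table, "taxon", column)


def compute_level_zscores(table: pd.DataFrame, column: str = "transformed") -> pd.Series:
    """z-scores pooling all taxa within each level (sample sd, n-1)."""
    return _grouped_z(table, "level", column)


def _grouped_z(table: pd.DataFrame, group_col: str, column: str) -> pd.Series:
    out = pd.Series(np.nan, index=table.index, dtype=float)
    for key, idx in table.groupby(group_col, sort=False).groups.items():
        vals = table.loc[idx, column].to_numpy(dtype=float)
        out.loc[idx] = _zscore_pooled(vals, str(key))
    return out


def standardize_table(raw_table: pd.DataFrame, granularity: str = "pooled") -> pd.DataFrame:
    """Standardize a long raw-divergence table into both z-score variants.

    Input columns: ``gene, taxon, level, raw``.  Output adds, for each
    pooling variant, the fitted lambda/shift, the transformed value, and
    the z-score: ``lambda_taxon, shift_taxon, transformed_taxon, z_taxon,
    lambda_level, shift_level, transformed_level, z_level``.

    With ``granularity="pooled"`` (default) one Box-Cox fit is made per
    taxon (all levels pooled) and one per level (all taxa pooled).  With
    ``granularity="per-dataset"`` one fit is made per (taxon, level) and
    both z-score variants pool the same per-dataset transforms, so the two
    transform column sets coincide.
    """
    if granularity not in GRANULARITIES:
        raise ValueError(f"granularity must be one of {GRANULARITIES}, got {granularity!r}")
    required = {"gene", "taxon", "level", "raw"}
    missing = required - set(raw_table.columns)
    if missing:
        raise ComputationError(f"raw table lacks columns {sorted(missing)}")

    out = raw_table.copy().reset_index(drop=True)

    if granularity == "pooled":
        for group_col, tag in (("taxon", "taxon"), ("level", "level")):
            lam = pd.Series(np.nan, index=out.index)
            shift = pd.Series(np.nan, index=out.index)
            transformed = pd.Series(np.nan, index=out.index)
            for key, idx in out.groupby(group_col, sort=False).groups.items():
                fit = fit_boxcox(out.loc[idx, "raw"].to_numpy(), group_id=f"{tag}:{key}")
                lam.loc[idx] = fit.lam
                shift.loc[idx] = fit.shift
                transformed.loc[idx] = apply_boxcox(out.loc[idx, "raw"].to_numpy(), fit)
            out[f"lambda_{tag}"] = lam
            out[f"shift_{tag}"] = shift
            out[f"transformed_{tag}"] = transformed
        out["z_taxon"] = compute_taxon_zscores(out, column="transformed_taxon")
        out["z_level"] = compute_level_zscores(out, column="transformed_level")
    else:
        lam = pd.Series(np.nan, index=out.index)
        shift = pd.Series(np.nan, index=out.index)
        transformed = pd.Series(np.nan, index=out.index)
        for (taxon, level), idx in out.groupby(["taxon", "level"], sort=False).groups.items():
            fit = fit_boxcox(out.loc[idx, "raw"].to_numpy(), group_id=f"{taxon}:{level}")
            lam.loc[idx] = fit.lam
            shift.loc[idx] = fit.shift
            transformed.loc[idx] = apply_boxcox(out.loc[idx, "raw"].to_numpy(), fit)
        for tag in ("taxon", "level"):
            out[f"lambda_{tag}"] = lam
            out[f"shift_{tag}"] = shift
            out[f"transformed_{tag}"] = transformed
        out["z_taxon"] = compute_taxon_zscores(out, column="transformed_taxon")
        out["z_level"] = compute_level_zscores(out, column="transformed_level")

    return out
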