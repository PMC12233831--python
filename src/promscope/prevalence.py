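"""Presence/absence statistics for per-cell speckle data.

The central test compares the proportion of cells carrying at least one
target speckle between two cell types with a binomial logistic regression:
response = speckle presence (0/1), predictors = a cell-type indicator plus
donor indicators (reference-coded fixed effects) to regress out the donor.
Significance is the Wald test on the cell-type coefficient; p-values across
pairwise tests are Bonferroni-corrected.  This is the standard GLM approach to
contingency tables of cell counts with a blocking covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _sstats

from .intervals import ValidationError

DONOR = "donor"
CELL_TYPE = "cell_type"
PRESENT = "present"  # 1 = at least one target speckle, 0 = empty

_SEPARATION_COEF = 15.0  # |log-odds| beyond this flags quasi-separation


@dataclass
class PairwiseTestResult:
    pair: tuple[str, str]
    coefficient: float  # log-odds of presence in pair[1] vs pair[0]
    std_error: float
    p_value: float
    n_per_group: dict[str, int]
    p_adjusted: Optional[float] = None
    warnings: list[str] = field(default_factory=list)


def presence_records(
    donors: Sequence[str], cell_types: Sequence[str], present: Sequence[int]
) -> pd.DataFrame:
    """Long-format table: one row per cell (donor, cell type, presence flag)."""
    df = pd.DataFrame({DONOR: donors, CELL_TYPE: cell_types, PRESENT: present})
    if not df[PRESENT].isin([0, 1]).all():
        raise ValidationError("presence must be binary (0 = empty, 1 = speckle)")
    return df


def presence_from_cell_table(
    cell_df: pd.DataFrame, donor: str, cell_type: str, channel: str = "upa"
) -> pd.DataFrame:
    """Convert a fish-quant per-cell export into presence records."""
    count_col = f"n_{channel}"
    return presence_records(
        [donor] * len(cell_df),
        [cell_type] * len(cell_df),
        (cell_df[count_col] > 0).astype(int).tolist(),
    )


def fit_presence_test(
    records: pd.DataFrame,
    pair: Optional[tuple[str, str]] = None,
    donor_covariate: bool = True,
    tol: float = 1e-8,
) -> PairwiseTestResult:
    """Logistic-regression test of speckle prevalence between two cell types.

    ``records`` may contain more cell types; fitting is restricted to the pair.
    With ``donor_covariate`` the donor enters as reference-coded fixed-effect
    indicators.  Complete (quasi-)separation is flagged in ``warnings`` rather
    than silently reported.
    """
    if pair is None:
        types = sorted(records[CELL_TYPE].unique())
        if len(types) != 2:
            raise ValidationError("pair must be given when more than two cell types present")
        pair = (types[0], types[1])
    sub = records[records[CELL_TYPE].isin(pair)].copy()
    n_per_group = {t: int((sub[CELL_TYPE] == t).sum()) for t in pair}
    if min(n_per_group.values()) == 0:
        raise ValidationError(f"both cell types must be present: {n_per_group}")

    X = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
    X["cell_type_effect"] = (sub[CELL_TYPE] == pair[1]).astype(float)
    if donor_covariate:
        donors = sorted(sub[DONOR].unique())
        if len(donors) < 2:
            raise ValidationError(
                "donor covariate requires at least two donors; disable it otherwise"
            )
        for donor in donors[1:]:
            X[f"donor_{donor}"] = (sub[DONOR] == donor).astype(float)

    model = sm.GLM(sub[PRESENT].astype(float), X, family=sm.families.Binomial())
    result = model.fit(tol=tol, maxiter=200)
    coef = float(result.params["cell_type_effect"])
    se = float(result.bse["cell_type_effect"])
    p = float(result.pvalues["cell_type_effect"])
    warnings = []
    if not result.converged:
        warnings.append("IRLS did not converge")
    if abs(coef) > _SEPARATION_COEF or not np.isfinite(se):
        warnings.append(
            "possible complete separation: cell-type coefficient diverges"
        )
    return PairwiseTestResult(
        pair=pair,
        coefficient=coef,
        std_error=se,
        p_value=p,
        n_per_group=n_per_group,
        warnings=warnings,
    )


def bonferroni(p_values: Sequence[float], n_tests: Optional[int] = None) -> np.ndarray:
    """Bonferroni adjustment: each p multiplied by the number of tests, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if n_tests is None else int(n_tests)
    return np.minimum(1.0, p * m)


def pairwise_presence_tests(
    records: pd.DataFrame, donor_covariate: bool = True
) -> pd.DataFrame:
    """All pairwise prevalence tests with Bonferroni-adjusted p-values."""
    types = sorted(records[CELL_TYPE].unique())
    if len(types) < 2:
        raise ValidationError("at least two cell types required")
    results = [
        fit_presence_test(records, pair=pair, donor_covariate=donor_covariate)
        for pair in itertools.combinations(types, 2)
    ]
    adjusted = bonferroni([r.p_value for r in results])
    rows = []
    for r, p_adj in zip(results, adjusted):
        r.p_adjusted = float(p_adj)
        rows.append(
            {
                "group_a": r.pair[0],
                "group_b": r.pair[1],
                "log_odds": r.coefficient,
                "std_error": r.std_error,
                "p_value": r.p_value,
                "p_bonferroni": r.p_adjusted,
                "n_a": r.n_per_group[r.pair[0]],
                "n_b": r.n_per_group[r.pair[1]],
                "warnings": ";".join(r.warnings),
            }
        )
    return pd.DataFrame(rows)


def normalized_fold_change(
    pct_target_treated: float,
    pct_target_control: float,
    pct_reporter_treated: float,
    pct_reporter_control: float,
) -> float:
    """Reporter-normalised fold change of a transfection readout.

    ``(target_treated / target_control) / (reporter_treated / reporter_control)``,
    for percent-positive or MFI inputs alike; NaN (undefined) when any
    denominator is zero.
    """
    if pct_target_control <= 0 or pct_reporter_control <= 0 or pct_reporter_treated <= 0:
        return float("nan")
    return (pct_target_treated / pct_target_control) / (
        pct_reporter_treated / pct_reporter_control
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact distribution for combined n <= 20
    without ties, normal approximation with tie correction otherwise."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    combined = np.concatenate([xa, ya])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = _sstats.mannwhitneyu(
        xa, ya, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)
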