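"""Error-rate summaries of pooled pairwise results.

The study's reported metric is the per-comparison error rate (PCER): the
fraction of individual pairwise decisions that are wrong, pooled over all
iterations of a design cell.  Under a type-I (complete null) design every
rejection is an error and all pairs count; under a type-II design only the
pairs involving the shifted group carry a real difference, and an error is a
failure to reject one of those pairs (null-null pairs are excluded).  The
two denominators are therefore deliberately asymmetric.

Also provided: the analytic experimentwise (familywise) error rate of m
independent unadjusted comparisons, 1 - (1-alpha)^m, and pooled p-value
distributions with a fixed 0.05-wide binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "ErrorSummary",
    "PValueSample",
    "pcer_type1",
    "pcer_type2",
    "fwer_unadjusted",
    "pvalue_distribution",
]


@dataclass(frozen=True)
class ErrorSummary:
    """PCER of one test in one design cell."""

    test_name: str
    design_id: str
    n_comparisons: int
    n_errors: int

    @property
    def pcer(self) -> float:
        return self.n_errors / self.n_comparisons


@dataclass(frozen=True)
class PValueSample:
    """Pooled per-comparison p-values of one test in one design cell."""

    test_name: str
    design_id: str
    p_values: np.ndarray

    def histogram(self, bin_width: float = 0.05) -> pd.DataFrame:
        """Counts on fixed [0, 1] bins (last bin closed at 1)."""
        edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
        counts, _ = np.histogram(self.p_values, bins=edges)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    @property
    def top_bin_mass(self) -> float:
        """Fraction of p-values at or above 0.95 (the 'peak near one')."""
        return float(np.mean(self.p_values >= 0.95))


def _check_columns(results: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise InvalidInputError(f"results table is missing columns {missing}")


def _summaries(grouped, error_col: str) -> list[ErrorSummary]:
    out = []
    for (design_id, test), block in grouped:
        out.append(
            ErrorSummary(
                test_name=test,
                design_id=design_id,
                n_comparisons=len(block),
                n_errors=int(block[error_col].sum()),
            )
        )
    return out


def summaries_to_frame(summaries: list[ErrorSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "design_id": [s.design_id for s in summaries],
            "test": [s.test_name for s in summaries],
            "n_comparisons": [s.n_comparisons for s in summaries],
            "n_errors": [s.n_errors for s in summaries],
            "pcer": [s.pcer for s in summaries],
        }
    )


def pcer_type1(results: pd.DataFrame, alpha: float = 0.05) -> list[ErrorSummary]:
    """Type-I PCER per (design, test): rejections over all pairs pooled.

    ``results`` must hold only type-I (complete-null) designs; every
    rejection at ``alpha`` is a false positive.
    """
    _check_columns(results, ("design_id", "error_type", "test", "p_value"))
    if len(results) == 0:
        raise InvalidInputError("empty results table")
    if not (results["error_type"] == "typeI").all():
        raise InvalidInputError("pcer_type1 requires typeI-design rows only")
    df = results.assign(_err=results["p_value"] < alpha)
    return _summaries(df.groupby(["design_id", "test"], sort=False), "_err")


def pcer_type2(
    results: pd.DataFrame, alpha: float = 0.05, shifted_group: str = "g1"
) -> list[ErrorSummary]:
    """Type-II PCER per (design, test): missed rejections among the pairs that
    involve the shifted group; null-null pairs are excluded."""
    _check_columns(
        results, ("design_id", "error_type", "test", "p_value", "group_i", "group_j")
    )
    if len(results) == 0:
        raise InvalidInputError("empty results table")
    if not (results["error_type"] == "typeII").all():
        raise InvalidInputError("pcer_type2 requires typeII-design rows only")
    sub = results[
        (results["group_i"] == shifted_group) | (results["group_j"] == shifted_group)
    ]
    if len(sub) == 0:
        raise InvalidInputError(f"no pairs involve shifted group {shifted_group!r}")
    df = sub.assign(_err=sub["p_value"] >= alpha)
    return _summaries(df.groupby(["design_id", "test"], sort=False), "_err")


def fwer_unadjusted(alpha: float, m: int) -> float:
    """Familywise (experimentwise) error rate of m independent comparisons
    each run unadjusted at level alpha: 1 - (1 - alpha)^m."""
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha}")
    if int(m) != m or m < 1:
        raise InvalidInputError(f"m must be an integer >= 1, got {m}")
    return float(-np.expm1(m * np.log1p(-alpha)))


def pvalue_distribution(
    results: pd.DataFrame, test_name: str, design_id: str
) -> PValueSample:
    """Pool all per-comparison p-values of one test in one design cell."""
    _check_columns(results, ("design_id", "test", "p_value"))
    sel = results[(results["test"] == test_name) & (results["design_id"] == design_id)]
    if len(sel) == 0:
        raise InvalidInputError(f"no rows for test {test_name!r} in design {design_id!r}")
    p = sel["p_value"].to_numpy(dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values outside [0, 1]")
    return PValueSample(test_name=test_name, design_id=design_id, p_values=p)
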