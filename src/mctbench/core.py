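"""One-way ANOVA and the nine parametric multiple-comparison tests (MCTs).

All tests consume a common :class:`AnovaFit` (group means, within-group mean
square, residual degrees of freedom) or, for the per-pair t-test variants, the
raw :class:`Dataset`, and emit one :class:`PairwiseResult` per unordered group
pair.  Every test reports a p-value on the decision scale, so the rejection
rule is uniformly ``p_value < alpha``:

* ``scheffe`` — contrast F-test; protected (cannot reject any pair when the
  omnibus ANOVA is nonsignificant).
* ``t_bonferroni`` / ``t_sidak`` — per-pair pooled-variance two-sample t-tests
  (df = n_i + n_j - 2) with the named p-value adjustment over all pairs.
* ``tukey_hsd`` — studentized-range test; Tukey-Kramer standardization under
  unequal group sizes.
* ``fisher_lsd`` (+ Bonferroni / Sidak variants) — t-tests pooled on the
  ANOVA mean-square error (df = N - k).
* ``duncan_mrt`` / ``snk`` — step-down multiple-range procedures on the
  ordered means; reported p-values are decision-equivalent (stepwise range
  tail probability, mapped to the working-alpha scale for Duncan, maximised
  over enclosing ranges so the blocking rule is encoded).

The "t-test with correction" and "LSD with correction" variants differ only
in the variance pooled into the standard error: the former uses the pair's
own two groups, the latter the ANOVA-wide error mean square.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateVarianceError, InvalidInputError
from .qdist import studentized_range_sf

__all__ = [
    "Dataset",
    "AnovaFit",
    "PairwiseResult",
    "AlphaPolicy",
    "TEST_NAMES",
    "fit_oneway",
    "adjust_bonferroni",
    "adjust_sidak",
    "pairwise_t",
    "fisher_lsd",
    "tukey_hsd",
    "scheffe",
    "snk",
    "duncan",
    "run_all_tests",
    "results_to_frame",
]

#: Canonical order of the nine tests (used by the study runner and outputs).
TEST_NAMES: tuple[str, ...] = (
    "scheffe",
    "t_bonferroni",
    "t_sidak",
    "tukey_hsd",
    "fisher_lsd",
    "lsd_bonferroni",
    "lsd_sidak",
    "duncan_mrt",
    "snk",
)

_CORRECTIONS = ("none", "bonferroni", "sidak")


@dataclass(frozen=True)
class Dataset:
    """Grouped numeric observations: one label and one value vector per group."""

    groups: tuple[str, ...]
    values: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise InvalidInputError("need at least 2 groups")
        if len(self.groups) != len(self.values):
            raise InvalidInputError("groups and values must have equal length")
        if len(set(self.groups)) != len(self.groups):
            raise InvalidInputError("group labels must be unique")
        vals = tuple(np.asarray(v, dtype=float) for v in self.values)
        for g, v in zip(self.groups, vals):
            if v.ndim != 1 or v.size < 2:
                raise InvalidInputError(f"group {g!r} needs >= 2 observations")
            if not np.all(np.isfinite(v)):
                raise InvalidInputError(f"group {g!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_pairs(self) -> int:
        return self.k * (self.k - 1) // 2

    @classmethod
    def from_groups(cls, groups: dict[str, Iterable[float]] | Sequence[Iterable[float]]) -> "Dataset":
        """Build from a mapping label -> values, or a sequence of value lists
        (labels then default to g1, g2, ...)."""
        if isinstance(groups, dict):
            labels = tuple(str(g) for g in groups)
            values = tuple(np.asarray(v, dtype=float) for v in groups.values())
        else:
            values = tuple(np.asarray(v, dtype=float) for v in groups)
            labels = tuple(f"g{i + 1}" for i in range(len(values)))
        return cls(labels, values)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, group_col: str = "group", value_col: str = "value") -> "Dataset":
        """Long-format table, one observation per row."""
        if group_col not in df.columns or value_col not in df.columns:
            raise InvalidInputError(f"need columns {group_col!r} and {value_col!r}")
        labels = tuple(str(g) for g in pd.unique(df[group_col]))
        values = tuple(
            df.loc[df[group_col].astype(str) == g, value_col].to_numpy(dtype=float) for g in labels
        )
        return cls(labels, values)

    @classmethod
    def read_csv(cls, path, sep: str = ",", group_col: str = "group", value_col: str = "value") -> "Dataset":
        return cls.from_dataframe(pd.read_csv(path, sep=sep), group_col, value_col)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.repeat(self.groups, [v.size for v in self.values]),
                "value": np.concatenate(self.values),
            }
        )


@dataclass(frozen=True)
class AnovaFit:
    """Fixed-effects one-way ANOVA summary shared by all MCTs."""

    groups: tuple[str, ...]
    n_i: np.ndarray
    means: np.ndarray
    mse: float
    df_within: int
    f_stat: float
    p_omnibus: float

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def N(self) -> int:
        return int(self.n_i.sum())


@dataclass(frozen=True)
class PairwiseResult:
    """One pairwise comparison under one test.

    ``pair`` holds the two group labels in dataset order; for a user-supplied
    Scheffe contrast it is the single string ``"contrast"``.  ``statistic`` is
    on the test's native scale (t, studentized range q, or contrast F).
    """

    test_name: str
    pair: tuple[str, str] | str
    diff: float
    statistic: float
    p_value: float
    reject: bool


@dataclass(frozen=True)
class AlphaPolicy:
    """Working significance level and (optional) family size.

    ``m`` is the number of comparisons the corrections divide over; when left
    ``None`` it defaults to all k(k-1)/2 pairs of the fit at hand.
    """

    alpha: float = 0.05
    m: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidInputError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.m is not None and self.m < 1:
            raise InvalidInputError(f"m must be >= 1, got {self.m}")

    def family_size(self, k: int) -> int:
        return self.m if self.m is not None else k * (k - 1) // 2


# ---------------------------------------------------------------------------
# ANOVA


def fit_oneway(data: Dataset) -> AnovaFit:
    """Fixed-effects one-way ANOVA decomposition.

    Raises :class:`DegenerateVarianceError` when the within-group mean square
    is zero (all groups internally constant), since every downstream test
    divides by it.
    """
    n_i = np.array([v.size for v in data.values], dtype=int)
    means = np.array([v.mean() for v in data.values])
    N = int(n_i.sum())
    k = data.k
    ss_within = float(sum(((v - m) ** 2).sum() for v, m in zip(data.values, means)))
    grand = float(np.concatenate(data.values).mean())
    ss_between = float((n_i * (means - grand) ** 2).sum())
    df_within = N - k
    df_between = k - 1
    mse = ss_within / df_within
    if mse <= 0.0:
        raise DegenerateVarianceError("zero within-group variance; pairwise tests undefined")
    f_stat = (ss_between / df_between) / mse
    p_omnibus = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaFit(
        groups=data.groups,
        n_i=n_i,
        means=means,
        mse=mse,
        df_within=df_within,
        f_stat=f_stat,
        p_omnibus=p_omnibus,
    )


# ---------------------------------------------------------------------------
# p-value adjusters


def _validate_pm(p, m: int):
    p = np.asarray(p, dtype=float)
    if int(m) != m or m < 1:
        raise InvalidInputError(f"m must be an integer >= 1, got {m}")
    if np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return p, int(m)


def adjust_bonferroni(p, m: int):
    """Bonferroni adjustment min(1, m*p); elementwise over arrays."""
    p, m = _validate_pm(p, m)
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


def adjust_sidak(p, m: int):
    """Sidak adjustment 1 - (1-p)^m; always <= Bonferroni."""
    p, m = _validate_pm(p, m)
    out = -np.expm1(m * np.log1p(-np.minimum(p, np.nextafter(1.0, 0.0))))
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


_ADJUSTERS = {
    "none": lambda p, m: np.asarray(p, dtype=float),
    "bonferroni": adjust_bonferroni,
    "sidak": adjust_sidak,
}


# ---------------------------------------------------------------------------
# helpers


def _pairs(labels: Sequence[str]) -> list[tuple[int, int]]:
    return list(itertools.combinations(range(len(labels)), 2))


def _check_correction(correction: str) -> str:
    if correction not in _CORRECTIONS:
        raise InvalidInputError(f"correction must be one of {_CORRECTIONS}, got {correction!r}")
    return correction


def _build_results(
    test_name: str,
    fit_groups: Sequence[str],
    pairs: Sequence[tuple[int, int]],
    diffs: np.ndarray,
    stats_: np.ndarray,
    pvals: np.ndarray,
    alpha: float,
) -> list[PairwiseResult]:
    return [
        PairwiseResult(
            test_name=test_name,
            pair=(fit_groups[i], fit_groups[j]),
            diff=float(d),
            statistic=float(s),
            p_value=float(p),
            reject=bool(p < alpha),
        )
        for (i, j), d, s, p in zip(pairs, diffs, stats_, pvals)
    ]


# ---------------------------------------------------------------------------
# the nine tests


def pairwise_t(
    data: Dataset,
    policy: AlphaPolicy = AlphaPolicy(),
    correction: str = "none",
) -> list[PairwiseResult]:
    """All-pairs two-sided pooled-variance two-sample t-tests.

    Each pair uses only its own two groups (df = n_i + n_j - 2); the raw
    p-value is then passed through the chosen adjuster with m = k(k-1)/2.
    """
    _check_correction(correction)
    pairs = _pairs(data.groups)
    m = policy.family_size(data.k)
    diffs, tstats, pvals = [], [], []
    for i, j in pairs:
        a, b = data.values[i], data.values[j]
        na, nb = a.size, b.size
        df = na + nb - 2
        sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / df
        if sp2 <= 0.0:
            raise DegenerateVarianceError(
                f"pair ({data.groups[i]}, {data.groups[j]}) has zero pooled variance"
            )
        d = a.mean() - b.mean()
        t = d / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        diffs.append(d)
        tstats.append(t)
        pvals.append(2.0 * stats.t.sf(abs(t), df))
    adj = _ADJUSTERS[correction](np.array(pvals), m)
    name = {"none": "t", "bonferroni": "t_bonferroni", "sidak": "t_sidak"}[correction]
    return _build_results(name, data.groups, pairs, np.array(diffs), np.array(tstats), adj, policy.alpha)


def fisher_lsd(
    fit: AnovaFit,
    policy: AlphaPolicy = AlphaPolicy(),
    correction: str = "none",
) -> list[PairwiseResult]:
    """Fisher's least-significant-difference t-tests on the ANOVA error term.

    t_ij = (mean_i - mean_j) / sqrt(mse * (1/n_i + 1/n_j)) on N - k df;
    optional Bonferroni/Sidak adjustment over all pairs.
    """
    _check_correction(correction)
    pairs = _pairs(fit.groups)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    diffs = fit.means[i_idx] - fit.means[j_idx]
    se = np.sqrt(fit.mse * (1.0 / fit.n_i[i_idx] + 1.0 / fit.n_i[j_idx]))
    t = diffs / se
    raw = 2.0 * stats.t.sf(np.abs(t), fit.df_within)
    adj = _ADJUSTERS[correction](raw, policy.family_size(fit.k))
    name = {"none": "fisher_lsd", "bonferroni": "lsd_bonferroni", "sidak": "lsd_sidak"}[correction]
    return _build_results(name, fit.groups, pairs, diffs, t, adj, policy.alpha)


def _range_q(fit: AnovaFit, i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Tukey-Kramer standardized range statistics for the given index pairs."""
    diffs = fit.means[i_idx] - fit.means[j_idx]
    se = np.sqrt(0.5 * fit.mse * (1.0 / fit.n_i[i_idx] + 1.0 / fit.n_i[j_idx]))
    return np.abs(diffs) / se


def tukey_hsd(fit: AnovaFit, policy: AlphaPolicy = AlphaPolicy()) -> list[PairwiseResult]:
    """Tukey's honest significant difference (Tukey-Kramer under unequal n).

    q_ij = |mean_i - mean_j| / sqrt((mse/2)(1/n_i + 1/n_j)); p-value from the
    studentized range of all k means on the residual df.
    """
    pairs = _pairs(fit.groups)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    diffs = fit.means[i_idx] - fit.means[j_idx]
    q = _range_q(fit, i_idx, j_idx)
    p = studentized_range_sf(q, fit.k, fit.df_within)
    return _build_results("tukey_hsd", fit.groups, pairs, diffs, q, np.atleast_1d(p), policy.alpha)


def scheffe(
    fit: AnovaFit,
    policy: AlphaPolicy = AlphaPolicy(),
    contrast: Sequence[float] | None = None,
) -> list[PairwiseResult]:
    """Scheffe's S test for contrasts of group means.

    For a contrast c (coefficients summing to 0), SS_c = (sum c_i m_i)^2 /
    (sum c_i^2 / n_i) and the statistic (SS_c / mse) / (k - 1) is referred to
    F(k-1, N-k).  With no contrast given, all +1/-1 pairwise contrasts are
    tested.  Because the maximal contrast SS equals the between-group SS, no
    pairwise comparison can be significant when the omnibus ANOVA is not
    (the "protected" property).
    """
    if contrast is not None:
        c = np.asarray(contrast, dtype=float)
        if c.size != fit.k:
            raise InvalidInputError(f"contrast length {c.size} != k = {fit.k}")
        if abs(c.sum()) > 1e-9 * max(1.0, np.abs(c).sum()):
            raise InvalidInputError("contrast coefficients must sum to 0")
        est = float(c @ fit.means)
        ss_c = est**2 / float((c**2 / fit.n_i).sum())
        f = (ss_c / fit.mse) / (fit.k - 1)
        p = float(stats.f.sf(f, fit.k - 1, fit.df_within))
        return [
            PairwiseResult("scheffe", "contrast", est, float(f), p, bool(p < policy.alpha))
        ]
    pairs = _pairs(fit.groups)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    diffs = fit.means[i_idx] - fit.means[j_idx]
    denom = 1.0 / fit.n_i[i_idx] + 1.0 / fit.n_i[j_idx]
    ss_c = diffs**2 / denom
    f = (ss_c / fit.mse) / (fit.k - 1)
    p = stats.f.sf(f, fit.k - 1, fit.df_within)
    return _build_results("scheffe", fit.groups, pairs, diffs, f, p, policy.alpha)


def _stepdown_both(fit: AnovaFit, policy: AlphaPolicy) -> tuple[list[PairwiseResult], list[PairwiseResult]]:
    """Shared step-down engine for SNK and Duncan's MRT.

    Sorts the sample means; a pair whose ordered positions span r means is
    tested with the studentized range of r on the residual df.  The reported
    p-value for a pair is the maximum mapped stepwise p over the pair's own
    range and every enclosing range, which encodes the blocking rule (a pair
    cannot be rejected unless all enclosing ranges are) while keeping
    ``reject iff p < alpha`` exact.  SNK maps stepwise p identically; Duncan
    runs the span-r test at the inflated level 1 - (1-alpha)^(r-1), i.e. maps
    stepwise p to 1 - (1-p)^(1/(r-1)).
    """
    k = fit.k
    alpha = policy.alpha
    # stable sort => ties among means broken by group (label) order
    order = np.argsort(fit.means, kind="stable")
    pos = np.empty(k, dtype=int)
    pos[order] = np.arange(k)

    pairs = _pairs(fit.groups)
    i_idx = np.array([p[0] for p in pairs])
    j_idx = np.array([p[1] for p in pairs])
    diffs = fit.means[i_idx] - fit.means[j_idx]
    q = _range_q(fit, i_idx, j_idx)
    a_pos = np.minimum(pos[i_idx], pos[j_idx])
    b_pos = np.maximum(pos[i_idx], pos[j_idx])
    span = b_pos - a_pos + 1

    # stepwise range p-values, one sf call per distinct span
    p_step = np.empty(len(pairs))
    for r in np.unique(span):
        sel = span == r
        p_step[sel] = np.atleast_1d(studentized_range_sf(q[sel], int(r), fit.df_within))

    def _report(p_mapped: np.ndarray) -> np.ndarray:
        # max over all enclosing position ranges, by dynamic programming from
        # the widest span inward
        grid = np.full((k, k), -np.inf)
        grid[a_pos, b_pos] = p_mapped
        rep = np.full((k, k), -np.inf)
        for r in range(k, 1, -1):
            for a in range(0, k - r + 1):
                b = a + r - 1
                best = grid[a, b]
                if a > 0:
                    best = max(best, rep[a - 1, b])
                if b < k - 1:
                    best = max(best, rep[a, b + 1])
                rep[a, b] = best
        return rep[a_pos, b_pos]

    snk_p = _report(p_step)
    with np.errstate(invalid="ignore"):
        dunc_mapped = np.where(
            span > 2,
            -np.expm1(np.log1p(-np.minimum(p_step, np.nextafter(1.0, 0.0))) / (span - 1)),
            p_step,
        )
    dunc_p = _report(np.clip(dunc_mapped, 0.0, 1.0))

    snk_res = _build_results("snk", fit.groups, pairs, diffs, q, np.clip(snk_p, 0, 1), alpha)
    dunc_res = _build_results("duncan_mrt", fit.groups, pairs, diffs, q, np.clip(dunc_p, 0, 1), alpha)
    return snk_res, dunc_res


def snk(fit: AnovaFit, policy: AlphaPolicy = AlphaPolicy()) -> list[PairwiseResult]:
    """Student-Newman-Keuls step-down multiple range test."""
    return _stepdown_both(fit, policy)[0]


def duncan(fit: AnovaFit, policy: AlphaPolicy = AlphaPolicy()) -> list[PairwiseResult]:
    """Duncan's multiple range test (step-down with inflated per-span levels)."""
    return _stepdown_both(fit, policy)[1]


def run_all_tests(data: Dataset, policy: AlphaPolicy = AlphaPolicy()) -> list[PairwiseResult]:
    """Run the full battery of nine MCTs on one dataset.

    Returns 9 * k(k-1)/2 rows in the canonical test order of
    :data:`TEST_NAMES`, with the same pair ordering for every test.
    """
    fit = fit_oneway(data)
    snk_res, dunc_res = _stepdown_both(fit, policy)
    blocks = {
        "scheffe": scheffe(fit, policy),
        "t_bonferroni": pairwise_t(data, policy, "bonferroni"),
        "t_sidak": pairwise_t(data, policy, "sidak"),
        "tukey_hsd": tukey_hsd(fit, policy),
        "fisher_lsd": fisher_lsd(fit, policy, "none"),
        "lsd_bonferroni": fisher_lsd(fit, policy, "bonferroni"),
        "lsd_sidak": fisher_lsd(fit, policy, "sidak"),
        "duncan_mrt": dunc_res,
        "snk": snk_res,
    }
    out: list[PairwiseResult] = []
    for name in TEST_NAMES:
        out.extend(blocks[name])
    return out


def results_to_frame(results: Iterable[PairwiseResult]) -> pd.DataFrame:
    """Tidy DataFrame with columns test, group_i, group_j, diff, statistic,
    p_value, reject."""
    rows = [
        {
            "test": r.test_name,
            "group_i": r.pair[0] if isinstance(r.pair, tuple) else r.pair,
            "group_j": r.pair[1] if isinstance(r.pair, tuple) else "",
            "diff": r.diff,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "reject": r.reject,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
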