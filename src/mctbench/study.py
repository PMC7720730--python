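"""End-to-end orchestration of the 16-design x 9-test Monte-Carlo study.

``run_study`` loops the design grid, draws each iteration's dataset from its
keyed RNG substream, runs the full MCT battery, and collects a tidy table of
every pairwise decision.  Summaries (type-I / type-II PCER per design and
test, pooled p-value histograms) are computed from that table and can be
recomputed from the raw CSV alone with ``summarize`` — the raw table carries
the design descriptors and shifted-group label, so it is self-describing.

Iterations whose draw has zero within-group variance (impossible under the
continuous generator, but possible with user-modified configs) are skipped
and counted rather than resampled, keeping RNG streams aligned across tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import TEST_NAMES, AlphaPolicy, run_all_tests
from .exceptions import DegenerateVarianceError, InvalidInputError
from .metrics import (
    ErrorSummary,
    pcer_type1,
    pcer_type2,
    pvalue_distribution,
    summaries_to_frame,
)
from .simulate import RngPolicy, SimulationDesign, StudyConfig, make_design_grid, simulate_dataset

__all__ = ["StudyResults", "run_study", "summarize"]

logger = logging.getLogger("mctbench")

_RAW_COLUMNS = [
    "design_id",
    "balance",
    "error_type",
    "treatment",
    "shifted_group",
    "iteration",
    "test",
    "group_i",
    "group_j",
    "diff",
    "statistic",
    "p_value",
    "reject",
    "master_seed",
]


@dataclass
class StudyResults:
    """Raw tidy results plus the summary tables derived from them."""

    results: pd.DataFrame
    summary: pd.DataFrame
    histograms: pd.DataFrame
    config: StudyConfig
    n_skipped: int

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "raw_results.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        self.histograms.to_csv(out / "pvalue_histograms.csv", index=False)
        manifest = {
            "config": self.config.to_dict(),
            "master_seed": self.config.master_seed,
            "n_skipped_iterations": self.n_skipped,
            "tests": list(TEST_NAMES),
            "versions": {
                "mctbench": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _run_design(
    design: SimulationDesign, rng: RngPolicy, policy: AlphaPolicy, cols: dict[str, list]
) -> int:
    """Append all iterations of one design cell to the column store."""
    shifted = (
        design.group_labels[design.shifted_group] if design.shifted_group is not None else ""
    )
    skipped = 0
    for it in range(design.iterations):
        data = simulate_dataset(design, rng, it)
        try:
            rows = run_all_tests(data, policy)
        except DegenerateVarianceError:
            skipped += 1
            logger.warning("degenerate variance: design=%s iteration=%d skipped", design.design_id, it)
            continue
        for r in rows:
            cols["iteration"].append(it)
            cols["test"].append(r.test_name)
            cols["group_i"].append(r.pair[0])
            cols["group_j"].append(r.pair[1])
            cols["diff"].append(r.diff)
            cols["statistic"].append(r.statistic)
            cols["p_value"].append(r.p_value)
            cols["reject"].append(r.reject)
        n_new = len(rows)
        cols["design_id"].extend([design.design_id] * n_new)
        cols["balance"].extend([design.balance] * n_new)
        cols["error_type"].extend([design.error_type] * n_new)
        cols["treatment"].extend([design.treatment] * n_new)
        cols["shifted_group"].extend([shifted] * n_new)
    return skipped


def _summarize_frame(results: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """PCER summary rows (both error types) from a tidy results table."""
    summaries: list[ErrorSummary] = []
    t1 = results[results["error_type"] == "typeI"]
    if len(t1):
        summaries.extend(pcer_type1(t1, alpha))
    t2 = results[results["error_type"] == "typeII"]
    for shifted, block in t2.groupby("shifted_group", sort=False):
        summaries.extend(pcer_type2(block, alpha, shifted_group=shifted))
    frame = summaries_to_frame(summaries)
    desc = results[["design_id", "balance", "error_type", "treatment"]].drop_duplicates()
    frame = desc.merge(frame, on="design_id", how="right")
    order = {d: i for i, d in enumerate(pd.unique(results["design_id"]))}
    trank = {t: i for i, t in enumerate(TEST_NAMES)}
    frame = frame.sort_values(
        by=["design_id", "test"],
        key=lambda s: s.map(order if s.name == "design_id" else trank),
        kind="stable",
    ).reset_index(drop=True)
    return frame


def _histogram_frame(results: pd.DataFrame) -> pd.DataFrame:
    blocks = []
    for design_id in pd.unique(results["design_id"]):
        for test in TEST_NAMES:
            sample = pvalue_distribution(results, test, design_id)
            h = sample.histogram()
            h.insert(0, "test", test)
            h.insert(0, "design_id", design_id)
            blocks.append(h)
    return pd.concat(blocks, ignore_index=True)


def run_study(
    config: StudyConfig | None = None,
    out_dir=None,
    designs: list[str] | None = None,
) -> StudyResults:
    """Run the Monte-Carlo study and (optionally) write its outputs.

    Parameters
    ----------
    config : StudyConfig, optional
        Generator and study parameters; defaults to the standard conditions.
    out_dir : path-like, optional
        Directory for raw/summary CSVs and the run manifest.
    designs : list of str, optional
        Subset of design ids (``balance:errorType:treatment``) to run;
        default all 16.
    """
    cfg = config or StudyConfig()
    grid = make_design_grid(cfg)
    if designs is not None:
        known = {d.design_id for d in grid}
        bad = set(designs) - known
        if bad:
            raise InvalidInputError(f"unknown design ids: {sorted(bad)}")
        grid = [d for d in grid if d.design_id in designs]
    rng = RngPolicy(cfg.master_seed)
    policy = AlphaPolicy(alpha=cfg.alpha)

    cols: dict[str, list] = {c: [] for c in _RAW_COLUMNS if c != "master_seed"}
    n_skipped = 0
    for design in grid:
        logger.info("running design %s (%d iterations)", design.design_id, design.iterations)
        n_skipped += _run_design(design, rng, policy, cols)
    results = pd.DataFrame(cols)
    results["master_seed"] = cfg.master_seed
    results = results[_RAW_COLUMNS]

    summary = _summarize_frame(results, cfg.alpha)
    histograms = _histogram_frame(results)
    study = StudyResults(
        results=results,
        summary=summary,
        histograms=histograms,
        config=cfg,
        n_skipped=n_skipped,
    )
    if out_dir is not None:
        study.write(out_dir)
    return study


def summarize(raw_csv, alpha: float = 0.05, out_dir=None) -> dict[str, pd.DataFrame]:
    """Recompute summary tables from a raw tidy CSV written by ``run_study``.

    Idempotent: on an unmodified raw file this reproduces ``run_study``'s own
    summaries exactly.
    """
    try:
        results = pd.read_csv(raw_csv, dtype={"shifted_group": str}, keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InvalidInputError(f"malformed raw CSV {raw_csv}: {exc}") from exc
    missing = [c for c in _RAW_COLUMNS if c not in results.columns]
    if missing:
        raise InvalidInputError(f"raw CSV {raw_csv} is missing columns {missing}")
    if len(results) == 0:
        raise InvalidInputError(f"raw CSV {raw_csv} has no rows")
    summary = _summarize_frame(results, alpha)
    histograms = _histogram_frame(results)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.csv", index=False)
        histograms.to_csv(out / "pvalue_histograms.csv", index=False)
    return {"summary": summary, "histograms": histograms}
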