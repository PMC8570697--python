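"""Developmental-timing confound analysis.

Apparent stress-induced expression changes in embryo pools can instead
reflect a shift in developmental stage.  The filter compares each DEG's
observed expression (on a regularized-log proxy scale) against the range
the gene traverses across a reference embryonic time course: mean +/- 1
standard deviation over all timepoints.  A DEG whose values in at least
one condition lie outside that band for every replicate cannot be
explained by sampling a different developmental time, and is marked
``not_timing``.  A whole-sample stage estimate by profile correlation
against the time course is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .de import DEGCall
from .io import CountMatrix


@dataclass
class EmbryoTimecourse:
    """Reference expression (regularized-log scale) over embryo timepoints."""

    expression: pd.DataFrame  # index gene, columns timepoints (minutes)

    def __post_init__(self) -> None:
        tp = np.asarray(self.expression.columns, dtype=float)
        if len(tp) and not np.all(np.diff(tp) > 0):
            raise ValidationError("timepoints must be strictly increasing")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.expression.columns, dtype=float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)


@dataclass
class EmbryoRange:
    """Per-gene mean +/- 1 SD band across embryo timepoints."""

    table: pd.DataFrame  # index gene; columns mean, sd, lo, hi


@dataclass
class TimingVerdict:
    """Per-DEG timing call: not_timing means the change cannot be a stage shift."""

    table: pd.DataFrame  # index gene; outside_<cond> booleans + verdict

    @property
    def fraction_not_timing(self) -> float:
        if len(self.table) == 0:
            return float("nan")
        return float((self.table["verdict"] == "not_timing").mean())


def rlog_proxy(
    counts: CountMatrix | np.ndarray,
    size_factors: np.ndarray,
    pseudocount: float = 1.0,
) -> pd.DataFrame | np.ndarray:
    """Regularized-log proxy: ``log2(count / size_factor + pseudocount)``."""
    size_factors = np.asarray(size_factors, dtype=float)
    if np.any(size_factors <= 0):
        raise ValidationError("size factors must be positive")
    if isinstance(counts, CountMatrix):
        values = np.log2(counts.counts / size_factors[None, :] + pseudocount)
        return pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids)
    return np.log2(np.asarray(counts, dtype=float) / size_factors + pseudocount)


def embryo_range(timecourse: EmbryoTimecourse) -> EmbryoRange:
    """Per-gene mean and sample SD (divisor n-1) across all timepoints."""
    expr = timecourse.expression
    if expr.shape[1] < 2:
        raise ValidationError("embryo range needs at least 2 timepoints")
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    table = pd.DataFrame({"mean": mean, "sd": sd, "lo": mean - sd, "hi": mean + sd})
    return EmbryoRange(table)


def flag_timing(
    degs: DEGCall | set[str],
    rlog_values: dict[str, pd.DataFrame],
    ranges: EmbryoRange,
) -> TimingVerdict:
    """Flag DEGs whose expression escapes the embryo range.

    ``rlog_values`` maps each of the two compared conditions to a
    genes-by-replicates frame of proxy values.  A DEG is ``not_timing``
    iff, for at least one condition, every replicate value lies strictly
    outside [lo, hi]; genes absent from the range table are
    ``possibly_timing`` with a warning recorded in the table.
    """
    genes = sorted(degs.significant if isinstance(degs, DEGCall) else degs)
    conditions = list(rlog_values)
    rows = []
    for g in genes:
        row: dict[str, object] = {"gene": g}
        if g not in ranges.table.index:
            for cond in conditions:
                row[f"outside_{cond}"] = False
            row["verdict"] = "possibly_timing"
            row["in_reference"] = False
            rows.append(row)
            continue
        lo = ranges.table.at[g, "lo"]
        hi = ranges.table.at[g, "hi"]
        any_outside = False
        for cond in conditions:
            vals = np.asarray(rlog_values[cond].loc[g], dtype=float)
            outside = bool(np.all((vals < lo) | (vals > hi)))
            row[f"outside_{cond}"] = outside
            any_outside = any_outside or outside
        row["verdict"] = "not_timing" if any_outside else "possibly_timing"
        row["in_reference"] = True
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["gene", *(f"outside_{c}" for c in conditions), "verdict", "in_reference"]
    )
    table = table.set_index("gene") if len(table) else table
    return TimingVerdict(table)


def assign_stage(
    profile: pd.Series,
    timecourse: EmbryoTimecourse,
) -> tuple[pd.Series, float]:
    """Estimate the developmental stage of a sample profile.

    Rank-correlates the per-gene profile against every timecourse column
    over shared genes and returns (correlation per timepoint, best
    timepoint).  Ties break toward the earlier timepoint.
    """
    shared = profile.index.intersection(timecourse.expression.index)
    if len(shared) < 10:
        raise ValidationError(
            f"need >=10 shared genes for stage assignment, got {len(shared)}"
        )
    x = profile.loc[shared].to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValidationError("constant profile: rank correlation undefined")
    cors = []
    for tp in timecourse.expression.columns:
        y = timecourse.expression.loc[shared, tp].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            cors.append(np.nan)
            continue
        rho, _ = stats.spearmanr(x, y)
        cors.append(rho)
    cors = pd.Series(cors, index=timecourse.timepoints, name="spearman_rho")
    best = float(cors.index[int(np.nanargmax(cors.to_numpy()))])
    return cors, best
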