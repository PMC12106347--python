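"""qPCR relative quantification (2^-ddCq) and swimming-track kinematics.

Relative expression follows the standard comparative-Cq method:
dCq = Cq(target gene) - Cq(reference gene) within a sample,
ddCq = dCq(target sample) - dCq(control sample), fold change = 2^-ddCq.
Cq replicates of 30 cycles or more are considered invalid and excluded.
Replicates are combined by the arithmetic mean of Cq before dCq; the
per-replicate dCq values feed a Welch (unequal-variance) t-test.

Motility enters as centroid tracks sampled at nominally 0.3-s intervals.
Speeds use consecutive-frame displacements without smoothing; circle fits
use the algebraic (Kasa) least squares formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("ciliome")

CQ_VALID_MAX = 30.0


@dataclass(frozen=True)
class QuantRecord:
    """Cq replicates for one (sample, gene) measurement."""

    sample: str
    gene: str
    cq_values: tuple[float, ...]

    @property
    def valid(self) -> bool:
        return all(c < CQ_VALID_MAX for c in self.cq_values)


@dataclass(frozen=True)
class FoldChange:
    gene: str
    delta_cq_target: float
    delta_cq_control: float
    ddcq: float
    fc: float
    log2fc: float
    sem: float
    p: float

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fold change must be positive")


def records_from_table(df: pd.DataFrame) -> list[QuantRecord]:
    """Build records from a long table with columns sample, gene, cq
    (one replicate per row)."""
    records = []
    for (sample, gene), group in df.groupby(["sample", "gene"], sort=True):
        records.append(QuantRecord(
            sample=str(sample), gene=str(gene),
            cq_values=tuple(float(c) for c in group["cq"])))
    return records


def _gather(records: Sequence[QuantRecord], sample: str,
            gene: str) -> list[float]:
    values: list[float] = []
    for r in records:
        if r.sample == sample and r.gene == gene:
            if not r.valid:
                logger.warning(
                    "excluding invalid record %s/%s (Cq >= %g)",
                    r.sample, r.gene, CQ_VALID_MAX)
                continue
            values.extend(r.cq_values)
    return values


def fold_change(
    records: Sequence[QuantRecord],
    gene: str,
    reference_gene: str,
    target_sample: str,
    control_sample: str,
) -> FoldChange:
    """2^-ddCq fold change of ``gene`` in ``target_sample`` relative to
    ``control_sample``, normalized to ``reference_gene``.

    Records failing the Cq < 30 validity rule are excluded with a logged
    warning; a gene with no valid replicates in any group raises ValueError.
    SEM and the Welch p-value come from the per-replicate dCq distributions
    (each target-gene replicate paired against the sample's mean reference
    Cq); both are NaN when either sample has fewer than two replicates.
    """
    groups = {}
    for label, (sample, g) in {
        "target/gene": (target_sample, gene),
        "target/ref": (target_sample, reference_gene),
        "control/gene": (control_sample, gene),
        "control/ref": (control_sample, reference_gene),
    }.items():
        values = _gather(records, sample, g)
        if not values:
            raise ValueError(
                f"no valid Cq replicates for {label} ({sample}, {g})")
        groups[label] = np.asarray(values, dtype=float)

    dcq_target_reps = groups["target/gene"] - groups["target/ref"].mean()
    dcq_control_reps = groups["control/gene"] - groups["control/ref"].mean()
    dcq_target = float(dcq_target_reps.mean())
    dcq_control = float(dcq_control_reps.mean())
    ddcq = dcq_target - dcq_control

    if len(dcq_target_reps) >= 2 and len(dcq_control_reps) >= 2:
        sem = float(math.hypot(stats.sem(dcq_target_reps),
                               stats.sem(dcq_control_reps)))
        p, _sig = significance(dcq_target_reps, dcq_control_reps)
    else:
        sem = float("nan")
        p = float("nan")

    return FoldChange(
        gene=gene,
        delta_cq_target=dcq_target,
        delta_cq_control=dcq_control,
        ddcq=ddcq,
        fc=2.0 ** (-ddcq),
        log2fc=-ddcq,
        sem=sem,
        p=p,
    )


def significance(group_a: Sequence[float], group_b: Sequence[float],
                 alpha: float = 0.01) -> tuple[float, bool]:
    """Welch two-sample t-test; significance at ``alpha`` (default 0.01).

    Two identical constant groups compare as p = 1 (no evidence of any
    difference); groups of fewer than two values are an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if a.std() == 0 and b.std() == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return p, p < alpha


# ---------------------------------------------------------------------------
# Track kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Track:
    """Timestamped centroid path: (t seconds, x um, y um) per frame."""

    t: tuple[float, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]
    track_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if any(b <= a for a, b in zip(self.t, self.t[1:])):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    """Tracks from a long table with columns track (optional), t, x, y."""
    if "track" not in df.columns:
        df = df.assign(track="track0")
    tracks = []
    for tid, group in df.groupby("track", sort=True):
        group = group.sort_values("t")
        tracks.append(Track(
            t=tuple(float(v) for v in group["t"]),
            x=tuple(float(v) for v in group["x"]),
            y=tuple(float(v) for v in group["y"]),
            track_id=str(tid)))
    return tracks


def speed(track: Track) -> tuple[float, np.ndarray]:
    """(mean speed um/s, per-step speeds) from consecutive displacements."""
    if len(track) < 2:
        raise ValueError("speed needs at least two points")
    t = np.asarray(track.t)
    xy = np.column_stack([track.x, track.y])
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    dts = np.diff(t)
    per_step = steps / dts
    return float(per_step.mean()), per_step


def straightness(track: Track) -> float:
    """Net displacement / path length, in [0, 1]; NaN for a stationary
    track (zero path length)."""
    if len(track) < 2:
        raise ValueError("straightness needs at least two points")
    xy = np.column_stack([track.x, track.y])
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    if path == 0.0:
        return float("nan")
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    return net / path


def circle_fit(track: Track) -> tuple[float, float]:
    """Algebraic least-squares circle fit: (radius um, radial RMSE).

    Degenerate (collinear or too-few) inputs return radius infinity with
    NaN RMSE.
    """
    if len(track) < 3:
        raise ValueError("circle_fit needs at least three points")
    x = np.asarray(track.x)
    y = np.asarray(track.y)
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x ** 2 + y ** 2
    sol, _res, rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        return float("inf"), float("nan")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx ** 2 + cy ** 2
    if r2 <= 0 or not np.isfinite(r2):
        return float("inf"), float("nan")
    radius = float(np.sqrt(r2))
    radial = np.hypot(x - cx, y - cy)
    rmse = float(np.sqrt(np.mean((radial - radius) ** 2)))
    return radius, rmse
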