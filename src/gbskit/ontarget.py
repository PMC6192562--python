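"""On-target assessment: intersect observed fragment spans with a predicted digest.

An observed fragment (e.g. the merged span of a read pair) is *on target*
when it overlaps a fragment predicted by the in-silico digestion by at
least ``min_overlap_bp``.  The per-sample on-target percentage summarizes
how well the sequencing assay reproduced the designed library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gbskit.digest import Fragment

logger = logging.getLogger(__name__)


@dataclass
class IntervalSet:
    """A named collection of half-open intervals, sorted by (chromosome, start).

    Accepts :class:`~gbskit.digest.Fragment` records or plain
    ``(chromosome, start, end)`` tuples.  Input that is not sorted is
    sorted on construction with a logged notice.
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            if isinstance(iv, Fragment):
                chrom, start, end = iv.chromosome, iv.start, iv.end
            else:
                chrom, start, end = iv
            if start >= end:
                raise ValueError(f"interval start must precede end: {iv}")
            norm.append((str(chrom), int(start), int(end)))
        if norm != sorted(norm):
            logger.info("auto-sorting %d unsorted intervals", len(norm))
            norm.sort()
        self.intervals = norm
        # per-chromosome arrays for the sweep
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in sorted({c for c, _, _ in norm}):
            rows = [(s, e) for c, s, e in norm if c == chrom]
            starts = np.asarray([s for s, _ in rows], dtype=np.int64)
            ends = np.asarray([e for _, e in rows], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)


def intersect(
    observed: IntervalSet, predicted: IntervalSet, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Flag each observed interval that overlaps a predicted interval.

    The overlap of ``[a, b)`` and ``[c, d)`` is ``max(0, min(b, d) - max(a, c))``;
    an observed interval is a hit when it shares at least ``min_overlap_bp``
    with at least one predicted interval on the same chromosome.  Implemented
    as a per-chromosome sweep over start-sorted predicted intervals with a
    running maximum of ends, so only candidate overlaps are examined.

    Returns
    -------
    DataFrame with one row per observed interval (in sorted set order):
    columns ``chromosome, start, end, hit, overlap_bp`` where ``overlap_bp``
    is the largest single-interval overlap found.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    missing = set(observed.chromosomes) - set(predicted.chromosomes)
    if missing:
        logger.warning(
            "observed chromosomes absent from predicted set (counted as misses): %s",
            ", ".join(sorted(missing)),
        )
    rows = []
    for chrom, start, end in observed.intervals:
        best = 0
        if chrom in predicted._by_chrom:
            ps, pe = predicted._by_chrom[chrom]
            cummax_end = np.maximum.accumulate(pe)
            hi = int(np.searchsorted(ps, end, side="left"))  # starts < end
            i = hi - 1
            while i >= 0 and cummax_end[i] > start:
                ov = min(end, int(pe[i])) - max(start, int(ps[i]))
                if ov > best:
                    best = ov
                i -= 1
        rows.append((chrom, start, end, best >= min_overlap_bp, best))
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "hit", "overlap_bp"]
    )


def on_target_rate(
    observed: IntervalSet, predicted: IntervalSet, min_overlap_bp: int = 1
) -> float:
    """Percentage of observed intervals hitting the predicted digest, in [0, 100]."""
    if len(observed) == 0:
        raise ValueError("on-target rate undefined for an empty observed set")
    hits = intersect(observed, predicted, min_overlap_bp)["hit"].sum()
    return 100.0 * float(hits) / len(observed)


def on_target_report(
    samples: dict[str, IntervalSet], predicted: IntervalSet, min_overlap_bp: int = 1
) -> pd.DataFrame:
    """Per-sample on-target table: sample, n_observed, n_hits, percent."""
    rows = []
    for sample, obs in samples.items():
        res = intersect(obs, predicted, min_overlap_bp)
        n_hits = int(res["hit"].sum())
        rows.append((sample, len(obs), n_hits, 100.0 * n_hits / max(len(obs), 1)))
    return pd.DataFrame(rows, columns=["sample", "n_observed", "n_hits", "percent"])
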