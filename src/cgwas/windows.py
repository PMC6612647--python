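"""Sliding 1 kb window grid with 500 bp overlap.

Windows are 1-based, fully closed intervals anchored at position 1 of each
chromosome, so starts are 1, 501, 1001, ...; every unique 2 kb region is
covered by three overlapping windows.  A window is analyzed only if, after
the variant-level filters (imputation r2 > 0.4 and genotype data in at
least half of the cohorts), it retains at least two member variants of the
requested class (CGS or non-CGS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence

from .annotation import CGSAnnotation

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 1000
WINDOW_OFFSET = 500
MIN_MEMBERS = 2
R2_MIN = 0.4
MIN_COHORT_FRACTION = 0.5


@dataclass
class Window:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    members: List[CGSAnnotation] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> List[str]:
        return [m.variant.id for m in self.members]

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @property
    def key(self):
        return (self.chrom, self.start, self.end)


def build_window_grid(
    chrom_lengths: Dict[str, int],
    length: int = WINDOW_LENGTH,
    offset: int = WINDOW_OFFSET,
) -> Iterator[Window]:
    """Yield the empty window frames fully contained in each chromosome."""
    if length % offset != 0:
        raise ValueError(f"window length {length} must be a multiple of offset {offset}")
    for chrom, chrom_len in chrom_lengths.items():
        if chrom_len < 1:
            raise ValueError(f"nonpositive length for chromosome {chrom!r}")
        start = 1
        while start + length - 1 <= chrom_len:
            yield Window(chrom=chrom, start=start, end=start + length - 1)
            start += offset


def passes_variant_filters(
    ann: CGSAnnotation,
    n_cohorts_total: int,
    r2_min: float = R2_MIN,
    min_cohort_fraction: float = MIN_COHORT_FRACTION,
) -> bool:
    """Imputation-quality and cohort-coverage filter (r2 strictly above, coverage at least half)."""
    v = ann.variant
    if v.imputation_r2 <= r2_min:
        return False
    if v.cohorts_present / n_cohorts_total < min_cohort_fraction:
        return False
    return True


def assign_and_filter(
    windows: Iterable[Window],
    annotations: Sequence[CGSAnnotation],
    n_cohorts_total: int = 1,
    r2_min: float = R2_MIN,
    min_cohort_fraction: float = MIN_COHORT_FRACTION,
    min_members: int = MIN_MEMBERS,
    member_class: str = "CGS",
) -> List[Window]:
    """Populate grid windows with surviving variants of ``member_class``.

    Annotations must be position-sorted within each chromosome.  A variant at
    position p joins every grid window with start <= p <= end (at most two on
    the interior of a chromosome).  Windows retaining fewer than
    ``min_members`` variants are suppressed.
    """
    if member_class not in ("CGS", "non-CGS"):
        raise ValueError(f"member_class must be 'CGS' or 'non-CGS', got {member_class!r}")
    want_cgs = member_class == "CGS"

    by_chrom: Dict[str, List[CGSAnnotation]] = {}
    seen_ids = set()
    last_pos: Dict[str, int] = {}
    for ann in annotations:
        v = ann.variant
        if v.pos < last_pos.get(v.chrom, 0):
            raise ValueError(f"annotations not sorted by position at {v.chrom}:{v.pos}")
        last_pos[v.chrom] = v.pos
        if v.id in seen_ids:
            logger.warning("duplicate variant id %s: keeping first occurrence", v.id)
            continue
        seen_ids.add(v.id)
        if ann.is_cgs != want_cgs:
            continue
        if not passes_variant_filters(ann, n_cohorts_total, r2_min, min_cohort_fraction):
            continue
        by_chrom.setdefault(v.chrom, []).append(ann)

    populated: List[Window] = []
    cursor: Dict[str, int] = {}
    for win in windows:
        anns = by_chrom.get(win.chrom, [])
        # windows arrive in grid order; advance a per-chromosome cursor past
        # variants left of the window, then scan the (<= window span) overlap
        i = cursor.get(win.chrom, 0)
        while i < len(anns) and anns[i].variant.pos < win.start:
            i += 1
        cursor[win.chrom] = i
        j = i
        members = []
        while j < len(anns) and anns[j].variant.pos <= win.end:
            members.append(anns[j])
            j += 1
        if len(members) >= min_members:
            populated.append(Window(win.chrom, win.start, win.end, members))
    logger.info("retained %d windows with >= %d %s members", len(populated), min_members, member_class)
    return populated


def windows_to_frame(windows: Iterable[Window]):
    """BED-like table of populated windows (1-based closed coordinates)."""
    import pandas as pd

    rows = [
        (w.chrom, w.start, w.end, w.n_members, ",".join(w.member_ids))
        for w in windows
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members", "member_ids"])
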