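"""Focal-point placement across the genome.

A focal point (FP) is a ±5 kb window intended to carry a cluster of SNPs
that together form one multi-allelic haploblock marker. Coverage is built in
three passes:

1. *anchored* — one FP per integer centimorgan of the genetic map, with the
   physical center interpolated linearly between flanking map points
   (constant kb/cM extrapolation beyond the mapped interval);
2. *bridge* — physical gaps larger than ``bridge_gap`` between consecutive
   FPs (or between a chromosome end and its nearest FP) are subdivided at
   roughly one FP per ``kb_per_cM``;
3. *terminal* — chromosome ends are enriched with extra FPs, since map ends
   are typically marker-poor and telomeric recombination is high.

Centers are kept at least ``half_width`` apart (deduplication), and windows
are clipped to chromosome bounds.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .formats import GeneticMapPoint, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FocalPointParams:
    half_width: int = 5_000
    target_spacing_cm: float = 1.0
    bridge_gap: int = 400_000
    kb_per_cm: int = 440_000
    terminal_window: int = 40_000
    terminal_fps_per_end: int = 4

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.bridge_gap < 2 * self.half_width:
            raise ValueError("bridge_gap must be at least 2 * half_width")


@dataclass
class FocalPoint:
    fp_id: str
    chrom: str
    center: int
    win_start: int
    win_end: int
    origin: str  # anchored | bridge | terminal
    candidates: list[str] = field(default_factory=list)

    def contains(self, pos: int) -> bool:
        return self.win_start <= pos <= self.win_end

    def to_dict(self) -> dict:
        return {
            "fp_id": self.fp_id, "chrom": self.chrom, "center": self.center,
            "win_start": self.win_start, "win_end": self.win_end,
            "origin": self.origin, "candidates": list(self.candidates),
        }


def _make_fp(chrom: str, center: int, origin: str, params: FocalPointParams,
             chrom_length: int | None) -> FocalPoint:
    center = int(round(center))
    if chrom_length is not None:
        center = max(1, min(center, chrom_length))
    start = center - params.half_width
    end = center + params.half_width
    if chrom_length is not None:
        start = max(1, start)
        end = min(chrom_length, end)
    else:
        start = max(1, start)
    return FocalPoint("", chrom, center, start, end, origin)


def _dedupe(fps: list[FocalPoint], params: FocalPointParams) -> list[FocalPoint]:
    """Drop later-pass centers closer than half_width to an accepted one.

    Anchored FPs take precedence over bridge, bridge over terminal; within a
    pass, left-to-right order wins.
    """
    rank = {"anchored": 0, "bridge": 1, "terminal": 2}
    out: list[FocalPoint] = []
    for chrom in sorted({fp.chrom for fp in fps}):
        chrom_fps = sorted(
            (fp for fp in fps if fp.chrom == chrom),
            key=lambda fp: (rank[fp.origin], fp.center),
        )
        kept: list[FocalPoint] = []
        for fp in chrom_fps:
            if any(abs(fp.center - k.center) < params.half_width for k in kept):
                continue
            kept.append(fp)
        out.extend(sorted(kept, key=lambda fp: fp.center))
    return out


def number_focal_points(fps: list[FocalPoint]) -> list[FocalPoint]:
    """Assign deterministic ids in (chrom, center) order."""
    fps = sorted(fps, key=lambda fp: (fp.chrom, fp.center))
    return [replace(fp, fp_id=f"FP{i:05d}") for i, fp in enumerate(fps, start=1)]


def anchor_focal_points(
    map_points: list[GeneticMapPoint],
    params: FocalPointParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[FocalPoint]:
    """One FP per integer cM, physically placed by linear interpolation.

    Duplicate-cM map points are collapsed (first kept, warning logged);
    positions beyond the mapped interval are extrapolated at ``kb_per_cM``.
    """
    params = params or FocalPointParams()
    fps: list[FocalPoint] = []
    for chrom in sorted({p.chrom for p in map_points}):
        rows = sorted((p for p in map_points if p.chrom == chrom), key=lambda p: p.genetic_pos)
        cms: list[float] = []
        bps: list[float] = []
        for p in rows:
            if cms and p.genetic_pos == cms[-1]:
                logger.warning("duplicate cM %.3f on %s; keeping first marker", p.genetic_pos, chrom)
                continue
            cms.append(p.genetic_pos)
            bps.append(float(p.physical_pos))
        if not cms:
            continue
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        step = params.target_spacing_cm
        for i in range(int(math.floor(max(cms) / step)) + 1):
            target = i * step
            if target < cms[0]:
                center = bps[0] - (cms[0] - target) * params.kb_per_cm
            elif target > cms[-1]:
                center = bps[-1] + (target - cms[-1]) * params.kb_per_cm
            else:
                center = float(np.interp(target, cms, bps))
            if length is not None:
                center = min(max(center, 1), length)
            elif center < 1:
                center = 1
            fps.append(_make_fp(chrom, center, "anchored", params, length))
    return _dedupe(fps, params)


def bridge_focal_points(
    fps: list[FocalPoint],
    chrom_lengths: dict[str, int],
    params: FocalPointParams | None = None,
) -> list[FocalPoint]:
    """Subdivide physical gaps larger than ``bridge_gap``.

    A gap of g bp receives ceil(g / kb_per_cM) − 1 equally spaced FPs.
    Chromosome start and end count as gap boundaries; a chromosome with no
    FPs at all is tiled every ``kb_per_cM`` across its usable span.
    """
    params = params or FocalPointParams()
    new: list[FocalPoint] = []
    for chrom, length in chrom_lengths.items():
        centers = sorted(fp.center for fp in fps if fp.chrom == chrom)
        if not centers:
            for center in range(params.half_width, length - params.half_width + 1, params.kb_per_cm):
                new.append(_make_fp(chrom, center, "bridge", params, length))
            continue
        boundaries = [0] + centers + [length]
        for a, b in zip(boundaries, boundaries[1:]):
            gap = b - a
            if gap <= params.bridge_gap:
                continue
            n_insert = math.ceil(gap / params.kb_per_cm) - 1
            for i in range(1, n_insert + 1):
                center = a + gap * i / (n_insert + 1)
                center = min(max(center, params.half_width), length - params.half_width)
                new.append(_make_fp(chrom, center, "bridge", params, length))
    return _dedupe(list(fps) + new, params)


def terminal_focal_points(
    fps: list[FocalPoint],
    chrom_lengths: dict[str, int],
    params: FocalPointParams | None = None,
) -> list[FocalPoint]:
    """Enrich chromosome ends with up to ``terminal_fps_per_end`` FPs per end.

    Candidate centers sit ``2 * half_width`` apart inside ``terminal_window``
    of each end, skipping positions within ``half_width`` of an existing FP.
    """
    params = params or FocalPointParams()
    new: list[FocalPoint] = []
    for chrom, length in chrom_lengths.items():
        existing = [fp.center for fp in fps if fp.chrom == chrom]
        placed: list[int] = []

        def try_add(center: int) -> None:
            if any(abs(center - c) < params.half_width for c in existing + placed):
                return
            placed.append(center)
            new.append(_make_fp(chrom, center, "terminal", params, length))

        added_left = 0
        center = params.half_width
        while added_left < params.terminal_fps_per_end and center <= min(params.terminal_window, length - params.half_width):
            before = len(placed)
            try_add(center)
            added_left += len(placed) - before
            center += 2 * params.half_width
        added_right = 0
        center = length - params.half_width
        while added_right < params.terminal_fps_per_end and center >= max(length - params.terminal_window, params.half_width):
            before = len(placed)
            try_add(center)
            added_right += len(placed) - before
            center -= 2 * params.half_width
    return _dedupe(list(fps) + new, params)


def place_focal_points(
    map_points: list[GeneticMapPoint],
    chrom_lengths: dict[str, int],
    params: FocalPointParams | None = None,
) -> list[FocalPoint]:
    """Anchor → bridge → terminal placement, finalized with stable ids."""
    params = params or FocalPointParams()
    fps = anchor_focal_points(map_points, params, chrom_lengths)
    fps = bridge_focal_points(fps, chrom_lengths, params)
    fps = terminal_focal_points(fps, chrom_lengths, params)
    return number_focal_points(fps)


def assign_candidates(
    fps: list[FocalPoint],
    candidates: list[VariantRecord],
) -> tuple[list[FocalPoint], list[VariantRecord]]:
    """Assign each candidate SNP to the FP whose closed window contains it.

    With overlapping windows the nearest center wins; ties go to the lower
    fp_id. Returns FPs with candidate id lists filled plus the outside-FP
    pool. Requires finalized (numbered) FPs.
    """
    if any(not fp.fp_id for fp in fps):
        raise ValueError("focal points must be numbered before assignment")
    fps = [replace(fp, candidates=[]) for fp in sorted(fps, key=lambda f: (f.chrom, f.center))]
    by_chrom: dict[str, list[FocalPoint]] = {}
    for fp in fps:
        by_chrom.setdefault(fp.chrom, []).append(fp)
    centers = {c: np.asarray([fp.center for fp in v], dtype=np.int64) for c, v in by_chrom.items()}
    outside: list[VariantRecord] = []
    for rec in candidates:
        chrom_fps = by_chrom.get(rec.chrom)
        if not chrom_fps:
            outside.append(rec)
            continue
        arr = centers[rec.chrom]
        i = int(np.searchsorted(arr, rec.pos))
        best: FocalPoint | None = None
        best_key: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(chrom_fps) and chrom_fps[j].contains(rec.pos):
                key = (abs(rec.pos - chrom_fps[j].center), chrom_fps[j].fp_id)
                if best_key is None or key < best_key:
                    best, best_key = chrom_fps[j], key
        if best is None:
            outside.append(rec)
        else:
            best.candidates.append(rec.snp_id)
    return fps, outside


def fp_spacing_stats(fps: list[FocalPoint], chrom_lengths: dict[str, int],
                     large_gap: int = 1_000_000) -> dict:
    """Inter-FP spacing summary: mean/max consecutive-center distance and
    gaps larger than ``large_gap``; single-FP chromosomes are noted and
    excluded from the mean."""
    distances: list[int] = []
    gaps: list[dict] = []
    single: list[str] = []
    for chrom in sorted(chrom_lengths):
        centers = sorted(fp.center for fp in fps if fp.chrom == chrom)
        if len(centers) < 2:
            if len(centers) == 1:
                single.append(chrom)
            continue
        diffs = np.diff(centers)
        distances.extend(int(d) for d in diffs)
        for a, d in zip(centers, diffs):
            if d > large_gap:
                gaps.append({"chrom": chrom, "start": int(a), "end": int(a + d), "length": int(d)})
    return {
        "mean_distance": float(np.mean(distances)) if distances else 0.0,
        "max_distance": int(max(distances)) if distances else 0,
        "large_gaps": gaps,
        "single_fp_chroms": single,
        "n_fps": len(fps),
    }


def write_fps_json(fps: list[FocalPoint], path: str) -> None:
    with open(path, "w") as fh:
        json.dump([fp.to_dict() for fp in fps], fh, indent=1)


def read_fps_json(path: str) -> list[FocalPoint]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        FocalPoint(d["fp_id"], d["chrom"], d["center"], d["win_start"], d["win_end"],
                   d["origin"], list(d.get("candidates", [])))
        for d in raw
    ]


def write_fps_bed(fps: list[FocalPoint], path: str) -> None:
    """FP windows as BED (0-based half-open; converted at this boundary)."""
    with open(path, "w") as fh:
        for fp in sorted(fps, key=lambda f: (f.chrom, f.center)):
            fh.write(f"{fp.chrom}\t{fp.win_start - 1}\t{fp.win_end}\t{fp.fp_id}\n")
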