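"""Argos location quality control.

All standard-class locations (3, 2, 1; 68th error percentile < 2.5 km) are
kept unconditionally.  Auxiliary-class locations (0, A, B, Z; 68th error
percentile 10-30 km) are kept only if they are *redundant* -- within
``maxredun_km`` (default 10 km) of a temporally adjacent retained fix -- or
pass the *rate test*: both implied segment speeds to the adjacent retained
fixes at most ``vmax_kmh`` (default 120 km/h, a maximum sustainable rate of
movement for these species).

Violating fixes are removed iteratively, worst offender first (largest
minimum implied speed; ties broken by earlier timestamp), and the implied
speeds are recomputed after each removal.  This is deterministic and
insensitive to scan order, and terminates because each step removes one fix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import Fix, PipelineConfig, Track, logger
from .geo import gc_distance_km, ground_speed_kmh

__all__ = ["FilterResult", "hybrid_filter"]


@dataclass
class FilterResult:
    """Partition of a track's fixes into retained and removed (with reasons)."""

    retained: list[Fix]
    removed: list[tuple[Fix, str]]   # reason in {"speed", "duplicate"}


def _dist(f1: Fix, f2: Fix) -> float:
    return float(gc_distance_km(f1.lat, f1.lon, f2.lat, f2.lon))


def _speed(f1: Fix, f2: Fix) -> float:
    return ground_speed_kmh(f1.lat, f1.lon, f1.timestamp, f2.lat, f2.lon, f2.timestamp)


def hybrid_filter(track: Track, cfg: PipelineConfig | None = None) -> FilterResult:
    """Apply class retention plus the speed/redundant-distance filter.

    Returns a :class:`FilterResult`; ``retained`` preserves time order and
    ``retained + removed`` is a partition of the input fixes.
    """
    cfg = cfg or PipelineConfig()
    fixes = list(track.fixes)
    if len(fixes) < 2:
        if fixes:
            logger.warning("track %s has < 2 fixes; filter is a no-op", track.individual_id)
        return FilterResult(retained=fixes, removed=[])

    removed: list[tuple[Fix, str]] = []
    active = list(range(len(fixes)))

    # exact duplicate timestamps should not survive reading, but guard anyway
    i = 1
    while i < len(active):
        f_prev, f_cur = fixes[active[i - 1]], fixes[active[i]]
        if f_cur.timestamp == f_prev.timestamp:
            removed.append((f_cur, "duplicate"))
            del active[i]
        else:
            i += 1

    def _violations(idxs: list[int]) -> dict[int, float]:
        """Map active auxiliary index -> its minimum implied speed, for violators."""
        out: dict[int, float] = {}
        for pos, idx in enumerate(idxs):
            fix = fixes[idx]
            if fix.is_standard:
                continue
            prev_fix = fixes[idxs[pos - 1]] if pos > 0 else None
            next_fix = fixes[idxs[pos + 1]] if pos + 1 < len(idxs) else None
            dists = [_dist(n, fix) for n in (prev_fix, next_fix) if n is not None]
            if not dists:
                continue
            if min(dists) <= cfg.maxredun_km:
                continue  # redundant with a neighbour: plausible short movement
            speeds = []
            if prev_fix is not None:
                speeds.append(_speed(prev_fix, fix))
            if next_fix is not None:
                speeds.append(_speed(fix, next_fix))
            if all(s <= cfg.vmax_kmh for s in speeds):
                continue
            out[idx] = min(speeds)
        return out

    while True:
        bad = _violations(active)
        if not bad:
            break
        # worst offender: largest minimum implied speed; tie -> earliest time
        worst_speed = max(bad.values())
        worst = min(
            (idx for idx, s in bad.items() if s == worst_speed),
            key=lambda idx: fixes[idx].timestamp,
        )
        removed.append((fixes[worst], "speed"))
        active.remove(worst)

    return FilterResult(retained=[fixes[i] for i in active], removed=removed)


def filtered_track(track: Track, cfg: PipelineConfig | None = None) -> Track:
    """Convenience: the track rebuilt from the retained fixes."""
    res = hybrid_filter(track, cfg)
    return Track(
        individual_id=track.individual_id, species=track.species,
        fixes=res.retained, release_time=track.release_time,
    )
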