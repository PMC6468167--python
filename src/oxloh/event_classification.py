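"""Classification of LOH / copy-number segments into recombination events.

Two entry points:

* :func:`classify_sector_pair` — red/white sector pairs from a sectored
  colony.  Reciprocal terminal LOH between the sectors diagnoses a
  crossover (CO); terminal LOH in one sector only, copy-neutral, is
  break-induced replication (BIR); interstitial tracts are conversions
  (CON).  Conversion tracts are typed 3:1 or 4:0 by summing haplotype
  copies across the two sectors, and a 4:0 sub-region places the
  initiating DSB in G1 (unreplicated chromosome).
* :func:`classify_unsectored` — single isolates, where segregation
  information is gone: terminal LOH is typed CO_or_BIR, and an
  interstitial tract of one haplotype adjacent to a terminal LOH of the
  opposite haplotype is merged into one CON_CO event (a crossover with
  its associated conversion, seen from one daughter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .array_calling import LohSegment
from .synthetic_data import GenomeMap

__all__ = [
    "SectorPair",
    "RecombinationEvent",
    "TractInterval",
    "type_conversion_tract",
    "classify_sector_pair",
    "classify_unsectored",
    "infer_initiation_phase",
]

EVENT_TYPES = (
    "CON", "CO", "CON_CO", "CO_or_BIR", "BIR",
    "terminal_del", "interstitial_del", "interstitial_dup", "terminal_dup",
    "trisomy", "monosomy", "UPD",
)

PLOIDY_MARKER_FRACTION = 0.90  # aberrant-marker fraction required for a whole-chromosome call


class AlignmentError(ValueError):
    """Sectors or segments do not share a marker frame."""


@dataclass(frozen=True)
class TractInterval:
    start_kb: float
    end_kb: float
    tract_class: str  # "3:1" or "4:0"


@dataclass
class RecombinationEvent:
    type: str
    chromosome: str
    tracts: list[TractInterval] = field(default_factory=list)
    co_breakpoint: tuple[float, float] | None = None
    donor: str | None = None  # haplotype over-represented in the tract / terminal LOH
    phase: str = "NA"  # G1 | G2_or_nick | NA
    isolate: str = ""
    start_kb: float | None = None
    end_kb: float | None = None
    flags: tuple[str, ...] = ()

    @property
    def has_40(self) -> bool:
        return any(t.tract_class == "4:0" for t in self.tracts)

    @property
    def is_conversion(self) -> bool:
        return self.type in ("CON", "CO", "CON_CO") and bool(self.tracts)


@dataclass
class SectorPair:
    """Segment lists for the red and white sectors of one colony."""

    red: list[LohSegment]
    white: list[LohSegment]
    genome: GenomeMap

    def __post_init__(self) -> None:
        def marker_count(segs: list[LohSegment]) -> dict[str, int]:
            out: dict[str, int] = {}
            for s in segs:
                out[s.chrom] = out.get(s.chrom, 0) + s.n_markers
            return out

        if marker_count(self.red) != marker_count(self.white):
            raise AlignmentError("red and white sectors cover different marker sets")


# ---------------------------------------------------------------------------

def type_conversion_tract(
    red_state: tuple[int, int], white_state: tuple[int, int]
) -> str | None:
    """Type a copy-neutral marker state pair as a 3:1 or 4:0 conversion.

    Copies of each haplotype are summed across the two sectors: (3,1) or
    (1,3) is a 3:1 tract, (4,0) or (0,4) a 4:0 tract, (2,2) no tract.
    Non-copy-neutral states must be routed through copy-number logic first.
    """
    for s in (red_state, white_state):
        if s[0] + s[1] != 2:
            raise ValueError(f"state {s} is not copy-neutral; route through CNV classification")
    w = red_state[0] + white_state[0]
    y = red_state[1] + white_state[1]
    if (w, y) in ((3, 1), (1, 3)):
        return "3:1"
    if (w, y) in ((4, 0), (0, 4)):
        return "4:0"
    return None


def infer_initiation_phase(event: RecombinationEvent) -> str:
    """G1 if any 4:0 sub-region (both sisters repaired, so the DSB preceded
    replication); G2_or_nick for a pure 3:1 tract; NA without tract typing."""
    if not event.tracts:
        return "NA"
    return "G1" if event.has_40 else "G2_or_nick"


# ---------------------------------------------------------------------------
# helpers shared by both classifiers
# ---------------------------------------------------------------------------

def _per_marker_states(
    segs: list[LohSegment], chrom: str, n: int
) -> np.ndarray | None:
    """Expand a chromosome's segments back to per-marker (cnW, cnY) arrays."""
    sub = [s for s in segs if s.chrom == chrom]
    if not sub:
        return None
    out = np.zeros((n, 2), dtype=int)
    covered = 0
    for s in sub:
        out[s.first_idx : s.last_idx + 1] = s.state
        covered += s.n_markers
    if covered != n:
        raise AlignmentError(f"segments do not tile the {n} markers of {chrom}")
    return out


def _blocks(nonbase: np.ndarray, min_gap: int) -> list[tuple[int, int]]:
    """Maximal non-baseline marker blocks, merging across gaps < min_gap."""
    idx = np.flatnonzero(nonbase)
    if len(idx) == 0:
        return []
    blocks = [[int(idx[0]), int(idx[0])]]
    for i in idx[1:]:
        if i - blocks[-1][1] - 1 < min_gap:
            blocks[-1][1] = int(i)
        else:
            blocks.append([int(i), int(i)])
    return [(a, b) for a, b in blocks]


def _bp_interval(pos: np.ndarray, i: int, j: int, chrom_len: float) -> tuple[float, float]:
    """Open interval between markers i (last of old state) and j (first of new)."""
    lo = 0.0 if i < 0 else float(pos[i])
    hi = float(chrom_len) if j >= len(pos) else float(pos[j])
    return (lo, hi)


def _tract_intervals(
    classes: list[str | None], pos: np.ndarray, lo: int, hi: int
) -> list[TractInterval]:
    """Contiguous 3:1 / 4:0 sub-intervals over marker index range [lo, hi]."""
    out: list[TractInterval] = []
    start = None
    cur = None
    for i in range(lo, hi + 2):
        c = classes[i] if i <= hi else None
        if c != cur:
            if cur is not None:
                out.append(TractInterval(float(pos[start]), float(pos[i - 1]), cur))
            start, cur = i, c
    return out


# ---------------------------------------------------------------------------
# Sectored colonies
# ---------------------------------------------------------------------------

def classify_sector_pair(pair: SectorPair, isolate: str = "") -> list[RecombinationEvent]:
    """Classify all events in a red/white sector pair, chromosome by chromosome."""
    events: list[RecombinationEvent] = []
    g = pair.genome
    for c in g.chromosomes:
        idx = g.marker_index(c.name)
        n = len(idx)
        if n == 0:
            continue
        pos = g.markers["pos_kb"].to_numpy()[idx]
        red = _per_marker_states(pair.red, c.name, n)
        white = _per_marker_states(pair.white, c.name, n)
        if red is None or white is None:
            if (red is None) != (white is None):
                raise AlignmentError(f"only one sector has segments on {c.name}")
            continue
        events.extend(_classify_chrom_pair(red, white, pos, c, isolate))
    return events


def _classify_chrom_pair(red, white, pos, chrom, isolate) -> list[RecombinationEvent]:
    n = len(pos)
    events: list[RecombinationEvent] = []

    # Whole-chromosome states first.  A ploidy/UPD call in one sector only
    # counts when the other sector is clean baseline: a crossover breaking
    # near the centromere-proximal end also makes one sector look
    # chromosome-wide homozygous, but then the sister sector carries the
    # reciprocal pattern rather than staying heterozygous.
    for sector_states, other in ((red, white), (white, red)):
        ev = _ploidy_event(sector_states, pos, chrom, isolate)
        other_het = bool(np.all((other[:, 0] == 1) & (other[:, 1] == 1)))
        if ev is not None and other_het:
            return [ev]

    neutral = (red.sum(axis=1) == 2) & (white.sum(axis=1) == 2)
    # per-marker conversion class where copy-neutral
    classes: list[str | None] = [
        type_conversion_tract(tuple(red[i]), tuple(white[i])) if neutral[i] else None
        for i in range(n)
    ]
    # reciprocal homozygosity: sectors homozygous for opposite haplotypes
    reciprocal = neutral & (
        ((red[:, 0] == 2) & (white[:, 1] == 2)) | ((red[:, 1] == 2) & (white[:, 0] == 2))
    )
    het_both = (red[:, 0] == 1) & (red[:, 1] == 1) & (white[:, 0] == 1) & (white[:, 1] == 1)

    # copy-number alterations, per sector
    for states, sector in ((red, "red"), (white, "white")):
        events.extend(_cnv_events(states, pos, chrom, isolate, flag=sector))

    nonbase = ~het_both & neutral
    for a, b in _blocks(nonbase, min_gap=2):
        terminal_recip = reciprocal[b] and b == n - 1
        tract_lo, tract_hi = a, b
        if terminal_recip:
            # crossover: the reciprocal region runs to the telomere; the
            # conversion tract is the contiguous 3:1/4:0 region proximal
            j = b
            while j >= a and reciprocal[j] and classes[j] is None:
                j -= 1
            co_bp = _bp_interval(pos, j, j + 1, chrom.length_kb)
            tract_hi = j
            tracts = _tract_intervals(classes, pos, tract_lo, tract_hi) if j >= a else []
            donor = _tract_donor(red, white, tract_lo, tract_hi) if tracts else None
            ev = RecombinationEvent(
                "CO", chrom.name, tracts, co_bp, donor,
                isolate=isolate, start_kb=float(pos[a]), end_kb=float(pos[b]),
            )
        else:
            one_sided_terminal = (
                b == n - 1
                and classes[b] == "3:1"
                and (tuple(red[b]) == (1, 1) or tuple(white[b]) == (1, 1))
            )
            if one_sided_terminal and all(classes[i] == "3:1" for i in range(a, b + 1)):
                donor = _tract_donor(red, white, a, b)
                ev = RecombinationEvent(
                    "BIR", chrom.name, [], None, donor,
                    isolate=isolate, start_kb=float(pos[a]), end_kb=float(pos[b]),
                )
            else:
                tracts = _tract_intervals(classes, pos, a, b)
                donor = _tract_donor(red, white, a, b)
                ev = RecombinationEvent(
                    "CON", chrom.name, tracts, None, donor,
                    isolate=isolate, start_kb=float(pos[a]), end_kb=float(pos[b]),
                )
        ev.phase = infer_initiation_phase(ev)
        events.append(ev)
    return events


def _tract_donor(red, white, lo, hi) -> str | None:
    w = int(red[lo : hi + 1, 0].sum() + white[lo : hi + 1, 0].sum())
    y = int(red[lo : hi + 1, 1].sum() + white[lo : hi + 1, 1].sum())
    if w == y:
        return None
    return "W" if w > y else "Y"


def _ploidy_event(states, pos, chrom, isolate) -> RecombinationEvent | None:
    n = len(pos)
    total = states.sum(axis=1)
    frac = PLOIDY_MARKER_FRACTION
    if (total == 3).sum() >= frac * n:
        return RecombinationEvent("trisomy", chrom.name, isolate=isolate,
                                  start_kb=float(pos[0]), end_kb=float(pos[-1]))
    if (total == 1).sum() >= frac * n:
        return RecombinationEvent("monosomy", chrom.name, isolate=isolate,
                                  start_kb=float(pos[0]), end_kb=float(pos[-1]))
    cen_ok = True  # UPD requires homozygosity across the centromere; with
    # >=90% of markers aberrant the centromere is always spanned
    for hap, col in (("W", 0), ("Y", 1)):
        if ((states[:, col] == 2) & (total == 2)).sum() >= frac * n and cen_ok:
            return RecombinationEvent("UPD", chrom.name, donor=hap, isolate=isolate,
                                      start_kb=float(pos[0]), end_kb=float(pos[-1]))
    return None


def _cnv_events(states, pos, chrom, isolate, flag=None) -> list[RecombinationEvent]:
    n = len(pos)
    total = states.sum(axis=1)
    events = []
    for a, b in _blocks(total != 2, min_gap=2):
        terminal = b == n - 1 or a == 0
        gain = total[a:b + 1].mean() > 2
        kind = ("terminal_" if terminal else "interstitial_") + ("dup" if gain else "del")
        # donor: the haplotype gained, or the one retained after loss
        w, y = states[a:b + 1, 0].sum(), states[a:b + 1, 1].sum()
        donor = "W" if w > y else "Y" if y > w else None
        flags = (flag,) if flag else ()
        events.append(
            RecombinationEvent(
                kind, chrom.name, donor=donor, isolate=isolate,
                start_kb=float(pos[a]), end_kb=float(pos[b]),
                flags=tuple(f for f in flags if f),
            )
        )
    return events


# ---------------------------------------------------------------------------
# Unsectored isolates
# ---------------------------------------------------------------------------

def classify_unsectored(
    segments: list[LohSegment],
    genome: GenomeMap,
    adjacency_kb: float = 25.0,
    short_terminal_markers: int = 2,
) -> list[RecombinationEvent]:
    """Classify one isolate's segments without sector information.

    Interstitial copy-neutral LOH is CON; LOH running to a telomere is
    CO_or_BIR (the two cannot be distinguished in a single daughter); a
    CON of one haplotype within ``adjacency_kb`` of a terminal LOH of the
    opposite haplotype merges into a single CON_CO event.  Copy-number
    segments become del/dup events; whole-chromosome states become
    trisomy / monosomy / UPD.
    """
    chroms = {s.chrom for s in segments}
    events: list[RecombinationEvent] = []
    for c in genome.chromosomes:
        if c.name not in chroms:
            continue
        idx = genome.marker_index(c.name)
        n = len(idx)
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        states = _per_marker_states(segments, c.name, n)
        ev = _ploidy_event(states, pos, c, "")
        if ev is not None:
            events.append(ev)
            continue
        events.extend(_cnv_events(states, pos, c, ""))

        total = states.sum(axis=1)
        neutral = total == 2
        hom_w = neutral & (states[:, 0] == 2)
        hom_y = neutral & (states[:, 1] == 2)
        raw: list[RecombinationEvent] = []
        for hap, hom in (("W", hom_w), ("Y", hom_y)):
            for a, b in _blocks(hom, min_gap=2):
                terminal = b == n - 1 or a == 0
                if terminal:
                    flags = ("short_terminal",) if b - a + 1 <= short_terminal_markers else ()
                    raw.append(RecombinationEvent(
                        "CO_or_BIR", c.name, donor=hap,
                        start_kb=float(pos[a]), end_kb=float(pos[b]), flags=flags,
                    ))
                else:
                    tr = [TractInterval(float(pos[a]), float(pos[b]), "3:1")]
                    raw.append(RecombinationEvent(
                        "CON", c.name, tr, donor=hap,
                        start_kb=float(pos[a]), end_kb=float(pos[b]),
                    ))
        events.extend(_merge_con_co(raw, adjacency_kb))
    return events


def _merge_con_co(
    raw: list[RecombinationEvent], adjacency_kb: float
) -> list[RecombinationEvent]:
    """Merge CON + opposite-haplotype terminal LOH within adjacency_kb.

    Symmetric in haplotype labels and input order: candidate pairs are
    evaluated on sorted coordinates.
    """
    raw = sorted(raw, key=lambda e: (e.start_kb, e.end_kb, e.type))
    used = [False] * len(raw)
    out: list[RecombinationEvent] = []
    for i, ev in enumerate(raw):
        if used[i] or ev.type != "CON":
            continue
        for j, other in enumerate(raw):
            if used[j] or other.type != "CO_or_BIR" or other.donor == ev.donor:
                continue
            gap = max(other.start_kb - ev.end_kb, ev.start_kb - other.end_kb)
            if gap <= adjacency_kb:
                used[i] = used[j] = True
                out.append(RecombinationEvent(
                    "CON_CO", ev.chromosome, list(ev.tracts),
                    co_breakpoint=None, donor=other.donor,
                    start_kb=min(ev.start_kb, other.start_kb),
                    end_kb=max(ev.end_kb, other.end_kb),
                    flags=other.flags,
                ))
                break
    for k, ev in enumerate(raw):
        if not used[k]:
            out.append(ev)
    return sorted(out, key=lambda e: (e.start_kb, e.end_kb))
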