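"""LOH / copy-number calling from two-allele SNP-array hybridization ratios.

The calling procedure mirrors the original array analysis: ratios are
normalized to the array-wide mean, scanned with a nine-marker moving
average to detect state transitions, and every detected transition is then
refined at single-marker resolution against the unsmoothed per-marker
calls.  Copy states are assigned per allele by nearest dosage centroid
(0.3 / 1.0 / 1.5 for 0 / 1 / 2 copies, extrapolated for amplifications).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import (
    GenomeMap,
    SnpProfile,
    InvalidConfigError,
    dosage_centroid,
)

__all__ = [
    "StateCall",
    "LohSegment",
    "CallingParams",
    "normalize_profile",
    "call_marker_states",
    "smooth_profile",
    "segment_states",
    "call_pipeline",
]


class DegenerateInputError(ValueError):
    pass


MAX_CN = 6
_CENTROIDS = dosage_centroid(np.arange(MAX_CN + 1))  # 0.3, 1.0, 1.5, 1.9, ...


@dataclass
class StateCall:
    """Per-marker integer copy calls for the two haplotypes plus call margin."""

    genome: GenomeMap
    cnW: np.ndarray
    cnY: np.ndarray
    margin: np.ndarray  # min over alleles of |d2nd - d1st| centroid distances

    def state(self, i: int) -> tuple[int, int]:
        return int(self.cnW[i]), int(self.cnY[i])


@dataclass(frozen=True)
class LohSegment:
    """A maximal run of markers sharing one (cnW, cnY) state.

    ``start_kb``/``end_kb`` are the first/last marker coordinates of the
    run.  Breakpoint intervals are open intervals between the last marker
    of the neighbouring state and the first marker of this one (chromosome
    ends use coordinate 0 / the chromosome length).
    """

    chrom: str
    cnW: int
    cnY: int
    start_kb: float
    end_kb: float
    bp_left: tuple[float, float]
    bp_right: tuple[float, float]
    n_markers: int
    first_idx: int = 0  # marker indices within the chromosome
    last_idx: int = 0

    @property
    def state(self) -> tuple[int, int]:
        return (self.cnW, self.cnY)

    @property
    def is_het(self) -> bool:
        return self.state == (1, 1)

    @property
    def copy_neutral(self) -> bool:
        return self.cnW + self.cnY == 2

    @property
    def length_kb(self) -> float:
        """Midpoint-to-midpoint extent across the flanking breakpoint intervals."""
        left = 0.5 * (self.bp_left[0] + self.bp_left[1])
        right = 0.5 * (self.bp_right[0] + self.bp_right[1])
        return right - left


@dataclass(frozen=True)
class CallingParams:
    window: int = 9
    min_markers: int = 2
    max_cn: int = MAX_CN


# ---------------------------------------------------------------------------

def normalize_profile(raw: SnpProfile) -> SnpProfile:
    """Divide every allele ratio by the mean over all allele values.

    This is the array-wide normalization: after it the mean hybridization
    ratio across every oligonucleotide equals 1, and the result is
    invariant to rescaling the raw intensities.
    """
    if raw.genome.n_markers == 0:
        raise DegenerateInputError("profile has no markers")
    total = np.concatenate([raw.ratio_W, raw.ratio_Y])
    mean = total.mean()
    if mean <= 0:
        raise DegenerateInputError("all-zero profile cannot be normalized")
    return SnpProfile(raw.genome, raw.ratio_W / mean, raw.ratio_Y / mean, label=raw.label)


def _nearest_cn(values: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.abs(values[:, None] - centroids[None, :])
    order = np.argsort(d, axis=1)
    best = order[:, 0]
    margin = d[np.arange(len(values)), order[:, 1]] - d[np.arange(len(values)), best]
    return best, margin


def call_marker_states(
    profile: SnpProfile, centroids: np.ndarray | None = None
) -> StateCall:
    """Assign each allele ratio to the nearest dosage centroid, independently.

    The margin records, per marker, the smaller of the two alleles'
    distances between best and second-best centroid — a crude confidence.
    """
    c = _CENTROIDS if centroids is None else np.asarray(centroids, dtype=float)
    if np.any(np.diff(c) <= 0):
        raise InvalidConfigError("centroids must be strictly increasing in copy number")
    cnW, mW = _nearest_cn(profile.ratio_W, c)
    cnY, mY = _nearest_cn(profile.ratio_Y, c)
    return StateCall(profile.genome, cnW, cnY, np.minimum(mW, mY))


def smooth_profile(profile: SnpProfile, window: int = 9) -> SnpProfile:
    """Centered moving average per chromosome; ends use the truncated window."""
    if window < 1 or window % 2 == 0:
        raise InvalidConfigError("window must be odd and >= 1")
    out = profile.copy()
    for chrom in profile.genome.chromosome_names:
        idx = profile.genome.marker_index(chrom)
        if len(idx) == 0:
            continue
        if window > len(idx):
            raise InvalidConfigError(
                f"window {window} exceeds marker count on {chrom} ({len(idx)})"
            )
        for arr_in, arr_out in ((profile.ratio_W, out.ratio_W), (profile.ratio_Y, out.ratio_Y)):
            s = pd.Series(arr_in[idx])
            arr_out[idx] = s.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return out


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _runs(states: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Run-length encode: list of (start, stop) half-open index ranges."""
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((start, i))
            start = i
    return runs


def _absorb_short_runs(
    runs: list[tuple[int, int]], states: list[tuple[int, int]], min_markers: int,
    cen_idx: int,
) -> list[tuple[int, int, tuple[int, int]]]:
    """Absorb runs shorter than ``min_markers`` into a flanking run.

    The short run joins whichever neighbour is longer; on a tie it joins
    the centromere-proximal flank (the neighbour whose markers lie closer
    to index ``cen_idx``).  Applied iteratively, shortest run first, until
    every surviving run has >= min_markers markers (a run with no
    neighbour is kept regardless).
    """
    tagged = [(a, b, states[a]) for a, b in runs]
    while True:
        if len(tagged) <= 1:
            break
        lens = [b - a for a, b, _ in tagged]
        short = [i for i, L in enumerate(lens) if L < min_markers]
        if not short:
            break
        i = min(short, key=lambda k: lens[k])
        a, b, _ = tagged[i]
        if i == 0:
            j = 1
        elif i == len(tagged) - 1:
            j = i - 1
        else:
            left_len, right_len = lens[i - 1], lens[i + 1]
            if left_len != right_len:
                j = i - 1 if left_len > right_len else i + 1
            else:
                # tie: absorb into the centromere-proximal flank
                left_d = abs((tagged[i - 1][0] + tagged[i - 1][1]) / 2 - cen_idx)
                right_d = abs((tagged[i + 1][0] + tagged[i + 1][1]) / 2 - cen_idx)
                j = i - 1 if left_d <= right_d else i + 1
        ja, jb, jstate = tagged[j]
        lo, hi = min(a, ja), max(b, jb)
        tagged[min(i, j)] = (lo, hi, jstate)
        del tagged[max(i, j)]
        # merging may have created adjacent equal states
        merged: list[tuple[int, int, tuple[int, int]]] = []
        for seg in tagged:
            if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
                merged[-1] = (merged[-1][0], seg[1], seg[2])
            else:
                merged.append(seg)
        tagged = merged
    return tagged


def _segments_from_runs(
    tagged: list[tuple[int, int, tuple[int, int]]],
    pos: np.ndarray,
    chrom: str,
    chrom_len: float,
) -> list[LohSegment]:
    segs = []
    for k, (a, b, state) in enumerate(tagged):
        left = (0.0, float(pos[a])) if k == 0 else (float(pos[a - 1]), float(pos[a]))
        right = (
            (float(pos[b - 1]), float(chrom_len))
            if k == len(tagged) - 1
            else (float(pos[b - 1]), float(pos[b]))
        )
        segs.append(
            LohSegment(
                chrom=chrom,
                cnW=state[0],
                cnY=state[1],
                start_kb=float(pos[a]),
                end_kb=float(pos[b - 1]),
                bp_left=left,
                bp_right=right,
                n_markers=b - a,
                first_idx=a,
                last_idx=b - 1,
            )
        )
    return segs


def segment_states(
    calls: StateCall, genome: GenomeMap, min_markers: int = 2
) -> list[LohSegment]:
    """Partition each chromosome's markers into maximal same-state runs.

    Runs shorter than ``min_markers`` are absorbed into a flanking run
    (longer flank wins; tie goes centromere-proximal), suppressing
    single-marker noise.  Breakpoint intervals always span the last marker
    of the previous state and the first marker of the new state.
    """
    segments: list[LohSegment] = []
    for c in genome.chromosomes:
        idx = genome.marker_index(c.name)
        if len(idx) == 0:
            continue
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        states = [(int(calls.cnW[i]), int(calls.cnY[i])) for i in idx]
        runs = _runs(states)
        cen_idx = int(np.searchsorted(pos, c.cen_kb))
        tagged = _absorb_short_runs(runs, states, min_markers, cen_idx)
        segments.extend(_segments_from_runs(tagged, pos, c.name, c.length_kb))
    return segments


# ---------------------------------------------------------------------------
# Full pipeline: smooth for detection, refine at single-marker resolution
# ---------------------------------------------------------------------------

def _refine_boundaries(
    tagged: list[tuple[int, int, tuple[int, int]]],
    ratios: tuple[np.ndarray, np.ndarray],
    window: int,
) -> list[tuple[int, int, tuple[int, int]]]:
    """Relocate each run boundary using unsmoothed per-marker evidence.

    For the boundary between runs of state A and state B, every marker
    within ``window`` markers of the smoothed boundary is scored by its
    distance to the A and B centroid pairs, and the split point minimizing
    total misassignment is chosen (leftmost on ties).
    """
    rW, rY = ratios
    n = len(rW)
    bounds = [b for _, b, _ in tagged[:-1]]
    new_bounds = []
    for k, b in enumerate(bounds):
        sA, sB = tagged[k][2], tagged[k + 1][2]
        lo = max(b - window, 1)
        hi = min(b + window, n - 1)
        if k > 0:
            lo = max(lo, new_bounds[-1] + 1)
        if k < len(bounds) - 1:
            hi = min(hi, bounds[k + 1] - 1)
        cA = (dosage_centroid(sA[0]), dosage_centroid(sA[1]))
        cB = (dosage_centroid(sB[0]), dosage_centroid(sB[1]))
        i_range = np.arange(lo - 1, hi + 1)  # markers that may switch side
        dA = np.abs(rW[i_range] - cA[0]) + np.abs(rY[i_range] - cA[1])
        dB = np.abs(rW[i_range] - cB[0]) + np.abs(rY[i_range] - cB[1])
        # cost of putting the split before marker j: markers < j scored as A
        costs = []
        for split in range(lo, hi + 1):
            left = i_range < split
            costs.append(dA[left].sum() + dB[~left].sum())
        new_bounds.append(lo + int(np.argmin(costs)))
    out = []
    prev = tagged[0][0]
    for k, (a, b, state) in enumerate(tagged):
        nb = new_bounds[k] if k < len(new_bounds) else tagged[-1][1]
        out.append((prev, nb, state))
        prev = nb
    # drop runs emptied by refinement and merge equal neighbours
    out = [(a, b, s) for a, b, s in out if b > a]
    merged: list[tuple[int, int, tuple[int, int]]] = []
    for seg in out:
        if merged and merged[-1][2] == seg[2]:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(seg)
    return merged


def call_pipeline(
    raw: SnpProfile,
    genome: GenomeMap,
    params: CallingParams = CallingParams(),
) -> tuple[SnpProfile, StateCall, list[LohSegment]]:
    """Normalize, detect transitions on the smoothed track, refine, segment.

    Detection runs on a ``params.window``-marker moving average (robust to
    marker-level noise); every detected transition is then re-located at
    single-marker resolution by scoring the unsmoothed ratios within
    ``window`` markers of the smoothed boundary.  Reported breakpoints
    therefore always come from unsmoothed markers.
    """
    profile = normalize_profile(raw)
    smoothed = smooth_profile(profile, params.window)
    smooth_calls = call_marker_states(smoothed)

    cnW = np.empty(genome.n_markers, dtype=int)
    cnY = np.empty(genome.n_markers, dtype=int)
    segments: list[LohSegment] = []
    for c in genome.chromosomes:
        idx = genome.marker_index(c.name)
        if len(idx) == 0:
            continue
        pos = genome.markers["pos_kb"].to_numpy()[idx]
        states = [(int(smooth_calls.cnW[i]), int(smooth_calls.cnY[i])) for i in idx]
        runs = _runs(states)
        cen_idx = int(np.searchsorted(pos, c.cen_kb))
        # A transition of the window-mean between centroids passes through
        # intermediate values for ~window/2 markers, so runs shorter than
        # half a window on the smoothed track are smoothing transients, not
        # states; absorb them before refining the surviving boundaries
        # against the unsmoothed per-marker evidence.
        detect_floor = max(params.min_markers, (params.window + 1) // 2)
        tagged = _absorb_short_runs(runs, states, detect_floor, cen_idx)
        tagged = _refine_boundaries(
            tagged, (profile.ratio_W[idx], profile.ratio_Y[idx]), params.window
        )
        for a, b, state in tagged:
            cnW[idx[a:b]], cnY[idx[a:b]] = state
        segments.extend(_segments_from_runs(tagged, pos, c.name, c.length_kb))

    margin = np.zeros(genome.n_markers)
    final_calls = StateCall(genome, cnW, cnY, margin)
    return profile, final_calls, segments
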