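"""TSV / BED readers and writers for every pipeline stage product.

All stage products are plain tab-separated text with a header row, plus
``#``-prefixed comment lines carrying the tool version, a configuration
hash, and the seeds used — enough to reproduce any file byte-for-byte.

Coordinate conventions: internal coordinates are 1-based kb with closed
intervals (SGD-style); BED feature files are the only 0-based, half-open,
base-pair boundary format, converted on read.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .array_calling import LohSegment
from .event_classification import RecombinationEvent, TractInterval
from .synthetic_data import Chromosome, GenomeMap, SnpProfile

__all__ = [
    "FormatError",
    "read_profile_tsv", "write_profile_tsv",
    "read_segments_tsv", "write_segments_tsv",
    "read_events_tsv", "write_events_tsv",
    "read_genome", "write_genome", "read_features_bed",
    "config_hash",
]


class FormatError(ValueError):
    pass


class SortOrderError(FormatError):
    pass


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    lines = [f"# oxloh {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for i, col in enumerate(required):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r} (header line)")
    if df.empty:
        raise FormatError(f"{path}: empty data section")
    return df


def _write_table(df: pd.DataFrame, path: str | Path, meta: dict | None) -> None:
    buf = _io.StringIO()
    buf.write(_header_lines(meta))
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def write_profile_tsv(profile: SnpProfile, path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame({
        "chrom": profile.genome.markers["chrom"],
        "pos_kb": profile.genome.markers["pos_kb"],
        "ratio_W": profile.ratio_W,
        "ratio_Y": profile.ratio_Y,
    })
    _write_table(df, path, {"sample": profile.label, **(meta or {})})


def read_profile_tsv(path: str | Path, genome: GenomeMap, label: str = "") -> SnpProfile:
    df = _read_table(path, ["chrom", "pos_kb", "ratio_W", "ratio_Y"])
    for chrom, sub in df.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos_kb"].to_numpy()) > 0):
            raise SortOrderError(f"{path}: positions not sorted within {chrom}")
    if len(df) != genome.n_markers:
        raise FormatError(
            f"{path}: {len(df)} rows but genome has {genome.n_markers} markers"
        )
    if not np.allclose(df["pos_kb"].to_numpy(), genome.markers["pos_kb"].to_numpy(), atol=5e-4):
        raise FormatError(f"{path}: marker coordinates do not match the genome map")
    return SnpProfile(genome, df["ratio_W"].to_numpy(float),
                      df["ratio_Y"].to_numpy(float), label=label)


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------

_SEG_COLS = ["chrom", "state_cnW", "state_cnY", "start_kb", "end_kb",
             "bp_left_lo", "bp_left_hi", "bp_right_lo", "bp_right_hi",
             "n_markers", "first_idx", "last_idx"]


def write_segments_tsv(segments: list[LohSegment], path: str | Path,
                       meta: dict | None = None) -> None:
    rows = [
        (s.chrom, s.cnW, s.cnY, s.start_kb, s.end_kb,
         s.bp_left[0], s.bp_left[1], s.bp_right[0], s.bp_right[1],
         s.n_markers, s.first_idx, s.last_idx)
        for s in segments
    ]
    _write_table(pd.DataFrame(rows, columns=_SEG_COLS), path, meta)


def read_segments_tsv(path: str | Path) -> list[LohSegment]:
    df = _read_table(path, _SEG_COLS[:10])
    segs = []
    for r in df.itertuples(index=False):
        segs.append(LohSegment(
            chrom=r.chrom, cnW=int(r.state_cnW), cnY=int(r.state_cnY),
            start_kb=float(r.start_kb), end_kb=float(r.end_kb),
            bp_left=(float(r.bp_left_lo), float(r.bp_left_hi)),
            bp_right=(float(r.bp_right_lo), float(r.bp_right_hi)),
            n_markers=int(r.n_markers),
            first_idx=int(getattr(r, "first_idx", 0)),
            last_idx=int(getattr(r, "last_idx", 0)),
        ))
    return segs


# ---------------------------------------------------------------------------
# Events
# ---------------------------------------------------------------------------

def write_events_tsv(events: list[RecombinationEvent], path: str | Path,
                     meta: dict | None = None) -> None:
    rows = []
    for e in events:
        tracts = ";".join(f"{t.start_kb:g}..{t.end_kb:g}:{t.tract_class}" for t in e.tracts)
        co = e.co_breakpoint or ("", "")
        rows.append((e.isolate, e.chromosome, e.type, e.donor or "",
                     tracts, co[0], co[1], e.phase,
                     "" if e.start_kb is None else e.start_kb,
                     "" if e.end_kb is None else e.end_kb,
                     ";".join(e.flags)))
    cols = ["isolate", "chrom", "type", "donor", "tracts",
            "co_bp_lo", "co_bp_hi", "phase", "start_kb", "end_kb", "flags"]
    _write_table(pd.DataFrame(rows, columns=cols), path, meta)


def read_events_tsv(path: str | Path) -> list[RecombinationEvent]:
    df = _read_table(path, ["isolate", "chrom", "type", "phase"])
    df = df.fillna("")
    events = []
    for r in df.itertuples(index=False):
        tracts = []
        if r.tracts:
            for part in str(r.tracts).split(";"):
                span, cls = part.split(":", 1)
                lo, hi = span.split("..")
                tracts.append(TractInterval(float(lo), float(hi), cls))
        co = None
        if r.co_bp_lo != "" and not pd.isna(r.co_bp_lo):
            co = (float(r.co_bp_lo), float(r.co_bp_hi))
        events.append(RecombinationEvent(
            type=r.type, chromosome=r.chrom, tracts=tracts, co_breakpoint=co,
            donor=r.donor or None, phase=r.phase, isolate=str(r.isolate),
            start_kb=float(r.start_kb) if r.start_kb != "" else None,
            end_kb=float(r.end_kb) if r.end_kb != "" else None,
            flags=tuple(str(r.flags).split(";")) if r.flags else (),
        ))
    return events


# ---------------------------------------------------------------------------
# Genome maps and features
# ---------------------------------------------------------------------------

def write_genome(genome: GenomeMap, chrom_path: str | Path, marker_path: str | Path,
                 meta: dict | None = None) -> None:
    chroms = pd.DataFrame(
        [(c.name, c.length_kb, c.cen_kb) for c in genome.chromosomes],
        columns=["name", "length_kb", "cen_kb"],
    )
    _write_table(chroms, chrom_path, meta)
    _write_table(genome.markers.copy(), marker_path, meta)


def read_genome(chrom_path: str | Path, marker_path: str | Path,
                features: dict | None = None) -> GenomeMap:
    chroms = _read_table(chrom_path, ["name", "length_kb", "cen_kb"])
    markers = _read_table(marker_path, ["chrom", "pos_kb"])
    for chrom, sub in markers.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos_kb"].to_numpy()) > 0):
            raise SortOrderError(f"{marker_path}: positions not sorted within {chrom}")
    return GenomeMap(
        chromosomes=tuple(Chromosome(r.name, float(r.length_kb), float(r.cen_kb))
                          for r in chroms.itertuples(index=False)),
        markers=markers[["chrom", "pos_kb"]].reset_index(drop=True),
        features=features or {},
    )


def read_features_bed(path: str | Path, genome: GenomeMap, track: str | None = None,
                      ) -> pd.DataFrame:
    """Read a 4+-column BED (0-based half-open, bp) into the internal
    1-based-kb closed convention; intervals are validated against the genome.

    Returns a feature frame (chrom, start_kb, end_kb, label); an empty
    file yields an empty track (with columns) rather than an error.
    """
    cols = ["chrom", "start", "end", "label"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=["chrom", "start_kb", "end_kb", "label"])
    if df.shape[1] < 4:
        raise FormatError(f"{path}: need >= 4 BED columns")
    df = df.iloc[:, :4]
    df.columns = cols
    lengths = {c.name: c.length_kb for c in genome.chromosomes}
    recs = []
    for i, r in enumerate(df.itertuples(index=False), start=1):
        if r.end <= r.start:
            raise FormatError(f"{path}: line {i}: end <= start")
        if r.chrom not in lengths:
            raise FormatError(f"{path}: line {i}: unknown chromosome {r.chrom!r}")
        # bp 0-based half-open [start, end) -> kb 1-based closed [start+1, end]
        start_kb = (r.start + 1) / 1000.0
        end_kb = r.end / 1000.0
        if end_kb > lengths[r.chrom]:
            raise FormatError(f"{path}: line {i}: interval exceeds {r.chrom} length")
        recs.append((r.chrom, start_kb, end_kb, r.label))
    return pd.DataFrame(recs, columns=["chrom", "start_kb", "end_kb", "label"])
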