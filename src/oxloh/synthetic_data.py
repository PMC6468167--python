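"""Synthetic genomes, planted recombination events, and simulated assays.

Everything downstream of this module (array calling, event classification,
rate statistics, DSB quantification) is exercised against data generated
here, so each generator mirrors one experimental observable:

* :func:`build_genome` — a 16-chromosome hybrid diploid marker map
  (heterozygous SNPs between two parental haplotypes, labelled W and Y).
* :func:`plant_event` — the canonical mitotic-recombination mechanisms
  (G1/G2 DSB-initiated crossovers, break-induced replication, conversion
  without crossover, deletions/duplications, aneuploidy, uniparental
  disomy) expressed as per-marker haplotype copy numbers in the two
  daughter cells of the division in which the event occurred.
* :func:`render_profile` — two-colour SNP-array hybridization ratios with
  dosage centroids 0.3 / 1.0 / 1.5 for 0 / 1 / 2 copies.
* :func:`simulate_fluctuation_cultures` — a Luria–Delbrück process for
  fluctuation assays.
* :func:`simulate_circular_breakage` — Poisson breakage of a circular
  chromosome reporter.
* :func:`generate_mutations` — multinomial draws over the six
  pyrimidine-strand substitution classes plus small in/dels.

All randomness flows through explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Chromosome",
    "GenomeMap",
    "PlantedEvent",
    "DaughterGenotype",
    "SnpProfile",
    "MECHANISMS",
    "SUBSTITUTION_CLASSES",
    "build_genome",
    "default_genome_config",
    "plant_event",
    "sample_events",
    "segregate_g2_crossover",
    "render_profile",
    "dosage_centroid",
    "simulate_fluctuation_cultures",
    "simulate_circular_breakage",
    "generate_mutations",
]


class InvalidConfigError(ValueError):
    """Raised for malformed generator configuration."""


class InvalidEventError(ValueError):
    """Raised when a planted-event specification is internally inconsistent."""


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    name: str
    length_kb: float
    cen_kb: float

    def __post_init__(self) -> None:
        if self.length_kb <= 0:
            raise InvalidConfigError(f"chromosome {self.name}: non-positive length")
        if not (0 < self.cen_kb < self.length_kb):
            raise InvalidConfigError(
                f"chromosome {self.name}: centromere {self.cen_kb} outside (0, {self.length_kb})"
            )


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome sizes, heterozygous marker positions, and feature tracks.

    Coordinates are 1-based kb throughout; feature intervals are closed
    ``[start_kb, end_kb]``.
    """

    chromosomes: tuple[Chromosome, ...]
    markers: pd.DataFrame  # columns: chrom, pos_kb; sorted within chromosome
    features: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {c.name: c.length_kb for c in self.chromosomes}
        if list(self.markers.columns[:2]) != ["chrom", "pos_kb"]:
            raise InvalidConfigError("markers frame needs columns chrom, pos_kb")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            if chrom not in lengths:
                raise InvalidConfigError(f"markers on unknown chromosome {chrom!r}")
            pos = sub["pos_kb"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise InvalidConfigError(f"marker coordinates not strictly increasing on {chrom}")
            if pos[0] <= 0 or pos[-1] > lengths[chrom]:
                raise InvalidConfigError(f"marker outside chromosome bounds on {chrom}")
        for track, frame in self.features.items():
            for row in frame.itertuples(index=False):
                if row.chrom not in lengths:
                    raise InvalidConfigError(f"{track}: interval on unknown chromosome {row.chrom!r}")
                if not (0 <= row.start_kb < row.end_kb <= lengths[row.chrom]):
                    raise InvalidConfigError(
                        f"{track}: interval ({row.start_kb}, {row.end_kb}) outside {row.chrom}"
                    )
        rdna = self.features.get("rDNA")
        if rdna is not None and len(rdna) != 1:
            raise InvalidConfigError("rDNA track must be a single interval")

    # -- convenience accessors -------------------------------------------

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def total_kb(self) -> float:
        return float(sum(c.length_kb for c in self.chromosomes))

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def marker_positions(self, chrom: str) -> np.ndarray:
        return self.markers.loc[self.markers["chrom"] == chrom, "pos_kb"].to_numpy()

    def marker_index(self, chrom: str) -> np.ndarray:
        """Row indices of the markers on ``chrom`` within the global table."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())

    def rdna_fraction(self) -> float:
        """Genome fraction occupied by the rDNA track (0 if absent)."""
        rdna = self.features.get("rDNA")
        if rdna is None or rdna.empty:
            return 0.0
        row = rdna.iloc[0]
        return float(row.end_kb - row.start_kb) / self.total_kb


# S288C-like chromosome sizes (kb) and centromere midpoints (kb); the rDNA
# interval on XII is widened to the physical ~920 kb tandem array so its
# genome fraction (~7.6%) matches what terminal-event expectations use.
_DEFAULT_CHROMS: list[tuple[str, float, float]] = [
    ("chrI", 230.0, 151.0),
    ("chrII", 813.0, 238.0),
    ("chrIII", 316.0, 114.0),
    ("chrIV", 1532.0, 450.0),
    ("chrV", 577.0, 152.0),
    ("chrVI", 270.0, 149.0),
    ("chrVII", 1091.0, 497.0),
    ("chrVIII", 563.0, 106.0),
    ("chrIX", 440.0, 356.0),
    ("chrX", 746.0, 436.0),
    ("chrXI", 667.0, 440.0),
    ("chrXII", 1078.0, 151.0),
    ("chrXIII", 924.0, 268.0),
    ("chrXIV", 784.0, 629.0),
    ("chrXV", 1091.0, 327.0),
    ("chrXVI", 948.0, 556.0),
]

_FEATURE_TRACKS = ("Ty", "LTR", "tRNA", "G4", "tandem_repeat", "high_GC")
# (count genome-wide, element length in kb) — synthetic placements with
# realistic element sizes and copy numbers for budding yeast.
_FEATURE_SHAPES = {
    "Ty": (50, 6.0),
    "LTR": (300, 0.33),
    "tRNA": (275, 0.1),
    "G4": (500, 0.03),
    "tandem_repeat": (120, 1.0),
    "high_GC": (200, 5.0),
}


def default_genome_config() -> dict:
    """Default genome configuration: 16 chromosomes, ~12 070 kb, 15 000 markers."""
    return {
        "chromosomes": list(_DEFAULT_CHROMS),
        "n_markers": 15_000,
        "features": True,
    }


def build_genome(config: Mapping | str = "default", seed: int = 0) -> GenomeMap:
    """Build a hybrid-diploid marker map.

    Parameters
    ----------
    config
        Either the preset name ``"default"`` or a mapping with keys
        ``chromosomes`` (list of ``(name, length_kb, cen_kb)``) and one of
        ``n_markers`` (total, allocated proportionally to length),
        ``markers_per_chrom`` (count for every chromosome) or ``markers``
        (explicit list of ``(chrom, pos_kb)``). Optional ``features``: True
        for seeded synthetic tracks, or a mapping track-name -> list of
        ``(chrom, start_kb, end_kb, label)``.
    seed
        Seed for marker placement and synthetic feature tracks.
    """
    if isinstance(config, str):
        if config != "default":
            raise InvalidConfigError(f"unknown preset {config!r}")
        config = default_genome_config()
    rng = np.random.default_rng(seed)

    chroms = tuple(Chromosome(*c) for c in config["chromosomes"])
    lengths = np.array([c.length_kb for c in chroms])

    if "markers" in config:
        markers = pd.DataFrame(config["markers"], columns=["chrom", "pos_kb"])
    else:
        if "markers_per_chrom" in config:
            per = np.full(len(chroms), int(config["markers_per_chrom"]))
        else:
            n = int(config["n_markers"])
            if n <= 0:
                raise InvalidConfigError("n_markers must be positive")
            per = np.maximum(1, np.round(n * lengths / lengths.sum()).astype(int))
            # trim/pad rounding drift on the largest chromosomes
            drift = per.sum() - n
            order = np.argsort(-lengths)
            i = 0
            while drift != 0:
                per[order[i % len(chroms)]] -= int(np.sign(drift))
                drift -= int(np.sign(drift))
                i += 1
        rows = []
        for c, k in zip(chroms, per):
            if k > c.length_kb * 1000:
                raise InvalidConfigError(f"marker density too high on {c.name}")
            pos = np.sort(rng.uniform(0.5, c.length_kb - 0.5, size=int(k)))
            # enforce strict ordering at 1 bp resolution
            pos = np.round(pos, 3)
            while len(np.unique(pos)) < len(pos):
                dup = np.flatnonzero(np.diff(pos) == 0)
                pos[dup + 1] += 0.001
                pos = np.sort(pos)
            rows.append(pd.DataFrame({"chrom": c.name, "pos_kb": pos}))
        markers = pd.concat(rows, ignore_index=True)

    features: dict[str, pd.DataFrame] = {}
    feat_cfg = config.get("features", False)
    if feat_cfg is True:
        for track in _FEATURE_TRACKS:
            count, elem_kb = _FEATURE_SHAPES[track]
            c_idx = rng.choice(len(chroms), size=count, p=lengths / lengths.sum())
            recs = []
            for ci in c_idx:
                c = chroms[ci]
                start = rng.uniform(0, max(c.length_kb - elem_kb, 0))
                recs.append((c.name, round(start, 3), round(start + elem_kb, 3), track))
            features[track] = pd.DataFrame(recs, columns=["chrom", "start_kb", "end_kb", "label"])
        # single interstitial rDNA array on XII: 920 kb => 7.62% of 12 070 kb
        features["rDNA"] = pd.DataFrame(
            [("chrXII", 155.0, 1075.0, "rDNA")],
            columns=["chrom", "start_kb", "end_kb", "label"],
        )
    elif isinstance(feat_cfg, Mapping):
        for track, ivals in feat_cfg.items():
            features[track] = pd.DataFrame(
                ivals, columns=["chrom", "start_kb", "end_kb", "label"]
            )

    return GenomeMap(chromosomes=chroms, markers=markers, features=features)


# ---------------------------------------------------------------------------
# Planted events
# ---------------------------------------------------------------------------

MECHANISMS = (
    "G1_DSB_CO",
    "G2_DSB_CO",
    "BIR",
    "CON_only",
    "interstitial_del",
    "interstitial_dup",
    "terminal_del",
    "terminal_dup",
    "trisomy",
    "monosomy",
    "UPD",
)


@dataclass(frozen=True)
class PlantedEvent:
    """Ground-truth specification of one mitotic alteration.

    ``tract_d1``/``tract_d2`` give the conversion-tract extents (kb from
    the break, measured toward the centromere) for the chromatids inherited
    by daughters 1 and 2; only crossover/conversion mechanisms use them.
    For interstitial mechanisms ``break_kb``/``end_kb`` bound the tract.
    """

    mechanism: str
    chromosome: str
    break_kb: float = 0.0
    end_kb: float | None = None
    tract_d1: float = 0.0
    tract_d2: float = 0.0
    donor: str = "W"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise InvalidEventError(f"unknown mechanism {self.mechanism!r}")
        if self.donor not in ("W", "Y"):
            raise InvalidEventError("donor must be 'W' or 'Y'")


@dataclass
class DaughterGenotype:
    """Per-marker integer copies of the W- and Y-derived haplotypes."""

    genome: GenomeMap
    cnW: np.ndarray
    cnY: np.ndarray

    @classmethod
    def diploid(cls, genome: GenomeMap) -> "DaughterGenotype":
        n = genome.n_markers
        return cls(genome, np.ones(n, dtype=int), np.ones(n, dtype=int))

    def copy(self) -> "DaughterGenotype":
        return DaughterGenotype(self.genome, self.cnW.copy(), self.cnY.copy())

    def state(self, i: int) -> tuple[int, int]:
        return int(self.cnW[i]), int(self.cnY[i])

    def _hom_donor(self, mask: np.ndarray, donor: str) -> None:
        if donor == "W":
            self.cnW[mask], self.cnY[mask] = 2, 0
        else:
            self.cnW[mask], self.cnY[mask] = 0, 2


def _chrom_mask(genome: GenomeMap, chrom: str, lo: float, hi: float) -> np.ndarray:
    m = genome.markers
    return ((m["chrom"] == chrom) & (m["pos_kb"] >= lo) & (m["pos_kb"] <= hi)).to_numpy()


def plant_event(
    genome: GenomeMap, spec: PlantedEvent, seed: int = 0
) -> tuple[DaughterGenotype, DaughterGenotype]:
    """Apply one planted event to a fully heterozygous diploid.

    Returns the genotypes of the two daughter cells of the division in
    which the event occurred.  Conventions per mechanism (donor = the
    haplotype gaining copies, recipient = the other):

    G1_DSB_CO
        A DSB at ``break_kb`` before replication breaks both future sister
        chromatids; each is repaired against the donor homolog with its own
        conversion tract (``tract_d1``/``tract_d2`` kb, extending proximally
        from the break), and the exchange is resolved as a crossover.
        Daughter 1 is homozygous donor from ``break_kb − tract_d1`` to the
        telomere; daughter 2 carries a donor tract over
        ``[break_kb − tract_d2, break_kb]`` and is homozygous recipient
        distal of the break.  The merged tract therefore contains a 3:1 and
        a 4:0 sub-region whenever the two tract lengths differ.
    G2_DSB_CO
        A single broken chromatid after replication; crossover with a 3:1
        tract (``tract_d1``) in daughter 1 and reciprocal terminal LOH.
    BIR
        Daughter 1 copies the donor homolog from ``break_kb`` to the
        telomere (copy-neutral terminal LOH); daughter 2 is unchanged.
    CON_only
        Interstitial donor tract over ``[break_kb, end_kb]``; in daughter 1
        only (3:1) or in both (4:0) when ``tract_d2 > 0``.
    interstitial/terminal del/dup, trisomy, monosomy, UPD
        Copy-number and whole-chromosome states in daughter 1; daughter 2
        unchanged.
    """
    chrom = genome.chromosome(spec.chromosome)
    tel = chrom.length_kb
    d1 = DaughterGenotype.diploid(genome)
    d2 = DaughterGenotype.diploid(genome)
    mech, b, donor = spec.mechanism, spec.break_kb, spec.donor
    recip = "Y" if donor == "W" else "W"

    def mask(lo: float, hi: float) -> np.ndarray:
        return _chrom_mask(genome, spec.chromosome, lo, hi)

    whole = mask(0, tel)

    if mech in ("G1_DSB_CO", "G2_DSB_CO", "BIR", "terminal_del", "terminal_dup"):
        if not (0 < b < tel):
            raise InvalidEventError(f"break {b} outside {spec.chromosome}")

    if mech == "G1_DSB_CO":
        if spec.tract_d1 <= 0 or spec.tract_d2 <= 0:
            raise InvalidEventError("G1_DSB_CO needs positive tract extents for both daughters")
        d1._hom_donor(mask(b - spec.tract_d1, tel), donor)
        d2._hom_donor(mask(b - spec.tract_d2, b), donor)
        d2._hom_donor(mask(np.nextafter(b, tel), tel), recip)
    elif mech == "G2_DSB_CO":
        if spec.tract_d1 <= 0:
            raise InvalidEventError("G2_DSB_CO needs a positive tract_d1")
        d1._hom_donor(mask(b - spec.tract_d1, tel), donor)
        d2._hom_donor(mask(np.nextafter(b, tel), tel), recip)
    elif mech == "BIR":
        d1._hom_donor(mask(b, tel), donor)
    elif mech == "CON_only":
        if spec.end_kb is None or not (0 < b < spec.end_kb < tel):
            raise InvalidEventError("CON_only needs 0 < break_kb < end_kb < telomere")
        d1._hom_donor(mask(b, spec.end_kb), donor)
        if spec.tract_d2 > 0:  # second chromatid converted too -> 4:0 core
            d2._hom_donor(mask(b, min(b + spec.tract_d2, spec.end_kb)), donor)
    elif mech in ("interstitial_del", "interstitial_dup"):
        if spec.end_kb is None or not (0 < b < spec.end_kb < tel):
            raise InvalidEventError(f"{mech} needs interstitial extents inside the chromosome")
        m = mask(b, spec.end_kb)
        _apply_cnv(d1, m, donor, delta=-1 if mech.endswith("del") else +1)
    elif mech in ("terminal_del", "terminal_dup"):
        m = mask(b, tel)
        _apply_cnv(d1, m, donor, delta=-1 if mech.endswith("del") else +1)
    elif mech == "trisomy":
        _apply_cnv(d1, whole, donor, delta=+1)
    elif mech == "monosomy":
        _apply_cnv(d1, whole, donor, delta=-1)
    elif mech == "UPD":
        d1._hom_donor(whole, donor)
    return d1, d2


def _apply_cnv(d: DaughterGenotype, m: np.ndarray, donor: str, delta: int) -> None:
    # gains duplicate the donor haplotype; losses remove the non-donor one
    arr = (d.cnW if donor == "W" else d.cnY) if delta > 0 else (d.cnY if donor == "W" else d.cnW)
    arr[m] = np.maximum(arr[m] + delta, 0)


DEFAULT_TRACT_MEDIAN_KB = 13.0   # combined crossover-associated median tract
DEFAULT_TRACT_SIGMA = 1.1        # log-sd: 10-90 percentiles span ~3-53 kb
DEFAULT_MIN_TRACT_KB = 6.0       # array-detectability floor (tracts must span SNPs)
DEFAULT_MIN_TRACT_MARKERS = 6    # >= half a 9-SNP detection window


def _ensure_marker_span(
    genome: GenomeMap, chrom: str, start: float, end: float, k: int
) -> tuple[float, float]:
    """Widen (start, end) until it contains >= k markers of ``chrom``.

    Marker placement is random, so a fixed-kb tract may locally span too
    few SNPs to be observable; an undetectably small event is not an event
    the assay could ever report.  The interval grows symmetrically in 1 kb
    steps, clamped to the chromosome arms.
    """
    length = genome.chromosome(chrom).length_kb
    pos = genome.marker_positions(chrom)
    lo, hi = start, end
    while ((pos >= lo) & (pos <= hi)).sum() < k:
        lo = max(lo - 1.0, pos[0])
        hi = min(hi + 1.0, 0.95 * length)
        if lo <= pos[0] and hi >= 0.95 * length:
            break
    return lo, hi


def sample_events(
    genome: GenomeMap,
    n: int,
    seed: int = 0,
    mechanisms: Sequence[str] = MECHANISMS,
    tract_median_kb: float = DEFAULT_TRACT_MEDIAN_KB,
    tract_sigma: float = DEFAULT_TRACT_SIGMA,
    min_tract_kb: float = DEFAULT_MIN_TRACT_KB,
) -> list[PlantedEvent]:
    """Draw ``n`` random planted-event specifications.

    Mechanisms are drawn uniformly from ``mechanisms``; chromosomes are
    weighted by length; tract and CNV lengths follow a truncated
    log-normal (median ``tract_median_kb``, log-sd ``tract_sigma``,
    floored at ``min_tract_kb`` — tracts shorter than a few kb rarely
    contain enough markers to be observable on the array, so the
    generator, like the assay, only produces detectable tracts).  Break
    coordinates stay in the central 20–80% of the chromosome so every
    terminal event leaves an informative marker run on both sides.
    """
    if n < 0:
        raise InvalidConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = np.array([c.length_kb for c in genome.chromosomes])
    events = []
    for _ in range(n):
        mech = mechanisms[rng.integers(len(mechanisms))]
        ci = rng.choice(len(genome.chromosomes), p=lengths / lengths.sum())
        c = genome.chromosomes[ci]
        donor = "W" if rng.integers(2) else "Y"

        def tract() -> float:
            t = float(rng.lognormal(math.log(tract_median_kb), tract_sigma))
            return min(max(t, min_tract_kb), 0.3 * c.length_kb)

        b = float(rng.uniform(0.2, 0.8) * c.length_kb)
        kw: dict = {}
        if mech in ("G1_DSB_CO", "G2_DSB_CO"):
            kw = {"break_kb": b, "tract_d1": min(tract(), 0.8 * b)}
            if mech == "G1_DSB_CO":
                kw["tract_d2"] = min(tract(), 0.8 * b)
        elif mech == "BIR":
            kw = {"break_kb": b}
        elif mech == "CON_only":
            end = min(b + tract(), 0.95 * c.length_kb)
            b2, end = _ensure_marker_span(genome, c.name, b, end, DEFAULT_MIN_TRACT_MARKERS)
            kw = {"break_kb": b2, "end_kb": end}
            if rng.integers(2):  # half of conversions get a 4:0 core
                kw["tract_d2"] = tract()
        elif mech in ("interstitial_del", "interstitial_dup"):
            end = min(b + tract(), 0.95 * c.length_kb)
            b2, end = _ensure_marker_span(genome, c.name, b, end, DEFAULT_MIN_TRACT_MARKERS)
            kw = {"break_kb": b2, "end_kb": end}
        elif mech in ("terminal_del", "terminal_dup"):
            kw = {"break_kb": b}
        events.append(PlantedEvent(mechanism=mech, chromosome=c.name, donor=donor, **kw))
    return events


def segregate_g2_crossover(
    genome: GenomeMap, spec: PlantedEvent, seed: int
) -> tuple[DaughterGenotype, DaughterGenotype, bool]:
    """Plant a G2 crossover and segregate the four chromatids at random.

    After a crossover between replicated homologs, the two recombinant
    chromatids go to opposite daughter cells in half of mitoses (producing
    reciprocal terminal LOH — a sectored colony) and to the same daughter
    in the other half (both daughters remain heterozygous distal of the
    exchange, so the crossover is invisible).  Returns the two daughters
    and whether the segregation was the LOH-producing pattern.
    """
    rng = np.random.default_rng(seed)
    reciprocal = bool(rng.integers(2))
    if reciprocal:
        d1, d2 = plant_event(genome, spec, seed)
    else:
        d1, d2 = DaughterGenotype.diploid(genome), DaughterGenotype.diploid(genome)
    return d1, d2, reciprocal


# ---------------------------------------------------------------------------
# Array-profile rendering
# ---------------------------------------------------------------------------

@dataclass
class SnpProfile:
    """Normalized two-allele hybridization ratios for one sample.

    ``ratio_W[i]`` / ``ratio_Y[i]`` are the sample-vs-heterozygous-control
    hybridization ratios at marker ``i`` of ``genome`` for the W- and
    Y-allele oligonucleotides.
    """

    genome: GenomeMap
    ratio_W: np.ndarray
    ratio_Y: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        n = self.genome.n_markers
        if len(self.ratio_W) != n or len(self.ratio_Y) != n:
            raise InvalidConfigError("profile length does not match genome marker count")
        if np.any(self.ratio_W < 0) or np.any(self.ratio_Y < 0):
            raise InvalidConfigError("hybridization ratios must be non-negative")

    def copy(self) -> "SnpProfile":
        return SnpProfile(self.genome, self.ratio_W.copy(), self.ratio_Y.copy(), self.label)


def dosage_centroid(cn: int | np.ndarray) -> np.ndarray:
    """Expected hybridization ratio for ``cn`` copies of one allele.

    0/1/2 copies map to 0.3/1.0/1.5; higher dosage extrapolates with the
    sub-linear slope 0.4 per extra copy seen in two-colour array response.
    """
    cn = np.asarray(cn)
    out = np.where(cn == 0, 0.3, np.where(cn == 1, 1.0, 1.5 + 0.4 * (cn - 2)))
    return out.astype(float)


def render_profile(
    genotype: DaughterGenotype, noise_sd: float = 0.1, seed: int = 0, label: str = ""
) -> SnpProfile:
    """Render per-marker hybridization ratios from a genotype.

    Each allele ratio is drawn from a truncated-at-zero
    ``Normal(centroid(cn), noise_sd)``.
    """
    if noise_sd < 0:
        raise InvalidConfigError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    muW = dosage_centroid(genotype.cnW)
    muY = dosage_centroid(genotype.cnY)
    if noise_sd == 0:
        rW, rY = muW, muY
    else:
        rW = np.maximum(rng.normal(muW, noise_sd), 0.0)
        rY = np.maximum(rng.normal(muY, noise_sd), 0.0)
    return SnpProfile(genotype.genome, rW, rY, label=label)


# ---------------------------------------------------------------------------
# Fluctuation cultures (Luria–Delbrück)
# ---------------------------------------------------------------------------

def simulate_fluctuation_cultures(
    rate: float, n_final_cells: float, n_cultures: int, seed: int = 0
) -> np.ndarray:
    """Grow cultures by synchronous binary fission with events at divisions.

    Each culture starts from one non-mutant cell and doubles for
    ``ceil(log2 n_final_cells)`` generations.  At every division of a
    non-mutant cell one daughter becomes a mutant with probability
    ``rate``; mutant lineages breed true.  Returns the number of mutant
    cells per culture at the final generation — the resistant-colony count
    of a fluctuation assay.
    """
    if not (0 <= rate <= 1):
        raise InvalidConfigError("rate must lie in [0, 1]")
    if n_final_cells < 2:
        raise InvalidConfigError("n_final_cells must be >= 2")
    if n_cultures < 1:
        raise InvalidConfigError("n_cultures must be >= 1")
    rng = np.random.default_rng(seed)
    generations = int(math.floor(math.log2(n_final_cells)))
    nonmut = np.ones(n_cultures, dtype=np.int64)
    mutants = np.zeros(n_cultures, dtype=np.int64)
    for _ in range(generations):
        new_mut = rng.binomial(nonmut, rate) if rate > 0 else 0
        mutants = 2 * mutants + new_mut
        nonmut = 2 * nonmut - new_mut
    # partial last generation: only enough cells divide to reach n_final,
    # so the total number of divisions is n_final - 1 regardless of whether
    # n_final is a power of two
    p_div = n_final_cells / float(2**generations) - 1.0
    if p_div > 0:
        div_non = rng.binomial(nonmut, p_div)
        div_mut = rng.binomial(mutants, p_div)
        new_mut = rng.binomial(div_non, rate) if rate > 0 else 0
        mutants = mutants + div_mut + new_mut
    return mutants


# ---------------------------------------------------------------------------
# Circular-chromosome breakage
# ---------------------------------------------------------------------------

def simulate_circular_breakage(
    breaks_per_kb: float, circle_kb: float, n_molecules: int, seed: int = 0
) -> float:
    """Fraction of circular molecules linearized by Poisson breakage.

    Each molecule receives ``Poisson(breaks_per_kb * circle_kb)`` breaks;
    any break linearizes the circle.  Converges to ``1 - exp(-lambda*L)``.
    """
    if breaks_per_kb < 0 or circle_kb <= 0 or n_molecules <= 0:
        raise InvalidConfigError("breakage parameters must be positive (rate may be 0)")
    if breaks_per_kb == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    lam = breaks_per_kb * circle_kb
    broken = rng.poisson(lam, size=int(n_molecules)) > 0
    return float(broken.mean())


# ---------------------------------------------------------------------------
# Point mutations
# ---------------------------------------------------------------------------

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def generate_mutations(
    class_probs: Sequence[float], n: int, seed: int = 0
) -> pd.DataFrame:
    """Draw ``n`` mutation records from a 7-class multinomial.

    ``class_probs`` gives probabilities for the six pyrimidine-strand
    substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) followed by the
    small-in/del probability; they must sum to 1.
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (7,) or np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise InvalidConfigError("class_probs must be 7 non-negative values summing to 1")
    if n < 0:
        raise InvalidConfigError("n must be >= 0")
    labels = list(SUBSTITUTION_CLASSES) + ["indel"]
    rng = np.random.default_rng(seed)
    if n == 0:
        return pd.DataFrame(columns=["mutation_class", "kind"])
    draws = rng.choice(7, size=n, p=probs)
    cls = [labels[i] for i in draws]
    kind = ["indel" if c == "indel" else "substitution" for c in cls]
    return pd.DataFrame({"mutation_class": cls, "kind": kind})
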