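"""Rates, corrections, tract statistics, enrichment tests, mutation spectra.

The quantitative conventions of the sectored-colony assay live here:

* A reciprocal crossover produces a red/white sectored colony in only half
  of chromatid segregations, so the crossover rate is twice the sectored
  frequency, and observed unselected crossover counts are doubled (with
  the hidden half subtracted from the apparent conversion-only count).
* Genome-wide event totals scale sectored frequencies by the assayed
  interval's genome fraction and by 1/viability² (a sectored colony needs
  both daughters of the treated cell to survive).
* Fluctuation-assay rates use the Lea–Coulson method of the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .event_classification import RecombinationEvent
from .synthetic_data import GenomeMap, SUBSTITUTION_CLASSES

__all__ = [
    "RateEstimate",
    "MutationSpectrum",
    "sector_frequency",
    "estimate_rate_median",
    "crossover_rate_from_sectors",
    "events_per_genome",
    "correct_co_con_counts",
    "tract_length_stats",
    "fraction_g1_initiated",
    "per_isolate_summary",
    "hotspot_test",
    "feature_enrichment",
    "rdna_expectation",
    "compare_spectra",
]


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class RateEstimate:
    estimate: float
    cl_lo: float
    cl_hi: float
    method: str  # "median-method" | "binomial-frequency"
    corrections: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.cl_lo <= self.estimate <= self.cl_hi) and "upper_bound" not in self.flags:
            raise ValueError("confidence limits must bracket the estimate")


@dataclass(frozen=True)
class MutationSpectrum:
    """Counts over the six pyrimidine-strand substitution classes + in/dels."""

    counts: tuple[int, ...]  # order: C>A, C>G, C>T, T>A, T>C, T>G
    indels: int = 0

    def __post_init__(self) -> None:
        if len(self.counts) != 6 or any(c < 0 for c in self.counts) or self.indels < 0:
            raise ValueError("spectrum needs 6 non-negative substitution counts")

    @property
    def total_substitutions(self) -> int:
        return sum(self.counts)

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "MutationSpectrum":
        counts = tuple(
            int((records["mutation_class"] == c).sum()) for c in SUBSTITUTION_CLASSES
        )
        return cls(counts, int((records["mutation_class"] == "indel").sum()))


# ---------------------------------------------------------------------------
# Frequencies and rates
# ---------------------------------------------------------------------------

def sector_frequency(
    n_sectored: int, n_total: int, ci_method: str = "wilson"
) -> RateEstimate:
    """Sectored-colony frequency with a 95% binomial confidence interval.

    ``ci_method`` is "wilson" (default) or "beta" (Clopper–Pearson exact).
    """
    if n_total <= 0:
        raise DegenerateInputError("n_total must be positive")
    if not (0 <= n_sectored <= n_total):
        raise ValueError("need 0 <= n_sectored <= n_total")
    lo, hi = proportion_confint(n_sectored, n_total, alpha=0.05, method=ci_method)
    est = n_sectored / n_total
    # guard against rounding placing a boundary an epsilon past the estimate
    return RateEstimate(est, min(float(lo), est), max(float(hi), est),
                        "binomial-frequency")


_LEA_COULSON_CONST = 1.24


def _lc_solve_m(median_count: float) -> float:
    """Solve r/m - ln(m) = 1.24 for m given the median count r (Lea–Coulson)."""
    if median_count <= 0:
        raise ValueError("median count must be positive")

    def f(log_m: float) -> float:
        m = math.exp(log_m)
        return median_count / m - log_m - _LEA_COULSON_CONST

    # f is strictly decreasing in log m; bracket and bisect
    lo, hi = -50.0, 50.0
    return math.exp(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def estimate_rate_median(
    counts: np.ndarray | list[int], n_final_cells: float
) -> RateEstimate:
    """Fluctuation-assay rate via the Lea–Coulson method of the median.

    The expected number of events per culture ``m`` solves
    ``r / m − ln m = 1.24`` where ``r`` is the median resistant-colony
    count; the rate is ``m / n_final_cells``.  Confidence limits transform
    the 95% binomial order-statistic interval of the sample median through
    the same equation.  An all-zero (or majority-zero) experiment yields a
    flagged upper bound: with median 0, ``P(no event) >= 1/2`` so
    ``m <= ln 2``.
    """
    counts = np.asarray(counts)
    if len(counts) < 5:
        raise DegenerateInputError("need >= 5 cultures")
    if n_final_cells <= 0:
        raise DegenerateInputError("n_final_cells must be positive")
    r = float(np.median(counts))
    if r == 0:
        ub = math.log(2) / n_final_cells
        return RateEstimate(0.0, 0.0, ub, "median-method", flags=("upper_bound",))
    m = _lc_solve_m(r)

    # distribution-free CI for the median via binomial order statistics
    srt = np.sort(counts)
    n = len(srt)
    k_lo = int(stats.binom.ppf(0.025, n, 0.5))
    k_hi = int(stats.binom.ppf(0.975, n, 0.5))
    r_lo = float(srt[max(k_lo - 1, 0)])
    r_hi = float(srt[min(k_hi, n - 1)])
    m_lo = _lc_solve_m(r_lo) if r_lo > 0 else 0.0
    m_hi = _lc_solve_m(r_hi) if r_hi > 0 else m
    return RateEstimate(
        m / n_final_cells, m_lo / n_final_cells, m_hi / n_final_cells, "median-method"
    )


def crossover_rate_from_sectors(freq: float) -> float:
    """Crossover rate = 2 x sectored-colony frequency (half of segregations
    hide the exchange)."""
    if freq < 0:
        raise ValueError("frequency must be >= 0")
    return 2.0 * freq


def events_per_genome(
    freq: float | None = None,
    interval_fraction: float | None = None,
    viability: float = 1.0,
    include_noncrossover: bool = False,
    crossovers_per_genome: float | None = None,
) -> RateEstimate:
    """Genome-wide recombination events per cell division.

    Either supply a sectored frequency plus the genome fraction of the
    assayed interval (the pre-viability crossovers/genome is then
    ``2 * freq / interval_fraction``), or supply that pre-viability figure
    directly via ``crossovers_per_genome``.  The result is divided by
    ``viability**2`` (both daughters must survive to form a sectored
    colony) and doubled again if ``include_noncrossover`` (conversions
    unassociated with crossovers are taken as equally frequent).
    """
    corrections = ["segregation x2"]
    if crossovers_per_genome is not None:
        pre = crossovers_per_genome
    else:
        if freq is None or interval_fraction is None:
            raise ValueError("need freq + interval_fraction, or crossovers_per_genome")
        if not (0 < interval_fraction <= 1):
            raise ValueError("interval_fraction must lie in (0, 1]")
        pre = crossover_rate_from_sectors(freq) / interval_fraction
        corrections.append("genome-fraction 1/f")
    if not (0 < viability <= 1):
        raise ValueError("viability must lie in (0, 1]")
    value = pre / viability**2
    corrections.append("viability 1/v^2")
    if include_noncrossover:
        value *= 2
        corrections.append("non-CO x2")
    return RateEstimate(value, value, value, "binomial-frequency", tuple(corrections))


def correct_co_con_counts(n_co: int, n_con: int) -> tuple[int, int, tuple[str, ...]]:
    """Segregation-correct observed crossover / conversion-only counts.

    Half of the crossovers segregate without producing reciprocal LOH and
    are observed as conversions: the true crossover count is ``2 * n_co``
    and the true conversion-only count is ``n_con - n_co``.  Returns
    ``(corrected_co, corrected_con, flags)``; a negative corrected
    conversion count is returned as-is with a flag, never clamped.
    """
    if n_co < 0 or n_con < 0:
        raise ValueError("counts must be non-negative")
    flags: tuple[str, ...] = ()
    if n_con < n_co:
        flags = ("negative-corrected-conversions",)
    return 2 * n_co, n_con - n_co, flags


# ---------------------------------------------------------------------------
# Tract lengths and conversion typing summaries
# ---------------------------------------------------------------------------

def tract_length_stats(
    lengths_kb: np.ndarray | list[float], n_boot: int = 10_000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Sample median tract length with a percentile-bootstrap 95% CL."""
    x = np.asarray(lengths_kb, dtype=float)
    if len(x) == 0:
        raise DegenerateInputError("no tracts")
    med = float(np.median(x))
    if len(x) == 1:
        return med, (med, med)
    rng = np.random.default_rng(seed)
    boots = np.median(
        x[rng.integers(0, len(x), size=(n_boot, len(x)))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return med, (min(float(lo), med), max(float(hi), med))


def fraction_g1_initiated(
    events: list[RecombinationEvent] | None = None,
    n_40: int | None = None,
    n_conversions: int | None = None,
) -> RateEstimate:
    """Fraction of conversion events whose tract contains a 4:0 region.

    A 4:0 sub-region means both sister chromatids were repaired, placing
    the initiating DSB before replication (G1).  Accepts either classified
    events or raw counts.
    """
    if events is not None:
        conv = [e for e in events if e.is_conversion]
        n_conversions = len(conv)
        n_40 = sum(1 for e in conv if e.has_40)
    if not n_conversions:
        raise DegenerateInputError("no conversion events")
    est = sector_frequency(n_40, n_conversions)
    return RateEstimate(est.estimate, est.cl_lo, est.cl_hi, "binomial-frequency")


def per_isolate_summary(
    events: list[RecombinationEvent], genome: GenomeMap
) -> dict:
    """Per-isolate and per-chromosome event summaries.

    Returns a dict with ``by_isolate`` (events, kb under copy-neutral LOH,
    kb under copy-number change, per isolate), ``mean_per_isolate``,
    ``by_chromosome`` totals, and a proportionality fit of per-chromosome
    counts against chromosome length (events are expected roughly in
    proportion to physical size) with a Poisson dispersion statistic.
    """
    loh_types = {"CON", "CO", "CON_CO", "CO_or_BIR", "BIR", "UPD"}
    cnv_types = {"terminal_del", "interstitial_del", "terminal_dup", "interstitial_dup",
                 "trisomy", "monosomy"}
    rows = []
    for e in events:
        span = (e.end_kb - e.start_kb) if e.start_kb is not None and e.end_kb is not None else 0.0
        rows.append({
            "isolate": e.isolate, "chrom": e.chromosome, "type": e.type,
            "loh_kb": span if e.type in loh_types else 0.0,
            "cnv_kb": span if e.type in cnv_types else 0.0,
        })
    if not rows:
        empty = pd.DataFrame(columns=["isolate", "n_events", "loh_kb", "cnv_kb"])
        return {"by_isolate": empty, "mean_per_isolate": 0.0,
                "by_chromosome": pd.DataFrame(), "length_fit": None}
    df = pd.DataFrame(rows)
    by_iso = df.groupby("isolate").agg(
        n_events=("type", "size"), loh_kb=("loh_kb", "sum"), cnv_kb=("cnv_kb", "sum")
    ).reset_index()
    by_chrom = df.groupby("chrom").size().rename("n_events")
    lengths = pd.Series({c.name: c.length_kb for c in genome.chromosomes})
    by_chrom = by_chrom.reindex(lengths.index, fill_value=0)

    total = int(by_chrom.sum())
    expected = lengths / lengths.sum() * total
    slope = total / lengths.sum()  # events per kb under proportionality
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = float((((by_chrom - expected) ** 2) / expected).replace([np.inf], np.nan).dropna().sum())
    dof = (expected > 0).sum() - 1
    dispersion_p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")

    return {
        "by_isolate": by_iso,
        "mean_per_isolate": float(by_iso["n_events"].mean()),
        "by_chromosome": pd.DataFrame({"n_events": by_chrom, "length_kb": lengths,
                                       "expected": expected}),
        "length_fit": {"events_per_kb": slope, "chi2": chi2, "dof": int(dof),
                       "dispersion_p": dispersion_p},
    }


# ---------------------------------------------------------------------------
# Positional statistics
# ---------------------------------------------------------------------------

def hotspot_test(
    event_positions: np.ndarray | list[float],
    intervals: list[tuple[float, float]],
    weights: np.ndarray | list[float] | None = None,
) -> pd.DataFrame:
    """Per-interval binomial hotspot/coldspot test with Bonferroni adjustment.

    ``intervals`` must tile the assayed region; ``weights`` (marker counts
    or lengths) give each interval's expected share of events under
    uniformity (interval lengths by default).
    """
    pos = np.asarray(event_positions, dtype=float)
    if len(pos) == 0:
        raise DegenerateInputError("no events")
    if weights is None:
        weights = [hi - lo for lo, hi in intervals]
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    p_exp = w / w.sum()
    n = len(pos)
    rows = []
    for (lo, hi), p0 in zip(intervals, p_exp):
        k = int(((pos >= lo) & (pos < hi)).sum())
        pval = stats.binomtest(k, n, p0, alternative="two-sided").pvalue
        rows.append({"start": lo, "end": hi, "observed": k,
                     "expected": n * p0, "p_raw": pval})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def _event_intervals(events: list[RecombinationEvent]) -> list[tuple[str, float, float]]:
    out = []
    for e in events:
        if e.start_kb is None or e.end_kb is None:
            continue
        out.append((e.chromosome, e.start_kb, e.end_kb))
    return out


def feature_enrichment(
    events: list[RecombinationEvent],
    genome: GenomeMap,
    n_perm: int = 10_000,
    seed: int = 0,
    tracks: list[str] | None = None,
) -> pd.DataFrame:
    """Permutation test of event-tract overlap with each feature track.

    The observed number of events whose tract overlaps >= 1 feature
    interval is compared against a null built by re-placing each tract
    uniformly on its own chromosome, preserving its length.  P-values are
    empirical and two-sided with add-one correction, computed on the
    distance from the null mean (the centred form stays calibrated on the
    discrete overlap-count distribution, where doubling the smaller tail
    is over-conservative); Bonferroni-adjusted across tracks.  Empty
    tracks are skipped.
    """
    ivals = _event_intervals(events)
    if not ivals:
        raise DegenerateInputError("no positioned events")
    rng = np.random.default_rng(seed)
    track_names = tracks if tracks is not None else list(genome.features)
    trees: dict[str, dict[str, IntervalTree]] = {}
    for t in track_names:
        frame = genome.features.get(t)
        if frame is None or frame.empty:
            continue
        per_chrom: dict[str, IntervalTree] = {}
        for row in frame.itertuples(index=False):
            per_chrom.setdefault(row.chrom, IntervalTree()).addi(row.start_kb, row.end_kb)
        trees[t] = per_chrom

    chrom_len = {c.name: c.length_kb for c in genome.chromosomes}

    def overlap_count(placed: list[tuple[str, float, float]], per_chrom) -> int:
        n = 0
        for chrom, lo, hi in placed:
            tree = per_chrom.get(chrom)
            if tree is not None and tree.overlap(lo, max(hi, np.nextafter(lo, np.inf))):
                n += 1
        return n

    # one shared set of null placements across tracks (paired permutations)
    nulls: list[list[tuple[str, float, float]]] = []
    for _ in range(n_perm):
        placed = []
        for chrom, lo, hi in ivals:
            L = hi - lo
            start = rng.uniform(0, chrom_len[chrom] - L)
            placed.append((chrom, start, start + L))
        nulls.append(placed)

    rows = []
    for t, per_chrom in trees.items():
        obs = overlap_count(ivals, per_chrom)
        null_counts = np.array([overlap_count(p, per_chrom) for p in nulls])
        mu = null_counts.mean()
        p = (1 + (np.abs(null_counts - mu) >= abs(obs - mu)).sum()) / (n_perm + 1)
        rows.append({"track": t, "observed": obs, "null_mean": float(null_counts.mean()),
                     "p_raw": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = np.minimum(out["p_raw"] * len(out), 1.0)
    return out


def rdna_expectation(n_terminal: int, rdna_fraction: float) -> tuple[float, float]:
    """Expected terminal events in the rDNA and the Poisson chance of zero.

    Under uniform placement, ``n_terminal * rdna_fraction`` terminal LOH
    events are expected inside the rDNA array; observing none has
    probability ``exp(-expected)``.
    """
    if not (0 <= rdna_fraction <= 1):
        raise ValueError("rdna_fraction must lie in [0, 1]")
    expected = n_terminal * rdna_fraction
    return expected, math.exp(-expected)


# ---------------------------------------------------------------------------
# Mutation spectra
# ---------------------------------------------------------------------------

def compare_spectra(s1: MutationSpectrum, s2: MutationSpectrum) -> dict:
    """Compare two six-class substitution spectra.

    Returns the overall chi-square p-value for homogeneity of the class
    proportions plus a per-class exact test (Fisher on the class-vs-rest
    2x2 table, which is two-sided and symmetric in the two spectra).
    """
    c1, c2 = np.array(s1.counts), np.array(s2.counts)
    n1, n2 = c1.sum(), c2.sum()
    if n1 == 0 or n2 == 0:
        raise DegenerateInputError("both spectra need at least one substitution")
    if np.array_equal(c1 / n1, c2 / n2):
        chi2_p, chi2_stat = 1.0, 0.0
    else:
        keep = (c1 + c2) > 0
        chi2_stat, chi2_p, *_ = stats.chi2_contingency(np.vstack([c1[keep], c2[keep]]))
    per_class = []
    for cls, k1, k2 in zip(SUBSTITUTION_CLASSES, c1, c2):
        table = [[int(k1), int(n1 - k1)], [int(k2), int(n2 - k2)]]
        per_class.append({"class": cls, "s1": int(k1), "s2": int(k2),
                          "p": float(stats.fisher_exact(table)[1])})
    return {
        "chi2_stat": float(chi2_stat),
        "chi2_p": float(chi2_p),
        "per_class": pd.DataFrame(per_class),
    }
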