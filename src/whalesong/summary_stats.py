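"""Theme-sharing statistics and the seven ABC summary statistics.

Theme sharing between two singer samples A and B is the mean, over singers
j of A, of the mean proportion of j's themes found in singer k of B:

    TS(A, B) = (1/ns_A) * sum_j [ (1/ns_B) * sum_k |t_Aj ∩ t_Bk| / |t_Aj| ]

For within-sample sharing (B = A) the pair k = j is excluded and the inner
mean divides by ns − 1.  TS is asymmetric in general and always lies in
[0, 1].

The seven summary statistics, each averaged over all populations and the
last 11 simulated years, are: (1) singleton themes, (2) mean song length,
(3) within-population s.d. of song length, (4) within-year within-
population sharing TS_FC, (5) theme turnover TS_FC − TS_FP (sharing with
the same population's previous-year sample), (6) the absolute difference
of previous-year sharing with the western and eastern neighbours
|TS_WP − TS_EP|, and (7) max(TS_WP, TS_EP).  Statistics 1, 3, 5 and 7 are
square-root transformed (turnover clamped at zero first), and each
statistic is normalised by its standard deviation over a reference set of
prior-predictive simulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model_core import SONG_SLOTS
from .simulator import SimulationRecord

N_STATS = 7
SQRT_STATS = (0, 2, 4, 6)  # statistics 1, 3, 5, 7 (zero-based)


@dataclass
class SongSample:
    """One year of one population: the theme sets of the sampled singers."""

    population: str
    year: int
    theme_sets: list

    def __post_init__(self):
        self.theme_sets = [frozenset(t) for t in self.theme_sets if len(t) > 0]

    @property
    def ns(self) -> int:
        return len(self.theme_sets)

    def padded(self) -> np.ndarray:
        arr = np.zeros((self.ns, SONG_SLOTS), dtype=np.int64)
        for j, t in enumerate(self.theme_sets):
            srt = sorted(t)
            arr[j, : len(srt)] = srt
        return arr


def _pairwise_share(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """share[j, k] = |t_Aj ∩ t_Bk| / |t_Aj| for padded theme arrays."""
    occ = A > 0
    inter = ((A[:, :, None, None] == B[None, None, :, :]) & occ[:, :, None, None]).sum(
        axis=(1, 3)
    )
    sizes = occ.sum(axis=1)
    return inter / sizes[:, None]


def theme_sharing(A: SongSample, B: SongSample | None = None, within: bool = False):
    """Mean theme sharing between samples A and B (or within A).

    ``within=True`` compares A with itself, excluding each singer's
    self-pair and dividing the inner sum by ns − 1; it requires ns >= 2.
    Between-sample sharing uses all pairs.
    """
    if within:
        if B is not None and B is not A:
            raise ValueError("within-sample sharing compares a sample with itself")
        if A.ns < 2:
            raise ValueError("within-sample sharing needs at least 2 singers")
        share = _pairwise_share(A.padded(), A.padded())
        np.fill_diagonal(share, 0.0)
        return float(share.sum(axis=1).mean() / (A.ns - 1))
    if B is None:
        raise ValueError("between-sample sharing needs a second sample")
    if A.ns < 1 or B.ns < 1:
        raise ValueError("samples must be non-empty")
    return float(_pairwise_share(A.padded(), B.padded()).mean())


def singleton_count(sample: SongSample) -> int:
    """Number of theme types sung by exactly one sampled singer."""
    counts: dict[int, int] = {}
    for t in sample.theme_sets:
        for theme in t:
            counts[theme] = counts.get(theme, 0) + 1
    return sum(1 for c in counts.values() if c == 1)


def length_stats(sample: SongSample) -> tuple[float, float]:
    """(mean, sample s.d.) of song lengths; s.d. is NaN below 2 singers."""
    lengths = np.array([len(t) for t in sample.theme_sets], dtype=float)
    mean = float(lengths.mean()) if lengths.size else math.nan
    sd = float(lengths.std(ddof=1)) if lengths.size >= 2 else math.nan
    return mean, sd


@dataclass
class SummaryVector:
    raw: np.ndarray
    transformed: np.ndarray
    normalized: np.ndarray | None = None

    @classmethod
    def from_raw(cls, raw) -> "SummaryVector":
        raw = np.asarray(raw, dtype=float)
        if raw.shape != (N_STATS,):
            raise ValueError(f"expected {N_STATS} summary statistics")
        return cls(raw=raw, transformed=transform(raw))

    def normalize(self, reference_sds) -> "SummaryVector":
        self.normalized = normalize(self.transformed, reference_sds)
        return self


def transform(raw: np.ndarray) -> np.ndarray:
    """Square-root transform statistics 1, 3, 5 and 7 (clamping at zero)."""
    out = np.asarray(raw, dtype=float).copy()
    for i in SQRT_STATS:
        out[i] = math.sqrt(max(0.0, out[i]))
    return out


def normalize(transformed, reference_sds) -> np.ndarray:
    ref = np.asarray(reference_sds, dtype=float)
    if np.any(ref <= 0) or np.any(~np.isfinite(ref)):
        raise ValueError("reference SDs must be strictly positive and finite")
    return np.asarray(transformed, dtype=float) / ref


def reference_sds(transformed_vectors) -> np.ndarray:
    """Per-statistic s.d. over a stack of transformed summary vectors."""
    stack = np.asarray(transformed_vectors, dtype=float)
    sds = np.nanstd(stack, axis=0, ddof=1)
    if np.any(sds <= 0) or np.any(~np.isfinite(sds)):
        raise ValueError("degenerate reference set: a statistic has zero spread")
    return sds


def distance(v1, v2) -> float:
    """Euclidean distance between two (normalised) summary vectors."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape:
        raise ValueError("summary vectors must have equal length")
    return float(np.linalg.norm(v1 - v2))


# ---------------------------------------------------------------------------
# record-level computations


def _nanmean(x) -> float:
    """nanmean that quietly returns NaN for an all-NaN slice."""
    x = np.asarray(x, dtype=float)
    good = np.isfinite(x)
    return float(x[good].mean()) if good.any() else math.nan


def _samples_by_key(record: SimulationRecord, plan=None) -> dict:
    out = {}
    for (year, pop), songs in record.samples.items():
        if plan is not None:
            size = plan.get((year, pop), 0)
            if size <= 0:
                continue
            songs = songs[:size]
        out[(year, pop)] = SongSample(pop, year, songs)
    return out


def _sharing_grid(record: SimulationRecord, years, plan=None):
    """Per (population, year) raw statistics over the requested years.

    Returns dict of 2-D arrays (pop, year) with NaN where a statistic is
    unavailable (missing sample, too few singers, or a missing directional
    neighbour).
    """
    topo = record.topology
    labels = record.populations
    samples = _samples_by_key(record, plan)
    P, Y = len(labels), len(years)
    g = {
        k: np.full((P, Y), np.nan)
        for k in ("s1", "s2", "s3", "ts_fc", "ts_fp", "ts_wp", "ts_ep")
    }
    for pi, pop in enumerate(labels):
        west, east = topo.west_east(pi)
        for yi, y in enumerate(years):
            sp = samples.get((y, pop))
            if sp is None or sp.ns < 1:
                continue
            g["s1"][pi, yi] = singleton_count(sp)
            mean, sd = length_stats(sp)
            g["s2"][pi, yi] = mean
            g["s3"][pi, yi] = sd
            if sp.ns >= 2:
                g["ts_fc"][pi, yi] = theme_sharing(sp, within=True)
            prev = samples.get((y - 1, pop))
            if prev is not None and prev.ns >= 1:
                g["ts_fp"][pi, yi] = theme_sharing(sp, prev)
            if west is not None:
                wp = samples.get((y - 1, labels[west]))
                if wp is not None and wp.ns >= 1:
                    g["ts_wp"][pi, yi] = theme_sharing(sp, wp)
            if east is not None:
                ep = samples.get((y - 1, labels[east]))
                if ep is not None and ep.ns >= 1:
                    g["ts_ep"][pi, yi] = theme_sharing(sp, ep)
    return g


def summarize(
    record: SimulationRecord,
    plan=None,
    last_years: int = 11,
    stat6_printed: bool = False,
) -> SummaryVector:
    """The seven summary statistics averaged over populations and years.

    Uses the last ``last_years`` recorded years (each needing the year
    before for the previous-year statistics, hence the record must cover
    at least ``last_years + 1`` years).  ``plan`` optionally truncates each
    (year, population) sample to an empirical sample-size matrix.
    ``stat6_printed`` switches statistic 6 to the literal printed variant
    TS_FP − TS_EP instead of |TS_WP − TS_EP| (sensitivity analysis only).
    """
    if record.years < last_years + 1:
        raise ValueError("record too short for previous-year statistics")
    years = list(range(record.years - last_years + 1, record.years + 1))
    g = _sharing_grid(record, years, plan)
    with np.errstate(invalid="ignore"):
        s5 = g["ts_fc"] - g["ts_fp"]
        if stat6_printed:
            s6 = g["ts_fp"] - g["ts_ep"]
        else:
            s6 = np.abs(g["ts_wp"] - g["ts_ep"])
        s7 = np.fmax(g["ts_wp"], g["ts_ep"])
    raw = np.array(
        [
            _nanmean(g["s1"]),
            _nanmean(g["s2"]),
            _nanmean(g["s3"]),
            _nanmean(g["ts_fc"]),
            _nanmean(s5),
            _nanmean(s6),
            _nanmean(s7),
        ]
    )
    return SummaryVector.from_raw(raw)


@dataclass
class DiagnosticStats:
    """Run-level sharing diagnostics and the revolution classification."""

    ts_fc: float
    ts_fp: float
    ts_wp: float
    ts_ep: float
    diff: float  # TS_WP − TS_EP; NaN when no population has both neighbours
    max_ts: float
    turnover: float  # TS_FC − TS_FP, exact by construction
    label: str  # "eastward" | "westward" | "none"

    THRESHOLD = 0.2

    @property
    def is_revolution(self) -> bool:
        return self.label in ("eastward", "westward")


def classify_revolution(diff: float, threshold: float = DiagnosticStats.THRESHOLD) -> str:
    """Label a run from Diff = TS_WP − TS_EP.

    Sharing biased towards the *western* neighbour's previous-year song
    means novel material travels west→east: ``Diff >= 0.2`` is an eastward
    revolutionary wave, ``Diff <= -0.2`` a westward one.
    """
    if not np.isfinite(diff):
        return "none"
    if diff >= threshold:
        return "eastward"
    if diff <= -threshold:
        return "westward"
    return "none"


def diagnostics(
    record: SimulationRecord, plan=None, last_years: int = 11
) -> DiagnosticStats:
    """Average sharing diagnostics over populations and the last years.

    Populations lacking a western or eastern neighbour contribute no
    directional terms (their Diff is unavailable).
    """
    if record.years < last_years + 1:
        raise ValueError("record too short for previous-year statistics")
    years = list(range(record.years - last_years + 1, record.years + 1))
    g = _sharing_grid(record, years, plan)
    with np.errstate(invalid="ignore"):
        diff_grid = g["ts_wp"] - g["ts_ep"]
        max_grid = np.fmax(g["ts_wp"], g["ts_ep"])
    ts_fc = _nanmean(g["ts_fc"])
    ts_fp = _nanmean(g["ts_fp"])
    both = np.isfinite(diff_grid)
    diff = _nanmean(diff_grid[both]) if both.any() else math.nan
    return DiagnosticStats(
        ts_fc=ts_fc,
        ts_fp=ts_fp,
        ts_wp=_nanmean(g["ts_wp"]),
        ts_ep=_nanmean(g["ts_ep"]),
        diff=diff,
        max_ts=_nanmean(max_grid),
        turnover=ts_fc - ts_fp,
        label=classify_revolution(diff),
    )
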