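"""Unit curation and Poisson spike-train statistics.

Covers drift and low-rate exclusion, 100-ms rate binning, the Poisson
silence criterion for inactivity at syncope onset (with its random-window
control), the Poisson latency statistic for laser responses, the
three-criteria activation classification, and per-region aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .session import LaserEvent, SpikeTrain, SyncopeEvent

__all__ = [
    "PoissonInactivityParams", "LatencyParams", "UnitClassification",
    "BinnedRates", "flag_drifting_units", "flag_low_rate_units", "curate_units",
    "bin_rates", "inactivity_bins_required", "inactive_at_syncope",
    "random_window_control", "response_probability", "laser_latency",
    "classify_laser_activated", "region_summary", "baseline_rate",
]


@dataclass
class PoissonInactivityParams:
    """Silence-period statistic: P(no spikes in k bins) = exp(-lambda k dt)."""

    p0: float = 0.01
    dt: float = 0.001          # s, 1-ms grid
    k_max: int = 4000          # bins (4 s) cap for low-rate units
    onset_tolerance: float = 0.25  # s
    # where the silent run may begin relative to onset: "pre" = the 250 ms
    # before onset (suppression starting at onset leaves its last spike
    # there), "post" = after, "two" = either side
    sided: str = "pre"

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1 and self.p0 != 1:
            raise ValueError("p0 must lie in (0, 1]")
        if self.dt <= 0 or self.k_max <= 0:
            raise ValueError("dt and k_max must be positive")


@dataclass
class LatencyParams:
    """Response-latency statistic over N aligned stimulation windows."""

    n_repetitions: int = 4
    p_threshold: float = 1e-6
    step: float = 0.001        # s
    max_window: float = 1.0    # s, search cap
    activation_latency_max: float = 0.25  # s
    onset_window: float = 0.8  # s

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ValueError("need at least one repetition")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")


@dataclass
class UnitClassification:
    unit_id: str
    region: str
    drift_flag: bool = False
    low_rate_flag: bool = False
    inactive_at_syncope: bool = False
    time_off: float | None = None
    latency: float | None = None
    laser_activated: bool = False
    criterion_positive_residual: bool = False
    criterion_exceeds_pre: bool = False
    criterion_fast_latency: bool = False


@dataclass
class BinnedRates:
    """Units x bins spike counts on a half-open 100-ms grid."""

    counts: np.ndarray         # (n_units, n_bins)
    bin_width: float
    t0: float
    unit_ids: list[str]
    regions: list[str]

    @property
    def rates(self) -> np.ndarray:
        """Counts converted to Hz."""
        return self.counts / self.bin_width

    def bin_times(self) -> np.ndarray:
        """Left edges of the bins."""
        return self.t0 + np.arange(self.counts.shape[1]) * self.bin_width


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def flag_drifting_units(units: list[SpikeTrain], duration: float,
                        bin_width: float = 0.1, sigma: float = 30.0,
                        factor: float = 5.0, rate_floor: float = 1e-3) -> np.ndarray:
    """Flag units whose slow firing-rate envelope varies by more than 5x.

    Each unit's 100-ms binned rate is smoothed with a Gaussian of width
    (sigma) 30 s; the unit drifts when max/min of the smoothed rate exceeds
    ``factor``.  The minimum is floored at ``rate_floor`` Hz so part-silent
    units are flagged.  Empty trains are not flagged here (the rate filter
    removes them).
    """
    if duration <= 60:
        warnings.warn("drift statistic is unreliable on recordings under a minute")
    n_bins = max(int(np.ceil(duration / bin_width)), 1)
    sig_bins = sigma / bin_width
    flags = np.zeros(len(units), dtype=bool)
    for i, u in enumerate(units):
        if u.n_spikes == 0:
            continue
        counts = np.bincount(
            np.clip((u.spike_times / bin_width).astype(int), 0, n_bins - 1),
            minlength=n_bins)
        rate = ndimage.gaussian_filter1d(counts / bin_width, sig_bins, mode="reflect")
        flags[i] = rate.max() / max(rate.min(), rate_floor) > factor
    return flags


def flag_low_rate_units(units: list[SpikeTrain], duration: float,
                        threshold: float = 0.25) -> np.ndarray:
    """Flag units firing strictly below ``threshold`` Hz overall."""
    return np.array([u.n_spikes / duration < threshold for u in units])


def curate_units(units: list[SpikeTrain], duration: float, **kwargs
                 ) -> tuple[list[SpikeTrain], pd.DataFrame]:
    """Drift filter then rate filter; returns kept units and a flag table."""
    drift = flag_drifting_units(units, duration,
                                **{k: v for k, v in kwargs.items()
                                   if k in ("bin_width", "sigma", "factor", "rate_floor")})
    low = flag_low_rate_units(units, duration, kwargs.get("threshold", 0.25))
    table = pd.DataFrame({
        "unit_id": [u.unit_id for u in units],
        "region": [u.region for u in units],
        "drift_flag": drift, "low_rate_flag": low,
    })
    kept = [u for u, d, lo in zip(units, drift, low) if not (d or lo)]
    return kept, table


def baseline_rate(unit: SpikeTrain, duration: float,
                  exclude: list[tuple[float, float]] | None = None) -> float:
    """Mean rate excluding the given (test) segments."""
    exclude = exclude or []
    keep_time = duration
    n = unit.n_spikes
    for s, e in exclude:
        s, e = max(s, 0.0), min(e, duration)
        if e <= s:
            continue
        keep_time -= e - s
        n -= int(((unit.spike_times >= s) & (unit.spike_times < e)).sum())
    if keep_time <= 0:
        raise ValueError("exclusion segments cover the whole recording")
    return n / keep_time


def bin_rates(units: list[SpikeTrain], duration: float,
              bin_width: float = 0.1, t0: float = 0.0) -> BinnedRates:
    """Spike counts on a half-open [t, t+dt) grid; a spike at a bin edge
    falls in the later bin."""
    n_bins = int(np.floor((duration - t0) / bin_width + 1e-9))
    counts = np.zeros((len(units), n_bins))
    for i, u in enumerate(units):
        idx = np.floor((u.spike_times - t0) / bin_width + 1e-9).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[i] = np.bincount(idx, minlength=n_bins)
    return BinnedRates(counts, bin_width, t0,
                       [u.unit_id for u in units], [u.region for u in units])


# ---------------------------------------------------------------------------
# Poisson inactivity at syncope onset
# ---------------------------------------------------------------------------

def inactivity_bins_required(lam: float, params: PoissonInactivityParams
                             ) -> int:
    """Silent-bin count k with chance probability p0 under Poisson firing.

    k = ceil(-ln(p0) / (lambda dt)), capped at ``k_max`` for low-rate units.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0; low-rate units are excluded upstream")
    if params.p0 == 1:
        return 0
    k = int(np.ceil(-np.log(params.p0) / (lam * params.dt)))
    return min(k, params.k_max)


def _silent_runs(unit: SpikeTrain, span: tuple[float, float]) -> np.ndarray:
    """(start, end) of inter-spike silent intervals intersecting ``span``.

    Runs are delimited by consecutive spikes; the stretches before the first
    and after the last spike in the span are bounded by the neighbouring
    spikes outside it (or the span edge when none exists).
    """
    s, e = span
    t = unit.spike_times
    lo = np.searchsorted(t, s, side="left")
    hi = np.searchsorted(t, e, side="right")
    # neighbouring spikes just outside the span bound the edge runs
    pts = t[max(lo - 1, 0):min(hi + 1, t.size)]
    if pts.size == 0:
        return np.array([[s, e]])
    # runs between consecutive points, plus edge runs bounded by the span
    runs = []
    if pts[0] > s:
        runs.append((s, pts[0]))
    for a, b in zip(pts[:-1], pts[1:]):
        runs.append((a, b))
    if pts[-1] < e:
        runs.append((pts[-1], e))
    return np.array(runs)


def inactive_at_syncope(unit: SpikeTrain, syncope: SyncopeEvent,
                        params: PoissonInactivityParams,
                        window_end: float | None = None
                        ) -> tuple[bool, float | None]:
    """Flag a unit inactive at syncope onset; report its time-off fraction.

    A unit is inactive when some inter-spike silent run of at least ``k``
    1-ms bins begins within ``onset_tolerance`` of the syncope onset
    (two-sided by default).  ``time_off`` — computed only for inactive
    units — is the fraction of the syncope window's 1-ms bins lying inside
    silent runs of at least ``k`` bins; the window runs from onset to the
    syncope offset, or to ``window_end`` when the offset is undefined.
    """
    if unit.baseline_rate is None or unit.baseline_rate <= 0:
        raise ValueError(f"unit {unit.unit_id}: baseline rate undefined")
    k = inactivity_bins_required(unit.baseline_rate, params)
    min_len = k * params.dt
    tol = params.onset_tolerance
    end = syncope.offset if syncope.offset is not None else window_end
    if end is None:
        raise ValueError("syncope offset undefined and no window_end given")
    span = (syncope.onset - tol - min_len - 1.0, end + min_len)
    runs = _silent_runs(unit, span)
    lengths = runs[:, 1] - runs[:, 0]
    long = runs[lengths >= min_len]

    if params.sided == "pre":
        lo, hi = syncope.onset - tol, syncope.onset
    elif params.sided == "post":
        lo, hi = syncope.onset, syncope.onset + tol
    else:  # "two"
        lo, hi = syncope.onset - tol, syncope.onset + tol
    flag = bool(np.any((long[:, 0] >= lo) & (long[:, 0] <= hi)))
    if not flag:
        return False, None

    # time-off on the 1-ms grid of the syncope window
    n_bins = max(int(round((end - syncope.onset) / params.dt)), 1)
    grid = syncope.onset + (np.arange(n_bins) + 0.5) * params.dt
    off = np.zeros(n_bins, dtype=bool)
    for a, b in long:
        off |= (grid >= a) & (grid < b)
    return True, float(off.mean())


def random_window_control(units: list[SpikeTrain], syncope: SyncopeEvent,
                          lasers: list[LaserEvent], duration: float,
                          params: PoissonInactivityParams,
                          rng: np.random.Generator | int | None = None,
                          window_end: float | None = None,
                          margin: float = 5.0) -> pd.DataFrame:
    """Inactivity criterion at a random baseline onset, paired per region.

    A control onset is drawn uniformly from times whose +/-250 ms window
    avoids all laser and syncope periods (with ``margin`` s of slack); the
    same silence criterion is applied there and at the true syncope onset.
    Returns a per-region table with inactive counts/fractions for both and
    a paired t-test across regions on the fractions.
    """
    rng = np.random.default_rng(rng)
    bad = [(ev.onset - margin, ev.end + margin) for ev in lasers]
    if syncope is not None:
        end = syncope.offset if syncope.offset is not None else (window_end or syncope.onset + 30)
        bad.append((syncope.onset - margin, end + margin))
    for _ in range(1000):
        t = rng.uniform(margin, duration - margin)
        if all(not (s <= t <= e) for s, e in bad):
            break
    else:
        raise RuntimeError("no eligible baseline span for the random-window control")

    control_event = SyncopeEvent(onset=t, offset=t + (
        (syncope.offset - syncope.onset) if syncope and syncope.offset else 10.0))
    rows = []
    for u in units:
        f_s, _ = inactive_at_syncope(u, syncope, params, window_end)
        f_c, _ = inactive_at_syncope(u, control_event, params)
        rows.append({"unit_id": u.unit_id, "region": u.region,
                     "inactive_syncope": f_s, "inactive_control": f_c})
    per_unit = pd.DataFrame(rows)
    table = per_unit.groupby("region").agg(
        n_units=("unit_id", "size"),
        inactive_syncope=("inactive_syncope", "sum"),
        inactive_control=("inactive_control", "sum"),
        frac_syncope=("inactive_syncope", "mean"),
        frac_control=("inactive_control", "mean"),
    ).reset_index()
    if len(table) > 1:
        tstat = stats.ttest_rel(table.frac_syncope, table.frac_control)
        table.attrs["paired_t_p"] = float(tstat.pvalue)
    else:
        table.attrs["paired_t_p"] = float("nan")
    table.attrs["control_onset"] = float(t)
    return table


# ---------------------------------------------------------------------------
# Laser-response latency (Poisson surprise)
# ---------------------------------------------------------------------------

def response_probability(n: int, lam: float, n_repetitions: int, t: float) -> float:
    """P of observing at least ``n`` spikes in N windows of length ``t``.

    1 - sum_{m<n} (N lambda t)^m exp(-N lambda t) / m!, i.e. the Poisson
    survival function at n-1 with mean N*lambda*t, evaluated stably in
    log space by scipy.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if t <= 0:
        raise ValueError("t must be > 0")
    if n == 0:
        return 1.0
    mu = n_repetitions * lam * t
    return float(np.clip(stats.poisson.sf(n - 1, mu), 0.0, 1.0))


def laser_latency(unit: SpikeTrain, laser_onsets: np.ndarray,
                  params: LatencyParams) -> float | None:
    """First window length at which the pooled response is implausibly large.

    Windows [onset, onset+t) grow in 1-ms steps; ``n`` pools spikes across
    the N aligned windows.  The latency is the first t whose probability
    under the unit's baseline Poisson rate falls below ``p_threshold``;
    ``None`` when no window up to ``max_window`` does.
    """
    if unit.baseline_rate is None or unit.baseline_rate <= 0:
        raise ValueError(f"unit {unit.unit_id}: baseline rate undefined")
    onsets = np.asarray(laser_onsets, dtype=float)[:params.n_repetitions]
    N = onsets.size
    steps = np.arange(params.step, params.max_window + params.step / 2, params.step)
    # cumulative spike counts per window length, pooled over onsets
    rel = np.concatenate([unit.spike_times[
        (unit.spike_times >= o) & (unit.spike_times < o + params.max_window)] - o
        for o in onsets]) if N else np.array([])
    if rel.size == 0:
        return None
    rel.sort()
    counts = np.searchsorted(rel, steps, side="left")
    mu = N * unit.baseline_rate * steps
    pvals = stats.poisson.sf(counts - 1, mu)
    pvals = np.where(counts == 0, 1.0, pvals)
    hit = np.where(pvals < params.p_threshold)[0]
    return float(steps[hit[0]]) if hit.size else None


def classify_laser_activated(unit: SpikeTrain,
                             residual_onset_means: np.ndarray,
                             residual_pre_means: np.ndarray,
                             latency: float | None,
                             params: LatencyParams,
                             base: UnitClassification | None = None
                             ) -> UnitClassification:
    """Three-criteria laser activation from residuals and latency.

    (1) mean residual over the N laser-onset windows strictly positive;
    (2) onset residual strictly exceeds the pre-laser residual for every
    stimulation; (3) latency defined and under 250 ms.
    """
    onset = np.asarray(residual_onset_means, dtype=float)
    pre = np.asarray(residual_pre_means, dtype=float)
    if onset.size < params.n_repetitions or pre.size < params.n_repetitions:
        raise ValueError(f"need residuals for {params.n_repetitions} lasers, "
                         f"got {onset.size}")
    onset = onset[:params.n_repetitions]
    pre = pre[:params.n_repetitions]
    c1 = bool(onset.mean() > 0)
    c2 = bool(np.all(onset > pre))
    c3 = latency is not None and latency < params.activation_latency_max
    cls = base or UnitClassification(unit_id=unit.unit_id, region=unit.region)
    cls.latency = latency
    cls.criterion_positive_residual = c1
    cls.criterion_exceeds_pre = c2
    cls.criterion_fast_latency = bool(c3)
    cls.laser_activated = c1 and c2 and bool(c3)
    return cls


def region_summary(classifications: list[UnitClassification]) -> pd.DataFrame:
    """Per-region medians and fractions: latency (activated units), % inactive,
    mean time-off, unit counts.  Regions without units are omitted."""
    if not classifications:
        raise ValueError("need at least one classified unit")
    df = pd.DataFrame([c.__dict__ for c in classifications])
    rows = []
    for region, g in df.groupby("region"):
        act = g[g.laser_activated & g.latency.notna()]
        inact = g[g.inactive_at_syncope]
        rows.append({
            "region": region,
            "n_units": len(g),
            "n_activated": int(g.laser_activated.sum()),
            "median_latency": float(act.latency.median()) if len(act) else np.nan,
            "pct_inactive": 100.0 * g.inactive_at_syncope.mean(),
            "mean_time_off": float(inact.time_off.mean()) if len(inact) else np.nan,
        })
    return pd.DataFrame(rows).sort_values("region").reset_index(drop=True)
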