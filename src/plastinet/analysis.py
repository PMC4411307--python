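"""Spike-train and weight-matrix statistics.

Readout populations are determined from stimulus-evoked firing rates: for
each neuron i and stimulus mu, the evoked rate nu_i^mu is the spike count of
i during mu-on epochs inside an analysis window divided by the total mu-on
time.  Neuron i codes for mu if nu_i^mu exceeds a threshold rule; the
default rule, max(10 Hz, median + 2 robust s.d. over neurons), separates
~30 Hz assembly responses from ~1 Hz background at any network scale.  Sets may
overlap; the complement of all readout sets is the reserve pool.  The
stimulus-evoked covariance matrix, population activity traces (50 ms bins),
interspike-interval statistics (CV-ISI) and peristimulus time histograms
complete the readout toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulation import ScheduledStimulus

__all__ = [
    "ReadoutSet",
    "evoked_rates",
    "assign_readouts",
    "population_activity",
    "evoked_covariance",
    "spike_stats",
    "psth",
]


@dataclass
class ReadoutSet:
    """Per-stimulus readout membership and the rates/threshold that produced it."""

    members: dict[int, np.ndarray]
    rates: np.ndarray  # (n_neurons, n_stimuli)
    thresholds: np.ndarray  # per-stimulus threshold actually applied
    reserve_pool: np.ndarray = field(default=None)

    def __post_init__(self):
        n = self.rates.shape[0]
        coding = np.zeros(n, dtype=bool)
        for ids in self.members.values():
            coding[ids] = True
        self.reserve_pool = np.flatnonzero(~coding)


def _split_raster(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    raster = np.asarray(raster)
    if raster.size == 0:
        return np.empty(0), np.empty(0, dtype=np.int64)
    return raster[:, 0], raster[:, 1].astype(np.int64)


def evoked_rates(
    raster: np.ndarray,
    schedule: list[ScheduledStimulus],
    window: tuple[float, float],
    n_neurons: int,
    n_stimuli: int,
) -> np.ndarray:
    """Stimulus-evoked firing rate nu_i^mu (Hz) inside the analysis window.

    Stimuli with zero on-time inside the window yield NaN rates (flagged,
    not an error) for every neuron.
    """
    t, ids = _split_raster(raster)
    rates = np.zeros((n_neurons, n_stimuli))
    on_time = np.zeros(n_stimuli)
    for st in schedule:
        a, b = max(st.t_start, window[0]), min(st.t_end, window[1])
        if b <= a:
            continue
        on_time[st.pattern_id] += b - a
        sel = (t >= a) & (t < b)
        if sel.any():
            rates[:, st.pattern_id] += np.bincount(ids[sel], minlength=n_neurons)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = rates / on_time
    rates[:, on_time == 0] = np.nan
    return rates


def assign_readouts(
    rates: np.ndarray,
    min_rate: float = 10.0,
    n_sd: float = 2.0,
    threshold: float | None = None,
) -> ReadoutSet:
    """Assign neurons to readout populations M_mu by thresholding evoked rates.

    The per-stimulus threshold is ``threshold`` if given, else
    max(min_rate, median_i + n_sd * robust s.d._i) where the robust s.d. is
    1.4826 * MAD of the evoked rates for that stimulus.  The robust centre
    keeps the rule anchored to the low-rate background even when a sizeable
    fraction of neurons responds at assembly rates.  Membership is
    deterministic given rates and thresholds.
    """
    rates = np.asarray(rates, dtype=float)
    n_stim = rates.shape[1]
    thr = np.empty(n_stim)
    members: dict[int, np.ndarray] = {}
    for mu in range(n_stim):
        col = rates[:, mu]
        if np.isnan(col).all():
            thr[mu] = np.inf
        elif threshold is not None:
            thr[mu] = threshold
        else:
            med = np.nanmedian(col)
            mad = np.nanmedian(np.abs(col - med))
            thr[mu] = max(min_rate, med + n_sd * 1.4826 * mad)
        with np.errstate(invalid="ignore"):
            members[mu] = np.flatnonzero(col > thr[mu])
    return ReadoutSet(members=members, rates=rates, thresholds=thr)


def population_activity(
    raster: np.ndarray,
    member_set: np.ndarray,
    t_range: tuple[float, float],
    bin_width: float = 0.050,
) -> tuple[np.ndarray, np.ndarray]:
    """Population firing rate (Hz) of a neuron set in fixed time bins.

    Returns (bin_centres, rate); rate is the mean over members of the
    per-neuron binned rate, i.e. total set spikes / (|M| * bin).
    """
    member_set = np.asarray(member_set, dtype=np.int64)
    if member_set.size == 0:
        raise ValueError("member set must be nonempty")
    t, ids = _split_raster(raster)
    sel = np.isin(ids, member_set)
    edges = np.arange(t_range[0], t_range[1] + bin_width / 2, bin_width)
    counts, _ = np.histogram(t[sel], edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts / (member_set.size * bin_width)


def evoked_covariance(rates: np.ndarray) -> np.ndarray:
    """Covariance over stimuli of the evoked response vectors.

    C_{mu,nu} = mean_i (nu_i^mu - mean^mu)(nu_i^nu - mean^nu) where mean^mu
    is the mean evoked population response for stimulus mu.  Symmetric
    positive semi-definite by construction (Gram matrix of centred columns).
    """
    r = np.asarray(rates, dtype=float)
    if r.shape[1] < 2:
        raise ValueError("need at least two stimuli")
    centred = r - np.nanmean(r, axis=0, keepdims=True)
    centred = np.nan_to_num(centred)
    return centred.T @ centred / r.shape[0]


def spike_stats(
    raster: np.ndarray,
    window: tuple[float, float],
    n_neurons: int,
    min_spikes_cv: int = 3,
) -> pd.DataFrame:
    """Per-neuron firing rate and CV-ISI inside the window.

    CV-ISI = s.d./mean of the interspike intervals; neurons with fewer than
    ``min_spikes_cv`` spikes get NaN (excluded from CV histograms but
    counted in the 'n_spikes' column).
    """
    if window[1] <= window[0]:
        raise ValueError("window must be nonempty")
    t, ids = _split_raster(raster)
    sel = (t >= window[0]) & (t < window[1])
    t, ids = t[sel], ids[sel]
    T = window[1] - window[0]
    rows = []
    for i in range(n_neurons):
        ti = np.sort(t[ids == i])
        cv = np.nan
        if ti.size >= min_spikes_cv:
            isi = np.diff(ti)
            if isi.mean() > 0:
                cv = isi.std() / isi.mean()
        rows.append((i, ti.size, ti.size / T, cv))
    return pd.DataFrame(rows, columns=["neuron", "n_spikes", "rate", "cv_isi"])


def psth(
    raster: np.ndarray,
    events: np.ndarray,
    member_set: np.ndarray,
    window: tuple[float, float] = (-0.2, 0.8),
    bin_width: float = 0.020,
) -> tuple[np.ndarray, np.ndarray]:
    """Trial- and population-averaged peristimulus time histogram in Hz.

    Spike times are aligned on each event onset; counts are averaged over
    trials and members and normalized by the bin width.
    """
    events = np.atleast_1d(np.asarray(events, dtype=float))
    if events.size == 0:
        raise ValueError("need at least one aligned event")
    member_set = np.asarray(member_set, dtype=np.int64)
    t, ids = _split_raster(raster)
    sel = np.isin(ids, member_set)
    t = t[sel]
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    acc = np.zeros(len(edges) - 1)
    for ev in events:
        counts, _ = np.histogram(t - ev, edges)
        acc += counts
    rate = acc / (events.size * max(member_set.size, 1) * bin_width)
    return 0.5 * (edges[:-1] + edges[1:]), rate
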