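"""Derived quantities from spike records.

Three per-neuron summary quantities describe each data set:

- R: mean number of spikes fired per trial of the indicated type,
- T: mean threshold adaptation theta at trial onset (mV), the neuronal
  ("global"/"local" fatigue) state immediately before stimulation,
- D: estimated peak EPSP lost to presynaptic depression (mV), a
  postsynaptic-impact measure of STD roughly commensurable with T.

Sequence contrasts (deviant minus many-standards control) of these
quantities, written dR, dT, dD, carry the deviance-detection analysis. The
deviance detection index (DDI) is the normalized contrast of the
network-mean target response between the deviant and control sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .network import Network
from .simulate import SpikeRecord

__all__ = [
    "trial_responses",
    "mean_theta_at_onset",
    "ddi",
    "ContributionMaps",
    "contribution_scores",
    "DepressionEstimate",
    "depression_loss",
    "latency_rank",
    "local_global_split",
    "distance_profile",
    "std_memory_correlation",
    "responsiveness_filter",
]


def trial_responses(record: SpikeRecord, trial_mask: np.ndarray) -> np.ndarray:
    """Per-neuron mean spikes per trial (R) over the selected trials.

    ``trial_mask`` is boolean over trials, e.g. ``record.trial_mask(site)``
    for target trials or ``record.nontarget_mask(target)`` for non-target
    trials. Spikes are counted within [onset, onset + soa).
    """
    trial_mask = np.asarray(trial_mask, dtype=bool)
    if trial_mask.sum() == 0:
        raise ValueError("trial filter selects no trials")
    counts = record.trial_spike_counts()
    return counts[trial_mask].mean(axis=0)


def mean_theta_at_onset(record: SpikeRecord, trial_mask: np.ndarray) -> np.ndarray:
    """Per-excitatory-neuron mean theta at trial onset (T) over selected trials."""
    trial_mask = np.asarray(trial_mask, dtype=bool)
    if trial_mask.sum() == 0:
        raise ValueError("trial filter selects no trials")
    return record.theta_at_onset[trial_mask].mean(axis=0)


def ddi(r_dev_mean: float, r_con_mean: float) -> float:
    """Deviance detection index: (dev - con) / (dev + con) of the
    network-mean target responses. NaN when both responses are zero."""
    total = r_dev_mean + r_con_mean
    if total == 0:
        return float("nan")
    return (r_dev_mean - r_con_mean) / total


@dataclass
class ContributionMaps:
    """Attribution of extra deviant-sequence firing to V_m vs threshold.

    All arrays are (window_steps, n_exc) except the network time courses.
    ``c_vm`` and ``c_theta`` partition each bin's attributable cause between
    higher voltage and lower threshold (they sum to 1 where defined, NaN
    elsewhere). ``mask`` marks the bins of interest: excitatory neurons
    firing more in the deviant sequence with a nonzero attributable cause.
    ``c_vm_t``/``c_theta_t`` are the delta-P-weighted per-step summaries.
    """

    delta_p: np.ndarray
    delta_vm: np.ndarray
    delta_theta: np.ndarray
    c_vm: np.ndarray
    c_theta: np.ndarray
    mask: np.ndarray
    c_vm_t: np.ndarray
    c_theta_t: np.ndarray


def contribution_scores(record_dev: SpikeRecord, record_con: SpikeRecord) -> ContributionMaps:
    """Contribution of lower thresholds vs higher voltages to greater
    deviant-sequence firing, from trial-averaged dense traces.

    Only a lower threshold (delta_theta < 0) or a higher voltage
    (delta_vm > 0) can cause more firing; each bin's contributions are the
    relative sizes of the positive parts [delta_vm]+ and [-delta_theta]+.
    Bins with delta_p <= 0, and bins where both positive parts vanish, are
    excluded from the mask. The time courses average C * delta_p over the
    masked neurons at each step.
    """
    if record_dev.traces is None or record_con.traces is None:
        raise ValueError("both records need trial-averaged dense traces")
    dev, con = record_dev.traces, record_con.traces
    if dev["P"].shape != con["P"].shape:
        raise ValueError("trace shapes differ between records")

    dp = dev["P"] - con["P"]
    dvm = dev["Vm"] - con["Vm"]
    dth = dev["theta"] - con["theta"]

    pos_vm = np.maximum(dvm, 0.0)
    pos_th = np.maximum(-dth, 0.0)
    denom = pos_vm + pos_th
    defined = denom > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c_vm = np.where(defined, pos_vm / np.where(defined, denom, 1.0), np.nan)
    c_theta = np.where(defined, 1.0 - c_vm, np.nan)

    mask = (dp > 0) & defined
    m_count = mask.sum(axis=1).astype(float)
    weighted_vm = np.where(mask, c_vm * dp, 0.0).sum(axis=1)
    weighted_th = np.where(mask, c_theta * dp, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c_vm_t = np.where(m_count > 0, weighted_vm / m_count, np.nan)
        c_theta_t = np.where(m_count > 0, weighted_th / m_count, np.nan)

    return ContributionMaps(
        delta_p=dp,
        delta_vm=dvm,
        delta_theta=dth,
        c_vm=c_vm,
        c_theta=c_theta,
        mask=mask,
        c_vm_t=c_vm_t,
        c_theta_t=c_theta_t,
    )


@dataclass
class DepressionEstimate:
    """Estimated peak EPSP lost to presynaptic depression, per neuron.

    ``r_hat`` is the cross-sequence mean response of each (presynaptic)
    neuron to the stimulus; ``x_bar`` maps sequence name to the mean
    depression of each excitatory neuron at the starts of the stimulus
    trials of that sequence; ``d`` maps sequence name to the per-neuron
    loss estimate D (mV).
    """

    stimulus_site: int
    k: float
    r_hat: np.ndarray
    x_bar: dict[str, np.ndarray]
    d: dict[str, np.ndarray]


def depression_loss(
    records: dict[str, SpikeRecord],
    network: Network,
    stimulus_site: int,
    k: float = 1.4,
) -> DepressionEstimate:
    """Estimate the peak EPSP lost to depression for stimulus ``S``.

    The presynaptic drive of neuron j is its response to S averaged across
    all three sequences (to minimize the influence of activity differences
    between them); each of j's spikes loses (1 - x_bar_j) * k mV of peak
    EPSP relative to the recovered state, where x_bar_j is the
    sequence-specific mean depression at the starts of S trials. Summing
    over the excitatory presynaptic partners of each neuron i gives D_i per
    sequence.
    """
    if len(records) == 0:
        raise ValueError("no records given")
    n = network.n_neurons
    n_exc = network.n_exc

    per_seq_r = []
    for seq, rec in records.items():
        mask = rec.trial_mask(stimulus_site)
        if mask.sum() == 0:
            raise ValueError(f"sequence {seq!r} has no trials at site {stimulus_site}")
        per_seq_r.append(rec.trial_spike_counts()[mask].mean(axis=0))
    r_hat = np.mean(per_seq_r, axis=0)

    # adjacency restricted to excitatory presynaptic neurons (exc come first)
    syn = network.synapses
    exc_syn = syn[network.is_excitatory[syn[:, 0]]]
    adj = sparse.csr_matrix(
        (np.ones(len(exc_syn)), (exc_syn[:, 1], exc_syn[:, 0])), shape=(n, n_exc)
    )

    x_bar: dict[str, np.ndarray] = {}
    d: dict[str, np.ndarray] = {}
    for seq, rec in records.items():
        mask = rec.trial_mask(stimulus_site)
        xb = rec.x_at_onset[mask].mean(axis=0)
        x_bar[seq] = xb
        d[seq] = k * (adj @ (r_hat[:n_exc] * (1.0 - xb)))

    return DepressionEstimate(stimulus_site=stimulus_site, k=k, r_hat=r_hat, x_bar=x_bar, d=d)


def latency_rank(records: list[SpikeRecord], site: int) -> np.ndarray:
    """Rank neurons by minimum first-spike latency across ``site`` trials of
    all given records.

    Latency is measured from trial onset; the minimum is taken over all
    matching trials of all records. Never-responding neurons rank last;
    ties break by neuron index. Returns 0-based ranks (rank r means the
    (r+1)-th earliest responder); the "early" subset of a network is the
    first 100 ranks.
    """
    if not records:
        raise ValueError("no records given")
    n = records[0].n_neurons
    best = np.full(n, np.inf)
    for rec in records:
        if not len(rec.spike_times):
            continue
        trial_idx = np.floor_divide(rec.spike_times, rec.soa).astype(np.int64)
        ok = (trial_idx >= 0) & (trial_idx < rec.n_trials)
        in_site = np.zeros(len(trial_idx), dtype=bool)
        in_site[ok] = rec.sites[trial_idx[ok]] == site
        rel = rec.spike_times[in_site] - rec.onsets[trial_idx[in_site]]
        np.minimum.at(best, rec.spike_neurons[in_site], rel)
    order = np.lexsort((np.arange(n), best))
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    return ranks


def local_global_split(network: Network, site: int, cutoff: float = 2.0) -> np.ndarray:
    """Boolean mask: True for "local" neurons within ``cutoff`` mm of the
    site center, False for the "global" remainder."""
    return network.site_distances(site) < cutoff


def distance_profile(
    values: np.ndarray,
    network: Network | None = None,
    site: int | None = None,
    *,
    distances: np.ndarray | None = None,
    n_bins: int = 200,
    dist_range: tuple[float, float] = (0.0, 6.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Radial profile of a per-neuron metric around a stimulation site.

    Returns (bin_edges, per-bin means). Values pooled across data sets can
    be passed as one concatenated array together with matching
    ``distances``. Empty bins are NaN, not zero. NaN values are ignored.
    """
    values = np.asarray(values, dtype=float)
    if distances is None:
        if network is None or site is None:
            raise ValueError("give either distances or (network, site)")
        distances = network.site_distances(site)
    distances = np.asarray(distances, dtype=float)
    if distances.shape != values.shape:
        raise ValueError("values and distances must align")
    edges = np.linspace(dist_range[0], dist_range[1], n_bins + 1)
    finite = np.isfinite(values)
    sums, _ = np.histogram(distances[finite], bins=edges, weights=values[finite])
    counts, _ = np.histogram(distances[finite], bins=edges)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return edges, means


def std_memory_correlation(record: SpikeRecord, target: int, lag: int = 1) -> float:
    """Correlation, across excitatory neurons, between target-trial spike
    counts and the depression variable x at the start of the trial ``lag``
    positions later.

    A strongly negative lag-1 value with a near-zero lag-2 value shows that
    depression only remembers the immediately preceding trial. NaN when
    either variable has zero variance (e.g. STD disabled, x identically 1).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    mask = record.trial_mask(target)
    trial_ids = np.flatnonzero(mask)
    trial_ids = trial_ids[trial_ids + lag < record.n_trials]
    if len(trial_ids) < 1 or mask.sum() < 3:
        raise ValueError("need at least 3 target trials")
    counts = record.trial_spike_counts()[trial_ids][:, : record.n_exc].mean(axis=0)
    x_next = record.x_at_onset[trial_ids + lag].mean(axis=0)
    if counts.std() == 0 or x_next.std() == 0:
        return float("nan")
    return float(np.corrcoef(counts, x_next)[0, 1])


def responsiveness_filter(
    r_per_sequence: np.ndarray,
    threshold: float = 0.1,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Keep neurons firing at least ``threshold`` spikes/trial in every
    sequence.

    ``r_per_sequence`` is (n_sequences, n_neurons). ``exclude`` optionally
    removes given neuron indices (e.g. the directly stimulated set) as
    well. Returns a boolean keep-mask.
    """
    r = np.atleast_2d(np.asarray(r_per_sequence, dtype=float))
    keep = (r >= threshold).all(axis=0)
    if exclude is not None:
        keep = keep.copy()
        keep[np.asarray(exclude, dtype=np.int64)] = False
    return keep
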