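"""Orchestration of full deviance-detection experiments.

An experiment generates and screens an ensemble of networks, calibrates the
unitary EPSP once and the stimulus amplitude per network, then runs every
data set (4 target/non-target pairings per network, each comprising a
deviant, a standard and a shared many-standards control sequence) under the
requested plasticity conditions and stimulus onset asynchronies (SOA), with
sequence seeds shared across conditions so that conditions are compared on
identical stimulus streams. Each network runs 4 physical oddball streams
per condition; each stream serves as the standard sequence of one pairing
and the deviant sequence of the complementary pairing.

The result is one tidy table row per (network, pairing, condition, soa)
with the deviance detection index and the per-data-set response, threshold
and depression contrasts used in the analyses.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .network import GenParams, Network, generate_network, screen_network
from .paradigm import make_dataset_plans, make_sequence
from .simulate import ModelParams, SpikeRecord, calibrate_epsp, calibrate_stimulus, run_sequence
from .metrics import (
    trial_responses,
    mean_theta_at_onset,
    ddi,
    depression_loss,
    latency_rank,
    local_global_split,
)
from .stats import TestResult, wilcoxon_signed_rank_one_sided, variance_and_mean_comparisons

__all__ = [
    "CONDITIONS",
    "ExperimentConfig",
    "build_ensemble",
    "run_experiment",
    "soa_sweep",
    "pair_distance_comparison",
]

logger = logging.getLogger(__name__)

# condition label -> (std_enabled, ta_enabled)
CONDITIONS: dict[str, tuple[bool, bool]] = {
    "none": (False, False),
    "std": (True, False),
    "ta": (False, True),
    "full": (True, True),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration of one experiment.

    Full-scale defaults mirror the study (30 networks, 500 trials, SOA
    500 ms, all four conditions). Scaled-down runs set ``n_networks`` and/or
    ``n_trials`` lower and should carry a ``label`` marking the scale.
    """

    master_seed: int = 0
    n_networks: int = 30
    conditions: tuple[str, ...] = ("none", "std", "ta", "full")
    soa_list: tuple[float, ...] = (500.0,)
    n_trials: int = 500
    gen_params: GenParams = field(default_factory=GenParams)
    model_params: ModelParams = field(default_factory=ModelParams)
    label: str = ""

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")
        if any(s <= 0 for s in self.soa_list):
            raise ValueError("soa_list must be positive")


def build_ensemble(config: ExperimentConfig) -> tuple[list[tuple[Network, float]], ModelParams]:
    """Generate, calibrate and screen networks until the ensemble is full.

    The EPSP scale is fitted once (it is network-independent); the stimulus
    amplitude is calibrated per network with the full model. Candidates
    failing calibration or screening are discarded and regenerated with
    incremented seeds, so the accepted ensemble is reproducible from the
    master seed. Aborts if the acceptance rate falls below 5%.

    Returns ([(network, stim_amplitude), ...], params with fitted
    epsp_scale).
    """
    peak, scale = calibrate_epsp(config.model_params)
    params = replace(config.model_params, epsp_scale=scale)
    logger.info("EPSP calibration: peak %.4f mV at scale %.4f", peak, scale)

    full_params = replace(params, std_enabled=True, ta_enabled=True)
    accepted: list[tuple[Network, float]] = []
    attempts = 0
    max_attempts = max(40, 40 * config.n_networks)
    while len(accepted) < config.n_networks:
        if attempts >= max_attempts or (
            attempts >= 20 and len(accepted) < 0.05 * attempts
        ):
            raise RuntimeError(
                f"network screening failure rate too high: accepted "
                f"{len(accepted)} of {attempts} candidates"
            )
        seed = (config.master_seed * 100003 + attempts) % 2**31
        attempts += 1
        net = generate_network(replace(config.gen_params, seed=seed))
        try:
            amp = calibrate_stimulus(net, full_params)
        except RuntimeError as err:
            logger.info("candidate seed %d rejected at calibration: %s", seed, err)
            continue
        ok, counts = screen_network(net, replace(full_params, stim_amplitude=amp))
        if ok:
            logger.info(
                "accepted network seed %d (amp %.3g nS, responders %s)",
                seed, amp, counts.tolist(),
            )
            accepted.append((net, amp))
        else:
            logger.info("candidate seed %d rejected at screening: %s", seed, counts.tolist())
    return accepted, params


def _pair_distance(net: Network, a: int, b: int) -> float:
    return float(np.hypot(*(net.site_centers[a - 1] - net.site_centers[b - 1])))


def _dataset_row(
    net: Network,
    a: int,
    b: int,
    rec_dev: SpikeRecord,
    rec_con: SpikeRecord,
    rec_std: SpikeRecord,
) -> dict:
    """All per-data-set metrics for one (target a, non-target b) pairing."""
    from .stats import pearson_wald_one_sided

    n_exc = net.n_exc
    exc = slice(0, n_exc)

    r_dev_i = trial_responses(rec_dev, rec_dev.trial_mask(a))
    r_con_i = trial_responses(rec_con, rec_con.trial_mask(a))
    r_std_i = trial_responses(rec_std, rec_std.trial_mask(a))
    r_dev, r_con, r_std = (float(v.mean()) for v in (r_dev_i, r_con_i, r_std_i))

    rn_dev_i = trial_responses(rec_dev, rec_dev.nontarget_mask(a))
    rn_con_i = trial_responses(rec_con, rec_con.nontarget_mask(a))

    ta_dev_i = mean_theta_at_onset(rec_dev, rec_dev.trial_mask(a))
    ta_con_i = mean_theta_at_onset(rec_con, rec_con.trial_mask(a))
    tb_dev_i = mean_theta_at_onset(rec_dev, rec_dev.trial_mask(b))
    tb_con_i = mean_theta_at_onset(rec_con, rec_con.trial_mask(b))

    d_r_a = (r_dev_i - r_con_i)[exc]
    d_r_n = (rn_dev_i - rn_con_i)[exc]
    d_t_a = ta_dev_i - ta_con_i
    d_t_b = tb_dev_i - tb_con_i

    def _rho(x: np.ndarray, y: np.ndarray, alt: str) -> TestResult:
        try:
            return pearson_wald_one_sided(x, y, alternative=alt)
        except ValueError:
            return TestResult(float("nan"), float("nan"), len(x), alt, "pearson_wald")

    rho_rn_ta = _rho(d_r_n, d_t_a, "greater")
    rho_ta_ra = _rho(d_t_a, d_r_a, "less")

    ranks = latency_rank([rec_dev, rec_con, rec_std], site=b)
    early = (ranks < 100)[exc]
    late = ~early

    local = local_global_split(net, a)
    local_exc = local[exc]

    records = {"dev": rec_dev, "con": rec_con, "std": rec_std}
    dep_a = depression_loss(records, net, stimulus_site=a)
    dep_b = depression_loss(records, net, stimulus_site=b)
    d_d_a = dep_a.d["dev"] - dep_a.d["con"]
    d_d_b = dep_b.d["dev"] - dep_b.d["con"]
    rho_da_ra = _rho(d_d_a[exc], d_r_a, "less")

    row = {
        "network_seed": net.seed,
        "target": a,
        "nontarget": b,
        "pair_distance": round(_pair_distance(net, a, b), 3),
        "ddi": ddi(r_dev, r_con),
        "r_dev": r_dev,
        "r_con": r_con,
        "r_std": r_std,
        "dR_A_med": float(np.median(d_r_a)),
        "dR_N_med": float(np.median(d_r_n)),
        "dT_A_med": float(np.median(d_t_a)),
        "dT_B_med": float(np.median(d_t_b)),
        "rho_dRN_dTA": rho_rn_ta.statistic,
        "p_rho_dRN_dTA": rho_rn_ta.p_value,
        "rho_dTA_dRA": rho_ta_ra.statistic,
        "p_rho_dTA_dRA": rho_ta_ra.p_value,
        "dR_N_early_med": float(np.median(d_r_n[early])),
        "dR_N_late_med": float(np.median(d_r_n[late])),
        "dT_B_early_med": float(np.median(d_t_b[early])),
        "dT_B_late_med": float(np.median(d_t_b[late])),
        "dD_A_med": float(np.median(d_d_a)),
        "dD_B_early_med": float(np.median(d_d_b[exc][early])),
        "dD_B_late_med": float(np.median(d_d_b[exc][late])),
        "rho_dDA_dRA": rho_da_ra.statistic,
        "n_local": int(local.sum()),
    }
    for seq, rec in records.items():
        t_a_i = mean_theta_at_onset(rec, rec.trial_mask(a))
        row[f"tA_local_{seq}"] = float(t_a_i[local_exc].mean())
        row[f"tA_global_{seq}"] = float(t_a_i[~local_exc].mean())
        row[f"dA_local_{seq}"] = float(dep_a.d[seq][local].mean())
        row[f"dA_global_{seq}"] = float(dep_a.d[seq][~local].mean())
    return row


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full experiment and return the tidy per-data-set table.

    Rows: one per (network, pairing, condition, soa); row count is
    4 * n_networks * len(conditions) * len(soa_list). Stimulus sequences
    are seeded per data set and shared across conditions and SOAs.
    Deterministic given the configuration.
    """
    ensemble, params = build_ensemble(config)
    plans = make_dataset_plans(config.n_networks, config.master_seed)
    rows = []
    for soa in config.soa_list:
        for cond in config.conditions:
            std_on, ta_on = CONDITIONS[cond]
            for net_id, (net, amp) in enumerate(ensemble):
                cparams = replace(
                    params, std_enabled=std_on, ta_enabled=ta_on, stim_amplitude=amp
                )
                net_plans = [p for p in plans if p.network_id == net_id]
                t0 = time.perf_counter()
                con_seq = make_sequence(
                    "A-in-con", target=1, n_trials=config.n_trials, soa=soa,
                    seed=net_plans[0].seq_seeds["A-in-con"],
                )
                runs: dict = {"con": run_sequence(net, con_seq, cparams)}
                for plan in net_plans:
                    a, b = plan.pairing
                    seq = make_sequence(
                        "A-as-std", a, b, n_trials=config.n_trials, soa=soa,
                        seed=plan.seq_seeds["A-as-std"],
                    )
                    runs[(a, b)] = run_sequence(net, seq, cparams)
                n_spikes = sum(len(r.spike_times) for r in runs.values())
                logger.info(
                    "net %d cond %s soa %g: %d runs, %d spikes, %.1f s",
                    net_id, cond, soa, len(runs), n_spikes, time.perf_counter() - t0,
                )
                for plan in net_plans:
                    a, b = plan.pairing
                    row = _dataset_row(
                        net, a, b,
                        rec_dev=runs[(b, a)], rec_con=runs["con"], rec_std=runs[(a, b)],
                    )
                    row.update(
                        network_id=net_id, condition=cond, soa=soa, label=config.label
                    )
                    rows.append(row)
    df = pd.DataFrame(rows)
    front = ["network_id", "network_seed", "target", "nontarget", "condition", "soa"]
    return df[front + [c for c in df.columns if c not in front]]


def soa_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """DDI versus SOA per condition, with significance tests.

    For each (condition, soa): mean, SEM and median DDI across data sets
    plus a one-sided Wilcoxon test of DDI > 0. Where the single-mechanism
    conditions and the full model are all present, each SOA also gets the
    synergy test of full - (ta + std) > 0 on paired data sets.
    """
    if len(config.soa_list) < 2:
        raise ValueError("an SOA sweep needs at least 2 SOA values")
    results = run_experiment(config)
    return summarize_soa_sweep(results)


def summarize_soa_sweep(results: pd.DataFrame) -> pd.DataFrame:
    keys = ["network_id", "target", "nontarget"]
    rows = []
    for (cond, soa), grp in results.groupby(["condition", "soa"]):
        vals = grp["ddi"].to_numpy()
        try:
            test = wilcoxon_signed_rank_one_sided(vals, alternative="greater")
            p_pos = test.p_value
        except ValueError:  # all-zero DDIs (no-plasticity condition)
            p_pos = float("nan")
        rows.append({
            "condition": cond,
            "soa": soa,
            "n": len(vals),
            "ddi_mean": float(vals.mean()),
            "ddi_sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"),
            "ddi_median": float(np.median(vals)),
            "p_positive": p_pos,
        })
    summary = pd.DataFrame(rows)

    have = set(results["condition"].unique())
    if {"full", "ta", "std"} <= have:
        pivot = results.pivot_table(
            index=keys + ["soa"], columns="condition", values="ddi"
        ).reset_index()
        for soa, grp in pivot.groupby("soa"):
            diff = (grp["full"] - (grp["ta"] + grp["std"])).to_numpy()
            try:
                p_syn = wilcoxon_signed_rank_one_sided(diff, alternative="greater").p_value
            except ValueError:
                p_syn = float("nan")
            summary.loc[
                (summary["condition"] == "full") & (summary["soa"] == soa),
                "p_synergy",
            ] = p_syn
    return summary


def pair_distance_comparison(results: pd.DataFrame) -> dict[str, TestResult]:
    """Compare DDI between nearby and distant stimulus-site pairings.

    Splits the rows at the median pair distance (nearby pairs share a
    shorter inter-site distance than distant pairs) and returns the
    independent-samples t-test on the mean DDI and the Brown-Forsythe test
    on its variance. Pass a single-condition, single-SOA slice.
    """
    dists = np.sort(results["pair_distance"].unique())
    if len(dists) < 2:
        raise ValueError("need both nearby and distant pairings")
    cut = dists.mean()
    near = results.loc[results["pair_distance"] < cut, "ddi"].to_numpy()
    far = results.loc[results["pair_distance"] >= cut, "ddi"].to_numpy()
    return variance_and_mean_comparisons(near, far)
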