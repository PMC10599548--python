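"""Oddball and many-standards stimulus sequences.

Three sequence types probe deviance detection around a target stimulus A
and a non-target B (sites are 1-based ids into the network's stimulation
sites):

- ``A-as-std``: 80% A, 20% B — A is the expected standard.
- ``A-as-dev``: 20% A, 80% B — A is the rare deviant interrupting B.
- ``A-in-con``: all sites equally rare (many-standards control) — A is as
  rare as in ``A-as-dev`` but no expectation of any stimulus forms.

All sequences are uniform random shuffles of an exactly fixed composition,
presented at regular onsets k*SOA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

SEQ_TYPES = ("A-as-std", "A-as-dev", "A-in-con")


@dataclass(frozen=True)
class StimulusSequence:
    """An ordered stimulus stream of (onset ms, site id) events."""

    onsets: tuple[float, ...]
    sites: tuple[int, ...]
    seq_type: str
    target_site: int
    nontarget_site: int | None
    soa: float  # ms
    seed: int

    @property
    def events(self) -> list[tuple[float, int]]:
        return list(zip(self.onsets, self.sites))

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def duration(self) -> float:
        """Total simulated span (ms): one SOA-long window per trial."""
        return self.n_trials * self.soa

    def trial_mask(self, trial_type: str) -> np.ndarray:
        """Boolean mask over trials for a trial-type label.

        ``"A"`` selects target-site trials, ``"B"`` non-target-site trials,
        and ``"N"`` all non-target trials (B in oddball sequences; B through
        E in the many-standards control). An integer site id selects that
        site's trials.
        """
        sites = np.asarray(self.sites)
        if trial_type == "A":
            return sites == self.target_site
        if trial_type == "B":
            if self.nontarget_site is None:
                raise ValueError("sequence has no designated non-target site")
            return sites == self.nontarget_site
        if trial_type == "N":
            return sites != self.target_site
        if isinstance(trial_type, (int, np.integer)):
            return sites == int(trial_type)
        raise ValueError(f"unknown trial type: {trial_type!r}")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "StimulusSequence":
        doc = json.loads(text)
        doc["onsets"] = tuple(doc["onsets"])
        doc["sites"] = tuple(doc["sites"])
        return cls(**doc)

    @classmethod
    def load(cls, path: str | Path) -> "StimulusSequence":
        return cls.from_json(Path(path).read_text())


def make_sequence(
    seq_type: str,
    target: int,
    nontarget: int | None = None,
    n_trials: int = 500,
    soa: float = 500.0,
    seed: int = 0,
    all_sites: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> StimulusSequence:
    """Build a randomized stimulus sequence of exact composition.

    ``A-as-std`` uses 80% target / 20% non-target trials, ``A-as-dev`` the
    reverse, and ``A-in-con`` an equal share for every site in ``all_sites``.
    The order is a uniform shuffle driven by ``seed``; onsets are k*soa.
    """
    if seq_type not in SEQ_TYPES:
        raise ValueError(f"seq_type must be one of {SEQ_TYPES}")
    if seq_type != "A-in-con":
        if nontarget is None:
            raise ValueError("oddball sequences need a non-target site")
        if nontarget == target:
            raise ValueError("target and non-target sites must differ")

    if n_trials == 0:
        sites: list[int] = []
    elif seq_type == "A-in-con":
        if target not in all_sites:
            raise ValueError("target must be among all_sites")
        n_each, rem = divmod(n_trials, len(all_sites))
        if rem:
            raise ValueError(f"n_trials={n_trials} not divisible among {len(all_sites)} sites")
        sites = [s for s in all_sites for _ in range(n_each)]
    else:
        n_major, rem = divmod(4 * n_trials, 5)
        if rem:
            raise ValueError(f"n_trials={n_trials} does not admit an exact 80/20 split")
        n_minor = n_trials - n_major
        # Majority site first, so that the deviant sequence of pairing (a, b)
        # and the standard sequence of pairing (b, a) are the same physical
        # stimulus stream when they share a seed.
        if seq_type == "A-as-std":
            sites = [target] * n_major + [nontarget] * n_minor
        else:  # A-as-dev
            sites = [nontarget] * n_major + [target] * n_minor

    order = np.random.default_rng(seed).permutation(len(sites))
    shuffled = tuple(int(sites[i]) for i in order)
    onsets = tuple(float(k * soa) for k in range(len(sites)))
    return StimulusSequence(
        onsets=onsets,
        sites=shuffled,
        seq_type=seq_type,
        target_site=target,
        nontarget_site=nontarget,
        soa=soa,
        seed=seed,
    )


# Target/non-target site pairings used for the oddball data sets. Each
# ordered pair (A, B) yields one data set; the four pairings cover both
# oddball roles for every site involved.
PAIRINGS: tuple[tuple[int, int], ...] = ((1, 2), (2, 1), (3, 5), (5, 3))


@dataclass
class DatasetPlan:
    """One data set: a network, a target/non-target pairing, and seeds.

    ``seq_seeds`` maps each sequence type to the seed of its random shuffle.
    The many-standards control is shared among the four plans of a network,
    so its seed is identical across them.
    """

    network_id: int
    pairing: tuple[int, int]
    seq_seeds: dict[str, int]

    @property
    def target(self) -> int:
        return self.pairing[0]

    @property
    def nontarget(self) -> int:
        return self.pairing[1]


def make_dataset_plans(n_networks: int, master_seed: int = 0) -> list[DatasetPlan]:
    """Enumerate the data sets of an experiment: 4 pairings per network.

    Each network runs 4 physical oddball streams (one per pairing, with the
    pairing's first site as the 80% majority) plus one shared many-standards
    control. A plan's standard sequence is its own pairing's stream and its
    deviant sequence is the complementary pairing's stream, so every stream
    is reused in two data sets, exactly as in the study design.
    Deterministic given ``master_seed``.
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    rng = np.random.default_rng(master_seed)
    plans = []
    for net in range(n_networks):
        con_seed = int(rng.integers(2**31))
        run_seeds = {pairing: int(rng.integers(2**31)) for pairing in PAIRINGS}
        for a, b in PAIRINGS:
            plans.append(
                DatasetPlan(
                    network_id=net,
                    pairing=(a, b),
                    seq_seeds={
                        "A-as-std": run_seeds[(a, b)],
                        "A-as-dev": run_seeds[(b, a)],
                        "A-in-con": con_seed,
                    },
                )
            )
    return plans
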