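"""Generation and screening of spatial random spiking networks.

Networks consist of excitatory and inhibitory point neurons placed uniformly
at random in a circular "dish". Each neuron makes fixed-weight synapses onto
a fixed number of randomly chosen partners within a type-specific axonal
range (longer for excitatory, shorter for inhibitory neurons). Stimulation
sites sit on a concentric circle inside the dish; each site drives the
handful of neurons closest to its center.

Generated networks are screened for minimum responsiveness before use: a
network is accepted only if single-pulse stimulation at every site, starting
from the fully recovered state, recruits at least ``min_responders`` neurons.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import ModelParams

_GENERATOR_VERSION = 1


@dataclass(frozen=True)
class GenParams:
    """Structural parameters of the network generator.

    Defaults reproduce the study conditions: 800 excitatory and 200
    inhibitory neurons in a 4 mm-radius dish, out-degree 50 within 2 mm
    (excitatory) or 1 mm (inhibitory), five stimulation sites regularly
    spaced on a 2.5 mm circle, each driving its 10 nearest neurons.
    """

    n_exc: int = 800
    n_inh: int = 200
    dish_radius: float = 4.0  # mm
    out_degree: int = 50
    exc_range: float = 2.0  # mm
    inh_range: float = 1.0  # mm
    n_sites: int = 5
    site_radius: float = 2.5  # mm
    n_stimulated: int = 10
    min_responders: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exc + self.n_inh, self.n_sites, self.n_stimulated) <= 0:
            raise ValueError("counts must be positive")
        if self.exc_range > 2 * self.dish_radius or self.inh_range > 2 * self.dish_radius:
            raise ValueError("connection ranges cannot exceed the dish diameter")
        if self.n_stimulated > self.n_exc + self.n_inh:
            raise ValueError("cannot stimulate more neurons than exist")


@dataclass
class Network:
    """A generated network: geometry, connectivity and stimulation sets.

    Attributes
    ----------
    positions : (n, 2) float array, mm
    is_excitatory : (n,) bool array
    synapses : (m, 2) int array of (pre, post) pairs; all weights equal ``w``
    site_centers : (n_sites, 2) float array, mm
    stimulated_sets : (n_sites, n_stimulated) int array; per site, the
        indices of the nearest neurons, closest first.
    """

    positions: np.ndarray
    is_excitatory: np.ndarray
    synapses: np.ndarray
    site_centers: np.ndarray
    stimulated_sets: np.ndarray
    seed: int
    gen_params: GenParams = field(default_factory=GenParams)

    @property
    def n_neurons(self) -> int:
        return len(self.positions)

    @property
    def n_exc(self) -> int:
        return int(self.is_excitatory.sum())

    def site_distances(self, site: int) -> np.ndarray:
        """Euclidean distance (mm) of every neuron to a site center (1-based id)."""
        center = self.site_centers[site - 1]
        return np.hypot(*(self.positions - center).T)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "generator_version": _GENERATOR_VERSION,
            "seed": self.seed,
            "gen_params": asdict(self.gen_params),
            "positions": self.positions.tolist(),
            "is_excitatory": self.is_excitatory.astype(int).tolist(),
            "synapses": self.synapses.tolist(),
            "site_centers": self.site_centers.tolist(),
            "stimulated_sets": self.stimulated_sets.tolist(),
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        return cls.from_json(Path(path).read_text())

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        return cls(
            positions=np.asarray(doc["positions"], dtype=float),
            is_excitatory=np.asarray(doc["is_excitatory"], dtype=bool),
            synapses=np.asarray(doc["synapses"], dtype=np.int64).reshape(-1, 2),
            site_centers=np.asarray(doc["site_centers"], dtype=float),
            stimulated_sets=np.asarray(doc["stimulated_sets"], dtype=np.int64),
            seed=int(doc["seed"]),
            gen_params=GenParams(**doc["gen_params"]),
        )


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    # uniform by area: radius sampled as R * sqrt(u)
    r = radius * np.sqrt(rng.random(n))
    phi = rng.random(n) * 2 * np.pi
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def generate_network(gen_params: GenParams) -> Network:
    """Generate a spatial random network.

    Placement is uniform over the disk area. Each neuron connects to
    ``out_degree`` partners sampled uniformly without replacement among the
    neurons within its type's range (all of them if fewer are in range); no
    self-connections, at most one synapse per ordered pair. Deterministic
    given ``gen_params.seed``.
    """
    p = gen_params
    rng = np.random.default_rng(p.seed)
    n = p.n_exc + p.n_inh
    positions = _uniform_disk(rng, n, p.dish_radius)
    is_exc = np.zeros(n, dtype=bool)
    is_exc[: p.n_exc] = True

    pre_list: list[np.ndarray] = []
    post_list: list[np.ndarray] = []
    for i in range(n):
        reach = p.exc_range if is_exc[i] else p.inh_range
        d = np.hypot(*(positions - positions[i]).T)
        candidates = np.flatnonzero((d <= reach))
        candidates = candidates[candidates != i]
        if len(candidates) == 0:
            continue
        k = min(p.out_degree, len(candidates))
        chosen = rng.choice(candidates, size=k, replace=False)
        pre_list.append(np.full(k, i, dtype=np.int64))
        post_list.append(np.asarray(chosen, dtype=np.int64))
    if pre_list:
        synapses = np.column_stack([np.concatenate(pre_list), np.concatenate(post_list)])
    else:
        synapses = np.empty((0, 2), dtype=np.int64)

    angles = np.arange(p.n_sites) * (2 * np.pi / p.n_sites)  # site 1 at angle 0
    site_centers = p.site_radius * np.column_stack([np.cos(angles), np.sin(angles)])

    stim_sets = np.empty((p.n_sites, p.n_stimulated), dtype=np.int64)
    for s in range(p.n_sites):
        d = np.hypot(*(positions - site_centers[s]).T)
        # stable sort breaks distance ties by neuron index
        stim_sets[s] = np.argsort(d, kind="stable")[: p.n_stimulated]

    return Network(
        positions=positions,
        is_excitatory=is_exc,
        synapses=synapses,
        site_centers=site_centers,
        stimulated_sets=stim_sets,
        seed=p.seed,
        gen_params=p,
    )


def screen_network(network: Network, sim_params: "ModelParams") -> tuple[bool, np.ndarray]:
    """Screen a network for minimum stimulus responsiveness.

    Stimulates each site once from the fully recovered state and counts the
    neurons that fire at least one spike within the trial window (one SOA).
    The network is accepted iff every site recruits at least
    ``min_responders`` neurons. Requires a calibrated ``stim_amplitude``.

    Returns
    -------
    (accepted, counts) where ``counts`` has one responder count per site.
    """
    from .simulate import single_trial_counts

    n_sites = len(network.site_centers)
    counts = np.empty(n_sites, dtype=np.int64)
    for site in range(1, n_sites + 1):
        spike_counts = single_trial_counts(network, site, sim_params)
        counts[site - 1] = int((spike_counts > 0).sum())
    accepted = bool((counts >= network.gen_params.min_responders).all())
    return accepted, counts


def synaptic_hop_distance(network: Network, site: int) -> np.ndarray:
    """Minimum number of excitatory synapses from a site's stimulated set.

    Breadth-first search over excitatory synapses only, seeded at the
    stimulated neurons of ``site`` (1-based). Returns an int array with hop
    counts; unreachable neurons are marked with -1.
    """
    n = network.n_neurons
    hops = np.full(n, -1, dtype=np.int64)
    adj: list[list[int]] = [[] for _ in range(n)]
    for pre, post in network.synapses:
        if network.is_excitatory[pre]:
            adj[pre].append(int(post))
    queue: deque[int] = deque()
    for i in network.stimulated_sets[site - 1]:
        hops[i] = 0
        queue.append(int(i))
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if hops[v] < 0:
                hops[v] = hops[u] + 1
                queue.append(v)
    return hops


def lens_area_fraction(
    dish_radius: float = 4.0, site_offset: float = 2.5, cutoff: float = 2.0
) -> float:
    """Analytic expected fraction of uniformly placed neurons within ``cutoff``
    of a point ``site_offset`` from the dish center (circle-circle
    intersection area divided by dish area)."""
    R, r, d = dish_radius, cutoff, site_offset
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        return min(r, R) ** 2 / R**2
    a1 = r**2 * np.arccos((d**2 + r**2 - R**2) / (2 * d * r))
    a2 = R**2 * np.arccos((d**2 + R**2 - r**2) / (2 * d * R))
    a3 = 0.5 * np.sqrt((-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R))
    return float((a1 + a2 - a3) / (np.pi * R**2))
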