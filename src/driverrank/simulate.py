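"""Synthetic networks and tumor cohorts with planted driver structure.

The generator emulates the statistical structure the ranking model
assumes: a driver alteration perturbs the expression of its downstream
genes in the interaction network, while passenger alterations inject
no expression signal.  Networks have heavy-tailed out-degree (a
configurable fraction of hub genes with elevated out-degree), drivers
are sampled preferentially from hubs, and the expression signal decays
geometrically with network depth (breadth-first, truncated at depth 3
by default).  Everything is deterministic given a seed, and cohorts
can be written in the same TSV formats the pipeline reads.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .condorcet import AlterationCatalog
from .network import GeneNetwork, write_edge_list

__all__ = ["generate_network", "generate_cohort", "SyntheticCohort"]

_HUB_BOOST = 6.0  # out-degree rate multiplier for hub genes


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_network(
    n_genes: int,
    mean_out_degree: float = 8.0,
    hub_fraction: float = 0.1,
    self_loop_prob: float = 0.02,
    feedback_fraction: float = 0.05,
    in_weight_sigma: float = 2.0,
    seed=None,
) -> GeneNetwork:
    """Random directed network emulating curated signaling networks.

    Three structural features of real gene-interaction networks are
    reproduced:

    * heavy-tailed out-degree — a ``hub_fraction`` of genes emit edges
      at a rate boosted by a constant factor, with the base rate set so
      the overall mean out-degree matches ``mean_out_degree``;
    * heavy-tailed in-degree — targets are drawn with lognormal
      propensity weights (``in_weight_sigma``), so most genes have few
      incoming edges, a sizable fraction none at all (dangling genes),
      and a few are heavily regulated;
    * hierarchy — each gene gets a hierarchy position and all but a
      ``feedback_fraction`` of its edges point strictly downward, so
      the network is predominantly feed-forward with sparse feedback
      loops, as in curated pathway collections.

    Feedback edges and self-loops (added with ``self_loop_prob``)
    attach only to genes that already have a feed-forward regulator, so
    no gene's sole regulation is a feedback loop; isolated feedback
    islands would otherwise trap the propagation recursion in modes
    curated networks do not exhibit.  There are no duplicate edges.
    Deterministic given ``seed``.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    for name, value in (
        ("hub_fraction", hub_fraction),
        ("self_loop_prob", self_loop_prob),
        ("feedback_fraction", feedback_fraction),
    ):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    if mean_out_degree <= 0 or mean_out_degree >= n_genes:
        raise ValueError(
            f"mean_out_degree must be in (0, n_genes); got {mean_out_degree} "
            f"with n_genes={n_genes}"
        )
    rng = _rng(seed)
    width = len(str(n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(n_genes)]

    n_hubs = int(round(hub_fraction * n_genes))
    is_hub = np.zeros(n_genes, dtype=bool)
    if n_hubs:
        is_hub[rng.choice(n_genes, size=n_hubs, replace=False)] = True
    base_rate = mean_out_degree / (1 - hub_fraction + hub_fraction * _HUB_BOOST)
    rates = np.where(is_hub, _HUB_BOOST * base_rate, base_rate)

    level = rng.random(n_genes)  # hierarchy position, 0 = most upstream
    in_weight = rng.lognormal(0.0, in_weight_sigma, n_genes)
    idx = np.arange(n_genes)

    # pass 1: downward (feed-forward) edges
    edges: set[tuple[int, int]] = set()
    fb_quota = np.zeros(n_genes, dtype=int)
    for i in range(n_genes):
        k = int(min(rng.poisson(rates[i]), n_genes - 1))
        k_fb = rng.binomial(k, feedback_fraction) if k else 0
        downstream = idx[(level > level[i]) & (idx != i)]
        k_down = min(k - k_fb, downstream.size)
        k_fb += (k - k_fb) - k_down  # overflow near the bottom becomes feedback
        fb_quota[i] = k_fb
        if k_down:
            p = in_weight[downstream] / in_weight[downstream].sum()
            for j in rng.choice(downstream, size=k_down, replace=False, p=p):
                edges.add((i, int(j)))

    # pass 2: feedback edges and self-loops attach only to genes that
    # already have a feed-forward regulator, as in curated pathways where
    # feedback acts on pathway-internal components; this guarantees no
    # gene's sole regulation is a feedback loop
    regulated = np.zeros(n_genes, dtype=bool)
    for _, b in edges:
        regulated[b] = True
    for i in range(n_genes):
        k_fb = fb_quota[i]
        if k_fb:
            pool = idx[regulated & (idx != i)]
            if pool.size:
                p = in_weight[pool] / in_weight[pool].sum()
                for j in rng.choice(pool, size=min(k_fb, pool.size), replace=False, p=p):
                    edges.add((i, int(j)))
        if regulated[i] and rng.random() < self_loop_prob:
            edges.add((i, i))
    return GeneNetwork.from_edges(
        [(genes[a], genes[b]) for a, b in sorted(edges)], genes=genes
    )


@dataclass
class SyntheticCohort:
    """A generated network plus tumor cohort with known ground truth."""

    network: GeneNetwork
    normal: pd.Series  # log-scale baseline expression, one value per gene
    tumor: pd.DataFrame  # genes x patients, log-scale
    catalog: AlterationCatalog
    drivers: dict[str, set[str]]  # planted drivers per patient
    passengers: dict[str, set[str]]  # planted passengers per patient
    params: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(self.tumor.columns)

    def driver_union(self) -> set[str]:
        return set().union(*self.drivers.values()) if self.drivers else set()

    def passenger_union(self) -> set[str]:
        return set().union(*self.passengers.values()) if self.passengers else set()

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for patient in self.patients:
            for gene in sorted(self.drivers[patient]):
                rows.append((patient, gene, "driver"))
            for gene in sorted(self.passengers[patient]):
                rows.append((patient, gene, "passenger"))
        return pd.DataFrame(rows, columns=["patient", "gene", "role"])

    def write(self, out_dir) -> None:
        """Write the cohort in the TSV formats the pipeline reads."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_edge_list(self.network, out / "edges.tsv")
        self.normal.rename("normal").rename_axis("gene").to_csv(
            out / "normal.tsv", sep="\t"
        )
        self.tumor.rename_axis("gene").to_csv(out / "tumor.tsv", sep="\t")
        self.catalog.table.to_csv(out / "alterations.tsv", sep="\t", index=False)
        self.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)


def _downstream_effect(
    network: GeneNetwork,
    start: int,
    signal: float,
    decay: float,
    max_depth: int,
) -> np.ndarray:
    """Signal * decay^depth over the breadth-first downstream cone."""
    effect = np.zeros(network.n_genes)
    indptr, indices = network.adjacency.indptr, network.adjacency.indices
    depth = {start: 0}
    queue = deque([start])
    effect[start] = signal
    while queue:
        node = queue.popleft()
        d = depth[node]
        if d >= max_depth:
            continue
        for nxt in indices[indptr[node]: indptr[node + 1]]:
            if nxt not in depth:
                depth[nxt] = d + 1
                effect[nxt] = signal * decay ** (d + 1)
                queue.append(nxt)
    return effect


def generate_cohort(
    network: GeneNetwork,
    n_patients: int = 50,
    drivers_per_patient: int = 2,
    passengers_per_patient: int = 8,
    signal: float = 5.0,
    decay: float = 0.5,
    noise_sd: float = 1.0,
    max_depth: int = 3,
    seed=None,
) -> SyntheticCohort:
    """Simulate a patient cohort with planted drivers and passengers.

    Per patient, ``drivers_per_patient`` genes are drawn with
    probability proportional to ``1 + out_degree`` (drivers tend to be
    hubs) and perturb their downstream cone: the tumor expression of a
    gene at breadth-first depth ``k <= max_depth`` from a driver is
    shifted by ``sign * signal * decay**k`` (one random sign per driver
    event).  Passengers are drawn uniformly from the remaining genes
    and leave expression untouched.  Gaussian noise with sd
    ``noise_sd`` is added to every tumor value.  The normal reference
    is a log-scale baseline drawn once per cohort from Normal(8, 2),
    floored at 0.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if signal < 0 or noise_sd < 0:
        raise ValueError("signal and noise_sd must be nonnegative")
    if not 0 < decay < 1:
        raise ValueError("decay must be in (0, 1)")
    n = network.n_genes
    if drivers_per_patient + passengers_per_patient > n:
        raise ValueError("drivers + passengers per patient exceed the gene pool")
    rng = _rng(seed)

    normal = pd.Series(
        np.clip(rng.normal(8.0, 2.0, size=n), 0.0, None),
        index=pd.Index(network.genes, name="gene"),
        name="normal",
    )
    weights = 1.0 + network.out_degree.astype(float)
    weights /= weights.sum()

    pat_width = len(str(n_patients - 1)) if n_patients > 1 else 1
    patients = [f"P{i:0{pat_width}d}" for i in range(n_patients)]
    tumor = {}
    drivers: dict[str, set[str]] = {}
    passengers: dict[str, set[str]] = {}
    alt_rows = []
    for patient in patients:
        d_idx = rng.choice(n, size=drivers_per_patient, replace=False, p=weights)
        remaining = np.setdiff1d(np.arange(n), d_idx)
        p_idx = rng.choice(remaining, size=passengers_per_patient, replace=False)
        effect = np.zeros(n)
        for i in d_idx:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            effect += sign * _downstream_effect(network, int(i), signal, decay, max_depth)
        noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
        tumor[patient] = normal.to_numpy() + effect + noise
        drivers[patient] = {network.genes[int(i)] for i in d_idx}
        passengers[patient] = {network.genes[int(i)] for i in p_idx}
        for g in sorted(drivers[patient]):
            alt_rows.append((patient, g, "point_mutation"))
        for g in sorted(passengers[patient]):
            alt_rows.append(
                (patient, g, "point_mutation" if rng.random() < 0.8 else "indel")
            )

    tumor_df = pd.DataFrame(tumor, index=normal.index)
    catalog = AlterationCatalog(
        pd.DataFrame(alt_rows, columns=["patient", "gene", "category"]), patients
    )
    params = {
        "n_genes": n,
        "n_patients": n_patients,
        "drivers_per_patient": drivers_per_patient,
        "passengers_per_patient": passengers_per_patient,
        "signal": signal,
        "decay": decay,
        "noise_sd": noise_sd,
        "max_depth": max_depth,
        "seed": None if isinstance(seed, np.random.Generator) else seed,
    }
    return SyntheticCohort(
        network=network,
        normal=normal,
        tumor=tumor_df,
        catalog=catalog,
        drivers=drivers,
        passengers=passengers,
        params=params,
    )
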